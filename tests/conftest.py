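import pytest

from bbdesign.patterns import BBClass
from bbdesign.synthetic_data import default_spec, generate_catalog, generate_paired_catalogs


@pytest.fixture(scope="session")
def small_amine_catalog():
    """120 synthetic primary amines, enough to have cluster structure."""
    return generate_catalog(default_spec(BBClass.PRIMARY_AMINE, 120, seed=11))


@pytest.fixture(scope="session")
def small_acid_catalog():
    return generate_catalog(default_spec(BBClass.CARBOXYLIC_ACID, 100, seed=12))


@pytest.fixture(scope="session")
def small_fmoc_catalog():
    return generate_catalog(default_spec(BBClass.FMOC_AA, 60, seed=13))


@pytest.fixture(scope="session")
def paired_catalogs():
    return generate_paired_catalogs(7, n_fmoc=40, n_amine=140, n_acid=90,
                                    overlap_fraction=0.5)


@pytest.fixture(scope="session")
def big_catalogs():
    """n=2000 catalogs for parameter-recovery checks (session-cached)."""
    return {
        cls: generate_catalog(default_spec(cls, 2000, seed=1))
        for cls in BBClass
    }
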