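"""Truncation transforms and the class / cost / property filters."""

import pytest
from rdkit import Chem

from bbdesign.catalog import BBClass, BuildingBlock, Catalog, compute_pcp
from bbdesign.errors import TruncationError
from bbdesign.truncate import (
    class_filter,
    cost_filter,
    pcp_filter,
    remove_fmoc,
    truncate_bb,
    truncate_catalog,
    truncate_mol,
    unique_truncates,
)

FMOC_ALANINE = "CC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O"


def _bb(smiles, cls, bb_id="X", cost=None):
    return BuildingBlock(bb_id, Chem.CanonSmiles(smiles), cls, cost=cost)


@pytest.mark.parametrize(
    "smiles, cls, expected",
    [
        ("CCN", BBClass.PRIMARY_AMINE, "CC"),  # ethylamine -> ethane
        ("OC(=O)c1ccccc1", BBClass.CARBOXYLIC_ACID, "c1ccccc1"),  # benzoic -> benzene
        (FMOC_ALANINE, BBClass.FMOC_AA, "CC"),  # Fmoc-Ala -> ethane
        ("NCc1ccc(C)cc1", BBClass.PRIMARY_AMINE, "Cc1ccc(C)cc1"),
    ],
)
def test_truncate_examples(smiles, cls, expected):
    trunc = truncate_bb(_bb(smiles, cls))
    assert trunc.smiles == Chem.CanonSmiles(expected)
    assert not trunc.polyfunctional


def test_truncate_strictly_reduces_and_is_idempotent(small_amine_catalog,
                                                     small_acid_catalog,
                                                     small_fmoc_catalog):
    for cat in (small_amine_catalog, small_acid_catalog, small_fmoc_catalog):
        truncs, report = truncate_catalog(cat)
        assert not report.rejected
        for bb, trunc in zip(cat, truncs):
            parent = bb.mol()
            child = Chem.MolFromSmiles(trunc.smiles)
            assert child.GetNumHeavyAtoms() < parent.GetNumHeavyAtoms()
            assert compute_pcp(trunc.smiles).mw < bb.pcp.mw
            # idempotence: no defining group left, re-truncation is a no-op
            again, n = truncate_mol(child, bb.bb_class)
            assert n == 0
            assert Chem.MolToSmiles(again) == trunc.smiles


def test_polyfunctional_flag_and_multi_replacement():
    trunc = truncate_bb(_bb("NCCCCN", BBClass.PRIMARY_AMINE, "diamine"))
    assert trunc.polyfunctional
    assert trunc.n_sites == 2
    assert trunc.smiles == Chem.CanonSmiles("CCCC")


def test_truncation_error_carries_parent_id():
    # glycine-like acid: truncating COOH from acetic acid leaves methane (ok),
    # but formic acid truncates to nothing
    with pytest.raises(TruncationError, match="FORMIC"):
        truncate_bb(_bb("OC=O", BBClass.CARBOXYLIC_ACID, "FORMIC"))


def test_remove_fmoc_restores_free_amine():
    assert remove_fmoc(FMOC_ALANINE) == Chem.CanonSmiles("CC(N)C(=O)O")


@pytest.mark.parametrize(
    "smiles, reason",
    [
        ("CCCCNC", "secondary_amine"),  # N-methylbutylamine
        ("Nc1ccccc1", "aniline_nitrogen"),  # aniline
        ("OC(=O)C1CCCN1", "secondary_amino_acid"),  # proline
    ],
)
def test_class_filter_rejections(smiles, reason):
    cat = Catalog(BBClass.PRIMARY_AMINE, [_bb(smiles, BBClass.PRIMARY_AMINE)])
    kept, report = class_filter(cat)
    assert len(kept) == 0
    assert report.rejected == [("X", reason)]


def test_class_filter_retains_primary_aliphatic_amine():
    cat = Catalog(
        BBClass.PRIMARY_AMINE,
        [_bb("NC1CCCCC1", BBClass.PRIMARY_AMINE, "cyclohexylamine")],
    )
    kept, report = class_filter(cat)
    assert kept.ids() == ["cyclohexylamine"]
    assert not report.rejected


def _cost_catalog():
    return Catalog(
        BBClass.PRIMARY_AMINE,
        [
            _bb("CCN", BBClass.PRIMARY_AMINE, "a", cost=80.0),
            _bb("CCCN", BBClass.PRIMARY_AMINE, "b", cost=250.0),
            _bb("CCCCN", BBClass.PRIMARY_AMINE, "c", cost=400.0),
            _bb("CCCCCN", BBClass.PRIMARY_AMINE, "d", cost=None),
        ],
    )


def test_cost_filter_inclusive_boundary_and_missing():
    kept, report = cost_filter(_cost_catalog(), 250.0)
    assert kept.ids() == ["a", "b"]  # <= is inclusive
    assert ("d", "cost_missing") in report.rejected
    assert report.n_out + len(report.rejected) == report.n_in


def test_cost_filter_monotone_nesting():
    cat = _cost_catalog()
    tiers = [set(cost_filter(cat, t)[0].ids()) for t in (100.0, 250.0, 500.0)]
    assert tiers[0] <= tiers[1] <= tiers[2]


def test_cost_and_class_filters_commute(small_amine_catalog):
    a = cost_filter(class_filter(small_amine_catalog)[0], 250.0)[0]
    b = class_filter(cost_filter(small_amine_catalog, 250.0)[0])[0]
    assert a.ids() == b.ids()


def test_ro3_mw_bound_is_strict():
    # MW exactly 300 must fail RO3's strict "< 300"
    bb = _bb("CCN", BBClass.PRIMARY_AMINE, "fake")
    from dataclasses import replace
    from bbdesign.catalog import PCPSet

    bb = replace(bb, pcp=PCPSet(mw=300.0, clogp=1.0, tpsa=20.0, hbd=1, hba=1))
    kept, report = pcp_filter(Catalog(BBClass.PRIMARY_AMINE, [bb]), "RO3")
    assert report.rejected == [("fake", "fails_RO3")]


def test_mw_cutoff_is_inclusive():
    bb = _bb("CCN", BBClass.PRIMARY_AMINE, "fake")
    from dataclasses import replace
    from bbdesign.catalog import PCPSet

    bb = replace(bb, pcp=PCPSet(mw=250.0, clogp=1.0, tpsa=20.0, hbd=1, hba=1))
    kept, _ = pcp_filter(Catalog(BBClass.PRIMARY_AMINE, [bb]), 250.0)
    assert kept.ids() == ["fake"]


def test_fmoc_aa_filtered_on_deprotected_mw():
    # full Fmoc-Ala is ~311 Da, the free amino acid ~89 Da
    cat = Catalog(BBClass.FMOC_AA, [_bb(FMOC_ALANINE, BBClass.FMOC_AA, "fa")])
    kept, _ = pcp_filter(cat, 200.0)
    assert kept.ids() == ["fa"]


def test_pcp_filter_all_pass_has_empty_rejections(small_amine_catalog):
    _, report = pcp_filter(small_amine_catalog, 10000.0)
    assert report.rejected == []


def test_unique_truncates_multiplicity_and_set_difference():
    counts = unique_truncates(["CC", "CC", "CCC"])
    assert counts == {"CC": 2, "CCC": 1}
    assert unique_truncates([]) == {}
    a = set(unique_truncates(["CC", "CCC", "CCCC", "c1ccccc1"]))
    b = set(unique_truncates(["CC", "c1ccccc1"]))
    assert a - b == {"CCC", "CCCC"}
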