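"""Synthetic building-block catalogs with vendor-like statistical structure.

Commercial BB catalogs cannot be redistributed, so every downstream stage
of the package is exercised on generated catalogs that emulate the
relevant structure of such sets:

* three classes — Fmoc-amino acids, primary amines, carboxylic acids —
  with class MW medians near 171 / 174 / 220 Da (the Fmoc-AA figure refers
  to the Fmoc-removed form) and clogP medians near -1.8 / 0.69 / 1.1;
* scaffolds drawn from a grammar of named chemotype families (linear and
  branched aliphatics, cycloalkanes, substituted benzenes, fused
  bicyclics and dihydrobenzofurans, naphthalenes, heteroaromatics,
  benzylsulfonamides, biphenyls) so chemical space has genuine cluster
  structure for projection and selection tests;
* roughly bimodal prices per 250 mg, modeled as a two-component
  log-normal mixture (a "cheap" and an "expensive" mode);
* relative set sizes |Fmoc-AA| < |acid| < |amine|, with a configurable
  fraction of Fmoc-AA scaffolds duplicated among the amines so that few
  Fmoc-AA truncates are unique to that class.

Scaffolds guarantee chemical validity and exactly one defining functional
group per BB by construction: the group is always attached through an
sp3 methylene/alpha carbon, so truncation and coupling are unambiguous.
Realistic vendor chemotype frequencies and prices are out of scope — the
generator exists to give tests controllable structure, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .catalog import BuildingBlock, Catalog, compute_pcp_mol
from .errors import ConfigError
from .patterns import BBClass

__all__ = [
    "CostMode",
    "CatalogSpec",
    "DEFAULT_SPECS",
    "default_spec",
    "generate_catalog",
    "generate_paired_catalogs",
    "SCAFFOLD_FAMILIES",
]

# -- scaffold grammar -------------------------------------------------------
# Each family is (name, weight, [template SMILES with a [*:1] attachment]).
# Templates are kept light (<= ~160 Da) so the per-BB aliphatic tail can
# steer molecular weight upward toward the class target.

SCAFFOLD_FAMILIES: tuple[tuple[str, float, tuple[str, ...]], ...] = (
    ("linear_aliphatic", 0.18, ("[*:1]C",)),  # tail supplies the chain
    ("branched_aliphatic", 0.10, ("[*:1]C(C)C", "[*:1]CC(C)C", "[*:1]C(C)(C)C")),
    (
        "cycloalkane",
        0.14,
        ("[*:1]C1CC1", "[*:1]C1CCC1", "[*:1]C1CCCC1", "[*:1]C1CCCCC1",
         "[*:1]C1CCCCCC1", "[*:1]C1CCC(C)CC1"),
    ),
    (
        "substituted_benzene",
        0.18,
        ("[*:1]c1ccccc1", "[*:1]c1ccc(C)cc1", "[*:1]c1ccc(F)cc1",
         "[*:1]c1ccc(Cl)cc1", "[*:1]c1ccc(OC)cc1", "[*:1]c1cccc(C)c1",
         "[*:1]c1ccc(C(F)(F)F)cc1"),
    ),
    (
        "dihydrobenzofuran",
        0.07,
        ("[*:1]C1Oc2ccccc2C1", "[*:1]C1Cc2ccccc2O1"),
    ),
    ("naphthalene", 0.07, ("[*:1]c1ccc2ccccc2c1", "[*:1]c1cccc2ccccc12")),
    (
        "heteroaromatic",
        0.12,
        ("[*:1]c1ccncc1", "[*:1]c1cccnc1", "[*:1]c1cccs1", "[*:1]c1ccco1",
         "[*:1]c1ccn(C)n1"),
    ),
    (
        "benzylsulfonamide",
        0.07,
        ("[*:1]CS(=O)(=O)N(C)C", "[*:1]c1ccc(CS(=O)(=O)N(C)C)cc1",
         "[*:1]c1ccc(S(=O)(=O)N(C)C)cc1"),
    ),
    ("biphenyl", 0.07, ("[*:1]c1ccc(-c2ccccc2)cc1", "[*:1]c1cccc(-c2ccccc2)c1")),
)

#: class-defining group fragments, attached at the scaffold's [*:1] point.
_GROUP_FRAGMENTS = {
    BBClass.PRIMARY_AMINE: "[*:1]CN",
    BBClass.CARBOXYLIC_ACID: "[*:1]CC(=O)O",
    BBClass.FMOC_AA: "[*:1]C(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
}
#: fragments used only for MW targeting (the Fmoc-AA target refers to the
#: Fmoc-removed free amino acid).
_TARGETING_FRAGMENTS = {
    BBClass.PRIMARY_AMINE: "[*:1]CN",
    BBClass.CARBOXYLIC_ACID: "[*:1]CC(=O)O",
    BBClass.FMOC_AA: "[*:1]C(N)C(=O)O",
}

_ID_PREFIX = {
    BBClass.PRIMARY_AMINE: "AM",
    BBClass.CARBOXYLIC_ACID: "CA",
    BBClass.FMOC_AA: "FA",
}


@dataclass(frozen=True)
class CostMode:
    """One log-normal price component: median USD/250 mg, log-sd, weight."""

    median: float
    sigma: float
    weight: float


@dataclass(frozen=True)
class CatalogSpec:
    """Parameters of one synthetic catalog."""

    bb_class: BBClass
    n: int
    mw_median_target: float
    clogp_median_target: float
    cost_modes: tuple[CostMode, CostMode]
    seed: int = 0
    missing_cost_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        w = sum(m.weight for m in self.cost_modes)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError("cost mode weights must sum to 1")
        if any(m.sigma <= 0 or m.median <= 0 for m in self.cost_modes):
            raise ConfigError("cost mode medians and sigmas must be positive")


#: "roughly bimodal" default price structure: a cheap and an expensive mode.
_DEFAULT_COST_MODES = (CostMode(75.0, 0.35, 0.6), CostMode(400.0, 0.35, 0.4))

DEFAULT_SPECS: dict[BBClass, dict] = {
    BBClass.FMOC_AA: dict(mw_median_target=171.0, clogp_median_target=-1.8),
    BBClass.PRIMARY_AMINE: dict(mw_median_target=174.0, clogp_median_target=0.69),
    BBClass.CARBOXYLIC_ACID: dict(mw_median_target=220.0, clogp_median_target=1.1),
}


def default_spec(bb_class: BBClass, n: int, seed: int = 0, **overrides) -> CatalogSpec:
    """Spec with the class's default MW/clogP medians and cost structure."""
    kwargs = dict(DEFAULT_SPECS[bb_class])
    kwargs.update(cost_modes=_DEFAULT_COST_MODES)
    kwargs.update(overrides)
    return CatalogSpec(bb_class=bb_class, n=n, seed=seed, **kwargs)


def _attach(scaffold: str, fragment: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(scaffold + "." + fragment)
    if mol is None:
        raise ConfigError(f"grammar produced invalid SMILES: {scaffold!r}")
    return Chem.molzip(mol)


def _mw_with_group(scaffold: str, bb_class: BBClass) -> float:
    return Descriptors.MolWt(_attach(scaffold, _TARGETING_FRAGMENTS[bb_class]))


def _draw_tail(rng: np.random.Generator, n_atoms: int, p_polar: float) -> str:
    """A short chain of C with occasional ether O (never first, last, or
    adjacent to another O) used to pad scaffolds toward a target MW."""
    atoms = []
    for i in range(n_atoms):
        if i > 0 and atoms[-1] != "O" and rng.random() < p_polar:
            atoms.append("O")  # ether only: never adjacent to the group or another O
        else:
            atoms.append("C")
    return "".join(atoms)


def _polar_fraction(clogp_target: float) -> float:
    # Rough steering of lipophilicity: more ether oxygens for hydrophilic
    # targets.  Mapping fixed once from a small calibration sweep.
    return float(np.clip(0.3 * (2.0 - clogp_target), 0.0, 0.7))


def _draw_scaffold(
    rng: np.random.Generator, spec: CatalogSpec, families, weights
) -> str:
    """One padded scaffold SMILES (with [*:1]) aimed at the class MW target."""
    target = rng.normal(spec.mw_median_target, 40.0)
    # redraw templates that already overshoot the per-BB target: padding can
    # only add mass, so without the redraw the class median drifts upward
    for _ in range(6):
        fam = families[rng.choice(len(families), p=weights)]
        template = fam[2][int(rng.integers(len(fam[2])))]
        base = _mw_with_group(template, spec.bb_class)
        if base <= target + 20.0:
            break
    n_pad = int(np.clip(round((target - base) / 14.0), 0, 12))
    if n_pad:
        tail = _draw_tail(rng, n_pad, _polar_fraction(spec.clogp_median_target))
        template = template.replace("[*:1]", "[*:1]" + tail, 1)
    return template


def _draw_cost(rng: np.random.Generator, spec: CatalogSpec) -> float | None:
    if spec.missing_cost_fraction and rng.random() < spec.missing_cost_fraction:
        return None
    weights = [m.weight for m in spec.cost_modes]
    mode = spec.cost_modes[rng.choice(len(spec.cost_modes), p=weights)]
    return round(float(np.exp(rng.normal(np.log(mode.median), mode.sigma))), 2)


def _build_bb(
    scaffold: str, bb_class: BBClass, bb_id: str, cost: float | None
) -> BuildingBlock:
    mol = _attach(scaffold, _GROUP_FRAGMENTS[bb_class])
    Chem.SanitizeMol(mol)
    return BuildingBlock(
        id=bb_id,
        smiles=Chem.MolToSmiles(mol),
        bb_class=bb_class,
        cost=cost,
        pcp=compute_pcp_mol(mol),
    )


def generate_catalog(
    spec: CatalogSpec, scaffolds: list[str] | None = None
) -> Catalog:
    """Generate a synthetic catalog, deterministic given the spec's seed.

    ``scaffolds`` optionally pins the padded scaffold of some members
    (used to share truncate scaffolds across classes); remaining members
    draw scaffolds from the grammar.
    """
    if not SCAFFOLD_FAMILIES:
        raise ConfigError("empty scaffold grammar")
    rng = np.random.default_rng(spec.seed)
    weights = np.array([f[1] for f in SCAFFOLD_FAMILIES])
    weights = weights / weights.sum()
    members: list[BuildingBlock] = []
    pinned = list(scaffolds or [])
    for i in range(spec.n):
        scaffold = (
            pinned[i] if i < len(pinned) else _draw_scaffold(
                rng, spec, SCAFFOLD_FAMILIES, weights
            )
        )
        bb_id = f"{_ID_PREFIX[spec.bb_class]}-{i:05d}"
        members.append(_build_bb(scaffold, spec.bb_class, bb_id, _draw_cost(rng, spec)))
    return Catalog(
        spec.bb_class, members, provenance=f"synthetic(seed={spec.seed}, n={spec.n})"
    )


def _truncate_key(scaffold: str) -> str:
    """Canonical SMILES of the truncate a scaffold yields (scaffold-CH3).

    All three classes attach their group through an sp3 carbon at [*:1],
    so truncation reduces every BB built on the same scaffold to the same
    scaffold-methyl structure; this key detects cross-class truncate
    collisions even between structurally different scaffold strings.
    """
    return Chem.MolToSmiles(_attach(scaffold, "[*:1]C"))


def generate_paired_catalogs(
    seed: int,
    n_fmoc: int = 300,
    n_amine: int = 1200,
    n_acid: int = 800,
    overlap_fraction: float = 0.6,
) -> dict[BBClass, Catalog]:
    """Three linked synthetic catalogs with vendor-like relative sizes.

    The Fmoc-AA set is the smallest; amines are the most numerous.
    ``overlap_fraction`` of the Fmoc-AA scaffolds are duplicated among the
    amine scaffolds, so those classes share truncates exactly (both attach
    their group through the same carbon and truncate to scaffold-CH3);
    the remaining amine scaffolds are resampled until they avoid the
    Fmoc-AA scaffold set, so overlap_fraction=0 yields zero shared
    truncates and 1.0 duplicates every Fmoc-AA truncate.
    """
    if not (n_fmoc <= n_acid and n_fmoc <= n_amine):
        raise ConfigError("|Fmoc-AA| must be the smallest set")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigError("overlap_fraction must be in [0, 1]")
    if round(overlap_fraction * n_fmoc) > n_amine:
        raise ConfigError("overlap demands more amines than requested")

    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31 - 1))  # noqa: E731

    fmoc_spec = default_spec(BBClass.FMOC_AA, n_fmoc, seed=sub())
    fmoc_scaffolds: list[str] = []
    fam_weights = np.array([f[1] for f in SCAFFOLD_FAMILIES])
    fam_weights = fam_weights / fam_weights.sum()
    fmoc_rng = np.random.default_rng(fmoc_spec.seed)
    for _ in range(n_fmoc):
        fmoc_scaffolds.append(
            _draw_scaffold(fmoc_rng, fmoc_spec, SCAFFOLD_FAMILIES, fam_weights)
        )
    fmoc = generate_catalog(fmoc_spec, scaffolds=fmoc_scaffolds)

    n_shared = int(round(overlap_fraction * n_fmoc))
    shared = [fmoc_scaffolds[i] for i in rng.choice(n_fmoc, n_shared, replace=False)]
    fmoc_keys = {_truncate_key(s) for s in fmoc_scaffolds}
    shared_keys = {_truncate_key(s) for s in shared}

    amine_spec = default_spec(BBClass.PRIMARY_AMINE, n_amine, seed=sub())
    amine_rng = np.random.default_rng(amine_spec.seed)
    amine_scaffolds = list(shared)
    while len(amine_scaffolds) < n_amine:
        cand = _draw_scaffold(amine_rng, amine_spec, SCAFFOLD_FAMILIES, fam_weights)
        if _truncate_key(cand) in fmoc_keys - shared_keys:
            continue  # keep non-shared truncates disjoint from the Fmoc set
        amine_scaffolds.append(cand)
    amine = generate_catalog(amine_spec, scaffolds=amine_scaffolds)

    acid = generate_catalog(default_spec(BBClass.CARBOXYLIC_ACID, n_acid, seed=sub()))
    return {BBClass.FMOC_AA: fmoc, BBClass.PRIMARY_AMINE: amine, BBClass.CARBOXYLIC_ACID: acid}
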