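"""Building-block truncation and the class / cost / property filters.

Truncation replaces every instance of a BB class's defining functional
group(s) with hydrogen: -NH2 for primary amines, -COOH for carboxylic
acids, and for Fmoc-amino acids the whole Fmoc carbamate (including the
nitrogen) together with the COOH.  The result — the "truncate" — isolates
the diversity scaffold the BB contributes to a library, and is the unit of
all chemical-space comparisons.

Filters mirror a practical DEL building-block triage:

* ``class_filter``   removes secondary amines, proline-like secondary
  amino acids and aniline nitrogens (poorly compatible with the coupling
  chemistry);
* ``cost_filter``    keeps BBs at or below a price per 250 mg pack;
  BBs without a quoted price are rejected (conservative purchasing);
* ``pcp_filter``     applies rule-of-3 / rule-of-5 / plain MW cutoffs.
  RO3/RO5 molecular-weight bounds are strict (<); standalone MW cutoffs
  are inclusive (<=).  Fmoc-AAs are judged on their Fmoc-removed form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Literal

from rdkit import Chem

from .catalog import BuildingBlock, Catalog, compute_pcp_mol
from .errors import TruncationError
from .patterns import (
    BBClass,
    CLASS_FILTER_PATTERNS,
    FMOC_GROUP_SMARTS,
    TRUNCATION_DELETIONS,
    count_matches,
    mol_from_smarts,
)

__all__ = [
    "Truncate",
    "FilterReport",
    "truncate_bb",
    "truncate_catalog",
    "remove_fmoc",
    "class_filter",
    "cost_filter",
    "pcp_filter",
    "unique_truncates",
]


@dataclass(frozen=True)
class Truncate:
    """A BB with its defining group(s) replaced by H.

    ``n_sites`` counts how many defining-group instances were removed;
    BBs with ``n_sites > 1`` are polyfunctional: ambiguous for coupling,
    but still valid points in truncate space.
    """

    smiles: str
    parent_id: str
    bb_class: BBClass
    n_sites: int = 1

    @property
    def polyfunctional(self) -> bool:
        return self.n_sites > 1


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass: n_out + len(rejected) == n_in."""

    n_in: int
    n_out: int
    rejected: list[tuple[str, str]]

    def __post_init__(self) -> None:
        assert self.n_out + len(self.rejected) == self.n_in


def _delete_all(mol: Chem.Mol, smarts: str) -> Chem.Mol:
    out = Chem.DeleteSubstructs(mol, mol_from_smarts(smarts))
    Chem.SanitizeMol(out)
    return out


def truncate_mol(mol: Chem.Mol, bb_class: BBClass) -> tuple[Chem.Mol, int]:
    """Apply the class's deletion transforms; returns (truncate, n_sites)."""
    n_sites = 0
    out = mol
    for smarts in TRUNCATION_DELETIONS[bb_class]:
        n = count_matches(out, smarts)
        n_sites = max(n_sites, n)
        if n:
            out = _delete_all(out, smarts)
    return out, n_sites


def truncate_bb(bb: BuildingBlock) -> Truncate:
    """Truncate one building block.

    Every instance of the defining group(s) is replaced by H.  Raises
    ``TruncationError`` carrying the parent id when the transform yields a
    disconnected or empty structure (e.g. glycine-like BBs that are nothing
    but their functional groups).
    """
    mol = bb.mol()
    if mol is None:
        raise TruncationError(bb.id, f"unparsable SMILES {bb.smiles!r}")
    out, n_sites = truncate_mol(mol, bb.bb_class)
    if n_sites == 0:
        raise TruncationError(bb.id, "no defining group to truncate")
    if out.GetNumAtoms() == 0:
        raise TruncationError(bb.id, "truncation removed the whole structure")
    if len(Chem.GetMolFrags(out)) != 1:
        raise TruncationError(bb.id, "truncation produced a disconnected structure")
    return Truncate(Chem.MolToSmiles(out), bb.id, bb.bb_class, n_sites)


def truncate_catalog(catalog: Catalog) -> tuple[list[Truncate], FilterReport]:
    """Truncate every member; failures are reported, not raised."""
    truncates: list[Truncate] = []
    rejected: list[tuple[str, str]] = []
    for bb in catalog:
        try:
            truncates.append(truncate_bb(bb))
        except TruncationError as exc:
            rejected.append((bb.id, str(exc)))
    return truncates, FilterReport(len(catalog), len(truncates), rejected)


def remove_fmoc(smiles: str) -> str:
    """Deprotect an Fmoc-amine: delete the Fmoc moiety, restoring N-H."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if count_matches(mol, FMOC_GROUP_SMARTS) == 0:
        return Chem.MolToSmiles(mol)
    out = _delete_all(mol, FMOC_GROUP_SMARTS)
    return Chem.MolToSmiles(out)


def _predicate_filter(
    catalog: Catalog,
    reject_reason: Callable[[BuildingBlock], str | None],
    provenance_suffix: str,
) -> tuple[Catalog, FilterReport]:
    kept: list[BuildingBlock] = []
    rejected: list[tuple[str, str]] = []
    for bb in catalog:
        reason = reject_reason(bb)
        if reason is None:
            kept.append(bb)
        else:
            rejected.append((bb.id, reason))
    out = Catalog(
        catalog.bb_class, kept, provenance=f"{catalog.provenance}{provenance_suffix}"
    )
    return out, FilterReport(len(catalog), len(kept), rejected)


def class_filter(catalog: Catalog) -> tuple[Catalog, FilterReport]:
    """Remove secondary amines, secondary amino acids and aniline nitrogens."""

    def reason(bb: BuildingBlock) -> str | None:
        mol = bb.mol()
        for name, smarts in CLASS_FILTER_PATTERNS:
            if count_matches(mol, smarts):
                return name
        return None

    return _predicate_filter(catalog, reason, "|class_filter")


def cost_filter(catalog: Catalog, max_cost: float) -> tuple[Catalog, FilterReport]:
    """Keep BBs with a known cost <= ``max_cost`` USD per 250 mg."""
    if max_cost <= 0:
        raise ValueError("max_cost must be positive")

    def reason(bb: BuildingBlock) -> str | None:
        if bb.cost is None:
            return "cost_missing"
        if bb.cost > max_cost:
            return "cost_above_threshold"
        return None

    return _predicate_filter(catalog, reason, f"|cost<={max_cost:g}")


PCPRule = Literal["RO3", "RO5"] | float


def pcp_filter(catalog: Catalog, rule: PCPRule) -> tuple[Catalog, FilterReport]:
    """Apply RO3, RO5 or a plain molecular-weight cutoff.

    ``rule`` is the string ``"RO3"`` / ``"RO5"`` or a number interpreted as
    an inclusive MW cutoff in Da.  RO3/RO5 use strict ``<`` on MW and logP
    per their standard statements.  Fmoc-AA members are evaluated on the
    PCPs of their Fmoc-removed (free amino acid) form.
    """
    catalog = catalog.with_pcp()

    def effective_pcp(bb: BuildingBlock):
        if bb.bb_class is BBClass.FMOC_AA:
            mol = Chem.MolFromSmiles(remove_fmoc(bb.smiles))
            return compute_pcp_mol(mol)
        return bb.pcp

    def reason(bb: BuildingBlock) -> str | None:
        pcp = effective_pcp(bb)
        if rule == "RO3":
            return None if pcp.passes_ro3() else "fails_RO3"
        if rule == "RO5":
            return None if pcp.passes_ro5() else "fails_RO5"
        cutoff = float(rule)
        return None if pcp.mw <= cutoff else f"mw_above_{cutoff:g}"

    return _predicate_filter(catalog, reason, f"|pcp:{rule}")


def unique_truncates(truncates: Iterable[Truncate | str]) -> Counter:
    """Deduplicate truncates by canonical SMILES, keeping multiplicity."""
    return Counter(t.smiles if isinstance(t, Truncate) else t for t in truncates)
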