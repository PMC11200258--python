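"""Two-cycle amide library enumeration and product property analysis.

The only BB-linking reaction modeled is amide condensation: cycle-1 BBs
supply a primary amine, cycle-2 BBs a carboxylic acid, and each product
forms with loss of one water (18.0153 Da, average weights).  Two library
schemes are supported, differing only in the constant scaffold the released
compound carries:

* ``DEL1`` — cycle 1 is an Fmoc-amino acid coupled through its acid to a
  photocleavable linker; photocleavage releases a pendant primary amide.
  Products are modeled as the deprotected amino acid whose COOH has become
  C(=O)NH2, amide-coupled to the cycle-2 acid.
* ``DEL2`` — cycle 1 is a primary amine attached via reductive amination;
  the released compound carries only the BB-connecting amide, so products
  are simply amine + acid condensations.

Properties are computed on the released compound, the species that matters
for hit physicochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .catalog import BuildingBlock, PCPSet, compute_pcp_mol
from .errors import AmbiguityError, ReactionError
from .patterns import COOH_SMARTS, PRIMARY_AMINE_SMARTS, count_matches
from .truncate import remove_fmoc

__all__ = [
    "WATER_MW",
    "LibraryProduct",
    "LibraryDesign",
    "EnumerationReport",
    "couple_amide",
    "amidate_acid",
    "enumerate_library",
    "scaffold_delta",
    "library_pcp_summary",
]

WATER_MW = 18.0153

_AMIDE_RXN = AllChem.ReactionFromSmarts(
    f"[NX3;H2;+0;!$([N]c);!$([N]C=O);!$([N]S):1].[CX3:2](=[OX1:3])[OX2H1]"
    f">>[N:1][C:2]=[O:3]"
)
_AMIDATION_RXN = AllChem.ReactionFromSmarts(
    "[CX3:1](=[OX1:2])[OX2H1]>>[C:1](=[O:2])[NH2]"
)


@dataclass(frozen=True)
class LibraryProduct:
    amine_id: str
    acid_id: str
    smiles: str
    pcp: PCPSet


@dataclass
class LibraryDesign:
    """A two-cycle library: which BBs enter each cycle, and the scheme."""

    scheme: Literal["DEL1", "DEL2"]
    cycle1: list[BuildingBlock]
    cycle2: list[BuildingBlock]

    #: constant fragment the released compound carries beyond the coupling
    #: amide, as a dummy-attached SMILES; None for no adduct.
    @property
    def scaffold_adduct(self) -> str | None:
        return "*C(N)=O" if self.scheme == "DEL1" else None


@dataclass
class EnumerationReport:
    n_pairs: int
    n_products: int
    failures: list[tuple[str, str, str]] = field(default_factory=list)  # (amine, acid, why)
    excluded_cycle1: list[tuple[str, str]] = field(default_factory=list)
    excluded_cycle2: list[tuple[str, str]] = field(default_factory=list)


def _require_single_site(mol: Chem.Mol, smarts: str, bb_id: str, what: str) -> None:
    n = count_matches(mol, smarts)
    if n != 1:
        raise AmbiguityError(bb_id, f"expected exactly one {what}, found {n}")


def couple_amide(
    amine_smiles: str, acid_smiles: str, amine_id: str = "amine", acid_id: str = "acid"
) -> str:
    """Condense a mono-amine with a mono-acid; returns the product SMILES.

    Preconditions: the amine partner has exactly one eligible primary
    aliphatic amine, the acid partner exactly one COOH (AmbiguityError
    otherwise).  The product satisfies the condensation mass balance
    MW(product) = MW(amine) + MW(acid) - 18.0153 Da.
    """
    amine = Chem.MolFromSmiles(amine_smiles)
    acid = Chem.MolFromSmiles(acid_smiles)
    if amine is None:
        raise ValueError(f"unparsable amine SMILES: {amine_smiles!r}")
    if acid is None:
        raise ValueError(f"unparsable acid SMILES: {acid_smiles!r}")
    _require_single_site(amine, PRIMARY_AMINE_SMARTS, amine_id, "primary amine")
    _require_single_site(acid, COOH_SMARTS, acid_id, "carboxylic acid")
    products = _AMIDE_RXN.RunReactants((amine, acid))
    if not products:
        raise ReactionError(f"amide coupling failed for {amine_id} + {acid_id}")
    mol = products[0][0]
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise ReactionError(
            f"unsanitizable product for {amine_id} + {acid_id}: {exc}"
        ) from exc
    return Chem.MolToSmiles(mol)


def amidate_acid(smiles: str) -> str:
    """Convert the single COOH of a structure into a primary amide C(=O)NH2."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    _require_single_site(mol, COOH_SMARTS, smiles, "carboxylic acid")
    out = _AMIDATION_RXN.RunReactants((mol,))[0][0]
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _prepare_cycle1(bb: BuildingBlock, scheme: str) -> str:
    """Released-compound amine synthon for a cycle-1 BB."""
    if scheme == "DEL2":
        return bb.smiles
    # DEL1: deprotect Fmoc, then turn the AA's acid into the pendant amide.
    return amidate_acid(remove_fmoc(bb.smiles))


def enumerate_library(
    design: LibraryDesign,
) -> tuple[list[LibraryProduct], EnumerationReport]:
    """Full cross-product enumeration of a two-cycle design.

    Every (cycle1, cycle2) pair yields one product; pairs that fail are
    logged in the report, never silently dropped, so
    ``n_products == |cycle1'| * |cycle2'| - len(failures)`` where the
    primed sets exclude BBs rejected upfront (ambiguous reaction sites).
    """
    if not design.cycle1 or not design.cycle2:
        raise ValueError("both cycles must be non-empty")
    report = EnumerationReport(n_pairs=0, n_products=0)

    amines: list[tuple[str, Chem.Mol]] = []
    for bb in design.cycle1:
        try:
            synthon = _prepare_cycle1(bb, design.scheme)
            mol = Chem.MolFromSmiles(synthon)
            _require_single_site(mol, PRIMARY_AMINE_SMARTS, bb.id, "primary amine")
            amines.append((bb.id, mol))
        except (AmbiguityError, ValueError) as exc:
            report.excluded_cycle1.append((bb.id, str(exc)))
    acids: list[tuple[str, Chem.Mol]] = []
    for bb in design.cycle2:
        try:
            mol = bb.mol()
            _require_single_site(mol, COOH_SMARTS, bb.id, "carboxylic acid")
            acids.append((bb.id, mol))
        except (AmbiguityError, ValueError) as exc:
            report.excluded_cycle2.append((bb.id, str(exc)))

    products: list[LibraryProduct] = []
    report.n_pairs = len(amines) * len(acids)
    for amine_id, amine in amines:
        for acid_id, acid in acids:
            try:
                out = _AMIDE_RXN.RunReactants((amine, acid))
                mol = out[0][0]
                Chem.SanitizeMol(mol)
            except Exception as exc:
                report.failures.append((amine_id, acid_id, str(exc)))
                continue
            products.append(
                LibraryProduct(
                    amine_id, acid_id, Chem.MolToSmiles(mol), compute_pcp_mol(mol)
                )
            )
    report.n_products = len(products)
    return products, report


def _adduct_props(adduct: str | None) -> tuple[float, int, int]:
    """(formula weight, hbd, hba) of a dummy-attached constant fragment."""
    if adduct is None:
        return 0.0, 0, 0
    frag = Chem.MolFromSmiles(adduct)
    mw = Descriptors.MolWt(frag)  # dummy atom contributes zero mass
    hbd = hba = 0
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            hba += 1
            if atom.GetTotalNumHs() > 0:
                hbd += 1
    return mw, hbd, hba


def scaffold_delta(design_a: LibraryDesign, design_b: LibraryDesign) -> dict:
    """Difference in the constant-adduct contribution between two schemes.

    For DEL1 vs DEL2 the delta is the pendant primary amide -C(=O)NH2
    (composition CH2NO): +44 Da, +1 H-bond donor, +2 acceptors.
    """
    mw_a, hbd_a, hba_a = _adduct_props(design_a.scaffold_adduct)
    mw_b, hbd_b, hba_b = _adduct_props(design_b.scaffold_adduct)
    return {"mw": mw_a - mw_b, "hbd": hbd_a - hbd_b, "hba": hba_a - hba_b}


RO5_THRESHOLDS = {"mw": 500.0, "clogp": 5.0, "tpsa": None, "hbd": 5}


def library_pcp_summary(
    products: list[LibraryProduct], ro5_lines: bool = True
) -> dict:
    """Distribution summary of product PCPs.

    Returns a dict with a per-product DataFrame, per-property medians,
    the RO5 pass fraction, and (when requested) the RO5 threshold marks
    used as dashed guide lines in the density plots.
    """
    if not products:
        raise ValueError("no products to summarise")
    df = pd.DataFrame(
        {
            "amine_id": [p.amine_id for p in products],
            "acid_id": [p.acid_id for p in products],
            "smiles": [p.smiles for p in products],
            "mw": [p.pcp.mw for p in products],
            "clogp": [p.pcp.clogp for p in products],
            "tpsa": [p.pcp.tpsa for p in products],
            "hbd": [p.pcp.hbd for p in products],
            "hba": [p.pcp.hba for p in products],
        }
    )
    medians = {k: float(df[k].median()) for k in ("mw", "clogp", "tpsa", "hbd", "hba")}
    ro5_pass = float(np.mean([p.pcp.passes_ro5() for p in products]))
    summary = {"table": df, "medians": medians, "ro5_pass_fraction": ro5_pass}
    if ro5_lines:
        summary["ro5_thresholds"] = dict(RO5_THRESHOLDS)
    return summary
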