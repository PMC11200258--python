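"""SMARTS patterns shared across the package.

The defining functional group of each building-block (BB) class is the group
consumed (or removed) during library synthesis: a primary aliphatic amine for
amine BBs, a carboxylic acid for acid BBs, and both an Fmoc-protected amine
and a carboxylic acid for Fmoc-amino-acid BBs.  Truncation replaces every
instance of the defining group(s) with H, isolating the diversity scaffold.

All patterns are module-level constants so that filter behaviour is
inspectable and testable; they are deliberately conservative:

* the primary-amine pattern excludes anilines (N-c), amides (N-C=O) and
  sulfonamides (N-S), which are not aminable in the coupling chemistry;
* the Fmoc carbamate is recognised explicitly as
  fluorenylmethyl-O-C(=O)-N rather than as a generic carbamate.
"""

from __future__ import annotations

import enum
from functools import lru_cache

from rdkit import Chem


class BBClass(enum.Enum):
    """Building-block class, named by its defining functional group."""

    FMOC_AA = "fmoc_aa"
    PRIMARY_AMINE = "primary_amine"
    CARBOXYLIC_ACID = "carboxylic_acid"


# -- defining groups -------------------------------------------------------

PRIMARY_AMINE_SMARTS = "[NX3;H2;+0;!$([N]c);!$([N]C=O);!$([N]S)]"
COOH_SMARTS = "[CX3](=[OX1])[OX2H1]"
# N-(fluorenylmethyloxycarbonyl) amine: the whole carbamate including the N.
FMOC_CARBAMATE_SMARTS = "[NX3;H1]C(=O)OC[CH]1c2ccccc2-c2ccccc21"
# The Fmoc moiety alone (carbamate carbon outward); deleting it deprotects
# the nitrogen back to a free amine.
FMOC_GROUP_SMARTS = "[CX3](=[OX1])OC[CH]1c2ccccc2-c2ccccc21"

#: SMARTS whose matches are deleted (all atoms of the match) when truncating
#: a BB of the given class.  For Fmoc-AAs the carbamate *including* the
#: nitrogen and the COOH are removed simultaneously.
TRUNCATION_DELETIONS: dict[BBClass, tuple[str, ...]] = {
    BBClass.PRIMARY_AMINE: (PRIMARY_AMINE_SMARTS,),
    BBClass.CARBOXYLIC_ACID: (COOH_SMARTS,),
    BBClass.FMOC_AA: (FMOC_CARBAMATE_SMARTS, COOH_SMARTS),
}

#: Substructures a BB must contain to belong to a class at all.
DEFINING_GROUPS: dict[BBClass, tuple[str, ...]] = {
    BBClass.PRIMARY_AMINE: (PRIMARY_AMINE_SMARTS,),
    BBClass.CARBOXYLIC_ACID: (COOH_SMARTS,),
    BBClass.FMOC_AA: (FMOC_CARBAMATE_SMARTS, COOH_SMARTS),
}

# -- class-filter patterns --------------------------------------------------
# Checked in order; the first hit supplies the rejection reason.  The
# secondary-amino-acid pattern (proline-like alpha-secondary amine) precedes
# the generic secondary amine so the more specific reason wins.

CLASS_FILTER_PATTERNS: tuple[tuple[str, str], ...] = (
    ("aniline_nitrogen", "[NX3;+0;!$([N]C=O);$([N]c)]"),
    ("secondary_amino_acid", "[NX3;H1;+0;!$([N]C=O)][CX4][CX3](=[OX1])[OX2H1]"),
    ("secondary_amine", "[NX3;H1;+0;!$([N]C=O);!$([N]c);!$([N]S)]([#6])[#6]"),
)


@lru_cache(maxsize=None)
def mol_from_smarts(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:  # pragma: no cover - all module constants are valid
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    return patt


def count_matches(mol: Chem.Mol, smarts: str) -> int:
    """Number of distinct matches of ``smarts`` in ``mol``."""
    return len(mol.GetSubstructMatches(mol_from_smarts(smarts)))


def has_defining_group(mol: Chem.Mol, bb_class: BBClass) -> bool:
    """True iff ``mol`` carries every defining group of ``bb_class``."""
    return all(count_matches(mol, s) >= 1 for s in DEFINING_GROUPS[bb_class])
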