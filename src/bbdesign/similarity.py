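"""Morgan fingerprints, all-by-all Tanimoto matrices and nn-Tanimoto stats.

Fingerprints are binary Morgan (circular) fingerprints of radius 3 bonds
hashed to 2048 bits (ECFP6-equivalent environments), computed without
chirality.  Distance is 1 - Tanimoto.  The nearest-neighbor Tanimoto
(nn-Tanimoto) of a set member is its maximum off-diagonal similarity to
any other member; the set median summarises internal redundancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FP_RADIUS",
    "FP_NBITS",
    "fingerprint",
    "tanimoto",
    "SimilarityMatrix",
    "DistanceMatrix",
    "all_by_all",
    "nn_tanimoto",
]

FP_RADIUS = 3
FP_NBITS = 2048

_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_NBITS, includeChirality=False
)


def fingerprint(smiles: str):
    """2048-bit radius-3 Morgan fingerprint of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return _GENERATOR.GetFingerprint(mol)


def tanimoto(a, b) -> float:
    """|a AND b| / |a OR b| for two equal-length bit vectors.

    Two all-zero vectors have an undefined ratio; by convention this
    returns 0.0 with a warning.
    """
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError("fingerprint lengths differ")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0.0")
        return 0.0
    return DataStructs.TanimotoSimilarity(a, b)


@dataclass
class SimilarityMatrix:
    """Symmetric all-by-all Tanimoto similarity matrix with row labels."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def to_distance(self) -> "DistanceMatrix":
        return DistanceMatrix(list(self.ids), 1.0 - self.values)

    def submatrix(self, subset: list[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(i) for i in subset]
        return SimilarityMatrix(list(subset), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


@dataclass
class DistanceMatrix:
    """1 - Tanimoto complement of a similarity matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")


def all_by_all(smiles: list[str], ids: list[str] | None = None) -> SimilarityMatrix:
    """All-by-all Tanimoto similarity over a list of structures.

    When comparing several BB sets, pass their concatenation so that every
    downstream projection shares one joint coordinate frame.
    """
    if len(smiles) < 2:
        raise ValueError("need at least 2 structures for an all-by-all matrix")
    if ids is None:
        ids = [str(i) for i in range(len(smiles))]
    if len(ids) != len(smiles):
        raise ValueError("ids and smiles lengths differ")
    fps = [fingerprint(s) for s in smiles]
    n = len(fps)
    values = np.eye(n)
    for i in range(1, n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        values[i, :i] = row
        values[:i, i] = row
    return SimilarityMatrix(list(ids), values)


def nn_tanimoto(
    matrix: SimilarityMatrix, subset: list[str] | None = None
) -> tuple[pd.Series, float]:
    """Per-member nearest-neighbor similarity within a set, plus the median.

    For each id the score is the maximum off-diagonal similarity to any
    other id in the subset (default: all ids).
    """
    ids = matrix.ids if subset is None else list(subset)
    if len(ids) < 2:
        raise ValueError("nn-Tanimoto needs at least 2 members")
    unknown = set(ids) - set(matrix.ids)
    if unknown:
        raise KeyError(f"ids not in matrix: {sorted(unknown)}")
    sub = matrix.submatrix(ids)
    vals = sub.values.copy()
    np.fill_diagonal(vals, -np.inf)
    scores = pd.Series(vals.max(axis=1), index=ids, name="nn_tanimoto")
    return scores, float(scores.median())
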