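"""2D chemical-space embedding (UMAP on a precomputed Tanimoto distance
matrix) and Gaussian-KDE density surfaces for coverage plots.

The embedding is always fit jointly across all BB sets under comparison;
per-set figures are *views* of the one joint embedding (``subset_view``),
never re-fits, so every set shares a coordinate frame.  Embedded distances
are not asserted to track Tanimoto distances — only cluster-level topology
is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ConfigError
from .similarity import DistanceMatrix

__all__ = ["EmbedParams", "Embedding", "DensitySurface", "embed", "density", "subset_view"]


@dataclass(frozen=True)
class EmbedParams:
    """UMAP hyperparameters. Defaults favour reproducibility over speed:
    a fixed seed forces single-threaded layout optimisation."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 42


@dataclass
class Embedding:
    """2D coordinates per id, in input order, from one joint UMAP fit."""

    ids: list[str]
    coords: np.ndarray
    params: EmbedParams

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be (n_ids, 2)")

    def coord_of(self, bb_id: str) -> np.ndarray:
        return self.coords[self.ids.index(bb_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.coords, index=self.ids, columns=["x", "y"])

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)


@dataclass
class DensitySurface:
    """Gaussian KDE of embedded points evaluated on a regular grid."""

    x: np.ndarray  # (nx,) grid abscissae
    y: np.ndarray  # (ny,) grid ordinates
    values: np.ndarray  # (ny, nx) density, >= 0
    bandwidth: str | float = "scott"

    def integral(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(np.trapezoid(np.trapezoid(self.values, dx=dx, axis=1), dx=dy))

    def mode_xy(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.x[ix]), float(self.y[iy])


def embed(dist: DistanceMatrix, params: EmbedParams | None = None) -> Embedding:
    """Embed a precomputed distance matrix to 2D with UMAP.

    Deterministic given (matrix, params): the seed fixes both the
    initialisation and the (single-threaded) layout optimisation.
    """
    params = params or EmbedParams()
    n = len(dist.ids)
    if n < params.n_neighbors + 1:
        raise ConfigError(
            f"n={n} too small for n_neighbors={params.n_neighbors}; "
            f"use n_neighbors <= {n - 1}"
        )
    import umap  # deferred: numba-backed import is slow

    with warnings.catch_warnings():
        # UMAP warns that a fixed random_state disables parallelism; that
        # trade is exactly what we want.
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            metric="precomputed",
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            random_state=params.seed,
            n_components=2,
        )
        coords = reducer.fit_transform(dist.values)
    return Embedding(list(dist.ids), np.asarray(coords, dtype=float), params)


def subset_view(embedding: Embedding, subset: list[str]) -> Embedding:
    """Restrict an embedding to a subset of ids, coordinates unchanged."""
    if len(subset) == 0:
        raise ValueError("empty subset")
    index = {bb_id: i for i, bb_id in enumerate(embedding.ids)}
    try:
        rows = [index[bb_id] for bb_id in subset]
    except KeyError as exc:
        raise KeyError(f"id not in embedding: {exc.args[0]!r}") from exc
    return Embedding(list(subset), embedding.coords[rows], embedding.params)


def density(
    embedding: Embedding,
    gridsize: int = 100,
    bandwidth: str | float = "scott",
    padding: float = 0.05,
) -> DensitySurface:
    """Gaussian KDE over the embedded points on a regular grid.

    The grid covers the bounding box of the points expanded by ``padding``
    (fraction of each range); the returned surface integrates to ~1 over
    the grid up to the mass outside the box.
    """
    pts = embedding.coords
    if pts.shape[0] < 3:
        raise ValueError("density needs at least 3 points")
    spread = pts.std(axis=0)
    if np.any(spread == 0) and np.allclose(pts, pts[0]):
        raise ValueError("degenerate spread: all points identical")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo = lo - padding * span - 3 * np.max(kde.covariance.diagonal()) ** 0.5
    hi = hi + padding * span + 3 * np.max(kde.covariance.diagonal()) ** 0.5
    x = np.linspace(lo[0], hi[0], gridsize)
    y = np.linspace(lo[1], hi[1], gridsize)
    xx, yy = np.meshgrid(x, y)
    vals = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(gridsize, gridsize)
    return DensitySurface(x, y, vals, bandwidth)
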