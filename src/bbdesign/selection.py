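"""Building-block selection strategies: random, diversity, uniform.

* ``select_random``   — uniform sampling without replacement from the
  filtered pool; mirrors picking whatever the catalog offers.
* ``select_diverse``  — greedy max-min in Tanimoto-distance space: seed
  with a random pool member, then repeatedly add the candidate whose
  minimum distance to the already-chosen set is largest (ties broken by
  lowest pool index).
* ``select_uniform``  — thinning in the 2D embedding: walk a seeded random
  permutation of the pool and accept a candidate iff it lies at least a
  threshold away (Euclidean, embedding space) from everything accepted so
  far; if a full pass accepts fewer than k, the threshold is relaxed
  geometrically and the walk continues over the remaining candidates.

The default split size k=192 corresponds to two 96-well plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, PoolExhaustedError
from .projection import Embedding
from .similarity import SimilarityMatrix

__all__ = [
    "DEFAULT_K",
    "SelectionResult",
    "select_random",
    "select_diverse",
    "select_uniform",
]

DEFAULT_K = 192  # 2 x 96-well plates


@dataclass
class SelectionResult:
    method: str
    chosen: list[str]
    k: int
    seed: int
    threshold: float | None = None  # uniform only: final (possibly relaxed)
    provenance: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chosen) != self.k:
            raise ValueError("selection size does not match k")
        if len(set(self.chosen)) != len(self.chosen):
            raise ValueError("duplicate ids in selection")


def _check_pool(pool: list[str], k: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pool) < k:
        raise PoolExhaustedError(f"pool has {len(pool)} members, requested {k}")
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate ids in pool")


def select_random(pool: list[str], k: int, seed: int) -> SelectionResult:
    """Uniform sampling of k ids without replacement, reproducible by seed."""
    pool = list(pool)
    _check_pool(pool, k)
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    return SelectionResult("random", chosen, k, seed, provenance=f"pool[{len(pool)}]")


def select_diverse(
    sim: SimilarityMatrix,
    k: int,
    seed: int,
    pool: list[str] | None = None,
) -> SelectionResult:
    """Greedy max-min diversity pick on Tanimoto distance.

    Starts from a seeded random pool member; each following pick maximises
    its minimum distance (1 - similarity) to the already-chosen set, with
    ties broken by the lowest pool index.
    """
    pool = list(pool) if pool is not None else list(sim.ids)
    _check_pool(pool, k)
    sub = sim.submatrix(pool)
    dist = 1.0 - sub.values
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(pool)))

    chosen_idx = [start]
    # min distance from each candidate to the chosen set so far
    min_dist = dist[:, start].copy()
    min_dist[start] = -np.inf
    while len(chosen_idx) < k:
        best = int(np.argmax(min_dist))  # argmax takes the first (lowest index) tie
        chosen_idx.append(best)
        min_dist = np.minimum(min_dist, dist[:, best])
        min_dist[best] = -np.inf
    chosen = [pool[i] for i in chosen_idx]
    return SelectionResult(
        "diversity", chosen, k, seed, provenance=f"pool[{len(pool)}]",
        extras={"start": pool[start]},
    )


def select_uniform(
    embedding: Embedding,
    k: int,
    initial_threshold: float,
    seed: int,
    pool: list[str] | None = None,
    relaxation: float = 0.9,
    floor: float = 1e-6,
) -> SelectionResult:
    """Minimum-distance thinning in embedding space.

    Accepts candidates from a seeded random permutation whenever their
    embedded Euclidean distance to every accepted point is at least the
    current threshold; relaxes the threshold by ``relaxation`` whenever a
    pass over the remaining candidates cannot reach k.  The realized final
    threshold is reported; all pairwise distances among chosen points are
    >= that threshold.
    """
    pool = list(pool) if pool is not None else list(embedding.ids)
    _check_pool(pool, k)
    if initial_threshold < 0:
        raise ValueError("initial_threshold must be >= 0")
    index = {bb_id: i for i, bb_id in enumerate(embedding.ids)}
    coords = np.array([embedding.coords[index[bb_id]] for bb_id in pool])

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(pool)))

    threshold = float(initial_threshold)
    accepted: list[int] = []
    remaining = order
    while len(accepted) < k:
        still: list[int] = []
        for cand in remaining:
            if len(accepted) >= k:
                still.append(cand)
                continue
            if accepted:
                d = np.linalg.norm(coords[accepted] - coords[cand], axis=1)
                if d.min() < threshold:
                    still.append(cand)
                    continue
            accepted.append(cand)
        remaining = still
        if len(accepted) < k:
            if threshold <= floor:
                raise ConvergenceError(
                    f"threshold relaxed to {threshold:g} without reaching k={k}"
                )
            threshold = max(threshold * relaxation, floor)
    chosen = [pool[i] for i in accepted]
    return SelectionResult(
        "uniform", chosen, k, seed, threshold=threshold,
        provenance=f"pool[{len(pool)}]",
    )
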