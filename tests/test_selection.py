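"""Random, diversity (greedy max-min) and uniform selection strategies."""

import itertools

import numpy as np
import pytest

from bbdesign.errors import PoolExhaustedError
from bbdesign.projection import EmbedParams, Embedding
from bbdesign.selection import select_diverse, select_random, select_uniform
from bbdesign.similarity import SimilarityMatrix


def brute_force_maxmin(dist: np.ndarray, start: int, k: int) -> list[int]:
    """Independent greedy max-min oracle: plain loops, lowest-index ties."""
    chosen = [start]
    while len(chosen) < k:
        best, best_d = None, -1.0
        for cand in range(dist.shape[0]):
            if cand in chosen:
                continue
            d = min(dist[cand, c] for c in chosen)
            if d > best_d:  # strict: first (lowest) index wins ties
                best, best_d = cand, d
        chosen.append(best)
    return chosen


def _random_similarity(n, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 1, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix([f"m{i}" for i in range(n)], v)


# -- random -----------------------------------------------------------------


def test_random_full_pool_and_determinism():
    pool = [f"m{i}" for i in range(10)]
    res = select_random(pool, 10, seed=5)
    assert set(res.chosen) == set(pool)
    assert select_random(pool, 4, 5).chosen == select_random(pool, 4, 5).chosen
    with pytest.raises(PoolExhaustedError):
        select_random(pool, 11, 0)


def test_random_pairs_approximately_uniform():
    """k=2 draws from a 4-pool hit each of the 6 pairs near-uniformly."""
    pool = ["a", "b", "c", "d"]
    counts = {}
    n_draws = 1000
    for seed in range(n_draws):
        pair = frozenset(select_random(pool, 2, seed).chosen)
        counts[pair] = counts.get(pair, 0) + 1
    assert len(counts) == 6
    expect = n_draws / 6
    sigma = np.sqrt(n_draws * (1 / 6) * (5 / 6))
    for pair, count in counts.items():
        assert abs(count - expect) <= 3 * sigma


# -- diversity --------------------------------------------------------------


def test_diverse_three_member_hand_case():
    # distances d(A,B)=0.1, d(A,C)=0.9, d(B,C)=0.8; starting at A, the
    # max-min pick for k=2 is C
    sim = SimilarityMatrix(
        ["A", "B", "C"],
        np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]]),
    )
    for seed in range(30):
        res = select_diverse(sim, 2, seed)
        if res.extras["start"] == "A":
            assert res.chosen == ["A", "C"]
            break
    else:
        pytest.fail("no seed started at A")


def test_diverse_k1_is_just_the_seeded_start():
    sim = _random_similarity(8)
    res = select_diverse(sim, 1, seed=3)
    assert res.chosen == [res.extras["start"]]


@pytest.mark.parametrize("n", [5, 12, 20])
def test_diverse_matches_brute_force_oracle(n):
    """Greedy max-min equals an independent loop-based oracle for every
    seed (hence every reachable start) on small pools."""
    sim = _random_similarity(n, seed=n)
    dist = 1.0 - sim.values
    for seed in range(20):
        res = select_diverse(sim, min(n, 7), seed)
        start = sim.ids.index(res.extras["start"])
        oracle = brute_force_maxmin(dist, start, min(n, 7))
        assert res.chosen == [sim.ids[i] for i in oracle]


def test_diverse_deterministic():
    sim = _random_similarity(15)
    assert select_diverse(sim, 6, 9).chosen == select_diverse(sim, 6, 9).chosen


# -- uniform ----------------------------------------------------------------


def _grid_embedding(n=10, spacing=1.0):
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    return Embedding([f"g{i}" for i in range(n * n)], coords, EmbedParams())


def test_uniform_grid_respects_threshold():
    emb = _grid_embedding()
    # every greedy pass yields a maximal 2-spaced set; on a 10x10 grid each
    # accepted point excludes at most its 8 sub-threshold neighbours, so any
    # maximal set has >= ceil(100/9) = 12 points: k=12 needs no relaxation
    res = select_uniform(emb, 12, initial_threshold=2.0, seed=1)
    assert res.threshold == 2.0
    coords = {i: emb.coord_of(i) for i in res.chosen}
    for a, b in itertools.combinations(res.chosen, 2):
        assert np.linalg.norm(coords[a] - coords[b]) >= 2.0 - 1e-12
    # k=25 equals the perfect packing; a random-order greedy may have to
    # relax, but the final threshold contract must still hold exhaustively
    res25 = select_uniform(emb, 25, initial_threshold=2.0, seed=1)
    assert res25.threshold <= 2.0
    coords = {i: emb.coord_of(i) for i in res25.chosen}
    for a, b in itertools.combinations(res25.chosen, 2):
        assert np.linalg.norm(coords[a] - coords[b]) >= res25.threshold - 1e-12


def test_uniform_threshold_zero_accepts_first_k_of_permutation():
    emb = _grid_embedding(4)
    res = select_uniform(emb, 5, initial_threshold=0.0, seed=7)
    rng = np.random.default_rng(7)
    order = list(rng.permutation(16))
    assert res.chosen == [emb.ids[i] for i in order[:5]]


def test_uniform_never_picks_both_duplicates_unrelaxed():
    coords = np.array([[0.0, 0], [0, 0], [5, 5], [9, 0], [0, 9], [9, 9]])
    emb = Embedding(list("abcdef"), coords, EmbedParams())
    for seed in range(10):
        res = select_uniform(emb, 5, initial_threshold=1.0, seed=seed)
        assert not {"a", "b"} <= set(res.chosen)


def test_uniform_relaxes_and_reports_threshold():
    emb = _grid_embedding(4)  # max pairwise distance ~4.24
    res = select_uniform(emb, 10, initial_threshold=3.0, seed=0)
    assert res.threshold < 3.0
    coords = {i: emb.coord_of(i) for i in res.chosen}
    for a, b in itertools.combinations(res.chosen, 2):
        assert np.linalg.norm(coords[a] - coords[b]) >= res.threshold - 1e-12


def test_uniform_pool_exhausted():
    emb = _grid_embedding(3)
    with pytest.raises(PoolExhaustedError):
        select_uniform(emb, 10, 1.0, 0)
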