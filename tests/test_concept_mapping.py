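"""Concept-mapping analytics: similarity counts, nonmetric scaling and
stress, the cluster ladder, bridging values, rating comparisons and sorter
reliability."""

import math

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from dtpd.concept_mapping import (
    ClusterSolution,
    MapConfiguration,
    RatingDataset,
    SimilarityMatrix,
    SortingDataset,
    bridging_values,
    build_similarity,
    cluster_ladder,
    embed_map,
    mean_pile_count,
    rating_summary,
    sorter_reliability,
    stress1,
)
from dtpd.errors import DegenerateInputError, InputError
from tests.conftest import make_sorts, random_sorts


# ---------------------------------------------------------------------------
# similarity


def brute_force_similarity(sorts: SortingDataset, sorters) -> np.ndarray:
    """Independent oracle: explicit loop over sorters and item pairs."""
    n = sorts.n_items
    counts = np.zeros((n, n), dtype=int)
    for s in sorters:
        for a in range(n):
            for b in range(n):
                if (
                    sorts.assignment[(s, sorts.items[a])]
                    == sorts.assignment[(s, sorts.items[b])]
                ):
                    counts[a, b] += 1
    return counts


def test_identical_sorters_copile_counts():
    sorts = make_sorts({"s1": [["A", "B"], ["C"]], "s2": [["A", "B"], ["C"]]})
    sim = build_similarity(sorts, exclude_invalid=False)
    idx = {it: i for i, it in enumerate(sim.items)}
    assert sim.counts[idx["A"], idx["B"]] == 2
    assert sim.counts[idx["A"], idx["C"]] == 0
    assert sim.counts[idx["B"], idx["C"]] == 0


def test_single_pile_sorter_counts_when_not_excluded():
    sorts = make_sorts({"s1": [["A", "B", "C", "D"]]})
    sim = build_similarity(sorts, exclude_invalid=False)
    off = sim.counts[~np.eye(4, dtype=bool)]
    assert np.all(off == 1)


def test_similarity_matches_bruteforce(rng):
    sorts = random_sorts(rng, n_items=8, n_sorters=5, n_piles=3)
    sim = build_similarity(sorts, exclude_invalid=True)
    expected = brute_force_similarity(sorts, sorts.valid_sorters())
    assert np.array_equal(sim.counts, expected)


def test_similarity_count_conservation(rng):
    """Sum of off-diagonal pair counts equals sum over sorters of piles'
    C(size, 2)."""
    for _ in range(5):
        sorts = random_sorts(rng, n_items=10, n_sorters=4, n_piles=4)
        sim = build_similarity(sorts, exclude_invalid=True)
        total_pairs = sim.counts[np.triu_indices(10, k=1)].sum()
        expected = sum(
            math.comb(len(pile), 2)
            for s in sorts.valid_sorters()
            for pile in sorts.piles_of(s).values()
        )
        assert total_pairs == expected


def test_invalid_sorter_predicate():
    sorts = make_sorts(
        {
            "one_pile": [["A", "B", "C"]],
            "all_alone": [["A"], ["B"], ["C"]],
            "ok": [["A", "B"], ["C"]],
        }
    )
    assert not sorts.is_valid_sorter("one_pile")
    assert not sorts.is_valid_sorter("all_alone")
    assert sorts.is_valid_sorter("ok")
    assert sorts.valid_sorters() == ("ok",)


def test_all_invalid_sorters_raises():
    sorts = make_sorts({"s1": [["A", "B", "C"]]})
    with pytest.raises(InputError, match="invalid"):
        build_similarity(sorts, exclude_invalid=True)


def test_incomplete_sort_rejected():
    with pytest.raises(InputError, match="exactly one pile"):
        SortingDataset(
            items=("A", "B"), sorters=("s1",), assignment={("s1", "A"): "p0"}
        )


# ---------------------------------------------------------------------------
# stress


def test_stress_zero_for_monotone_distances():
    """Distances already a monotone transform of the dissimilarities fit
    perfectly."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 3.0]])
    d = pdist(coords)
    diss = squareform(np.sqrt(d))  # monotone transform
    assert stress1(coords, diss) == pytest.approx(0.0, abs=1e-12)


def test_stress_three_point_hand_case():
    """Hand-enumerated pooled-adjacent-violators on 3 pairs.

    Distances (AB, AC, BC) = (1, 2, sqrt 5); dissimilarity order AC < BC < AB
    gives the distance sequence (2, sqrt 5, 1), which PAV pools entirely into
    its mean m. Stress-1 = sqrt(sum (d - m)^2 / sum d^2).
    """
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    diss = np.array(
        [
            [0.0, 0.9, 0.1],
            [0.9, 0.0, 0.5],
            [0.1, 0.5, 0.0],
        ]
    )
    m = (2.0 + math.sqrt(5.0) + 1.0) / 3.0
    num = (1.0 - m) ** 2 + (2.0 - m) ** 2 + (math.sqrt(5.0) - m) ** 2
    expected = math.sqrt(num / (1.0 + 4.0 + 5.0))
    assert abs(stress1(coords, diss) - expected) < 1e-10


def test_stress_permutation_invariance(rng):
    coords = rng.normal(size=(7, 2))
    diss = squareform(rng.random(21))
    perm = rng.permutation(7)
    assert stress1(coords[perm], diss[np.ix_(perm, perm)]) == pytest.approx(
        stress1(coords, diss), abs=1e-12
    )


def test_stress_degenerate_zero_distances():
    with pytest.raises(DegenerateInputError):
        stress1(np.zeros((4, 2)), squareform(np.ones(6)))


# ---------------------------------------------------------------------------
# embedding


def pav_reference(values):
    """Independent pooled-adjacent-violators, pure python."""
    blocks = [[v, 1] for v in values]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            total = blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]
            n = blocks[i][1] + blocks[i + 1][1]
            blocks[i] = [total / n, n]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for value, n in blocks:
        out.extend([value] * n)
    return np.array(out)


def reference_stress1(coords, diss_mat):
    """Independent stress-1 evaluation using the pure-python PAV."""
    d = pdist(coords)
    delta = squareform(diss_mat, checks=False)
    order = np.lexsort((d, delta))
    dhat = np.empty_like(d)
    dhat[order] = pav_reference(d[order])
    return math.sqrt(((d - dhat) ** 2).sum() / (d**2).sum())


def sim_from_counts(counts, n_sorters):
    n = counts.shape[0]
    c = np.array(counts)
    np.fill_diagonal(c, n_sorters)
    return SimilarityMatrix(
        items=tuple(f"i{j}" for j in range(n)), counts=c, n_sorters=n_sorters
    )


def test_perfectly_embeddable_reaches_near_zero_stress():
    """Counts whose dissimilarities are exact plane distances (3-4-5
    rectangle) embed with stress < 1e-3."""
    c = np.zeros((4, 4), dtype=int)
    pairs = {(0, 1): 7, (2, 3): 7, (1, 2): 6, (0, 3): 6, (0, 2): 5, (1, 3): 5}
    for (a, b), v in pairs.items():
        c[a, b] = c[b, a] = v
    sim = sim_from_counts(c, 10)
    cfg = embed_map(sim, seed=0, n_starts=4)
    assert cfg.stress < 1e-3


def test_embedded_stress_matches_independent_evaluator(rng):
    sorts = random_sorts(rng, n_items=10, n_sorters=6, n_piles=3)
    sim = build_similarity(sorts)
    cfg = embed_map(sim, seed=3, n_starts=4)
    assert 0.0 <= cfg.stress <= 1.0
    assert abs(cfg.stress - reference_stress1(cfg.coords, sim.dissimilarity())) < 1e-8
    assert abs(cfg.stress - stress1(cfg.coords, sim.dissimilarity())) < 1e-8


def test_embedding_descent_is_monotone(rng):
    sorts = random_sorts(rng, n_items=12, n_sorters=6, n_piles=4)
    sim = build_similarity(sorts)
    cfg = embed_map(sim, seed=5, n_starts=3)
    history = np.array(cfg.stress_history)
    assert np.all(np.diff(history) <= 0.0)


def test_embedding_is_deterministic(rng):
    sorts = random_sorts(rng, n_items=9, n_sorters=5, n_piles=3)
    sim = build_similarity(sorts)
    a = embed_map(sim, seed=11, n_starts=3)
    b = embed_map(sim, seed=11, n_starts=3)
    assert np.array_equal(a.coords, b.coords)
    assert a.stress == b.stress


def test_embedding_input_errors():
    tiny = sim_from_counts(np.zeros((2, 2), dtype=int), 3)
    with pytest.raises(InputError):
        embed_map(tiny)
    constant = sim_from_counts(np.full((4, 4), 2), 4)
    with pytest.raises(DegenerateInputError):
        embed_map(constant)


# ---------------------------------------------------------------------------
# cluster ladder


def map_from_coords(coords):
    return MapConfiguration(
        items=tuple(f"i{j}" for j in range(len(coords))),
        coords=np.asarray(coords, dtype=float),
        stress=0.0,
        seed=0,
        n_starts=1,
    )


def brute_force_ward(coords, k_target):
    """Naive Ward agglomeration: repeatedly merge the pair with the smallest
    increase in within-cluster sum of squares."""
    clusters = [[i] for i in range(len(coords))]
    coords = np.asarray(coords, dtype=float)
    while len(clusters) > k_target:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = coords[clusters[a]], coords[clusters[b]]
                na, nb = len(ca), len(cb)
                delta = (
                    na * nb / (na + nb) * np.sum((ca.mean(0) - cb.mean(0)) ** 2)
                )
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(coords), dtype=int)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    return labels


def test_ladder_each_item_own_cluster(rng):
    coords = rng.normal(size=(6, 2))
    cfg = map_from_coords(coords)
    top = cluster_ladder(cfg, k_max=6, k_min=6)[0]
    assert len(set(top.labels.values())) == 6


def test_ladder_partitions_are_nested(rng):
    coords = rng.normal(size=(20, 2))
    cfg = map_from_coords(coords)
    ladder = cluster_ladder(cfg, k_max=15, k_min=2)
    for finer, coarser in zip(ladder, ladder[1:]):
        assert coarser.k == finer.k - 1
        # every finer cluster maps into exactly one coarser cluster
        mapping = {}
        for item in cfg.items:
            fc, cc = finer.labels[item], coarser.labels[item]
            assert mapping.setdefault(fc, cc) == cc


def test_ladder_recovers_blobs_and_matches_bruteforce_ward(rng):
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [20, 5], [5, 20]])
    blob = np.repeat(np.arange(6), 2)  # 12 points scattered over 6 blobs
    coords = centers[blob] + 0.05 * rng.normal(size=(12, 2))
    cfg = map_from_coords(coords[:10])
    for k in range(2, 10):
        sol = cluster_ladder(cfg, k_max=k, k_min=k)[0]
        ours = [sol.labels[i] for i in cfg.items]
        oracle = brute_force_ward(coords[:10], k)
        assert adjusted_rand_score(ours, oracle) == pytest.approx(1.0)
    full = map_from_coords(coords)
    sol6 = cluster_ladder(full, k_max=6, k_min=6)[0]
    assert adjusted_rand_score([sol6.labels[i] for i in full.items], blob) == 1.0


def test_ladder_input_errors(rng):
    cfg = map_from_coords(rng.normal(size=(5, 2)))
    with pytest.raises(InputError):
        cluster_ladder(cfg, k_max=2, k_min=3)
    with pytest.raises(InputError):
        cluster_ladder(cfg, k_max=6, k_min=2)


# ---------------------------------------------------------------------------
# bridging


def test_bridging_matches_bruteforce_double_loop():
    coords = np.array([[0, 0], [1, 0], [2, 0], [0, 2], [3, 3]], dtype=float)
    counts = np.array(
        [
            [5, 4, 1, 0, 1],
            [4, 5, 3, 1, 0],
            [1, 3, 5, 2, 2],
            [0, 1, 2, 5, 4],
            [1, 0, 2, 4, 5],
        ]
    )
    sim = sim_from_counts(counts, 5)
    cfg = map_from_coords(coords)
    values = bridging_values(cfg, sim)

    # oracle: explicit weighted mean distance, then min-max
    D = squareform(pdist(coords))
    raw = []
    for i in range(5):
        num = den = 0.0
        for j in range(5):
            if j != i:
                num += counts[i, j] * D[i, j]
                den += counts[i, j]
        raw.append(num / den)
    lo, hi = min(raw), max(raw)
    for i, item in enumerate(cfg.items):
        assert values[item] == pytest.approx((raw[i] - lo) / (hi - lo), abs=1e-12)
    assert min(values.values()) == 0.0
    assert max(values.values()) == 1.0


def test_bridging_degenerate_normalization_gives_zeros():
    """A fully symmetric design: equal counts and an equilateral triangle."""
    counts = np.full((3, 3), 2)
    sim = sim_from_counts(counts, 4)
    coords = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
    values = bridging_values(map_from_coords(coords), sim)
    assert all(v == 0.0 for v in values.values())


def test_bridging_undefined_item_is_nan(caplog):
    counts = np.array([[3, 2, 0], [2, 3, 0], [0, 0, 3]])
    sim = sim_from_counts(counts, 3)
    values = bridging_values(map_from_coords([[0, 0], [1, 0], [0, 1]]), sim)
    assert math.isnan(values["i2"])
    assert not math.isnan(values["i0"])


def test_bridging_isometry_invariance(rng):
    coords = rng.normal(size=(6, 2))
    counts = np.triu(rng.integers(0, 5, (6, 6)), 1)
    counts = counts + counts.T
    sim = sim_from_counts(counts, 5)
    base = bridging_values(map_from_coords(coords), sim)
    theta = 0.73
    R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    moved = coords @ R.T + np.array([3.0, -2.0])
    rotated = bridging_values(map_from_coords(moved), sim)
    for item in base:
        assert rotated[item] == pytest.approx(base[item], abs=1e-8)


# ---------------------------------------------------------------------------
# rating summary


def solution_from_labels(labels):
    return ClusterSolution(k=len(set(labels.values())), labels=labels)


def test_six_clusters_use_fifteen_comparisons_and_printed_threshold(rng):
    """k = 6 gives 15 pairwise tests at threshold 0.05/15, i.e. p < 0.0033,
    matching the conventional 'p < 0.003' reporting."""
    labels = {f"i{j}": j % 6 + 1 for j in range(18)}
    ratings = RatingDataset(
        {("r1", f"i{j}"): int(rng.integers(1, 7)) for j in range(18)}
    )
    summary = rating_summary(ratings, solution_from_labels(labels))
    assert summary.n_comparisons == 15
    assert summary.threshold == pytest.approx(0.05 / 15)
    assert 0.003 < summary.threshold < 0.0034
    assert len(summary.tests) == 15


def test_identical_ratings_yield_zero_t_and_no_significance():
    labels = {f"i{j}": j % 2 + 1 for j in range(8)}
    ratings = RatingDataset({("r1", f"i{j}"): 4 for j in range(8)})
    summary = rating_summary(ratings, solution_from_labels(labels))
    assert (summary.tests["t"] == 0.0).all()
    assert not summary.tests["significant"].any()


def test_shifted_cluster_is_significant_and_t_matches_formula(rng):
    """One cluster shifted upward with tiny within-cluster spread must flag
    its pairs, and the statistic must equal the textbook pooled-t formula."""
    labels = {f"i{j}": (1 if j < 5 else 2) for j in range(10)}
    ratings = {}
    for j in range(10):
        base = 2.0 if j < 5 else 5.0
        for r in range(4):
            ratings[(f"r{r}", f"i{j}")] = int(
                np.clip(np.rint(base + rng.normal(0, 0.2)), 1, 6)
            )
    ds = RatingDataset(ratings)
    summary = rating_summary(ds, solution_from_labels(labels))
    row = summary.tests.iloc[0]
    assert row["significant"]

    means = ds.item_means()
    a = np.array([means[f"i{j}"] for j in range(5)])
    b = np.array([means[f"i{j}"] for j in range(5, 10)])
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    t_oracle = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    assert row["t"] == pytest.approx(t_oracle, abs=1e-10)


def test_small_cluster_pair_marked_not_computable():
    labels = {"i0": 1, "i1": 2, "i2": 2}
    ratings = RatingDataset({("r1", i): 3 for i in labels})
    summary = rating_summary(ratings, solution_from_labels(labels))
    assert not summary.tests["computable"].iloc[0]


# ---------------------------------------------------------------------------
# reliability


def test_identical_sorters_are_perfectly_reliable():
    piles = [["A", "B"], ["C", "D"]]
    sorts = make_sorts({f"s{j}": piles for j in range(4)})
    rel = sorter_reliability(sorts)
    assert all(r == pytest.approx(1.0) for r in rel.per_sorter_r.values())
    assert rel.mean_r == pytest.approx(1.0)
    assert rel.sb_corrected == pytest.approx(1.0)


def test_reliability_matches_hand_enumerated_pearson():
    sorts = make_sorts(
        {
            "s1": [["A", "B"], ["C", "D", "E"]],
            "s2": [["A", "B", "C"], ["D", "E"]],
            "s3": [["A"], ["B", "C"], ["D", "E"]],
            "s4": [["A", "B"], ["C"], ["D", "E"]],
        }
    )
    rel = sorter_reliability(sorts, spearman_brown=False)

    # oracle: enumerate the 10 pairs per sorter and compute Pearson by formula
    items = sorts.items
    pairs = [(a, b) for ai, a in enumerate(items) for b in items[ai + 1 :]]

    def copile_vec(s):
        return np.array(
            [
                1.0 if sorts.assignment[(s, a)] == sorts.assignment[(s, b)] else 0.0
                for a, b in pairs
            ]
        )

    for s in sorts.sorters:
        x = copile_vec(s)
        ref = sum(copile_vec(t) for t in sorts.sorters if t != s)
        xm, rm = x - x.mean(), ref - ref.mean()
        r_oracle = (xm * rm).sum() / math.sqrt((xm**2).sum() * (rm**2).sum())
        assert rel.per_sorter_r[s] == pytest.approx(r_oracle, abs=1e-12)
    assert rel.sb_corrected is None
    assert not rel.correction_applied


def test_random_sorters_have_near_zero_reliability():
    means = []
    for rep in range(20):
        rng = np.random.default_rng(900 + rep)
        sorts = random_sorts(rng, n_items=60, n_sorters=8, n_piles=6)
        means.append(sorter_reliability(sorts).mean_r)
    assert abs(np.mean(means)) < 0.1


def test_spearman_brown_exceeds_mean_r():
    rng = np.random.default_rng(5)
    sorts = random_sorts(rng, n_items=20, n_sorters=6, n_piles=4)
    rel = sorter_reliability(sorts, spearman_brown=True)
    if 0.0 < rel.mean_r < 1.0:
        assert rel.sb_corrected >= rel.mean_r


def test_reliability_needs_two_valid_sorters():
    sorts = make_sorts({"s1": [["A", "B"], ["C"]], "lump": [["A", "B", "C"]]})
    with pytest.raises(InputError):
        sorter_reliability(sorts)


def test_mean_pile_count():
    sorts = make_sorts(
        {"s1": [["A", "B"], ["C", "D"]], "s2": [["A"], ["B"], ["C", "D"]]}
    )
    assert mean_pile_count(sorts) == pytest.approx(2.5)
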