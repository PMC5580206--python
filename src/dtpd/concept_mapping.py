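"""Group concept mapping analytics.

Turns expert card sorts into a co-occurrence similarity matrix, embeds the
items in the plane by nonmetric multidimensional scaling, builds the
agglomerative cluster ladder, computes bridging values, summarizes 1-6
relevance ratings per cluster, and estimates sorter reliability.

The pipeline follows the classical concept-mapping tradition (Kane &
Trochim): similarity is the number of sorters who co-piled two items, the
map is a 2-D nonmetric scaling of the complementary dissimilarity, clusters
are Ward merges of the map coordinates, and bridging measures whether an
item was co-sorted mainly with nearby (low) or distant (high) items.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SortingDataset",
    "RatingDataset",
    "SimilarityMatrix",
    "MapConfiguration",
    "ClusterSolution",
    "RatingSummary",
    "ReliabilityReport",
    "build_similarity",
    "stress1",
    "embed_map",
    "cluster_ladder",
    "bridging_values",
    "rating_summary",
    "sorter_reliability",
    "mean_pile_count",
]


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class SortingDataset:
    """Complete card sorts: every sorter assigns every item to exactly one pile.

    Pile labels are local to each sorter; only co-membership matters.
    """

    items: tuple[str, ...]
    sorters: tuple[str, ...]
    assignment: Mapping[tuple[str, str], str]
    item_text: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise InputError("a sorting dataset needs at least 2 items")
        if len(self.sorters) < 1:
            raise InputError("a sorting dataset needs at least 1 sorter")
        if len(set(self.items)) != len(self.items):
            raise InputError("duplicate item identifiers")
        if len(set(self.sorters)) != len(self.sorters):
            raise InputError("duplicate sorter identifiers")
        expected = {(s, i) for s in self.sorters for i in self.items}
        got = set(self.assignment)
        if got != expected:
            missing = sorted(expected - got)[:3]
            extra = sorted(got - expected)[:3]
            raise InputError(
                "incomplete sort: every (sorter, item) pair needs exactly one "
                f"pile label (missing e.g. {missing}, unexpected e.g. {extra})"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    def pile_labels(self, sorter: str) -> np.ndarray:
        """Integer pile codes for one sorter, aligned with ``items``."""
        raw = [self.assignment[(sorter, i)] for i in self.items]
        _, codes = np.unique(raw, return_inverse=True)
        return codes

    def piles_of(self, sorter: str) -> dict[str, list[str]]:
        piles: dict[str, list[str]] = {}
        for item in self.items:
            piles.setdefault(self.assignment[(sorter, item)], []).append(item)
        return piles

    def is_valid_sorter(self, sorter: str) -> bool:
        """A sort is invalid if all items share one pile or every item is alone."""
        n_piles = len(set(self.assignment[(sorter, i)] for i in self.items))
        return 1 < n_piles < self.n_items

    def valid_sorters(self) -> tuple[str, ...]:
        return tuple(s for s in self.sorters if self.is_valid_sorter(s))

    def copile_matrix(self, sorter: str) -> np.ndarray:
        """Binary N x N co-pile matrix for one sorter (diagonal = 1)."""
        codes = self.pile_labels(sorter)
        return (codes[:, None] == codes[None, :]).astype(int)


@dataclass(frozen=True)
class RatingDataset:
    """Relevance ratings on the 1-6 integer scale; missing entries allowed."""

    ratings: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (rater, item), value in self.ratings.items():
            if not (isinstance(value, (int, np.integer)) and 1 <= value <= 6):
                raise InputError(
                    f"rating for ({rater!r}, {item!r}) is {value!r}; "
                    "ratings must be integers in [1, 6]"
                )

    def raters(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(r for r, _ in self.ratings))

    def rated_items(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(i for _, i in self.ratings))

    def item_means(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for (_, item), value in self.ratings.items():
            sums[item] = sums.get(item, 0.0) + value
            counts[item] = counts.get(item, 0) + 1
        return {item: sums[item] / counts[item] for item in sums}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Co-sort counts: entry (i, j) = number of sorters who co-piled i and j."""

    items: tuple[str, ...]
    counts: np.ndarray
    n_sorters: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.items), len(self.items)):
            raise InputError("counts must be N x N for N items")
        if not np.array_equal(c, c.T):
            raise InputError("similarity counts must be symmetric")
        if c.min() < 0 or c.max() > self.n_sorters:
            raise InputError("counts must lie in [0, n_sorters]")
        if not np.all(np.diag(c) == self.n_sorters):
            raise InputError("diagonal must equal n_sorters")

    def dissimilarity(self) -> np.ndarray:
        """delta(i, j) = (n_sorters - counts(i, j)) / n_sorters, in [0, 1]."""
        d = (self.n_sorters - self.counts.astype(float)) / self.n_sorters
        np.fill_diagonal(d, 0.0)
        return d


@dataclass(frozen=True)
class MapConfiguration:
    """2-D nonmetric scaling solution with its Kruskal stress-1 value."""

    items: tuple[str, ...]
    coords: np.ndarray
    stress: float
    seed: int
    n_starts: int
    stress_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.stress <= 1.0):
            raise InputError(f"stress-1 must lie in [0, 1], got {self.stress}")


@dataclass(frozen=True)
class ClusterSolution:
    """One rung of the cluster ladder: a partition of the items into k clusters."""

    k: int
    labels: Mapping[str, int]
    item_bridging: Mapping[str, float] | None = None
    cluster_bridging: Mapping[int, float] | None = None
    cluster_rating_mean: Mapping[int, float] | None = None

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, c in self.labels.items():
            out.setdefault(c, []).append(item)
        return out

    def with_bridging(self, item_bridging: Mapping[str, float]) -> "ClusterSolution":
        """Attach item bridging values; cluster bridging is the plain mean of members."""
        cb = {
            c: float(np.mean([item_bridging[i] for i in items]))
            for c, items in self.members().items()
        }
        return replace(self, item_bridging=dict(item_bridging), cluster_bridging=cb)

    def with_ratings(self, ratings: RatingDataset) -> "ClusterSolution":
        means = ratings.item_means()
        cm = {
            c: float(np.mean([means[i] for i in items]))
            for c, items in self.members().items()
        }
        return replace(self, cluster_rating_mean=cm)


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-sorter correlation with the group sort and the panel average."""

    per_sorter_r: Mapping[str, float]
    mean_r: float
    sb_corrected: float | None
    correction_applied: bool
    excluded: tuple[str, ...] = ()
    leave_one_out: bool = True


@dataclass(frozen=True)
class RatingSummary:
    """Per-cluster mean ratings with the Bonferroni-corrected pairwise t-tests."""

    cluster_means: Mapping[int, float]
    threshold: float
    n_comparisons: int
    tests: pd.DataFrame


# ---------------------------------------------------------------------------
# operations


def build_similarity(sorts: SortingDataset, exclude_invalid: bool = True) -> SimilarityMatrix:
    """Count, over retained sorters, how often each pair of items was co-piled."""
    sorters = sorts.valid_sorters() if exclude_invalid else sorts.sorters
    if not sorters:
        raise InputError(
            "no sorter left after excluding invalid sorts (a sort is invalid "
            "when all items share one pile or every item is alone)"
        )
    n = sorts.n_items
    counts = np.zeros((n, n), dtype=int)
    for s in sorters:
        codes = sorts.pile_labels(s)
        counts += codes[:, None] == codes[None, :]
    return SimilarityMatrix(items=sorts.items, counts=counts, n_sorters=len(sorters))


def _monotone_disparities(dist: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Kruskal disparities: isotonic regression of map distances on the rank
    order of dissimilarities, primary tie handling (ties broken by distance,
    so tied dissimilarities may receive unequal disparities)."""
    order = np.lexsort((dist, diss))
    fitted = isotonic_regression(dist[order]).x
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return dhat


def stress1(coords: np.ndarray, dissimilarities: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    stress1 = sqrt( sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2 ), where
    d are Euclidean map distances and dhat the monotone-regression disparities.
    """
    X = np.asarray(coords, dtype=float)
    D = np.asarray(dissimilarities, dtype=float)
    if D.ndim == 2:
        diss = squareform(D, checks=False)
    else:
        diss = D
    d = pdist(X)
    if d.shape != diss.shape:
        raise InputError("coords and dissimilarities disagree on the number of items")
    denom = float(np.sum(d**2))
    if denom == 0.0:
        raise DegenerateInputError("all map distances are zero; stress undefined")
    dhat = _monotone_disparities(d, diss)
    return float(math.sqrt(np.sum((d - dhat) ** 2) / denom))


def _stress_or_inf(X: np.ndarray, diss: np.ndarray) -> float:
    d = pdist(X)
    denom = float(np.sum(d**2))
    if denom == 0.0:
        return float("inf")
    dhat = _monotone_disparities(d, diss)
    return float(math.sqrt(np.sum((d - dhat) ** 2) / denom))


def _classical_init(delta: np.ndarray, n_dims: int) -> np.ndarray:
    """Torgerson double-centering of the squared dissimilarities as a warm start."""
    n = delta.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (delta**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_dims]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def _smacof_nonmetric(
    X0: np.ndarray, diss: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    """One start of nonmetric scaling by iterative majorization.

    Each sweep fits disparities by pooled-adjacent-violators and applies the
    Guttman transform; an update is accepted only if stress-1 decreases, so
    the recorded history is non-increasing by construction.
    """
    n = X0.shape[0]
    X = X0 - X0.mean(axis=0)
    history = [_stress_or_inf(X, diss)]
    for _ in range(max_iter):
        d = pdist(X)
        dhat = _monotone_disparities(d, diss)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        R = squareform(ratio)
        B = np.diag(R.sum(axis=1)) - R
        X_new = (B @ X) / n
        s_new = _stress_or_inf(X_new, diss)
        if not (s_new < history[-1] - 1e-15):
            break
        X = X_new
        history.append(s_new)
        if history[-2] - history[-1] < tol:
            break
    return X, history[-1], history


def embed_map(
    sim: SimilarityMatrix,
    n_dims: int = 2,
    seed: int = 0,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> MapConfiguration:
    """Embed the items in ``n_dims`` dimensions by nonmetric scaling.

    Dissimilarity is the complementary co-sort fraction
    ``(n_sorters - counts) / n_sorters``. The first start is a classical
    (Torgerson) scaling of the dissimilarities; the remaining ``n_starts - 1``
    are random. The lowest-stress configuration wins, and the reported stress
    is exactly :func:`stress1` of the returned coordinates.
    """
    n = len(sim.items)
    if n < 3:
        raise InputError("scaling needs at least 3 items")
    delta = sim.dissimilarity()
    diss = squareform(delta, checks=False)
    if np.ptp(diss) == 0.0:
        raise DegenerateInputError(
            "constant dissimilarities: every pair is equally (dis)similar, "
            "no informative configuration exists"
        )
    rng = np.random.default_rng(seed)
    inits = [_classical_init(delta, n_dims)]
    inits += [rng.standard_normal((n, n_dims)) for _ in range(max(0, n_starts - 1))]

    best: tuple[np.ndarray, float, list[float]] | None = None
    for X0 in inits:
        X, s, history = _smacof_nonmetric(X0, diss, max_iter, tol)
        if best is None or s < best[1]:
            best = (X, s, history)
    assert best is not None
    X, s, history = best
    return MapConfiguration(
        items=sim.items,
        coords=X,
        stress=s,
        seed=seed,
        n_starts=n_starts,
        stress_history=tuple(history),
    )


def cluster_ladder(
    map_config: MapConfiguration, k_max: int = 15, k_min: int = 2
) -> list[ClusterSolution]:
    """Ward agglomeration of the map coordinates from ``k_max`` down to ``k_min``.

    Consecutive solutions are nested: each step merges exactly two clusters,
    so the k-1 partition coarsens the k partition.
    """
    n = len(map_config.items)
    if k_min > k_max:
        raise InputError(f"k_min={k_min} exceeds k_max={k_max}")
    if k_min < 1 or k_max > n:
        raise InputError(f"need 1 <= k_min <= k_max <= {n} items")
    Z = hierarchy.linkage(map_config.coords, method="ward")
    solutions = []
    for k in range(k_max, k_min - 1, -1):
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        # relabel to 1..k in order of first appearance for stable output
        remap: dict[int, int] = {}
        labels = {}
        for item, c in zip(map_config.items, raw):
            labels[item] = remap.setdefault(int(c), len(remap) + 1)
        solutions.append(ClusterSolution(k=k, labels=labels))
    return solutions


def bridging_values(
    map_config: MapConfiguration, sim: SimilarityMatrix
) -> dict[str, float]:
    """Co-sort-weighted mean map distance per item, min-max normalized to [0, 1].

    Raw value ``b_i = sum_j counts(i,j) d_ij / sum_j counts(i,j)`` over j != i.
    An item co-sorted mainly with far-away items scores near 1. Items never
    co-piled with anything get NaN (undefined, with a logged warning). If all
    raw values coincide the normalization is degenerate and all defined values
    are returned as 0.
    """
    if map_config.items != sim.items:
        raise InputError("map and similarity matrix cover different items")
    n = len(sim.items)
    if n < 2:
        raise InputError("bridging needs at least 2 items")
    D = squareform(pdist(map_config.coords))
    C = sim.counts.astype(float).copy()
    np.fill_diagonal(C, 0.0)
    weight = C.sum(axis=1)
    raw = np.full(n, np.nan)
    ok = weight > 0
    raw[ok] = (C * D).sum(axis=1)[ok] / weight[ok]
    if not np.all(ok):
        undefined = [sim.items[i] for i in np.flatnonzero(~ok)]
        logger.warning(
            "bridging undefined (never co-piled with any other item): %s", undefined
        )
    defined = raw[ok]
    values = np.full(n, np.nan)
    if defined.size:
        lo, hi = float(defined.min()), float(defined.max())
        if hi - lo > 1e-12 * max(1.0, abs(hi)):
            values[ok] = (raw[ok] - lo) / (hi - lo)
        else:
            values[ok] = 0.0  # degenerate normalization: fully symmetric design
    return dict(zip(sim.items, values))


def rating_summary(
    ratings: RatingDataset, solution: ClusterSolution, alpha: float = 0.05
) -> RatingSummary:
    """Cluster mean ratings and all pairwise two-sample t-tests on the
    item-level mean ratings, Bonferroni-corrected over k(k-1)/2 comparisons."""
    if solution.k < 2:
        raise InputError("rating comparison needs at least 2 clusters")
    item_means = ratings.item_means()
    missing = [i for i in solution.labels if i not in item_means]
    if missing:
        raise InputError(f"items without any rating: {missing[:5]}")
    members = solution.members()
    cluster_values = {c: np.array([item_means[i] for i in items]) for c, items in members.items()}
    cluster_means = {c: float(v.mean()) for c, v in cluster_values.items()}
    n_comp = solution.k * (solution.k - 1) // 2
    threshold = alpha / n_comp
    rows = []
    clusters = sorted(cluster_values)
    for a_idx, ca in enumerate(clusters):
        for cb in clusters[a_idx + 1 :]:
            va, vb = cluster_values[ca], cluster_values[cb]
            computable = len(va) >= 2 and len(vb) >= 2
            if computable:
                if va.var(ddof=1) == 0.0 and vb.var(ddof=1) == 0.0:
                    # pooled variance zero: identical means give t = 0, else +/-inf
                    diff = va.mean() - vb.mean()
                    t = 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
                    p = 1.0 if diff == 0.0 else 0.0
                else:
                    t, p = stats.ttest_ind(va, vb)
                df = len(va) + len(vb) - 2
                sig = bool(p < threshold)
            else:
                t = p = df = float("nan")
                sig = False
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "t": float(t) if computable else np.nan,
                    "df": df,
                    "p": float(p) if computable else np.nan,
                    "significant": sig,
                    "computable": computable,
                }
            )
    return RatingSummary(
        cluster_means=cluster_means,
        threshold=threshold,
        n_comparisons=n_comp,
        tests=pd.DataFrame(rows),
    )


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def sorter_reliability(
    sorts: SortingDataset,
    spearman_brown: bool = True,
    leave_one_out: bool = True,
) -> ReliabilityReport:
    """Correlate each valid sorter's binary co-pile matrix with the group matrix.

    By default the group matrix excludes the sorter being evaluated
    (leave-one-out), which avoids self-correlation inflation. Sorters whose
    co-pile vector (or reference vector) is constant have an undefined
    correlation and are excluded with a logged warning. With
    ``spearman_brown`` the panel-level reliability k*r / (1 + (k-1)*r) is
    also reported, k = number of sorters entering the average.
    """
    valid = sorts.valid_sorters()
    if len(valid) < 2:
        raise InputError("reliability needs at least 2 valid sorters")
    vecs = {s: _upper(sorts.copile_matrix(s)).astype(float) for s in valid}
    total = np.sum(list(vecs.values()), axis=0)
    per_sorter: dict[str, float] = {}
    excluded: list[str] = []
    for s in valid:
        x = vecs[s]
        ref = total - x if leave_one_out else total
        if x.std() == 0.0 or ref.std() == 0.0:
            logger.warning("sorter %r has a constant co-pile vector; correlation undefined", s)
            excluded.append(s)
            continue
        per_sorter[s] = float(np.corrcoef(x, ref)[0, 1])
    if not per_sorter:
        raise DegenerateInputError("no sorter with a defined correlation")
    mean_r = float(np.mean(list(per_sorter.values())))
    k = len(per_sorter)
    sb = k * mean_r / (1.0 + (k - 1) * mean_r) if spearman_brown else None
    return ReliabilityReport(
        per_sorter_r=per_sorter,
        mean_r=mean_r,
        sb_corrected=sb,
        correction_applied=spearman_brown,
        excluded=tuple(excluded),
        leave_one_out=leave_one_out,
    )


def mean_pile_count(sorts: SortingDataset, valid_only: bool = True) -> float:
    """Average number of piles per sorter — a diagnostic the working group
    uses when choosing the number of clusters."""
    sorters = sorts.valid_sorters() if valid_only else sorts.sorters
    if not sorters:
        raise InputError("no sorters to average over")
    return float(np.mean([len(sorts.piles_of(s)) for s in sorters]))
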