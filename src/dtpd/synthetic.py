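"""Synthetic study generators.

Emulates the two data sources the analysis pipeline consumes: an expert
card-sort-and-rate study (by default 95 items sorted by 22 experts who
perturb a 6-cluster latent structure) and a multi-centre patient cohort
(by default 368 patients across 7 centres) whose referral judgement follows
a logistic model on the seven criteria with within-centre correlation.

Every generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .concept_mapping import RatingDataset, SortingDataset
from .decision_tool import NA, NO, YES, PatientRecord
from .errors import InputError

logger = logging.getLogger(__name__)

# Simulation truth for the log-odds effects of the seven criteria on the
# referral judgement. The magnitudes follow the validated tool's fitted
# model: strong effects for negative affect, comorbidity and failed prior
# treatment; near-null effects for traumatisation and therapeutic-relation
# difficulties.
DEFAULT_CRITERION_EFFECTS: tuple[float, ...] = (
    2.530693,   # severe negative affect with disadaptive coping
    0.917365,   # severe destructive behaviour to oneself or others
    1.737646,   # multiple comorbid axis I/II disorders
    0.825936,   # severe social and societal dysfunction (GAF)
    0.214238,   # severe chronic traumatisation in childhood
    -0.004092,  # difficulties developing a therapeutic relationship
    1.208202,   # treatment in specialized care was not successful
)

# referral prevalence the intercept is calibrated to (110 of 378 judged
# in need of highly specialized care in the validation cohort tables)
DEFAULT_TARGET_PREVALENCE = 110 / 378

__all__ = [
    "SortSimConfig",
    "PatientSimConfig",
    "DEFAULT_CRITERION_EFFECTS",
    "simulate_sorting",
    "simulate_ratings",
    "simulate_patients",
    "calibrate_intercept",
]


@dataclass(frozen=True)
class SortSimConfig:
    """Card-sort simulator settings.

    Each sorter starts from the latent partition, may split piles
    (probability ``split_prob`` per pile) and merge one random pile pair
    (probability ``merge_prob``), then reassigns each item to a random other
    pile with probability ``noise``. The split/merge defaults push the mean
    pile count per sorter toward ~10, matching what expert panels typically
    produce over ~95 statements; ``noise`` = 0.15 yields maps with stress in
    the range concept-mapping studies report as a reasonable fit.
    """

    n_items: int = 95
    n_sorters: int = 22
    n_true_clusters: int = 6
    noise: float = 0.15
    split_prob: float = 0.6
    merge_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise", "split_prob", "merge_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InputError(f"{name} must lie in [0, 1], got {p}")
        if self.n_true_clusters > self.n_items:
            raise InputError("n_true_clusters cannot exceed n_items")
        if self.n_items < 2 or self.n_sorters < 1 or self.n_true_clusters < 1:
            raise InputError("need n_items >= 2, n_sorters >= 1, n_true_clusters >= 1")


def simulate_sorting(config: SortSimConfig) -> tuple[SortingDataset, dict[str, int]]:
    """Generate a sorting study plus its latent ground-truth partition."""
    if config.noise >= 1.0 and config.n_true_clusters == config.n_items:
        warnings.warn(
            "noise=1 with every item its own cluster is unrecoverable by design",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    items = tuple(f"item_{i + 1:03d}" for i in range(config.n_items))
    truth_codes = np.repeat(
        np.arange(config.n_true_clusters),
        -(-config.n_items // config.n_true_clusters),
    )[: config.n_items]
    rng.shuffle(truth_codes)
    truth = {item: int(c) + 1 for item, c in zip(items, truth_codes)}

    sorters = tuple(f"sorter_{s + 1:02d}" for s in range(config.n_sorters))
    assignment: dict[tuple[str, str], str] = {}
    for sorter in sorters:
        piles: list[list[str]] = [
            [i for i in items if truth[i] == c]
            for c in range(1, config.n_true_clusters + 1)
        ]
        piles = [p for p in piles if p]
        # structural perturbations: split piles, then possibly merge one pair
        new_piles: list[list[str]] = []
        for pile in piles:
            if len(pile) >= 2 and rng.random() < config.split_prob:
                perm = list(pile)
                rng.shuffle(perm)
                cut = int(rng.integers(1, len(perm)))
                new_piles.extend([perm[:cut], perm[cut:]])
            else:
                new_piles.append(list(pile))
        piles = new_piles
        if len(piles) >= 2 and rng.random() < config.merge_prob:
            a, b = rng.choice(len(piles), size=2, replace=False)
            piles[a].extend(piles[b])
            del piles[b]
        # item-level noise: move items to a random other pile
        if len(piles) >= 2:
            membership = {i: idx for idx, pile in enumerate(piles) for i in pile}
            for item in items:
                if rng.random() < config.noise:
                    current = membership[item]
                    target = int(rng.integers(0, len(piles) - 1))
                    if target >= current:
                        target += 1
                    piles[current].remove(item)
                    piles[target].append(item)
                    membership[item] = target
            piles = [p for p in piles if p]
        for idx, pile in enumerate(piles):
            for item in pile:
                assignment[(sorter, item)] = f"pile_{idx + 1:02d}"
    return SortingDataset(items=items, sorters=sorters, assignment=assignment), truth


def simulate_ratings(
    labels: dict[str, int],
    cluster_means: dict[int, float],
    sd: float = 0.5,
    n_raters: int = 22,
    seed: int = 0,
) -> RatingDataset:
    """Integer 1-6 ratings: clipped, rounded Gaussians around each item's
    cluster mean."""
    if sd < 0:
        raise InputError("sd must be non-negative")
    for c, m in cluster_means.items():
        if not (1.0 <= m <= 6.0):
            raise InputError(f"cluster mean for {c} must lie in [1, 6], got {m}")
    missing = set(labels.values()) - set(cluster_means)
    if missing:
        raise InputError(f"no mean for clusters {sorted(missing)}")
    rng = np.random.default_rng(seed)
    ratings: dict[tuple[str, str], int] = {}
    for r in range(n_raters):
        rater = f"rater_{r + 1:02d}"
        for item, cluster in labels.items():
            value = rng.normal(cluster_means[cluster], sd)
            ratings[(rater, item)] = int(np.clip(np.rint(value), 1, 6))
    return RatingDataset(ratings=ratings)


@dataclass(frozen=True)
class PatientSimConfig:
    """Multi-centre cohort simulator settings.

    Criteria are correlated binaries from a Gaussian copula with exchangeable
    latent correlation, thresholded at their prevalences. The referral
    judgement is Bernoulli with logit = intercept + centre shift + effects x
    criteria; centre shifts are Gaussian, creating within-centre correlation.
    ``intercept=None`` auto-calibrates (by bisection on a fixed Monte-Carlo
    draw) so the marginal referral prevalence hits ``target_prevalence``.
    """

    n_patients: int = 368
    n_centres: int = 7
    n_therapists: int = 88
    true_coefficients: tuple[float, ...] = DEFAULT_CRITERION_EFFECTS
    intercept: float | None = None
    centre_effect_sd: float = 0.5
    criterion_prevalences: tuple[float, ...] = (0.5,) * 7
    criterion_correlation: float = 0.35
    na_rate_c6: float = 0.05
    na_rate_c7: float = 0.05
    na_rate_q8: float = 0.05
    gate_yes_prob_referral: float = 0.9
    gate_yes_prob_no_referral: float = 0.5
    target_prevalence: float = DEFAULT_TARGET_PREVALENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_coefficients) != 7 or len(self.criterion_prevalences) != 7:
            raise InputError("coefficients and prevalences must have length 7")
        if not all(0.0 < p < 1.0 for p in self.criterion_prevalences):
            raise InputError("criterion prevalences must lie in (0, 1)")
        if not (0.0 <= self.criterion_correlation < 1.0):
            raise InputError("criterion_correlation must lie in [0, 1)")
        if self.n_centres < 2:
            raise InputError("need at least 2 centres")
        if self.n_patients < self.n_centres:
            raise InputError("need at least one patient per centre")
        for name in ("na_rate_c6", "na_rate_c7", "na_rate_q8",
                     "gate_yes_prob_referral", "gate_yes_prob_no_referral"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InputError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.target_prevalence < 1.0):
            raise InputError("target_prevalence must lie in (0, 1)")
        if self.centre_effect_sd < 0:
            raise InputError("centre_effect_sd must be non-negative")


def _latent_criteria(
    rng: np.random.Generator, n: int, prevalences: np.ndarray, rho: float
) -> np.ndarray:
    """Exchangeable Gaussian copula, thresholded to 0/1 at the prevalences."""
    shared = rng.standard_normal(n)
    noise = rng.standard_normal((n, 7))
    z = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * noise
    return (z < norm.ppf(prevalences)[None, :]).astype(int)


def calibrate_intercept(config: PatientSimConfig, n_mc: int = 100_000) -> float:
    """Bisection for the intercept hitting the target referral prevalence.

    Uses a fixed internal Monte-Carlo draw so the result depends only on the
    distributional settings, not on the simulation seed.
    """
    rng = np.random.default_rng(20170831)
    X = _latent_criteria(
        rng, n_mc, np.asarray(config.criterion_prevalences), config.criterion_correlation
    )
    shift = rng.normal(0.0, config.centre_effect_sd, n_mc)
    base = X @ np.asarray(config.true_coefficients) + shift

    def prevalence(b: float) -> float:
        return float(np.mean(expit(base + b)))

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < config.target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_patients(
    config: PatientSimConfig,
) -> tuple[list[PatientRecord], dict]:
    """Generate a multi-centre cohort plus the ground-truth parameters."""
    rng = np.random.default_rng(config.seed)
    intercept = (
        config.intercept if config.intercept is not None else calibrate_intercept(config)
    )
    n = config.n_patients
    centre_idx = np.arange(n) % config.n_centres
    therapists_per_centre = max(1, config.n_therapists // config.n_centres)
    therapist_idx = rng.integers(0, therapists_per_centre, n)
    centre_effects = rng.normal(0.0, config.centre_effect_sd, config.n_centres)

    X = _latent_criteria(
        rng, n, np.asarray(config.criterion_prevalences), config.criterion_correlation
    )
    lp = intercept + centre_effects[centre_idx] + X @ np.asarray(config.true_coefficients)
    judged = rng.random(n) < expit(lp)
    gate_true = rng.random(n) < np.where(
        judged, config.gate_yes_prob_referral, config.gate_yes_prob_no_referral
    )
    na_c6 = rng.random(n) < config.na_rate_c6
    na_c7 = rng.random(n) < config.na_rate_c7
    na_q8 = rng.random(n) < config.na_rate_q8

    records = []
    for i in range(n):
        answers = [YES if X[i, j] else NO for j in range(7)]
        if na_c6[i]:
            answers[5] = NA
        if na_c7[i]:
            answers[6] = NA
        gate = NA if na_q8[i] else (YES if gate_true[i] else NO)
        records.append(
            PatientRecord(
                centre_id=f"centre_{centre_idx[i] + 1}",
                therapist_id=f"centre_{centre_idx[i] + 1}_therapist_{therapist_idx[i] + 1}",
                answers=tuple(answers),
                gate_q8=gate,
                clinical_judgement=bool(judged[i]),
            )
        )
    truth = {
        "coefficients": tuple(config.true_coefficients),
        "intercept": float(intercept),
        "centre_effects": centre_effects,
        "criterion_matrix": X,
        "prevalence": float(np.mean(judged)),
    }
    return records, truth
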