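"""Validation analytics for the decision rule.

Covers the pilot agreement percentages, the clustered marginal logistic
model (generalized estimating equations with exchangeable working
correlation, clustered by treatment centre), the ROC curve and its AUC with
a DeLong confidence interval, the cut-off sensitivity/specificity table,
Cronbach's alpha for the seven binary criteria, and Welch two-sample tests
from summary statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .decision_tool import NA, YES, PatientRecord, ToolConfig, score_patient
from .errors import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

COEF_NAMES = ("intercept",) + tuple(f"c{i}" for i in range(1, 8))

__all__ = [
    "GEEFit",
    "AUCResult",
    "CutoffTable",
    "WelchResult",
    "ValidationReport",
    "design_matrix",
    "pilot_agreement",
    "fit_marginal_logistic",
    "roc_auc",
    "cutoff_table",
    "cronbach_alpha",
    "welch_t",
    "validate_cohort",
]


def design_matrix(
    records: Sequence[PatientRecord], cluster_by: str = "centre_id"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0/1 criterion matrix (NA coded as no, mirroring the tool's policy),
    binary judgement outcome, and the cluster id per record."""
    if not records:
        raise InputError("no records")
    if cluster_by not in ("centre_id", "therapist_id"):
        raise InputError(f"unknown cluster variable {cluster_by!r}")
    X = np.array([[1 if a == YES else 0 for a in r.answers] for r in records], dtype=float)
    y = np.array([1 if r.clinical_judgement else 0 for r in records], dtype=float)
    groups = np.array([getattr(r, cluster_by) for r in records])
    return X, y, groups


def pilot_agreement(
    records: Sequence[PatientRecord], definition: str = "agreement"
) -> dict[int, float]:
    """Per-criterion similarity with the clinical judgement, as a percentage.

    ``definition="agreement"`` (default): share of records where the criterion
    answer matches the judgement (yes with referral, no with no referral);
    records with NA on that criterion are left out of its denominator.
    ``definition="joint_positive"``: share of all records where the criterion
    is yes and the clinician judged referral.
    """
    if not records:
        raise InputError("no records")
    if definition not in ("agreement", "joint_positive"):
        raise InputError(f"unknown definition {definition!r}")
    out: dict[int, float] = {}
    for pos in range(7):
        answers = [r.answers[pos] for r in records]
        judged = [r.clinical_judgement for r in records]
        if definition == "agreement":
            pairs = [(a, j) for a, j in zip(answers, judged) if a != NA]
            if not pairs:
                logger.warning("criterion %d entirely NA; agreement not computable", pos + 1)
                out[pos + 1] = float("nan")
                continue
            agree = sum(1 for a, j in pairs if (a == YES) == j)
            out[pos + 1] = 100.0 * agree / len(pairs)
        else:
            joint = sum(1 for a, j in zip(answers, judged) if a == YES and j)
            out[pos + 1] = 100.0 * joint / len(records)
    return out


@dataclass(frozen=True)
class GEEFit:
    """Marginal logistic model fit: coefficients, robust inference, the
    working-correlation parameter and the per-record linear predictor."""

    params: Mapping[str, float]
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    working_corr: float | None
    linear_predictor: np.ndarray
    method: str
    n_obs: int
    n_clusters: int

    def __post_init__(self) -> None:
        for p in self.pvalues.values():
            if np.isfinite(p) and not (0.0 <= p <= 1.0):
                raise InputError("p-values must lie in [0, 1]")


def _check_separation(params: np.ndarray) -> None:
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15.0:
        raise DegenerateInputError(
            "logistic fit diverged (coefficient magnitude > 15): the data are "
            "(quasi-)completely separated; remove or merge the offending criterion"
        )


def fit_marginal_logistic(
    records: Sequence[PatientRecord],
    cluster_by: str = "centre_id",
    cov_struct: str = "exchangeable",
) -> GEEFit:
    """Fit the marginal logistic model of the referral judgement on the seven
    criteria, clustered by centre, via generalized estimating equations.

    Standard errors use the bias-reduced (Mancl-DeRouen) sandwich estimator,
    which keeps confidence intervals close to nominal with a handful of
    clusters — the regime multi-centre studies live in. With a single cluster
    the model degrades to an ordinary logistic regression with a logged
    warning.
    ``cov_struct`` may be "exchangeable" (default) or "independence"; with
    independence the point estimates coincide with the ordinary logistic MLE.
    """
    X, y, groups = design_matrix(records, cluster_by)
    if y.min() == y.max():
        raise InputError("both judgement classes must be present")
    exog = sm.add_constant(X, has_constant="add")
    unique_groups = np.unique(groups)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(unique_groups) < 2:
            logger.warning(
                "single cluster: falling back to ordinary logistic regression"
            )
            res = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params)
            _check_separation(params)
            bse = np.asarray(res.bse)
            pvals = np.asarray(res.pvalues)
            working = None
            method = "glm"
        else:
            if cov_struct == "exchangeable":
                cs = sm.cov_struct.Exchangeable()
            elif cov_struct == "independence":
                cs = sm.cov_struct.Independence()
            else:
                raise InputError(f"unknown cov_struct {cov_struct!r}")
            model = sm.GEE(
                y, exog, groups=groups, family=sm.families.Binomial(), cov_struct=cs
            )
            res = model.fit(maxiter=200, ctol=1e-10, cov_type="bias_reduced")
            params = np.asarray(res.params)
            _check_separation(params)
            bse = np.asarray(res.bse)
            pvals = np.asarray(res.pvalues)
            dep = getattr(cs, "dep_params", None)
            working = float(dep) if np.isscalar(dep) or isinstance(dep, float) else None
            method = "gee"

    lp = exog @ params
    return GEEFit(
        params=dict(zip(COEF_NAMES, map(float, params))),
        bse=dict(zip(COEF_NAMES, map(float, bse))),
        pvalues=dict(zip(COEF_NAMES, map(float, pvals))),
        working_corr=working,
        linear_predictor=lp,
        method=method,
        n_obs=len(y),
        n_clusters=len(unique_groups),
    )


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise InputError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise InputError("confidence interval must bracket the AUC")


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    ci_method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCResult:
    """AUC as tie-adjusted pairwise concordance, with a DeLong (default) or
    stratified-bootstrap confidence interval."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if s.shape != lab.shape:
        raise InputError("scores and labels must align")
    pos, neg = s[lab], s[~lab]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be present to compute an AUC")

    # midrank (placement) formulation: exact Mann-Whitney with ties counted 1/2
    tz = stats.rankdata(s)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    m, n = pos.size, neg.size
    v10 = (tz[lab] - tx) / n          # placement of each positive among negatives
    v01 = 1.0 - (tz[~lab] - ty) / m   # placement of each negative among positives
    auc = float(v10.mean())

    if ci_method == "delong":
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
            np.var(v01, ddof=1) / n if n > 1 else 0.0
        )
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            pb = pos[rng.integers(0, m, m)]
            nb = neg[rng.integers(0, n, n)]
            comb = np.concatenate([pb, nb])
            r = stats.rankdata(comb)
            reps[b] = (r[:m].sum() - m * (m + 1) / 2) / (m * n)
        alpha = 1 - level
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise InputError(f"unknown ci_method {ci_method!r}")
    return AUCResult(auc=auc, ci_low=float(lo), ci_high=float(hi), method=ci_method)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC coordinates at every distinct score threshold (score >= t flags)."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    thresholds = np.unique(s)[::-1]
    rows = []
    for t in thresholds:
        flag = s >= t
        sens = float(np.mean(flag[lab])) if lab.any() else float("nan")
        spec = float(np.mean(~flag[~lab])) if (~lab).any() else float("nan")
        rows.append(
            {"threshold": float(t), "sensitivity": sens, "one_minus_specificity": 1 - spec}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CutoffTable:
    """Sensitivity and specificity of the sum score at each cut-off 1..7."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["cutoff", "sensitivity", "specificity"]:
            raise InputError("cut-off table columns must be cutoff/sensitivity/specificity")
        sens = t["sensitivity"].to_numpy()
        spec = t["specificity"].to_numpy()
        if np.any(np.diff(sens) > 1e-12) or np.any(np.diff(spec) < -1e-12):
            raise InputError(
                "sensitivity must be non-increasing and specificity non-decreasing in k"
            )
        if ((t[["sensitivity", "specificity"]] < -1e-12).any().any()
                or (t[["sensitivity", "specificity"]] > 1 + 1e-12).any().any()):
            raise InputError("sensitivity/specificity must lie in [0, 1]")

    def row(self, cutoff: int) -> tuple[float, float]:
        r = self.table[self.table["cutoff"] == cutoff]
        if r.empty:
            raise InputError(f"no row for cutoff {cutoff}")
        return float(r["sensitivity"].iloc[0]), float(r["specificity"].iloc[0])


def cutoff_table(
    records: Sequence[PatientRecord], config: ToolConfig | None = None
) -> CutoffTable:
    """Sensitivity P(score >= k | judged yes) and specificity
    P(score < k | judged no) for every cut-off k = 1..7."""
    cfg = config or ToolConfig()
    scores = np.array([score_patient(r, cfg).score for r in records])
    judged = np.array([r.clinical_judgement for r in records], dtype=bool)
    if not (judged.any() and (~judged).any()):
        raise InputError("both judgement classes must be present")
    rows = []
    for k in range(1, 8):
        rows.append(
            {
                "cutoff": k,
                "sensitivity": float(np.mean(scores[judged] >= k)),
                "specificity": float(np.mean(scores[~judged] < k)),
            }
        )
    return CutoffTable(pd.DataFrame(rows))


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Internal consistency alpha = k/(k-1) * (1 - sum(item var) / var(total)).

    Sample variances (ddof=1) throughout. Returns NaN with a warning when the
    total-score variance is zero (undefined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise InputError("alpha needs at least 2 respondents and 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        logger.warning("zero total-score variance; Cronbach's alpha undefined")
        return float("nan")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch two-sample t with Satterthwaite degrees of freedom, from
    summary statistics (two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


@dataclass(frozen=True)
class ValidationReport:
    gee: GEEFit
    auc: AUCResult
    cutoffs: CutoffTable
    cronbach_alpha: float
    pilot_agreement: Mapping[int, float]
    group_tests: tuple[WelchResult, ...] = ()


def validate_cohort(
    records: Sequence[PatientRecord],
    config: ToolConfig | None = None,
    cluster_by: str = "centre_id",
    ci_method: str = "delong",
    seed: int = 0,
) -> ValidationReport:
    """Run the full validation battery on a cohort.

    The ROC is computed on the fitted model's linear predictor against the
    clinical judgement; alpha is computed on the 0/1 criterion matrix.
    """
    cfg = config or ToolConfig()
    gee = fit_marginal_logistic(records, cluster_by=cluster_by)
    X, y, _ = design_matrix(records, cluster_by)
    auc = roc_auc(gee.linear_predictor, y.astype(bool), ci_method=ci_method, seed=seed)
    cut = cutoff_table(records, cfg)
    alpha = cronbach_alpha(X)
    agreement = pilot_agreement(records)
    return ValidationReport(
        gee=gee,
        auc=auc,
        cutoffs=cut,
        cronbach_alpha=alpha,
        pilot_agreement=agreement,
    )
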