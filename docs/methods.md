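# Methods

This note documents the statistical procedures the package implements, the
choices made where the concept-mapping and validation traditions leave room,
and what the synthetic generators do and do not emulate.

## Concept mapping

**Similarity and dissimilarity.** For items *i, j* and the set of retained
sorters, `build_similarity` counts co-pile events; the diagonal equals the
number of retained sorters. A sort is *invalid* — and excluded by default —
when all items share one pile or every item is alone: such sorts carry no
pairwise information and correspond to an incorrectly executed sorting
task. Dissimilarity is δ = (S − c)/S with S the retained-sorter count,
bounded in [0, 1]; this is the standard complement transform for co-sort
data. The total pair count is conserved: Σ_{i<j} c_ij equals the sum over
sorters and piles of C(pile size, 2), which the tests check exactly.

**Nonmetric scaling.** `embed_map` minimizes Kruskal stress-1 by iterative
majorization: each sweep fits disparities to the map distances by
pooled-adjacent-violators under the rank order of δ (Kruskal's *primary*
tie handling — tied δ may receive unequal disparities; ties in the PAV
input are pre-sorted by distance), then applies the Guttman transform. An
update is accepted only if stress-1 strictly decreases, so the per-start
stress history is non-increasing by construction; iteration stops when the
improvement drops below 1e-9 or a sweep fails to improve. The first start
is a classical (Torgerson) scaling of δ, the remaining `n_starts − 1`
(default 8 total) are seeded Gaussian configurations; the lowest-stress
configuration is returned and its stress always equals a fresh `stress1`
evaluation of the returned coordinates. Constant dissimilarities and
all-coincident configurations raise degenerate-input errors rather than
returning a meaningless number.

**Cluster ladder.** Ward agglomeration of the 2-D map coordinates (not of
the raw similarities), following the Kane–Trochim procedure of clustering
the map. Solutions are produced from k_max (default 15) down to k_min
(default 2); nesting (exactly one merge per rung) is inherited from the
linkage tree. The package deliberately does **not** choose an "optimal" k:
that decision belongs to the working group, so the module only emits the
diagnostics that inform it (mean pile count per sorter, bridging per
solution, rating contrasts).

**Bridging.** The bridging value of item *i* is the co-sort-weighted mean
map distance Σ_{j≠i} c_ij d_ij / Σ_{j≠i} c_ij, min–max normalized across
items. Low values mean an item was co-sorted with items that ended up
nearby — a coherent cluster; values near 1 mark items pulled between
regions. The exact formula used by legacy concept-mapping software is not
published, so this definition is isolated behind one function and can be
swapped. Two degenerate cases are handled explicitly: an item never
co-piled with anything gets NaN (flagged, never silently 0), and if all raw
values coincide (to a 1e-12 relative tolerance) all values are defined as
0. The normalized values are invariant under rigid motions of the map,
which the tests verify to 1e-8.

**Rating contrasts.** Cluster means are means of item-level mean ratings;
all k(k−1)/2 pairwise two-sample pooled t-tests are computed and flagged
against the Bonferroni threshold α / (k(k−1)/2) — 0.05/15 ≈ 0.0033 at
k = 6. Pairs where either cluster has fewer than two item-level values are
marked not computable. When both samples are constant the statistic is
defined as 0 (equal means) or ±∞ (unequal), avoiding NaN propagation.

**Reliability.** Each valid sorter's binary co-pile vector (upper triangle)
is Pearson-correlated with the group count vector computed from the *other*
sorters (leave-one-out). Including the sorter in the reference inflates the
correlation by construction; the leave-one-out form is the conservative
reading of "individual sort versus total matrix" and inclusion is available
via a flag. Sorters with a constant vector are excluded with a warning.
The Spearman–Brown step-up k·r/(1 + (k−1)·r) extrapolates the mean
single-sorter correlation to the panel.

## Decision rule

The rule is a faithful transcription of the tool form: score = number of
YES answers over the seven criteria; below the cut-off (default 4) the
patient is not referred; at or above it the gate question decides, with NA
on the gate counting as referral (the gate exists to screen out patients
who cannot meet minimal treatment conditions; "not applicable" is not such
evidence). NA is allowed only on criteria 6 and 7 and contributes 0 to the
score under the default `as_no` policy; an `exclude_rescale` policy
(drop the item, rescale the cut-off by answered/7) is provided for
sensitivity analyses. The rule is monotone: flipping any criterion from no
to yes can never revoke a referral, and raising the cut-off can never
increase the number of referrals — both checked exhaustively. A helper
dichotomizes a raw 0–100 GAF rating at a configurable threshold (default
≤ 50, the pilot-revised value; 45 was the original draft).

## Validation analytics

**Marginal model.** "Multilevel model with exchangeable correlation and a
logit link" is implemented as a GEE marginal logistic regression clustered
by centre — the estimating-equation reading of that vocabulary; a
random-intercept logistic model is a noted alternative but not the default,
because the marginal (population-averaged) coefficients are what the ROC
scoring uses. Standard errors use the bias-reduced (Mancl–DeRouen)
sandwich estimator: with only ~7 clusters the plain sandwich is known to be
anti-conservative, and in null simulations (800 patients, 8 centres, 50
replicates) the bias-reduced intervals hold ~91% coverage where the plain
ones dip below 90%. NA answers enter the design matrix as 0, mirroring the
tool's scoring policy so the model and the rule see identical inputs.
Coefficients above 15 in magnitude raise a separation diagnostic instead of
returning a silently diverged fit; a single-centre dataset falls back to
ordinary logistic regression with a warning. With working independence the
point estimates coincide with the ordinary logistic MLE to 1e-6, which the
tests verify against an independently coded IRLS fit.

**ROC/AUC.** Scores are the fitted model's linear predictor. AUC is the
tie-adjusted pairwise concordance (ties count ½), computed via midranks;
the default confidence interval is DeLong's, from the variance of the
positive and negative placement values, cross-checked in the tests against
R's pROC on a frozen dataset. A stratified bootstrap CI is available with a
seed.

**Cut-off table.** For k = 1..7, sensitivity = P(score ≥ k | judged yes)
and specificity = P(score < k | judged no). Monotonicity (sensitivity
non-increasing, specificity non-decreasing) is enforced as a type invariant
— it holds by construction, so a violation indicates a bug upstream.

**Cronbach's alpha.** α = k/(k−1)·(1 − Σ item variances / total variance),
sample variances (ddof = 1) throughout; zero total variance yields NaN with
a warning. **Welch tests** from summary statistics use the Satterthwaite
degrees of freedom. On the published therapist-experience summaries
(16.3 ± 8.7, n = 29 vs 8.7 ± 7.1, n = 59) the direct formula gives
t ≈ 4.08 with df ≈ 46.9; reported values from unrounded source data can
differ, so the tests assert the formula, not any printed rounding.

**Agreement percentages.** Default definition: share of records where the
criterion answer matches the clinician's judgement (NA records leave that
criterion's denominator); a joint-positive share (criterion yes AND judged
yes, over all records) is available behind a flag since "similarity with
clinical decision" admits both readings.

## Synthetic data

**Sorting studies** (defaults: 95 items, 22 sorters, 6 latent clusters).
Each sorter starts from the latent partition, splits each pile with
probability 0.6, merges one random pile pair with probability 0.2, then
moves each item to a random other pile with probability 0.15. The
split/merge defaults put the mean pile count per sorter near 10, the
typical panel behaviour for ~95 statements; the noise level yields stress
around 0.19 at this scale — synthetic experts are somewhat more consistent
than real panels, whose stress values mostly fall in 0.20–0.37, because
item-level noise is independent across sorters and items. Recovery tests
(planted partition found at k = truth) and the monotone stress-vs-noise
relationship are therefore statements about this generative family, not
about any particular expert panel.

**Ratings.** Clipped rounded Gaussians around per-cluster means on the 1–6
scale; half-integer means round half-to-even.

**Cohorts** (defaults: 368 patients, 7 centres, 88 therapists nested in
centres). Criteria are correlated binaries from an exchangeable Gaussian
copula (latent correlation 0.35, prevalence 0.5 each — moderate positive
dependence chosen so the seven-item internal consistency lands in the
0.6–0.7 range typical of broad clinical constructs). The judgement follows
logit⁻¹(intercept + centre shift + β·criteria) with the default β taken
from the validated tool's fitted model (2.53, 0.92, 1.74, 0.83, 0.21,
−0.004, 1.21) and Gaussian centre shifts (sd 0.5) inducing within-centre
correlation. The intercept is calibrated by bisection on a fixed
Monte-Carlo draw so the marginal referral prevalence hits 110/378 ≈ 0.29;
the calibration is deterministic and independent of the simulation seed.
NA is injected at 5% on criteria 6–7 and the gate question. Therapists are
generated but the analysis clusters by centre, mirroring the analysis level
of the validation design.

One estimand subtlety: GEE estimates *marginal* coefficients, which are
attenuated relative to the conditional (centre-shifted) generating values
whenever centre heterogeneity is present. The parameter-recovery tests
therefore simulate with centre_effect_sd = 0 (and no NA), where the two
estimands coincide; the default generator keeps the heterogeneity because
realistic cohorts have it.

## Problem sizes and numerical choices

Tests run the full-scale generators only where the check needs them
(100-replicate parameter recovery at n = 368; the sorting study at 95 × 22
in the acceptance script) and use 10–60-item studies elsewhere; the whole
suite completes in well under a minute on one core. All randomness flows
from explicit seeds; the pipeline derives per-stage seeds from a single
root seed via `numpy.random.SeedSequence`. Known limitations: no
random-intercept alternative to GEE is wired in; bridging uses one fixed
formula; the simulators draw NA independently of the latent criterion
values (real missingness is unlikely to be completely at random); and the
gate question is generated from the judgement with fixed conditional
probabilities rather than modelled.
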