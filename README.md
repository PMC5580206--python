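# dtpd

Analytics for developing and validating a clinical referral decision rule
for personality-disorder care, built around two workhorses:

1. **Group concept mapping** — experts sort ~95 candidate criteria into
   piles and rate their relevance (1–6). The package turns the sorts into a
   co-occurrence similarity matrix, embeds the criteria in the plane by
   nonmetric multidimensional scaling (Kruskal stress-1), builds the
   hierarchical (Ward) cluster ladder, computes per-item *bridging values*
   (low = the item was co-sorted with its map neighbours, i.e. a coherent
   cluster), compares cluster rating means with Bonferroni-corrected
   t-tests, and estimates sorter-vs-group reliability with an optional
   Spearman–Brown correction.
2. **Decision-rule validation** — the resulting tool (DTPD) has seven
   yes/no criteria, a sum-score cut-off (default 4) and a gate question
   that decides referral to highly specialized care. The package scores
   patient records, fits a marginal logistic model of the clinician's
   referral judgement on the seven criteria with exchangeable within-centre
   correlation (GEE, bias-reduced sandwich errors), computes the ROC curve
   and AUC with a DeLong confidence interval, the full cut-off
   sensitivity/specificity table, Cronbach's alpha, and per-criterion
   agreement percentages.

Because expert sorting studies and multi-centre patient cohorts are rarely
shareable, the package ships generators that emulate both: sorters
perturbing a latent cluster structure, and a 7-centre cohort whose referral
judgement follows a logistic model on correlated binary criteria. Every
analysis stage is therefore testable end to end against known ground truth.

## The statistics in brief

For items *i, j* sorted by *S* valid sorters, similarity is the co-pile
count *c_ij*; dissimilarity is δ_ij = (S − c_ij)/S. Nonmetric scaling
minimizes Kruskal's stress-1,

    stress1 = sqrt( Σ_{i<j} (d_ij − d̂_ij)² / Σ_{i<j} d_ij² ),

with d the map distances and d̂ monotone-regression disparities; values of
0.20–0.35 are conventionally a reasonable fit. The bridging value of item
*i* is the co-sort-weighted mean map distance Σ_j c_ij d_ij / Σ_j c_ij,
min–max normalized to [0, 1]. Reliability averages each sorter's Pearson
correlation between their binary co-pile vector and the leave-one-out group
count vector. On the validation side, the model is
logit P(referral) = β₀ + Σ_k β_k x_k estimated by GEE with exchangeable
working correlation per centre; AUC is the tie-adjusted concordance of the
model's linear predictor.

## Worked example

```python
from dtpd import (SortSimConfig, simulate_sorting, build_similarity,
                  embed_map, cluster_ladder, sorter_reliability,
                  PatientSimConfig, simulate_patients, validate_cohort)

sorts, truth = simulate_sorting(SortSimConfig(seed=1))   # 95 items, 22 sorters
sim = build_similarity(sorts, exclude_invalid=True)
chart = embed_map(sim, seed=1)                           # 8 restarts
rel = sorter_reliability(sorts)
print(f"stress-1 {chart.stress:.3f}, reliability {rel.mean_r:.2f}")

records, _ = simulate_patients(PatientSimConfig(seed=3)) # 368 patients, 7 centres
val = validate_cohort(records)
print(f"AUC {val.auc.auc:.3f} (95% CI {val.auc.ci_low:.3f}-{val.auc.ci_high:.3f})")
print(f"alpha {val.cronbach_alpha:.2f}")
print(val.cutoffs.table)
```

prints (seeds as shown):

```
stress-1 0.189, reliability 0.57
AUC 0.890 (95% CI 0.858-0.923)
alpha 0.63
   cutoff  sensitivity  specificity
0       1     1.000000     0.100386
1       2     0.990826     0.270270
2       3     0.954128     0.474903
3       4     0.834862     0.722008
4       5     0.623853     0.861004
5       6     0.412844     0.934363
6       7     0.165138     0.972973
```

i.e. the synthetic sorting panel produces a map with a reasonable fit and
moderate sorter agreement, and at the default cut-off of 4 the rule flags
~83% of the patients clinicians would refer while clearing ~72% of the rest.

There is also a CLI (`dtpd simulate|map|cluster|bridge|rate|reliability|
score|validate|run`); `dtpd run --seed 7 --out demo/` executes the whole
pipeline and writes every artifact plus a JSON run report.

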