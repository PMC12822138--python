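# gmpatterns

Data-driven discovery and characterization of grey-matter (GM) patterns in
cognitively healthy older adults: an analysis pipeline for population
neuroimaging studies that cluster regional brain morphometry, profile the
resulting subgroups against clinical and biomarker data, and follow them
over time.

## What it does

The pipeline works on 41 regional GM measures per subject — 34
Desikan–Killiany cortical thicknesses (mm, hemisphere-averaged) and 7
subcortical volumes (mm³, residualized on total intracranial volume) — and
runs five stages:

1. **Preparation** (`gmpatterns.prep`). Hemisphere averaging, TIV
   residual adjustment of volumes (`vol_i − (â + b̂·TIV_i)` from a
   per-volume least-squares fit), surface-area-weighted cortical
   signatures, fixed tertile schemes (WMHV < 2.7 / 2.7–5.5 / > 5.5;
   FA < 0.3 / 0.3–0.4 / > 0.4; LDL ≤ 3 / 3.1–3.9 / ≥ 4 mmol/L), verbatim
   risk dichotomizations (BMI ≥ 25, ≥ 100 g alcohol/week, BP ≥ 140/90 or
   treatment, …) and baseline-anchored z-scoring of the cognitive battery.
2. **Clustering** (`gmpatterns.cluster`). Unsupervised random-forest
   proximity clustering: a forest (default ntree = 6000, mtry = 6,
   nodesize = 3) separates the real subjects from a contrast class drawn
   from the product of the feature marginals; the out-of-bag proximity
   `P_ij = #{trees: i, j both OOB, same leaf} / #{trees: i, j both OOB}`
   is transformed to the dissimilarity `d_ij = √(1 − P_ij)`, embedded by
   classical (Torgerson) multidimensional scaling, and cut by
   average-linkage agglomeration. The number of clusters k ∈ {2, …, 8} is
   chosen by the composite (mean z-score) of the Dunn and
   Calinski–Harabasz indices.
3. **Effect maps** (`gmpatterns.effects`). Per-ROI Cohen's d (pooled SD)
   of each cluster versus the reference cluster with two-sample t-tests
   and Benjamini–Hochberg FDR; regions with |d| > 1.2 and adjusted
   p < 0.05 are flagged discriminative.
4. **Association** (`gmpatterns.association`). Table-1 style
   cross-cluster tests (χ², ANOVA, Kruskal–Wallis), four registered
   multinomial logistic models (clinical, neuroimaging, inflammation, CSF)
   estimating odds ratios with Wald 95% CIs against the reference
   cluster, VIF collinearity checks, and Gaussian GLMs for the six
   cognition outcomes.
5. **Trajectories** (`gmpatterns.longitudinal`). Linear mixed-effects
   models per outcome (fixed: timepoint, cluster, timepoint × cluster,
   sex, education; random: intercept + slope per subject; ML estimation)
   whose interaction coefficients β_slope are each cluster's excess
   5-year change; FDR across the outcome battery, AIC/BIC comparison of
   random-effects structures, and attrition analysis.

Because cohort data of this kind are access-restricted, the package ships
a first-class synthetic generator (`gmpatterns.synthetic`) that emulates
the study's statistical structure — ~750 subjects in 5 latent clusters
with frontoparietal effect-size patterns, risk-factor prevalences set by
odds ratios, cognitive shifts, and a 5-year second visit with ~40%
cluster-dependent dropout — so every stage is testable against known
ground truth.

## Worked example

```python
import gmpatterns as g
from gmpatterns.association import ModelSpec, fit_multinomial
from gmpatterns.effects import roi_effect_table
from gmpatterns.longitudinal import (LongitudinalSpec,
                                     fit_longitudinal_model, make_long_table)

cohort = g.generate_cohort(g.default_paper_config(n_subjects=746, seed=2))
features = g.build_feature_matrix(cohort.baseline_table)
labels = cohort.true_labels            # ground truth from the generator

eff = roi_effect_table(features, labels.to_numpy())
print(eff[eff.cluster == 2].head(3).round(3))
rec = fit_multinomial(cohort.baseline_table.set_index("subject_id"), labels,
                      ModelSpec("risk", ("diabetes", "alcohol_atrisk")))
print(rec.query("cluster == 2").round(2))
long = make_long_table(cohort.baseline_table, cohort.followup_table,
                       ("mmse",), labels)
fit = fit_longitudinal_model(long, "mmse", LongitudinalSpec(outcomes=("mmse",)))
print(fit.contrasts.round(3))
```

prints (seed 2):

```
             roi  cluster      d  p_adj  discriminative
superiorparietal        2 -1.750    0.0            True
 superiorfrontal        2 -1.742    0.0            True
      precentral        2 -1.704    0.0            True

     predictor contrast   OR  ci_low  ci_high
      diabetes   2_vs_1 3.58    2.06     6.19
alcohol_atrisk   2_vs_1 1.79    1.14     2.81

outcome  cluster  beta_slope    se     p
   mmse        2      -0.437 0.050 0.000
   mmse        3       0.018 0.046 0.699
   mmse        4       0.033 0.042 0.425
   mmse        5      -0.064 0.076 0.401
```

Cluster 2 — the diffuse GM-loss subgroup — shows its generated signature:
frontoparietal thinning beyond the |1.2| discriminative threshold,
elevated odds of diabetes and at-risk alcohol use, and an excess MMSE
decline of −0.44 points over the 5-year interval (generated: −0.45);
the other clusters' slopes sit at their generated null.

A command-line interface mirrors the stages
(`gmpatterns simulate | prep | cluster | effects | characterize |
longitudinal | report | all`); `gmpatterns all --seed 1 --out run/`
executes the full pipeline on the default synthetic scenario and writes
every artifact plus a provenance manifest.

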