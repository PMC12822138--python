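# Methods

This note documents the statistical procedures implemented in
`gmpatterns`, the choices made where the methodology was genuinely open,
and what the synthetic-cohort tests do and do not demonstrate.

## Feature preparation

The analysis matrix holds 41 features per subject: 34 cortical
thicknesses (mm) and 7 subcortical volumes (mm³), each the arithmetic
mean of the left and right hemisphere measurements. Volumes are adjusted
for head size by replacing them with the residuals of a simple
least-squares regression on total intracranial volume (TIV), fitted over
complete cases; thicknesses are left unadjusted. Residuals are invariant
to affine rescaling of the TIV unit, and averaging hemispheres before or
after adjustment is equivalent when both hemispheres share the subject's
TIV.

Cortical signatures are surface-area-weighted mean thicknesses,
`Σ a_r t_r / Σ a_r` over a named region set; with equal areas this is the
plain mean, and when no area columns are supplied equal weights are used
with a log note. The atlas has no single "anterior cingulate" parcel, so
the resilience signature defaults to {rostral anterior cingulate, caudal
anterior cingulate, temporal pole}; the region sets are arguments.

Tertile schemes use fixed, published cutpoints, never data-driven ones.
A value equal to a printed boundary falls in the closed middle interval
(WMHV 2.7 and 5.5 → T2; FA 0.3 and 0.4 → T2). The LDL notation
(T1 ≤ 3, T2 = 3.1–3.9, T3 ≥ 4 mmol/L) leaves the open gaps 3–3.1 and
3.9–4 unassigned; both are mapped to T2, the same closed-middle rule.
Dichotomizations (BMI ≥ 25 kg/m²; ≥ 100 g alcohol/week; SBP ≥ 140 or
DBP ≥ 90 mmHg or antihypertensive treatment; triglycerides ≥ 1.7 mmol/L
or lipid-lowering treatment; HDL < 1.03 / < 1.29 mmol/L for men/women;
homocysteine > 13.5 µmol/L; CRP ≥ 8 mg/L; CSF Aβ42 ≤ 530, t-tau ≥ 350,
p-tau ≥ 80 pg/mL) are applied verbatim; boundary behaviour follows the
printed comparison operator. Missing inputs propagate as missing
indicators, logged per variable (complete-case analysis downstream).

Cognitive tests are z-scored with the **baseline** mean and SD; domain
scores average their constituent test z-scores, the global composite is
the mean of the five domain scores, and follow-up scores reuse the
baseline parameters so longitudinal change is measured on a fixed scale.

## Random-forest proximity clustering

The clustering stage is fully unsupervised. A contrast class is built by
resampling each feature column independently with replacement from its
observed values — the product-of-marginals reference distribution, which
preserves every marginal and destroys inter-feature dependence. A
classification forest (defaults ntree = 6000, mtry = 6, nodesize = 3,
matching the study-scale setting; desk-scale runs use ntree = 1000) is
trained to separate real from contrast rows; each tree grows on a
bootstrap of the pooled rows, and out-of-bag (OOB) membership of the real
rows is recorded. The OOB proximity of subjects i, j is the fraction of
trees, among those where both are OOB, in which they share a terminal
leaf. The matrix is symmetric with unit diagonal and entries in [0, 1];
pairs never jointly OOB are flagged, and more than 1% of undefined pairs
is an error (grow more trees). Forest determinism is owned by the
package: one root generator seeds per-tree bootstrap draws and tree
split streams, so identical seeds give bit-identical forests. Variable
importance is mean impurity decrease across trees.

Downstream, the dissimilarity is `√(1 − proximity)` (the RF-clustering
convention; plain `1 − proximity` is available by flag). Classical
(Torgerson) MDS double-centers the squared dissimilarities and
eigendecomposes the Gram matrix; coordinates, the full spectrum and the
negative-eigenvalue mass are reported, and requests beyond the positive
rank are truncated with a warning. Average-linkage (UPGMA) agglomeration
is applied to the dissimilarity matrix (the MDS embedding is an
alternative substrate, kept for visualization and for the
Calinski–Harabasz index, which needs a coordinate space and uses the
first 3 MDS axes by default). For each k in 2..8 the tree is cut; the
Dunn index (minimum between-cluster distance over maximum within-cluster
diameter, on the dissimilarity) and the Calinski–Harabasz index
(df-normalized between/within dispersion ratio, on the embedding) are
standardized to z-scores across the candidate k and averaged; the argmax
wins, ties toward smaller k. z-scoring makes the composite exactly
invariant to affine rescaling of either index; degenerate (infinite)
candidates are flagged and cannot win. Final labels are renumbered 1..k
by decreasing cluster size, so cluster 1 — the reference for all
downstream contrasts under the default "largest" policy — is always the
biggest cluster. Proximity-based stability is summarized per cluster as
mean within-cluster proximity minus mean proximity to everyone else;
this gap statistic is this package's own definition.

## Effect maps

For each ROI and each cluster c versus the reference: a two-sample
pooled-variance t-test (Welch by flag, kept consistent with the
pooled-SD Cohen's d), Cohen's d = (mean_c − mean_ref)/s_p, and
Benjamini–Hochberg adjustment within each cluster-contrast family of 41
tests (a global family across all contrasts is available — with 4
contrasts the table holds 164 records). A record is discriminative when
|d| > 1.2 and adjusted p < 0.05; the 1.2 constant is stored as a named
threshold, chosen in the source analysis because effect sizes declined
beyond that magnitude. The BH implementation is the step-up definition
(sort, p·m/i, enforce monotonicity, cap at 1) and is exercised against a
literal-definition oracle and statsmodels in the tests.

## Association models

Descriptive cross-cluster comparisons use Pearson's χ² without
continuity correction for categorical variables, one-way ANOVA for
variables declared normal and Kruskal–Wallis otherwise; the
normality triage is declared by the variable schema, not auto-tested.
Four registered multinomial logistic models (clinical, neuroimaging,
inflammation, CSF) regress cluster membership (baseline category =
reference cluster) on their predictor sets; categorical predictors
declare reference levels (tertiles expand to T2/T3 dummies against T1).
Estimates are maximum likelihood (Newton), odds ratios are exp(β) with
Wald 95% intervals (β ± 1.96·SE, exponentiated), per-model complete-case
counts are reported, fewer than 10 cases per parameter logs a warning,
rank-deficient designs fail naming the aliased terms, and
non-convergence (separation) is an error with a diagnostic. VIF is
1/(1 − R²) from regressing each predictor on the others, flagged above
1.7 (the bound observed in the source analysis). Cognition models are
identity-link Gaussian GLMs of the global composite and five domain
scores on cluster indicators — numerically identical to OLS, which the
tests assert.

## Longitudinal models

The two visits are coded timepoint = 0/1, so each cluster's
timepoint × cluster coefficient (β_slope) is its excess change per
5-year interval relative to the reference cluster; a per-year coding is
a matter of dividing by the elapsed time. Fixed effects: timepoint,
cluster, their interaction, sex and education years. Random effects per
subject follow one of three structures — intercept + slope (default),
intercept only, slope only — estimated by maximum likelihood (not REML)
so AIC/BIC are comparable across structures; the comparison table
reports all three with the per-criterion minimizer, and non-converged
fits are retained flagged as non-comparable. Optimization runs Powell
first and then an L-BFGS polish: gradient descent from the default start
can stall on a likelihood ridge and report convergence at a worse
optimum, which breaks the nested-model likelihood ordering. Clusters
with no follow-up rows would make the interaction column identically
zero; those contrasts are dropped with a machine-parsable warning. The
overall cluster × time effect is a joint Wald χ² across the interaction
coefficients. FDR is applied across the whole outcome battery's slope
contrasts, excluding non-converged fits with a warning.

The "heterogeneous" option fits cluster-specific residual variances by
direct maximum likelihood: the marginal covariance per subject is
`Z G Zᵀ + σ²_c I` with G parameterized by its log-diagonal Cholesky
factor, fixed effects profiled out by GLS at each step, and the
covariance parameters optimized by L-BFGS-B. The default is
homoscedastic, and on equal-variance data both routes agree (asserted in
the tests).

Attrition analysis compares baseline characteristics across follow-up
status (participant / dropout / deceased) using the same descriptive
test machinery, always including the cluster-by-status table; groups
that cannot be tested (e.g. a single status level) yield flagged,
untestable rows rather than silent omissions.

## Synthetic cohort generator

The generator is the ground-truth instrument for every stage. Subjects
draw a latent cluster from the mixing proportions (0.373, 0.190, 0.162,
0.211, 0.064); ROI values are `baseline mean + d·σ_resid + b·(TIV − μ_TIV)
(volumes only) + σ_resid·ε`, where d is the configured Cohen's-d shift
versus the reference cluster and ε has exchangeable correlation ρ = 0.3
across the 41 ROIs (one shared factor per subject plus independent
noise) — a deliberately simple covariance. TIV is Gaussian
(1.45 × 10⁶ ± 1.3 × 10⁵ mm³) and volumes load on it with slope 0.003, so
TIV adjustment is a meaningful step. Binary covariates draw from
cluster-conditional probabilities `expit(logit(p₀) + Δ_c)` with log-odds
patterned on the reported odds ratios (e.g. diabetes log 2.54 and
at-risk alcohol log 1.83 on cluster 2, heart disease log 3.44 on
cluster 5); WMHV is lognormal around the tertile cutpoints, FA and LDL
Gaussian. Cognitive shifts are z-unit effects for the five domains plus
MMSE (29.1 ± 1.2 points); the global composite is always derived
downstream as the domain mean, so it carries no independent generating
parameter. Follow-up values are `baseline + annual slope · 5 +
subject-slope noise · 5 + visit noise`, with cluster 2 carrying the
excess declines (−0.45 MMSE, −0.23 verbal fluency, +1.84 WMHV per
interval). Dropout is missing-at-random given cluster — logistic around
the 40% base rate with modifiers favouring retention of preserved-GM
clusters — plus a 1.6% death rate, yielding ~58–59% retention at study
scale. The default effect patterns mirror the described cluster
profiles: cluster 2 diffusely thinner with a frontoparietal peak
(−1.5…−1.8 d), cluster 3 thicker posteriorly (+1.4…+1.5), cluster 4
diffusely, mildly thicker (+1.05, below the discriminative threshold),
cluster 5 mixed (−1.7 frontoparietal, +0.5 cingulate/orbitofrontal).
`scale_separation` rescales the whole pattern matrix so that every
cluster pair is separated by at least a requested d on its most
discriminative ROI (the default matrix's weakest pair, reference versus
cluster 4, sits at 1.05).

What the generator does **not** emulate: realistic ROI covariance beyond
the exchangeable factor, scanner or site effects, measurement
reliability, non-Gaussian morphometry tails, informative (outcome-
dependent) dropout, and the selection mechanism of the CSF subsample
(a random subset flag stands in). Passing tests therefore demonstrate
correctness of the estimators under a known, simplified data-generating
process — not performance on real cohort data.

## Known limitation: recovering a central null cluster

The proximity-clustering stage faithfully reproduces the reference
methodology, and this exposes a real limitation of that methodology
under this generator's conditions. The reference cluster is defined by
the *absence* of shifts; its members share no joint structure that
distinguishes them from the product-of-marginals contrast class, so
their mutual OOB proximity sits at chance (within-minus-between gap
≈ 0.005, versus 0.05–0.18 for the shifted clusters). The exchangeable
noise factor compounds this: trees track the shared factor, smearing
between-cluster proximity into a continuum that average linkage chains
across. The net effect is that on the default 5-cluster scenario —
even with all between-cluster separations scaled to ≥ 1.5 d, where the
clusters are Bayes-separable (pairwise Mahalanobis distances 5–11) —
hierarchical cuts of the proximity dissimilarity mix the reference
cluster into its neighbours (ARI ≈ 0.2) and the composite index
prefers k = 2. This is not an implementation artifact: the R
randomForest reference implementation (unsupervised mode, OOB
proximity) produces the same proximity structure and the same failure
on identical data, and clustering the MDS embedding instead, removing
the noise correlation, enlarging effects up to 3 d, or varying
nodesize does not close the gap. The corresponding recovery check in
the acceptance suite is retained at its stated conditions and fails
honestly; the stages downstream of clustering are validated against
ground-truth labels, where all generating parameters are recovered
within their stated tolerances.

## Problem sizes and numerics

The test suite runs at desk scale by choice: forests of 150–2000 trees
(2000 where proximity saturation is asserted, 1000 for the recovery
scenario), cohorts of 120–750 subjects (5000 for asymptotic odds-ratio
checks), 50–200 replicates for calibration studies. The acceptance
script uses n = 746–750 and ntree = 1000. Numerical tolerances: index
and regression oracles at 1e-10…1e-12; TIV orthogonality at |r| < 1e-8;
mixed-model oracle agreement at 1e-6; stochastic recovery bands as
stated per test. Ties in hierarchical merges follow SciPy's
deterministic order; cluster renumbering breaks size ties by first
appearance; BH adjustment uses a stable sort so equal p-values keep
input order.
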