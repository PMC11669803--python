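# Methods

## The estimand: a cross-lagged panel network

The object of interest is a directed, weighted network over 24 symptom
nodes measured at two waves roughly a year apart. The nodes belong to four
constructs: three psychotic-like-experience (PLEs) factors of the CAPE-P15
(persecutory ideation PI, bizarre experiences BEs, perceptual abnormalities
PAs), the nine PHQ-9 depression items, the seven GAD-7 anxiety items, and
five adverse-life-event factors of the ASLEC. Edge $W_{ij}$ is the
regression coefficient of wave-1 node $i$ predicting wave-2 node $j$,
controlling for all other wave-1 nodes and for socio-demographic
covariates. The diagonal holds autoregressive effects; it is reported but
removed from every centrality and comparison computation, since those are
meant to describe between-symptom dynamics.

The model is deliberately linear-Gaussian: node scores are item or factor
means on 1–4 / 1–5 Likert scales, treated as continuous. No contemporaneous
(within-wave) network is estimated, and only one lag is modelled.

## Estimation

Both waves are z-scored per node (population SD) within each analysis
group before fitting, so edge weights are comparable across nodes and
absolute-value centrality sums are meaningful. Each of the 24 outcome
regressions is an L1-penalized (LASSO) fit in scikit-learn's
parameterization, objective $(1/2n)\,\mathrm{RSS} + \lambda \|\beta\|_1$.

**Penalty selection.** Per node, $\lambda$ is chosen by K-fold
cross-validation (default K = 10, fold assignment seeded per node from the
estimator seed). The default picks the prediction-error minimum
(`cv_min`); the one-standard-error rule (`cv_1se`) and fixed-$\lambda$
modes are available. `cv_min` intentionally over-selects: under a null
with no cross-lagged effects it retains ~10–15% of spurious edges at
n = 2,000, whereas `cv_1se` prunes essentially all of them. Analyses that
need sparsistency (e.g. edge-support claims under weak signal) should use
`cv_1se`; analyses that need weight accuracy should keep `cv_min`.

**Covariate adjustment.** Covariates (age, sex, ethnicity, birth place,
chronic condition, personal and family mental-health history) are
unpenalized by default: adjustment should not be shrunk away. Since the
underlying solver has no per-feature penalty weights, the implementation
projects the response and all wave-1 predictors onto the orthogonal
complement of the covariates (plus intercept) before the LASSO. For a
partially penalized L1 objective this Frisch–Waugh–Lovell reduction is
exact, not an approximation; covariate coefficients are recovered
afterwards by OLS on the LASSO residual. Covariates never enter the weight
matrix. A `penalize_covariates` mode adds them to the penalized design for
sensitivity. Categorical covariates are dummy-coded against the first
level.

Complete cases only: participants with any missing node score at either
wave are dropped before fitting, and the two screening groups
(baseline-positive / baseline-negative at the 1.57 cut-off) are
standardized and fit independently.

## Scoring and screening

The CAPE-P15 weighted score is the sum of valid items divided by the
number of valid items; a participant screens positive at `score >= 1.57`
(the boundary is inclusive by default and exposed as a flag, since
"above the cut-off" and "at the cut-off" readings both circulate).
Factor scores are means of valid items, missing when fewer than 80% of a
factor's items are valid; the CAPE whole-scale score is exempt from the
completeness rule because its definition already averages over valid
items. The CAPE item→subtype map (PI 5, BEs 7, PAs 3 items) and the ASLEC
five-factor blocks (7/3/6/5/6 items: being punished, loss, adjustment,
interpersonal stress, academic stress) are shipped defaults and fully
configurable — the instruments' factor assignments are conventions, not
identities.

Exclusions run in a fixed order: duplicate records per (participant,
wave) keeping the earliest timestamp, records faster than 5 minutes,
participants with a psychotic-disorder history, participants refusing the
verification interview. Flow-report step counts refer to baseline
records, so `collected − removals = valid baseline` holds by construction
and is asserted on every run.

## Centrality

in-EI and out-EI are absolute column and row sums of the off-diagonal
weight matrix; bridge in-/out-EI restrict the sums to edges whose other
endpoint lies in a different construct. Absolute sums are the default
(matching the verbal definition of expected influence for a matrix whose
within-measure signs are meaningful); a signed mode exists for
sensitivity. Exact invariants — conservation
($\sum_j \text{in-EI}_j = \sum_i \text{out-EI}_i = \sum_{i\ne j}|W_{ij}|$),
bridge ≤ total elementwise, homogeneity under scaling, permutation
equivariance — are enforced by property tests.

## Accuracy and stability

Edge precision uses a nonparametric bootstrap: participants resampled
with replacement, the whole estimation rerun per resample, percentile
2.5/97.5% intervals per edge (percentile rather than BCa: simplest to
verify, and the convention of the stability framework this follows).
Pairwise edge differences are judged significant when the percentile CI
of the difference excludes zero.

Centrality stability uses case-drop bootstrapping: at each drop
proportion in a grid (default 10%–75% by 5%), subsamples without
replacement are refit and each centrality vector is Pearson-correlated
with its full-sample counterpart across the 24 nodes. The CS coefficient
of an index is the largest drop proportion — reached contiguously from
the smallest grid value, the monotone convention — at which ≥ 95% of
subsample correlations are ≥ 0.7. Both thresholds are config-exposed.
CS ≥ 0.25 is conventionally acceptable, > 0.5 strong. A subsample whose
centrality vector is constant (everything shrunk to zero) contributes
correlation 0, since it carries no ranking information. Resamples that
leave a node with zero variance are redrawn and counted; a dataset where
redraws cannot succeed raises instead of looping.

Every resampling routine is reproducible from (seed, iterations, grid).

## The synthetic cohort generator

Restricted-access cohort data are emulated by a seeded linear two-wave
system over the 24 latent node scores:

* wave-1 latents drawn from a unit-variance block covariance (default
  within-construct correlation 0.4, between 0.1 — typical magnitudes for
  symptom batteries);
* wave-2 latents = wave-1 × truth matrix + centred covariate effects +
  Gaussian noise. The default truth has autoregressive 0.25 on the
  diagonal and 30 sparse cross-lagged effects with magnitudes in
  [0.15, 0.35] (~20% negative), drawn once from a fixed internal seed so
  the default truth is a package constant. Default noise SDs give each
  wave-2 node a latent R² of about 0.3 — a realistic signal level for
  year-apart panel data;
* observed Likert items per node: `clip(round(intercept + 0.8·latent +
  N(0, 0.6)), scale)`. PLEs factors carry 5/7/3 items, PHQ and GAD nodes
  are single items, ASLEC factors carry 7/3/6/5/6 items;
* the CAPE item intercept is calibrated by bisection on an independent
  seeded quantile draw so the realized screen-positive fraction matches
  the 13.5% default prevalence target at the fixed 1.57 cut-off
  (realized prevalence lands within ±2 percentage points at n ≥ 2,000 —
  the discreteness of the 15-item sum makes exact targeting impossible);
* administrative artifacts (duplicate submissions with later timestamps,
  sub-5-minute response times, psychotic-history and refusal flags,
  follow-up loss) are injected at configurable rates with deterministic
  counts (`round(rate·n)`), drawn disjointly so the exclusion cascade
  removes exactly the injected numbers. Covariates are simple synthetic
  draws (sex Bernoulli(0.5), age uniform 17–22, binary flags at low base
  rates) — only their adjustment role matters.

What the generator does **not** emulate: item-response-theory measurement
structure, floor/ceiling asymmetries of real symptom scales beyond
clipping, informative missingness or dropout, and any dependence of
follow-up loss on symptom level. Passing tests therefore demonstrate that
the estimation machinery recovers a known linear lagged structure under
Likert discretization — not that real symptom dynamics are linear.

## Numerical and design choices

* Standardization uses the population (ddof = 0) convention; stated here
  because standardized autoregressive effects are attenuated by the
  outcome's total variance (a true latent 0.5 on the diagonal appears as
  ≈ 0.45 after standardization).
* λ = 0 requests fall back to explicit least squares rather than a
  zero-penalty coordinate-descent run.
* The 0.05 display threshold filters edge *exports* only; the weight
  matrix itself is never thresholded, and comparisons use the full
  post-LASSO matrices (a thresholded replication mode exists).
* Edge replication requires matching sign, not mere nonzero-ness; sign
  flips are not meaningful replication. A lenient mode is provided.
* Matrix correlation excludes the diagonal by default, consistent with
  removing autoregressive effects elsewhere; switchable.
* The pipeline derives per-stage seeds from one global seed via
  `SeedSequence([seed, stage_tag])`, all below 2³¹, so stages can be
  rerun in isolation.
* Ground-truth export writes floats at 17 significant digits and reads
  them back with round-trip parsing, so export/import is lossless.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks are sized to be decisive yet quick: ground-truth
recovery uses n = 5,000 cohorts (20 seeds in the test suite, 5 in the
acceptance script; both report medians); stability growth is checked at
n ∈ {500, 2,000, 8,000} with 250 case-drop iterations per level on a
10%–50% drop grid (50% is the largest drop for which the n = 500
subsamples keep the required 10 × nodes observations) with a fixed
penalty, which isolates subsampling variability from tuning variability;
replication uses independent n = 5,000 cohort pairs. Full-scale runs
(n ≈ 3,000, 1,000 bootstrap iterations, the full 10–75% grid) use the
same code paths with larger settings.

## Known limitations

* Ordinal node scores are treated as continuous; no mixed graphical or
  IRT-based alternative is provided.
* Only two waves and one lag; no contemporaneous network.
* Cross-validated penalty selection makes edge *support* seed-dependent
  near the selection boundary; weight magnitudes are stable but
  presence/absence of very weak edges is not, which is exactly what the
  bootstrap machinery is there to expose.
* The CS coefficient's grid resolution (5 percentage points by default)
  bounds the precision of any stability statement.
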