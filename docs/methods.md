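# Methods

## Problem and model

A single-arm trial (SAT) in a rare, often genomically-defined population is
compared against an external control arm assembled by pooling several
real-world comparator cohorts (rwCCs). Pooling presumes homogeneity: comparing
the SAT to any one rwCC should give the same answer up to sampling noise. The
package implements and evaluates heterogeneity assessments for this use case
with a binary response outcome.

Each of the I rwCCs yields an effect estimate against the SAT
(risk difference `p̂_SAT − p̂_i`, or log odds ratio), giving a vector
θ̂ = (θ̂₁, …, θ̂_k), k = I. Because every comparison reuses the same SAT arm,
the θ̂ᵢ are positively correlated: for risk differences,

    Cov(θ̂ᵢ, θ̂ⱼ) = Var(p̂_SAT) = p_SAT(1 − p_SAT)/n_SAT   (i ≠ j).

Classic Cochran's Q,

    Q = Σᵢ wᵢ (θ̂ᵢ − θ̄_w)²,  wᵢ = 1/SEᵢ²,

assumes independence and is therefore *conservative* here — the shared SAT
removes between-comparison variability that the weights expect to see, so Q's
null rejection rate falls far below its nominal level and power is lost.

### Adjusted Q

The adjusted test replaces the independence assumption with an estimated
covariance matrix Σ of θ̂:

1. **Σ by bootstrap.** Per bootstrap iteration b = 1..B, draw one resample of
   the SAT shared by all k comparisons and an independent resample of each
   rwCC; recompute the k effect estimates. Σ̂ is the empirical covariance of
   the B vectors (B = 1000 by default).
2. **Whitening.** With L the lower Cholesky factor of Σ̂, the transformed
   vector L⁻¹θ̂ has (approximately) identity covariance.
3. **Q on the whitened scale.** The statistic actually computed is the
   generalized least squares quadratic form

       Q_adj = θ̂ᵀΣ⁻¹θ̂ − (1ᵀΣ⁻¹θ̂)² / (1ᵀΣ⁻¹1),

   evaluated stably through the whitened representation
   (z = L⁻¹θ̂, u = L⁻¹1, Q_adj = zᵀz − (uᵀz)²/(uᵀu)). This is the standard
   heterogeneity statistic for dependent estimates: it subtracts the
   GLS-projected common mean rather than treating the whitened coordinates as
   exchangeable, reduces *exactly* to Cochran's Q when Σ is diagonal, and is
   χ²(k−1) under homogeneity when Σ is known. Step 2 alone does not define a
   common-mean projection, so this quadratic form is the well-posed reading of
   the three-step recipe.

With Σ estimated (finite B, finite arms), the χ²(k−1) reference is an
approximation and can inflate the Type I error slightly; at B = 1000 and 100
subjects per arm the measured null size is ≈ 0.055 at α = 0.05.
Bootstrap-calibrated reference distributions are out of scope.

The companion fixed-effect pooled estimate uses the same Σ:
`θ̂_pool = (1ᵀΣ⁻¹θ̂)/(1ᵀΣ⁻¹1)` with `SE = (1ᵀΣ⁻¹1)^{−1/2}`; positive
off-diagonal covariance widens this SE relative to naive inverse-variance
pooling.

### Bootstrap implementation

Subject-level resampling of an exchangeable 0/1 outcome vector with
replacement gives a responder count that is exactly Binomial(n, r/n), so the
engine draws counts directly — one shared SAT draw per iteration, reused
across all k comparisons, then one independent draw per rwCC, in a fixed
order. This is distributionally identical to index-level resampling (nothing
but the counts enters any estimate) and orders of magnitude faster.

Zero cells in a resampled 2×2 table get the Haldane–Anscombe +0.5 on every
cell (log odds ratio only), keeping bootstrap replicates finite.

### PSD repair and singularities

Estimated covariance matrices are symmetrized; eigenvalues below
−10⁻¹⁰·tr(Σ)/k trigger a clip-to-zero projection (counted and reported by the
CLI); a diagonal jitter of 10⁻¹⁰·tr(Σ)/k is added before Cholesky. A matrix
that is *structurally* rank-deficient (smallest eigenvalue ≤ 10⁻¹⁰ of the
largest, e.g. two collinear comparisons) raises an error naming the offending
pair rather than being silently jittered into invertibility.

## IPD heterogeneity test

When subject-level data from the rwCCs can be combined, the cohorts are
compared directly. The default is the logistic-regression Wald test of cohort
membership, which without covariates is the closed-form 2×2 log-odds-ratio
z-test (the closed form and the regression fit are cross-checked in the test
suite). Switches: likelihood-ratio (the 2×2 deviance G²) and the exact
conditional test (`fisher_exact`). Degenerate tables where the Wald estimate
is unbounded (a zero cell) fall back to the exact conditional test; two
cohorts with equal observed proportions give p = 1 directly.

Optional per-subject weights support ATT ("average treatment effect on the
treated") weighting: a logistic propensity model for SAT membership is fitted
on the stacked covariates (constant columns dropped; perfect separation is a
hard error signalling non-overlap), and each rwCC subject receives the odds
e(x)/(1−e(x)). Weights are normalized to mean 1 before entering the weighted
logistic fit as frequency weights, making the test invariant to uniform
rescaling; uniform weights reproduce the unweighted test exactly.

## Simulation studies

### Detection study (power curves)

Per replicate: SAT and two rwCCs of 100 subjects each are drawn with true
response rates (0.5, 0.5, RR₂); RR₂ traces the grid. Three tests are applied
at α = 0.05: classic Cochran's Q on the two risk-difference estimates with
analytic SEs, the Adjusted Q with a B = 1000 bootstrap Σ̂, and the IPD Wald
test between the rwCCs. 1000 replicates per grid point. Expected behaviour,
confirmed by the acceptance suite: classic Q's null size ≪ 0.05, Adjusted Q
close to nominal, and Adjusted-Q power indistinguishable from the IPD method
and well above classic Q.

### Test-then-pool study (operating characteristics)

The design under study: the SAT (n = 50, sized for 90% power against an
80%-vs-50% response difference at two-sided 5%) is to be compared to two
pooled rwCCs of 25 subjects each. The two-step rule pools the rwCCs only if
an IPD heterogeneity test between them has p > 0.10, then tests SAT vs the
merged arm at 5%. Recorded per grid point: pooling probability, rejection
conditional on pooling, rejection if always pooling, the closed-form expected
difference under always-pooling (RR_SAT − (RR₁+RR₂)/2), and the average
estimated difference among pooled replicates — each with its Monte Carlo
standard error. Degenerate arms are analyzed as-is; replicates are never
discarded (discarding would bias the operating characteristics).

**Which binary tests?** Exact size/power enumeration over all 2×2 tables
identifies the *exact conditional* test as the calibration that reproduces
the reference operating characteristics at these sample sizes: at n = 25 per
cohort and threshold 0.10 its heterogeneity-detection rate for true rates
0.5 vs 0.5/0.4/0.3/0.2 is 0.065/0.131/0.334/0.638 (the asymptotic
Wald/LRT/score tests all have size ≈ 0.12 at the null), and at n = 50 vs 50
its power for 80% vs 50% at α = 0.05 is 0.853 (Pearson χ² without correction:
0.895). The pooling-study configuration therefore defaults to
`het_method="fisher_exact"` and `comparison_test="fisher"`; both steps are
switchable (`wald`/`lrt`, `pearson`/`pearson_corrected`).

The engine is fully vectorized across replicates: without covariates every
test reduces to a closed form or a cached exact test on counts, so 10⁵
replicates take about a second on one CPU.

### Randomness

All streams derive from a root seed plus a content hash (SHA-256) of the
scenario parameters and grid point — never from spawn order — so adding or
reordering grid points cannot perturb other grid points' results, and every
entry point is bit-reproducible given its config and seed. The detection
study additionally keys per replicate and per role (SAT draw, each rwCC
draw, bootstrap); the vectorized pooling engine keys per role and draws each
role's replicate vector in one call.

### Design sample size

`required_sample_size` implements the standard normal-approximation
two-proportion formula (pooled variance under the null), rounded up. For the
reference design (80% vs 50%, 90% power, α = 0.05) the continuous formula
value is 51.01, i.e. 52 after ceiling and "roughly 50" at the design's
granularity of ten.

## What the generator does and does not emulate

Arms are independent binomial draws; heterogeneity/bias is injected directly
through the second rwCC's true response rate. Real pooled-RWD analyses face
covariate confounding, missing or differentially-ascertained outcomes, and
deduplication across sources — none of which are simulated (ATT weighting is
exposed but no confounded scenario is generated). Passing tests therefore
validate the *statistical machinery* under clean sampling, not robustness to
real-world data quality issues.

## Default problem sizes

Library defaults mirror the reference study conditions (1000 replicates and
B = 1000 for detection; 10⁵ replicates for the null pooling scenario and 10⁶
for the effective-treatment scenario in the packaged configs). The packaged
acceptance script uses 2×10⁴ (null scenario), 5×10⁴ (effective-treatment
scenario), and 1000×B=1000 (detection) — scales at which every reported
quantity's Monte Carlo standard error is at least an order of magnitude
smaller than the effects of interest.

## Known limitations

- χ²(k−1) reference with estimated Σ (mild null inflation; no bootstrap
  calibration of the reference distribution).
- Binary outcomes only; no time-to-event measures, no matching estimators,
  no random-effects meta-analysis for many rwCCs.
- The weighted IPD test treats normalized ATT weights as frequency weights;
  no robust (sandwich) variance is implemented.
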