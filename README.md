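# poolhet

Heterogeneity assessment for pooled real-world comparator cohorts of a
single-arm trial.

## The problem

Single-arm trials (SATs) in rare — often genomically defined — populations
frequently lack a randomized control arm. A common workaround is an external
control assembled by **pooling several real-world comparator cohorts
(rwCCs)**. Pooling is only defensible if the cohorts are homogeneous:
comparing the SAT to any one rwCC should give the same answer up to sampling
variability. Testing that assumption is awkward, because the k SAT-vs-rwCC
effect estimates all reuse the *same* SAT arm and are therefore positively
correlated — classic Cochran's Q, which assumes independence, becomes
severely conservative and underpowered.

`poolhet` provides, for binary response outcomes:

- **Adjusted Q** — Cochran's Q generalized to correlated estimates. A
  bootstrap that shares one SAT resample across all comparisons estimates the
  covariance matrix Σ of the effect vector θ̂; after whitening by the inverse
  Cholesky factor Σ^(−1/2), the test statistic is the GLS quadratic form

      Q = θ̂ᵀΣ⁻¹θ̂ − (1ᵀΣ⁻¹θ̂)² / (1ᵀΣ⁻¹1)  ~  χ²(k−1),

  which reduces exactly to Cochran's Q when Σ is diagonal.
- **IPD heterogeneity testing** — direct subject-level comparison of the
  rwCCs (logistic Wald / LRT / exact conditional), with optional
  propensity-based ATT weighting toward the SAT.
- **Dependence-aware fixed-effect pooling** — `(1ᵀΣ⁻¹θ̂)/(1ᵀΣ⁻¹1)` with
  SE `(1ᵀΣ⁻¹1)^(−1/2)`.
- **Monte-Carlo study engines** — power curves for the three heterogeneity
  tests, and the operating characteristics (pooling probability, type I
  error, power, bias) of the *test-then-pool* two-step rule that pools the
  rwCCs only when a heterogeneity test does not reject.

See `docs/methods.md` for the full model description, numerical policies and
limitations.

## Worked example

Three synthetic subject-level cohorts: a SAT and one rwCC with a 50% true
response rate, and a second rwCC biased down to 35%:

```sh
poolhet --seed 7 --out-dir . fixture --n 100 --rr 0.5  --label SAT       --out sat.csv
poolhet --seed 8 --out-dir . fixture --n 100 --rr 0.5  --label registryA --out rwcc_a.csv
poolhet --seed 9 --out-dir . fixture --n 100 --rr 0.35 --label registryB --out rwcc_b.csv
poolhet --seed 1 --out-dir . adjq --sat sat.csv --rwcc rwcc_a.csv --rwcc rwcc_b.csv
```

which prints (abridged):

```json
{
  "estimates": [
    {"measure": "risk_difference", "value": -0.08, "se": 0.0703},
    {"measure": "risk_difference", "value":  0.06, "se": 0.0688}
  ],
  "cochran_q":  {"Q": 2.026, "df": 1, "p_value": 0.1547},
  "adjusted_q": {"Q": 4.216, "df": 1, "p_value": 0.0400},
  "gls_pooled_estimate": {"value": -0.0011, "se": 0.0617}
}
```

The two risk differences (−0.08 vs +0.06) disagree by 14 points. Classic
Cochran's Q treats them as independent, over-counts their joint variance, and
misses the heterogeneity (p = 0.15); the Adjusted Q accounts for the shared
SAT and flags it (p = 0.04). The GLS pooled estimate is what a fixed-effect
meta-analysis with dependence-corrected SE would report *if* one pooled
anyway.

The same machinery from Python:

```python
from poolhet import PoolingConfig, run_test_then_pool_study

oc = run_test_then_pool_study(PoolingConfig(rr_rwcc2_grid=(0.5, 0.2),
                                            replicates=20_000, seed=1))
print(oc.frame)
```

```
 rr_rwcc2  pooling_probability  rejection_conditional_on_pooling  rejection_if_always_pool  average_difference_when_pooling
      0.5               0.9349                            0.0371                    0.0369                          -0.0011
      0.2               0.3678                            0.3037                    0.2695                           0.1606
```

Reading the second row (a 30-point bias in one rwCC of 25 subjects): the
heterogeneity screen catches the bias only 63% of the time (pooling
probability 0.37), and *conditional on pooling* the type I error of the
SAT-vs-pooled comparison is 30% — six times the nominal 5%. This is the
central caution the simulations quantify: with small cohorts, test-then-pool
offers weak protection, so heterogeneity tests are best used descriptively.

Study configurations can also be supplied as YAML (`poolhet pool --config
...`); packaged scenario files live in `src/poolhet/scenarios/`. Every CLI
run writes a manifest (config echo, seed, version, output checksums) from
which it can be reproduced exactly.

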