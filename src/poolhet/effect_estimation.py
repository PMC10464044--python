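"""Effect estimates and subject-level tests for binary-outcome arms.

This module covers the individual-participant-data (IPD) side of comparing a
single-arm trial (SAT) to real-world comparator cohorts (rwCCs) with a binary
response outcome:

* :class:`ArmData` holds one arm (counts, optionally per-subject outcomes and
  baseline covariates).
* :func:`estimate_effect` computes a SAT-vs-rwCC contrast (risk difference or
  log odds ratio) with its analytic standard error.
* :func:`ipd_heterogeneity_test` compares two rwCCs directly at the subject
  level — the "IPD method" of heterogeneity assessment — via logistic
  regression (Wald by default) or the exact conditional test.
* :func:`att_weights` fits a propensity model and returns
  average-treatment-effect-on-the-treated odds weights that reweight a rwCC
  toward the SAT's covariate distribution.
* :func:`sat_vs_pooled_test` is the primary-analysis comparison of the SAT
  against a (possibly pooled) comparator arm.

Effects are oriented SAT minus rwCC (risk difference) or SAT over rwCC (odds
ratio), so a beneficial treatment gives positive values.
"""

from __future__ import annotations

import dataclasses
import warnings
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RISK_DIFFERENCE = "risk_difference"
LOG_ODDS_RATIO = "log_odds_ratio"
MEASURES = (RISK_DIFFERENCE, LOG_ODDS_RATIO)

#: running counts of degenerate-data policy activations (reported by the CLI)
policy_counters = {"zero_cell_corrections": 0, "exact_test_fallbacks": 0}


def reset_policy_counters() -> None:
    for key in policy_counters:
        policy_counters[key] = 0


class SeparationError(ValueError):
    """Propensity model is perfectly separated: the arms do not overlap."""


@dataclasses.dataclass
class ArmData:
    """One treatment arm with a binary response outcome.

    Parameters
    ----------
    label : str
        Cohort identifier.
    n : int
        Number of subjects (>= 1 for any analysis).
    responders : int
        Number of subjects with ``outcome == 1``; ``0 <= responders <= n``.
    outcomes : ndarray of 0/1, optional
        Per-subject outcomes; must sum to ``responders``.
    covariates : ndarray (n, p), optional
        Per-subject baseline covariates.
    """

    label: str
    n: int
    responders: int
    outcomes: Optional[np.ndarray] = None
    covariates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.n = int(self.n)
        self.responders = int(self.responders)
        if self.n < 0:
            raise ValueError(f"arm {self.label!r}: n must be >= 0, got {self.n}")
        if not 0 <= self.responders <= self.n:
            raise ValueError(
                f"arm {self.label!r}: responders must be in [0, n], "
                f"got {self.responders} with n={self.n}"
            )
        if self.outcomes is not None:
            self.outcomes = np.asarray(self.outcomes, dtype=np.int8)
            if self.outcomes.shape != (self.n,):
                raise ValueError(f"arm {self.label!r}: outcomes must have length n")
            if not np.isin(self.outcomes, (0, 1)).all():
                raise ValueError(f"arm {self.label!r}: outcomes must be 0/1")
            if int(self.outcomes.sum()) != self.responders:
                raise ValueError(
                    f"arm {self.label!r}: outcomes sum to {int(self.outcomes.sum())},"
                    f" expected responders={self.responders}"
                )
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.n:
                raise ValueError(f"arm {self.label!r}: covariates must have n rows")

    @classmethod
    def from_counts(cls, label: str, n: int, responders: int) -> "ArmData":
        return cls(label=label, n=n, responders=responders)

    @classmethod
    def from_outcomes(cls, label, outcomes, covariates=None) -> "ArmData":
        outcomes = np.asarray(outcomes, dtype=np.int8)
        return cls(
            label=label,
            n=outcomes.size,
            responders=int(outcomes.sum()),
            outcomes=outcomes,
            covariates=covariates,
        )

    @property
    def p_hat(self) -> float:
        """Observed response rate."""
        if self.n == 0:
            raise ValueError(f"arm {self.label!r} is empty")
        return self.responders / self.n

    def subject_outcomes(self) -> np.ndarray:
        """Per-subject outcomes, expanding counts deterministically.

        When only counts are stored, subjects are materialized responders
        first (so expansion is reproducible); order carries no information
        for any statistic in this package.
        """
        if self.outcomes is not None:
            return np.asarray(self.outcomes)
        out = np.zeros(self.n, dtype=np.int8)
        out[: self.responders] = 1
        return out

    def pooled_with(self, other: "ArmData", label: str = "pooled") -> "ArmData":
        """Merge two arms into one (concatenating any subject-level data)."""
        outcomes = None
        if self.outcomes is not None and other.outcomes is not None:
            outcomes = np.concatenate([self.outcomes, other.outcomes])
        return ArmData(
            label=label,
            n=self.n + other.n,
            responders=self.responders + other.responders,
            outcomes=outcomes,
        )


@dataclasses.dataclass
class EffectEstimate:
    """A point estimate of a treatment-effect contrast with its SE."""

    measure: str
    value: float
    se: float

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.measure == RISK_DIFFERENCE and not -1.0 <= self.value <= 1.0:
            raise ValueError("risk difference must lie in [-1, 1]")

    def to_record(self) -> dict:
        return {"measure": self.measure, "value": self.value, "se": self.se}

    @classmethod
    def from_record(cls, record: dict) -> "EffectEstimate":
        return cls(record["measure"], record["value"], record["se"])


@dataclasses.dataclass
class TestResult:
    """A test statistic with its two-sided p-value."""

    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclasses.dataclass
class SatPooledComparison:
    """Outcome of the primary SAT-vs-pooled-comparator analysis."""

    test: TestResult
    difference: float  # p_hat(SAT) - p_hat(pooled rwCC)
    alpha: float
    reject: bool


# ---------------------------------------------------------------------------
# effect estimation


def _cells(sat: ArmData, rwcc: ArmData) -> tuple[float, float, float, float]:
    return (
        float(sat.responders),
        float(sat.n - sat.responders),
        float(rwcc.responders),
        float(rwcc.n - rwcc.responders),
    )


def estimate_effect(
    sat: ArmData, rwcc: ArmData, measure: str = RISK_DIFFERENCE
) -> EffectEstimate:
    """Estimate the SAT-vs-rwCC contrast on the requested scale.

    Risk difference: ``p_SAT - p_rwCC`` with the usual binomial SE.
    Log odds ratio: Woolf SE from reciprocal cell counts; if any cell of the
    2x2 table is zero, 0.5 is added to every cell (Haldane–Anscombe) so the
    estimate and SE stay finite.
    """
    if sat.n < 1 or rwcc.n < 1:
        raise ValueError("both arms must contain at least one subject")
    if measure == RISK_DIFFERENCE:
        ps, pc = sat.p_hat, rwcc.p_hat
        se = np.sqrt(ps * (1 - ps) / sat.n + pc * (1 - pc) / rwcc.n)
        return EffectEstimate(measure, ps - pc, float(se))
    if measure == LOG_ODDS_RATIO:
        a, b, c, d = _cells(sat, rwcc)
        if min(a, b, c, d) == 0:
            policy_counters["zero_cell_corrections"] += 1
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        value = np.log(a / b) - np.log(c / d)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return EffectEstimate(measure, float(value), float(se))
    raise ValueError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# two-sample tests on 2x2 tables (closed forms shared with the simulation
# engine; the unweighted logistic Wald test on a cohort indicator is exactly
# the 2x2 log-odds-ratio z-test)


@lru_cache(maxsize=100_000)
def _fisher_p(r1: int, n1: int, r2: int, n2: int) -> float:
    return float(stats.fisher_exact([[r1, n1 - r1], [r2, n2 - r2]])[1])


def wald_2x2(r1, n1, r2, n2):
    """Vectorized two-sided Wald z-test of the 2x2 log odds ratio.

    Degenerate tables (any zero cell, where the Wald estimate is unbounded)
    fall back to the exact conditional test, except that equal observed
    proportions give p = 1 directly.  Returns ``(z, p)`` arrays.
    """
    scalar = np.ndim(r1) == 0 and np.ndim(r2) == 0
    r1 = np.atleast_1d(np.asarray(r1, dtype=float))
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    a, b = r1, n1 - r1
    c, d = r2, n2 - r2
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logor = np.log(a * d) - np.log(b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = np.where(zero, 0.0, logor / np.where(se > 0, se, 1.0))
    p = 2.0 * stats.norm.sf(np.abs(z))
    for i in np.nonzero(zero)[0]:
        x1, x2 = int(r1[i % r1.size]), int(r2[i % r2.size])
        if x1 * n2 == x2 * n1:  # equal observed proportions
            p[i] = 1.0
        else:
            policy_counters["exact_test_fallbacks"] += 1
            p[i] = _fisher_p(x1, int(n1), x2, int(n2))
    if scalar:
        return float(z[0]), float(p[0])
    return z, p


def g2_2x2(r1: int, n1: int, r2: int, n2: int) -> tuple[float, float]:
    """Likelihood-ratio (deviance) test on a 2x2 table: ``(G2, p)``.

    Identical to the logistic-regression LRT of cohort membership; finite for
    zero cells (``0 * log 0 = 0``).
    """
    obs = np.array([[r1, n1 - r1], [r2, n2 - r2]], dtype=float)
    total = obs.sum()
    if total == 0 or obs.sum(axis=1).min() == 0:
        return 0.0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():  # a margin is empty: no information
        return 0.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = obs * np.log(obs / expected)
    g2 = 2.0 * float(np.nansum(terms))
    g2 = max(g2, 0.0)
    return g2, float(stats.chi2.sf(g2, 1))


def pearson_chi2_2x2(r1, n1, r2, n2):
    """Vectorized Pearson chi-square (no continuity correction): (stat, p).

    Degenerate margins (a row or column total of zero) give statistic 0 and
    p = 1; such tables carry no evidence against equality.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    a, b = r1, n1 - r1
    c, d = r2, n2 - r2
    total = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, total * (a * d - b * c) ** 2 / np.where(den > 0, den, 1.0), 0.0)
    p = stats.chi2.sf(stat, 1)
    if np.ndim(r1) == 0:
        return float(np.asarray(stat).reshape(())), float(np.asarray(p).reshape(()))
    return stat, p


# ---------------------------------------------------------------------------
# IPD heterogeneity test


def _weighted_glm_test(y, x, weights, method):
    import statsmodels.api as sm

    exog = sm.add_constant(x)
    model = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=weights)
    fit = model.fit()
    if method == "wald":
        z = fit.params[1] / fit.bse[1]
        return TestResult(float(z), float(2 * stats.norm.sf(abs(z))), "ipd_logistic_wald_weighted")
    null = sm.GLM(y, np.ones_like(y, dtype=float), family=sm.families.Binomial(),
                  freq_weights=weights).fit()
    g2 = float(null.deviance - fit.deviance)
    g2 = max(g2, 0.0)
    return TestResult(g2, float(stats.chi2.sf(g2, 1)), "ipd_logistic_lrt_weighted")


def ipd_heterogeneity_test(
    rwcc_a: ArmData,
    rwcc_b: ArmData,
    weights: Optional[Sequence[float]] = None,
    method: str = "wald",
) -> TestResult:
    """Direct subject-level comparison of two comparator cohorts.

    The null hypothesis is that both cohorts share the same response rate —
    the homogeneity assumption behind pooling them into a single comparator
    arm. ``method`` selects the logistic-regression Wald test (default), the
    likelihood-ratio test, or the exact conditional test (``fisher_exact``).

    ``weights`` are per-subject nonnegative weights over the concatenated
    subjects (cohort a first). They are normalized to mean 1 before use, so
    the test is invariant to uniform rescaling; all-equal weights reproduce
    the unweighted test.
    """
    if method not in ("wald", "lrt", "fisher_exact"):
        raise ValueError(f"unknown method {method!r}")
    if rwcc_a.n < 1 or rwcc_b.n < 1:
        raise ValueError("both cohorts must contain at least one subject")
    r1, n1 = rwcc_a.responders, rwcc_a.n
    r2, n2 = rwcc_b.responders, rwcc_b.n

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n1 + n2,):
            raise ValueError("weights must align with the concatenated subjects")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.allclose(w, w[0]):
            weights = None  # uniform: identical to the unweighted test
        elif method == "fisher_exact":
            raise ValueError("fisher_exact does not support weights")
        else:
            w = w / w.mean()
            y = np.concatenate([rwcc_a.subject_outcomes(), rwcc_b.subject_outcomes()])
            x = np.concatenate([np.zeros(n1), np.ones(n2)])
            wr1, wr2 = float(w[:n1] @ (y[:n1])), float(w[n1:] @ (y[n1:]))
            wn1, wn2 = float(w[:n1].sum()), float(w[n1:].sum())
            degenerate = min(wr1, wn1 - wr1, wr2, wn2 - wr2) <= 1e-12
            if degenerate:
                if abs(wr1 / wn1 - wr2 / wn2) < 1e-12:
                    return TestResult(0.0, 1.0, "ipd_degenerate_equal")
                policy_counters["exact_test_fallbacks"] += 1
                warnings.warn(
                    "degenerate weighted fit; falling back to the exact "
                    "conditional test on unweighted counts",
                    stacklevel=2,
                )
                p = _fisher_p(r1, n1, r2, n2)
                return TestResult(np.nan, p, "ipd_fisher_exact_fallback")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return _weighted_glm_test(y, x, w, method)

    if method == "fisher_exact":
        p = _fisher_p(r1, n1, r2, n2)
        return TestResult(np.nan, p, "ipd_fisher_exact")
    if method == "lrt":
        g2, p = g2_2x2(r1, n1, r2, n2)
        return TestResult(g2, p, "ipd_logistic_lrt")
    z, p = wald_2x2(r1, n1, r2, n2)
    label = "ipd_logistic_wald"
    if min(r1, n1 - r1, r2, n2 - r2) == 0:
        label = (
            "ipd_degenerate_equal"
            if r1 * n2 == r2 * n1
            else "ipd_fisher_exact_fallback"
        )
    return TestResult(float(z), float(p), label)


# ---------------------------------------------------------------------------
# propensity-based ATT weighting


def att_weights(sat: ArmData, rwcc: ArmData) -> np.ndarray:
    """Odds weights rebalancing a rwCC toward the SAT's covariate mix.

    Fits a logistic propensity model for SAT membership on the stacked
    covariates and returns ``e(x) / (1 - e(x))`` for every rwCC subject
    (SAT subjects implicitly carry weight 1). This is the standard
    average-treatment-effect-on-the-treated weighting.

    Raises
    ------
    SeparationError
        If the propensity model is perfectly separated, i.e. the covariate
        distributions do not overlap.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if sat.covariates is None or rwcc.covariates is None:
        raise ValueError("both arms must carry covariates")
    if sat.covariates.shape[1] != rwcc.covariates.shape[1]:
        raise ValueError("covariate dimensions differ between arms")
    X = np.vstack([sat.covariates, rwcc.covariates])
    # constant columns are collinear with the intercept; drop them
    keep = X.std(axis=0) > 1e-12
    X = X[:, keep]
    y = np.concatenate([np.ones(sat.n), np.zeros(rwcc.n)])
    exog = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(
            "propensity model perfectly separated: SAT and rwCC covariates do not overlap"
        ) from err
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        raise SeparationError(
            "propensity model perfectly separated: SAT and rwCC covariates do not overlap"
        )
    e = fit.predict(exog[sat.n :])
    if np.any(e >= 1 - 1e-10):
        raise SeparationError("propensity scores of 1 among rwCC subjects: no overlap")
    return np.asarray(e / (1 - e), dtype=float)


# ---------------------------------------------------------------------------
# SAT vs pooled comparator


def sat_vs_pooled_test(
    sat: ArmData,
    pooled_rwcc: ArmData,
    alpha: float = 0.05,
    test: str = "pearson",
) -> SatPooledComparison:
    """Two-sided comparison of the SAT against the pooled comparator arm.

    ``test`` is one of ``pearson`` (chi-square without continuity
    correction), ``pearson_corrected`` (Yates), or ``fisher`` (exact).
    The estimated effect is the response-rate difference
    ``p_SAT - p_pooled``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if sat.n < 1 or pooled_rwcc.n < 1:
        raise ValueError("both arms must contain at least one subject")
    r1, n1 = sat.responders, sat.n
    r2, n2 = pooled_rwcc.responders, pooled_rwcc.n
    if test == "pearson":
        stat, p = pearson_chi2_2x2(r1, n1, r2, n2)
        result = TestResult(stat, p, "pearson_chi2")
    elif test == "pearson_corrected":
        table = [[r1, n1 - r1], [r2, n2 - r2]]
        if min(r1 + r2, (n1 - r1) + (n2 - r2)) == 0:
            result = TestResult(0.0, 1.0, "pearson_chi2_yates")
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=True)
            result = TestResult(float(stat), float(p), "pearson_chi2_yates")
    elif test == "fisher":
        p = _fisher_p(r1, n1, r2, n2)
        result = TestResult(np.nan, p, "fisher_exact")
    else:
        raise ValueError(f"unknown test {test!r}")
    diff = sat.p_hat - pooled_rwcc.p_hat
    return SatPooledComparison(
        test=result, difference=float(diff), alpha=alpha, reject=result.p_value <= alpha
    )


# ---------------------------------------------------------------------------
# delimited-text input


def read_subject_table(source) -> list[ArmData]:
    """Read subject-level arms from CSV (or a DataFrame).

    Expected columns: ``cohort_label``, ``outcome`` (0/1), and optionally
    further numeric covariate columns. Returns one :class:`ArmData` per
    cohort, in order of first appearance.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    for col in ("cohort_label", "outcome"):
        if col not in df.columns:
            raise ValueError(f"subject-level table must contain a {col!r} column")
    cov_cols = [c for c in df.columns if c not in ("cohort_label", "outcome")]
    arms = []
    for label in df["cohort_label"].drop_duplicates():
        sub = df[df["cohort_label"] == label]
        covs = sub[cov_cols].to_numpy(dtype=float) if cov_cols else None
        arms.append(
            ArmData.from_outcomes(str(label), sub["outcome"].to_numpy(), covariates=covs)
        )
    return arms


def read_counts_table(source) -> list[ArmData]:
    """Read arm-level counts from CSV with columns cohort_label, n, responders."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    for col in ("cohort_label", "n", "responders"):
        if col not in df.columns:
            raise ValueError(f"counts table must contain a {col!r} column")
    return [
        ArmData.from_counts(str(row.cohort_label), int(row.n), int(row.responders))
        for row in df.itertuples()
    ]
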