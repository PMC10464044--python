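"""Monte-Carlo engines for heterogeneity detection and test-then-pool studies.

Two study designs are implemented:

* the *detection study*: one SAT and two rwCCs are simulated per replicate;
  the rejection probability of classic Cochran's Q, the Adjusted Q (with a
  bootstrap covariance matrix), and the direct IPD test is traced along a
  grid of true response rates for the second rwCC
  (:func:`run_detection_study`, returning a :class:`PowerCurve`);

* the *test-then-pool study*: a two-step procedure that pools two rwCCs into
  one comparator arm only if an IPD heterogeneity test between them does not
  reject, then compares the SAT to the pooled arm
  (:func:`run_test_then_pool_study`, returning
  :class:`OperatingCharacteristics` — pooling probability, rejection rates
  conditional on pooling and under always-pooling, and the estimated
  response-rate difference, each with a Monte Carlo standard error).

Randomness is content-keyed: every stream is derived from the root seed plus
a stable hash of the scenario and the grid point (and, in the detection
study, the replicate index and role), so adding grid points or reordering
the grid never perturbs the draws of other grid points.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import effect_estimation as ee
from . import heterogeneity as het
from .effect_estimation import ArmData, MEASURES, RISK_DIFFERENCE

IPD_METHODS = ("wald", "lrt", "fisher_exact")
COMPARISON_TESTS = ("pearson", "pearson_corrected", "fisher")


class ConfigError(ValueError):
    """Invalid configuration; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


def _check(ok: bool, field: str, message: str) -> None:
    if not ok:
        raise ConfigError(field, message)


def _key_int(*parts) -> int:
    """Stable 62-bit integer key from the string form of the parts."""
    text = "|".join(f"{p:.12g}" if isinstance(p, float) else str(p) for p in parts)
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big") >> 2


def _stream(seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed) % (2**31), _key_int(*parts)))
    )


def _probability(x) -> bool:
    return np.isscalar(x) and 0.0 <= float(x) <= 1.0


# ---------------------------------------------------------------------------
# configurations


@dataclasses.dataclass
class DetectionConfig:
    """Scenario for the heterogeneity-detection (power curve) study.

    Defaults are the study conditions of the reference design: 100 subjects
    in the SAT and in each rwCC, true response rate 50% in the SAT and the
    first rwCC, 1000 replicates, 1000 bootstrap samples per replicate, tests
    at the two-sided 5% level on the risk-difference scale.
    """

    n_sat: int = 100
    n_rwcc: int = 100
    rr_sat: float = 0.5
    rr_rwcc1: float = 0.5
    rr_rwcc2_grid: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    replicates: int = 1000
    bootstrap_B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    effect_measure: str = RISK_DIFFERENCE
    ipd_method: str = "wald"

    def validate(self) -> None:
        _check(int(self.n_sat) >= 1, "n_sat", "must be a positive integer")
        _check(int(self.n_rwcc) >= 1, "n_rwcc", "must be a positive integer")
        _check(_probability(self.rr_sat), "rr_sat", "must be a probability in [0, 1]")
        _check(_probability(self.rr_rwcc1), "rr_rwcc1", "must be a probability in [0, 1]")
        _check(
            len(tuple(self.rr_rwcc2_grid)) >= 1
            and all(_probability(r) for r in self.rr_rwcc2_grid),
            "rr_rwcc2_grid",
            "must be a non-empty list of probabilities in [0, 1]",
        )
        _check(int(self.replicates) >= 1, "replicates", "must be >= 1")
        _check(int(self.bootstrap_B) >= 2, "bootstrap_B", "must be >= 2")
        _check(
            np.isscalar(self.alpha) and 0.0 < float(self.alpha) < 1.0,
            "alpha",
            "must lie in (0, 1)",
        )
        _check(self.effect_measure in MEASURES, "effect_measure", f"must be one of {MEASURES}")
        _check(self.ipd_method in IPD_METHODS, "ipd_method", f"must be one of {IPD_METHODS}")

    @classmethod
    def from_dict(cls, data: dict) -> "DetectionConfig":
        return _from_dict(cls, data)


@dataclasses.dataclass
class PoolingConfig:
    """Scenario for the test-then-pool operating-characteristics study.

    Defaults are the reference two-step design: a SAT of 50 subjects
    (designed for 90% power against an 80%-vs-50% response-rate difference)
    and two rwCCs of 25 subjects each; the rwCCs are pooled only if the IPD
    heterogeneity test between them has p > 0.10, and the pooled comparison
    is two-sided at 5%. Both tests default to their exact (conditional)
    forms, which reproduce the reference operating characteristics; see
    docs/methods.md for the calibration analysis.
    """

    n_sat: int = 50
    n_rwcc_each: int = 25
    rr_sat: float = 0.5
    rr_rwcc1: float = 0.5
    rr_rwcc2_grid: Sequence[float] = (0.5, 0.4, 0.3, 0.2)
    het_alpha: float = 0.10
    comparison_alpha: float = 0.05
    replicates: int = 100_000
    seed: int = 0
    het_method: str = "fisher_exact"
    comparison_test: str = "fisher"

    def validate(self) -> None:
        _check(int(self.n_sat) >= 1, "n_sat", "must be a positive integer")
        _check(int(self.n_rwcc_each) >= 1, "n_rwcc_each", "must be a positive integer")
        _check(_probability(self.rr_sat), "rr_sat", "must be a probability in [0, 1]")
        _check(_probability(self.rr_rwcc1), "rr_rwcc1", "must be a probability in [0, 1]")
        _check(
            len(tuple(self.rr_rwcc2_grid)) >= 1
            and all(_probability(r) for r in self.rr_rwcc2_grid),
            "rr_rwcc2_grid",
            "must be a non-empty list of probabilities in [0, 1]",
        )
        _check(
            np.isscalar(self.het_alpha) and 0.0 < float(self.het_alpha) < 1.0,
            "het_alpha",
            "must lie in (0, 1)",
        )
        _check(
            np.isscalar(self.comparison_alpha) and 0.0 < float(self.comparison_alpha) < 1.0,
            "comparison_alpha",
            "must lie in (0, 1)",
        )
        _check(int(self.replicates) >= 1, "replicates", "must be >= 1")
        _check(self.het_method in IPD_METHODS, "het_method", f"must be one of {IPD_METHODS}")
        _check(
            self.comparison_test in COMPARISON_TESTS,
            "comparison_test",
            f"must be one of {COMPARISON_TESTS}",
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PoolingConfig":
        return _from_dict(cls, data)


def _from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - fields)
    if unknown:
        raise ConfigError(unknown[0], "unknown configuration field")
    config = cls(**data)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class PowerCurve:
    """Rejection probability per grid point and method, with MCSEs.

    ``frame`` is tidy: one row per (rr_rwcc2, method) with columns
    ``rejection_rate``, ``mcse``, ``replicates``.
    """

    frame: pd.DataFrame
    config: DetectionConfig

    def rejection_rate(self, method: str, rr_rwcc2: float) -> float:
        sub = self.frame[
            (self.frame["method"] == method)
            & (np.isclose(self.frame["rr_rwcc2"], rr_rwcc2))
        ]
        return float(sub["rejection_rate"].iloc[0])

    def to_tidy(self) -> pd.DataFrame:
        return self.frame.copy()

    def plot(self, path=None):
        """Rejection probability against the second rwCC's true RR."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for method, label in (
            ("cochran_q", "Cochran's Q"),
            ("adjusted_q", "Adjusted Q"),
            ("ipd", "IPD method"),
        ):
            sub = self.frame[self.frame["method"] == method].sort_values("rr_rwcc2")
            ax.errorbar(
                sub["rr_rwcc2"], sub["rejection_rate"], yerr=sub["mcse"],
                marker="o", capsize=2, label=label,
            )
        ax.axhline(self.config.alpha, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("true response rate in second rwCC")
        ax.set_ylabel("probability of detecting heterogeneity")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


@dataclasses.dataclass
class OperatingCharacteristics:
    """Test-then-pool operating characteristics per grid point.

    ``frame`` has one row per ``rr_rwcc2`` with columns
    ``pooling_probability``, ``rejection_conditional_on_pooling``,
    ``rejection_if_always_pool``, ``expected_difference_always_pool``
    (closed form, no MC error), ``average_difference_when_pooling`` and a
    ``*_mcse`` companion for each simulated quantity, plus ``n_pooled`` and
    ``replicates``.
    """

    frame: pd.DataFrame
    config: PoolingConfig

    def value(self, statistic: str, rr_rwcc2: float) -> float:
        sub = self.frame[np.isclose(self.frame["rr_rwcc2"], rr_rwcc2)]
        return float(sub[statistic].iloc[0])

    def to_tidy(self) -> pd.DataFrame:
        stats_cols = [
            "pooling_probability",
            "rejection_conditional_on_pooling",
            "rejection_if_always_pool",
            "expected_difference_always_pool",
            "average_difference_when_pooling",
        ]
        rows = []
        for _, row in self.frame.iterrows():
            for col in stats_cols:
                rows.append(
                    {
                        "rr_rwcc2": row["rr_rwcc2"],
                        "statistic": col,
                        "value": row[col],
                        "mcse": row.get(f"{col}_mcse", 0.0),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# primitives


def simulate_arm(n: int, p: float, rng: np.random.Generator, label: str = "arm") -> ArmData:
    """Draw one binomial arm with materialized subject-level outcomes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    responders = int(rng.binomial(n, p))
    outcomes = np.zeros(n, dtype=np.int8)
    outcomes[:responders] = 1
    return ArmData(label=label, n=n, responders=responders, outcomes=outcomes)


def mcse_proportion(p_hat: float, R: int) -> float:
    """Monte Carlo standard error of a proportion over R replicates."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / R))


def mcse_mean(sd_hat: float, R: int) -> float:
    """Monte Carlo standard error of a mean over R replicates."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return float(sd_hat / np.sqrt(R))


def required_sample_size(
    p_treatment: float, p_control: float, power: float = 0.9, alpha: float = 0.05
) -> int:
    """Per-arm sample size for a two-sided two-proportion comparison.

    Normal-approximation formula with pooled variance under the null:

        n = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2
            / (p1 - p2)^2

    rounded up to the next integer.
    """
    for name, p in (("p_treatment", p_treatment), ("p_control", p_control)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    if p_treatment == p_control:
        raise ValueError("proportions must be distinct")
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("power and alpha must lie in (0, 1)")
    n = _sample_size_exact(p_treatment, p_control, power, alpha)
    return int(np.ceil(n - 1e-12))


def _sample_size_exact(p1: float, p2: float, power: float, alpha: float) -> float:
    """The continuous (unrounded) value of the sample-size formula."""
    pbar = 0.5 * (p1 + p2)
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    num = za * np.sqrt(2.0 * pbar * (1.0 - pbar)) + zb * np.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    return float(num**2 / (p1 - p2) ** 2)


# ---------------------------------------------------------------------------
# detection study (power curves)


def run_detection_study(config: DetectionConfig) -> PowerCurve:
    """Rejection probabilities of Cochran's Q, Adjusted Q and the IPD test.

    Per replicate: simulate the SAT and two rwCCs; form the two SAT-vs-rwCC
    effect estimates; test with (a) classic Cochran's Q using the analytic
    SEs, (b) the Adjusted Q with a bootstrap covariance matrix sharing the
    SAT resample, and (c) the direct IPD comparison of the two rwCCs.
    Rejection is ``p <= alpha``. Degenerate replicates (e.g. a singular
    covariance) are counted as non-rejections, never discarded.
    """
    config.validate()
    scen = (
        "detect", config.n_sat, config.n_rwcc, float(config.rr_sat),
        float(config.rr_rwcc1), config.bootstrap_B, config.effect_measure,
        config.ipd_method,
    )
    R = int(config.replicates)
    rows = []
    for rr2 in config.rr_rwcc2_grid:
        counts = {"cochran_q": 0, "adjusted_q": 0, "ipd": 0}
        grid_key = _key_int(*scen, float(rr2))
        for i in range(R):
            ss = np.random.SeedSequence(
                entropy=(int(config.seed) % (2**31), grid_key, i)
            )
            k_sat, k_c1, k_c2, k_boot = ss.spawn(4)
            sat = simulate_arm(config.n_sat, config.rr_sat,
                               np.random.default_rng(k_sat), "SAT")
            c1 = simulate_arm(config.n_rwcc, config.rr_rwcc1,
                              np.random.default_rng(k_c1), "rwCC1")
            c2 = simulate_arm(config.n_rwcc, float(rr2),
                              np.random.default_rng(k_c2), "rwCC2")
            est1 = ee.estimate_effect(sat, c1, config.effect_measure)
            est2 = ee.estimate_effect(sat, c2, config.effect_measure)
            try:
                q = het.cochran_q([est1, est2])
                counts["cochran_q"] += q.p_value <= config.alpha
            except ValueError:
                pass  # zero SE in a degenerate replicate: no evidence, no rejection
            try:
                cov = het.bootstrap_covariance(
                    sat, [c1, c2], config.effect_measure,
                    B=config.bootstrap_B, rng=np.random.default_rng(k_boot),
                )
                adj = het.adjusted_q([est1.value, est2.value], cov)
                counts["adjusted_q"] += adj.p_value <= config.alpha
            except het.SingularCovarianceError:
                pass
            p_ipd = ee.ipd_heterogeneity_test(c1, c2, method=config.ipd_method).p_value
            counts["ipd"] += p_ipd <= config.alpha
        for method, count in counts.items():
            rate = count / R
            rows.append(
                {
                    "rr_rwcc2": float(rr2),
                    "method": method,
                    "rejection_rate": rate,
                    "mcse": mcse_proportion(rate, R),
                    "replicates": R,
                }
            )
    return PowerCurve(frame=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# test-then-pool study (operating characteristics)


def _het_pvalues(r1, n1, r2, n2, method: str) -> np.ndarray:
    if method == "wald":
        _, p = ee.wald_2x2(r1, n1, r2, n2)
        return np.asarray(p, dtype=float)
    if method == "lrt":
        return np.array([ee.g2_2x2(int(a), n1, int(b), n2)[1] for a, b in zip(r1, r2)])
    # exact conditional test; cache over the (small) set of distinct tables
    p = np.empty(r1.size, dtype=float)
    for idx in range(r1.size):
        p[idx] = ee._fisher_p(int(r1[idx]), n1, int(r2[idx]), n2)
    return p


def _comparison_pvalues(r1, n1, r2, n2, test: str) -> np.ndarray:
    if test == "pearson":
        _, p = ee.pearson_chi2_2x2(r1, n1, r2, n2)
        return np.asarray(p, dtype=float)
    p = np.empty(r1.size, dtype=float)
    if test == "fisher":
        for idx in range(r1.size):
            p[idx] = ee._fisher_p(int(r1[idx]), n1, int(r2[idx]), n2)
        return p
    for idx in range(r1.size):
        p[idx] = ee.sat_vs_pooled_test(
            ArmData("SAT", n1, int(r1[idx])),
            ArmData("pooled", n2, int(r2[idx])),
            test="pearson_corrected",
        ).test.p_value
    return p


def run_test_then_pool_study(config: PoolingConfig) -> OperatingCharacteristics:
    """Operating characteristics of the two-step (test-then-pool) procedure.

    Per replicate: simulate the SAT and the two rwCCs; test the rwCCs for
    heterogeneity at the subject level; pool them iff ``p > het_alpha``;
    among pooled replicates, compare the SAT to the merged comparator at
    ``comparison_alpha`` and record rejection and the estimated
    response-rate difference. The always-pool rejection rate and difference
    are recorded for every replicate regardless of the decision. Degenerate
    arms are analyzed as-is; no replicate is ever discarded.

    The engine is vectorized over replicates (all tests reduce to closed
    forms or cached exact tests on 2x2 counts when no covariates are
    simulated).
    """
    config.validate()
    R = int(config.replicates)
    if R < 100:
        warnings.warn(
            "fewer than 100 replicates: Monte Carlo standard errors are unreliable",
            stacklevel=2,
        )
    n_sat, n_e = int(config.n_sat), int(config.n_rwcc_each)
    n_pool = 2 * n_e
    scen = (
        "pool", n_sat, n_e, float(config.rr_sat), float(config.rr_rwcc1),
        float(config.het_alpha), float(config.comparison_alpha),
        config.het_method, config.comparison_test,
    )
    rows = []
    for rr2 in config.rr_rwcc2_grid:
        key = (*scen, float(rr2))
        r_sat = _stream(config.seed, *key, "sat").binomial(n_sat, config.rr_sat, R)
        r_c1 = _stream(config.seed, *key, "rwcc1").binomial(n_e, config.rr_rwcc1, R)
        r_c2 = _stream(config.seed, *key, "rwcc2").binomial(n_e, float(rr2), R)

        p_het = _het_pvalues(r_c1, n_e, r_c2, n_e, config.het_method)
        pooled = p_het > config.het_alpha

        r_pool = r_c1 + r_c2
        p_cmp = _comparison_pvalues(r_sat, n_sat, r_pool, n_pool, config.comparison_test)
        reject = p_cmp <= config.comparison_alpha
        diff = r_sat / n_sat - r_pool / n_pool

        n_pooled = int(pooled.sum())
        pool_prob = n_pooled / R
        rej_always = float(reject.mean())
        if n_pooled > 0:
            rej_cond = float(reject[pooled].mean())
            avg_diff = float(diff[pooled].mean())
            sd_diff = float(diff[pooled].std(ddof=1)) if n_pooled > 1 else 0.0
            rej_cond_mcse = mcse_proportion(rej_cond, n_pooled)
            avg_diff_mcse = mcse_mean(sd_diff, n_pooled)
        else:
            rej_cond = avg_diff = rej_cond_mcse = avg_diff_mcse = float("nan")
        rows.append(
            {
                "rr_rwcc2": float(rr2),
                "pooling_probability": pool_prob,
                "pooling_probability_mcse": mcse_proportion(pool_prob, R),
                "rejection_conditional_on_pooling": rej_cond,
                "rejection_conditional_on_pooling_mcse": rej_cond_mcse,
                "rejection_if_always_pool": rej_always,
                "rejection_if_always_pool_mcse": mcse_proportion(rej_always, R),
                "expected_difference_always_pool": float(
                    config.rr_sat - 0.5 * (config.rr_rwcc1 + float(rr2))
                ),
                "average_difference_when_pooling": avg_diff,
                "average_difference_when_pooling_mcse": avg_diff_mcse,
                "n_pooled": n_pooled,
                "replicates": R,
            }
        )
    return OperatingCharacteristics(frame=pd.DataFrame(rows), config=config)
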