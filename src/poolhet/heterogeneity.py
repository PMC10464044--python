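"""Aggregate-level heterogeneity tests for SAT-vs-rwCC effect estimates.

When a single-arm trial (SAT) is compared to each of several real-world
comparator cohorts (rwCCs), the resulting effect estimates are *correlated*:
every comparison reuses the same SAT. Classic Cochran's Q assumes
independent estimates and is therefore conservative here — the shared SAT
removes variability that Q's weights expect to see.

This module provides:

* :func:`cochran_q` — the classic (independence-assuming) Q test;
* :func:`bootstrap_covariance` — the k-by-k covariance matrix of the k
  SAT-vs-rwCC estimates, estimated by resampling the SAT once per bootstrap
  iteration (shared across comparisons) and each rwCC independently;
* :func:`whiten` — the inverse-Cholesky transform ``S^{-1/2} theta`` that
  renders the estimates uncorrelated with unit variance;
* :func:`adjusted_q` — Cochran's Q generalized to a known covariance,
  ``Q = theta' S^-1 theta - (1' S^-1 theta)^2 / (1' S^-1 1)``, referred to
  chi-square with k-1 degrees of freedom. For diagonal S this reduces
  exactly to :func:`cochran_q`.
* :func:`gls_pooled_estimate` — the fixed-effect pooled estimate with a
  standard error that accounts for the dependence,
  ``(1' S^-1 theta) / (1' S^-1 1)`` with SE ``sqrt(1 / (1' S^-1 1))``.

With estimated (rather than known) covariance the chi-square reference is
approximate and can inflate the Type I error slightly; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy import linalg, stats

from .effect_estimation import (
    LOG_ODDS_RATIO,
    RISK_DIFFERENCE,
    ArmData,
    EffectEstimate,
)

policy_counters = {"psd_repairs": 0}


def reset_policy_counters() -> None:
    for key in policy_counters:
        policy_counters[key] = 0


class SingularCovarianceError(np.linalg.LinAlgError):
    """Covariance matrix is singular even after PSD repair and jitter."""


@dataclasses.dataclass
class CovMatrix:
    """Covariance matrix of k SAT-vs-rwCC effect estimates."""

    matrix: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = self.matrix.shape[0]
        if self.matrix.shape != (k, k):
            raise ValueError("covariance matrix must be square")
        if len(self.labels) != k:
            raise ValueError("labels must match the matrix dimension")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8 * scale):
            raise ValueError("covariance matrix must be symmetric")
        if (np.diag(self.matrix) < -1e-12 * scale).any():
            raise ValueError("covariance diagonal must be nonnegative")
        if np.linalg.eigvalsh(0.5 * (self.matrix + self.matrix.T)).min() < -1e-6 * scale:
            raise ValueError("covariance matrix must be positive semi-definite")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class QResult:
    """A heterogeneity test statistic with its reference distribution."""

    Q: float
    df: int
    p_value: float
    method: str  # "cochran_q" or "adjusted_q"

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be nonnegative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


ThetaLike = Union[Sequence[float], Sequence[EffectEstimate], np.ndarray]


def _theta_vector(estimates: ThetaLike) -> np.ndarray:
    values = [
        e.value if isinstance(e, EffectEstimate) else float(e) for e in estimates
    ]
    return np.asarray(values, dtype=float)


def cochran_q(estimates: Sequence[EffectEstimate]) -> QResult:
    """Classic Cochran's Q test assuming independent effect estimates.

    ``Q = sum w_i (theta_i - theta_bar)^2`` with inverse-variance weights
    ``w_i = 1/se_i^2`` and the weighted mean ``theta_bar``; chi-square with
    k-1 df under homogeneity.
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q needs at least two effect estimates")
    measures = {e.measure for e in estimates}
    if len(measures) > 1:
        raise ValueError("all estimates must use the same effect measure")
    theta = _theta_vector(estimates)
    se = np.array([e.se for e in estimates], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be strictly positive")
    w = 1.0 / se**2
    theta_bar = float(w @ theta / w.sum())
    q = float(w @ (theta - theta_bar) ** 2)
    df = len(estimates) - 1
    return QResult(q, df, float(stats.chi2.sf(q, df)), "cochran_q")


# ---------------------------------------------------------------------------
# bootstrap covariance of the SAT-vs-rwCC estimate vector


def bootstrap_covariance(
    sat: ArmData,
    rwccs: Sequence[ArmData],
    measure: str = RISK_DIFFERENCE,
    B: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CovMatrix:
    """Bootstrap covariance matrix of the k SAT-vs-rwCC effect estimates.

    For each bootstrap iteration one subject-level resample of the SAT is
    drawn and shared across all k comparisons (this is what induces the
    off-diagonal covariance), together with an independent resample of each
    rwCC. For exchangeable binary outcomes the responder count of an
    n-out-of-n resample with replacement is exactly Binomial(n, r/n), so
    counts are drawn directly; the distribution is identical to resampling
    subject indices.

    Deterministic given ``seed`` (or a supplied ``rng``). Draw order is
    fixed: SAT first, then each rwCC in the given order.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if len(rwccs) < 2:
        raise ValueError("at least two rwCCs are required")
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed or an rng for reproducibility")
        rng = np.random.default_rng(seed)
    r_sat = rng.binomial(sat.n, sat.p_hat, size=B).astype(float)
    p_sat = r_sat / sat.n
    k = len(rwccs)
    theta = np.empty((k, B), dtype=float)
    for i, arm in enumerate(rwccs):
        r_c = rng.binomial(arm.n, arm.p_hat, size=B).astype(float)
        if measure == RISK_DIFFERENCE:
            theta[i] = p_sat - r_c / arm.n
        elif measure == LOG_ODDS_RATIO:
            a, b = r_sat.copy(), sat.n - r_sat
            c, d = r_c, arm.n - r_c
            zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
            a, b = a + 0.5 * zero, b + 0.5 * zero
            c, d = c + 0.5 * zero, d + 0.5 * zero
            theta[i] = np.log(a / b) - np.log(c / d)
        else:
            raise ValueError(f"unknown measure {measure!r}")
    cov = np.cov(theta, ddof=1)
    cov = 0.5 * (cov + cov.T)
    labels = [arm.label for arm in rwccs]
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10 * max(np.trace(cov) / k, 1e-300):
        warnings.warn("bootstrap covariance not PSD; projecting", stacklevel=2)
        cov = _project_psd(cov)
    return CovMatrix(matrix=cov, labels=labels)


def analytic_covariance_risk_difference(
    sat: ArmData, rwccs: Sequence[ArmData]
) -> CovMatrix:
    """Closed-form covariance of risk-difference estimates sharing one SAT.

    ``Var(theta_i) = p_s q_s / n_s + p_i q_i / n_i`` and
    ``Cov(theta_i, theta_j) = p_s q_s / n_s`` for ``i != j`` — both
    estimates contain the same ``-p_hat_SAT`` term. Useful as an oracle for
    the bootstrap estimate.
    """
    ps = sat.p_hat
    v_sat = ps * (1 - ps) / sat.n
    k = len(rwccs)
    cov = np.full((k, k), v_sat)
    for i, arm in enumerate(rwccs):
        pc = arm.p_hat
        cov[i, i] = v_sat + pc * (1 - pc) / arm.n
    return CovMatrix(matrix=cov, labels=[a.label for a in rwccs])


# ---------------------------------------------------------------------------
# whitening and the adjusted Q


def _project_psd(matrix: np.ndarray) -> np.ndarray:
    policy_counters["psd_repairs"] += 1
    vals, vecs = np.linalg.eigh(0.5 * (matrix + matrix.T))
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def _cholesky_factor(cov: CovMatrix) -> np.ndarray:
    """Lower Cholesky factor after PSD repair and diagonal jitter."""
    S = 0.5 * (cov.matrix + cov.matrix.T)
    k = S.shape[0]
    trace = float(np.trace(S))
    if trace <= 0:
        raise SingularCovarianceError("covariance matrix has zero trace")
    eigvals = np.linalg.eigvalsh(S)
    if eigvals.min() < -1e-10 * trace / k:
        S = _project_psd(S)
        eigvals = np.clip(eigvals, 0.0, None)
    # structurally rank-deficient (a collinear pair of comparisons): jitter
    # would only mask the problem, so fail loudly instead
    if eigvals.min() <= 1e-10 * eigvals.max():
        _raise_singular(S, cov)
    S = S + (1e-10 * trace / k) * np.eye(k)
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        _raise_singular(S, cov)


def _raise_singular(S: np.ndarray, cov: CovMatrix) -> None:
    diag = np.clip(np.diag(S), 1e-300, None)
    corr = S / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
    raise SingularCovarianceError(
        "covariance singular after jitter; comparisons "
        f"{cov.labels[i]!r} and {cov.labels[j]!r} are collinear "
        f"(correlation {corr[i, j]:+.4f})"
    ) from None


def whiten(estimates: ThetaLike, cov: CovMatrix) -> np.ndarray:
    """Decorrelate the estimate vector: returns ``L^-1 theta``.

    ``L`` is the lower Cholesky factor of the covariance, so the whitened
    vector has identity covariance when the input covariance is exact.
    """
    theta = _theta_vector(estimates)
    if theta.size != cov.k:
        raise ValueError("estimate vector and covariance dimension differ")
    L = _cholesky_factor(cov)
    return linalg.solve_triangular(L, theta, lower=True)


def adjusted_q(estimates: ThetaLike, cov: CovMatrix) -> QResult:
    """Heterogeneity test for correlated effect estimates (Adjusted Q).

    Computes the generalized least squares quadratic form

        Q = theta' S^-1 theta - (1' S^-1 theta)^2 / (1' S^-1 1)

    through the whitened representation: with ``z = L^-1 theta`` and
    ``u = L^-1 1``, ``Q = z'z - (u'z)^2 / (u'u)``. Under homogeneity with
    known covariance, Q is chi-square with k-1 degrees of freedom; for
    diagonal S this is exactly Cochran's Q.
    """
    theta = _theta_vector(estimates)
    if theta.size != cov.k:
        raise ValueError("estimate vector and covariance dimension differ")
    if theta.size < 2:
        raise ValueError("at least two estimates are required")
    L = _cholesky_factor(cov)
    z = linalg.solve_triangular(L, theta, lower=True)
    u = linalg.solve_triangular(L, np.ones_like(theta), lower=True)
    q = float(z @ z - (u @ z) ** 2 / (u @ u))
    q = max(q, 0.0)
    df = theta.size - 1
    return QResult(q, df, float(stats.chi2.sf(q, df)), "adjusted_q")


def gls_pooled_estimate(
    estimates: ThetaLike, cov: CovMatrix, measure: str = RISK_DIFFERENCE
) -> EffectEstimate:
    """Fixed-effect pooled estimate with dependence-adjusted standard error.

    ``value = (1' S^-1 theta) / (1' S^-1 1)``, ``se = sqrt(1/(1' S^-1 1))``.
    For diagonal S this is the classic inverse-variance fixed-effect
    estimate; off-diagonal covariance (the shared SAT) widens the SE.
    """
    theta = _theta_vector(estimates)
    if theta.size != cov.k:
        raise ValueError("estimate vector and covariance dimension differ")
    L = _cholesky_factor(cov)
    z = linalg.solve_triangular(L, theta, lower=True)
    u = linalg.solve_triangular(L, np.ones_like(theta), lower=True)
    precision = float(u @ u)
    value = float(u @ z / precision)
    return EffectEstimate(measure=measure, value=value, se=float(np.sqrt(1.0 / precision)))


# ---------------------------------------------------------------------------
# JSON interface (for sites that can share aggregates but not IPD)


def estimates_from_json(source) -> tuple[np.ndarray, CovMatrix]:
    """Parse ``{"estimates": [...], "cov": [[...]], "labels": [...]}``.

    ``labels`` is optional; missing labels are numbered. Accepts a JSON
    string, a dict, or a file path.
    """
    if isinstance(source, dict):
        payload = source
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    theta = np.asarray(payload["estimates"], dtype=float)
    cov = np.asarray(payload["cov"], dtype=float)
    labels = payload.get("labels") or [f"comparison_{i + 1}" for i in range(theta.size)]
    return theta, CovMatrix(matrix=cov, labels=labels)
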