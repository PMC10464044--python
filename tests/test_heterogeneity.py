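"""Cochran's Q, bootstrap covariance, whitening, Adjusted Q, GLS pooling."""

import numpy as np
import pytest
from scipy import stats

from poolhet import (
    ArmData,
    CovMatrix,
    EffectEstimate,
    RISK_DIFFERENCE,
    SingularCovarianceError,
    adjusted_q,
    analytic_covariance_risk_difference,
    bootstrap_covariance,
    cochran_q,
    estimates_from_json,
    gls_pooled_estimate,
    whiten,
)

from conftest import make_arm


def rd(value, se):
    return EffectEstimate(RISK_DIFFERENCE, value, se)


class TestCochranQ:
    def test_identical_estimates_show_no_heterogeneity(self):
        res = cochran_q([rd(0.3, 0.07), rd(0.3, 0.09)])
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_study_closed_form(self):
        # equal SEs: Q = (theta1-theta2)^2 / (2 se^2) = .0196/.0098 = 2
        res = cochran_q([rd(0.0, 0.07), rd(0.14, 0.07)])
        assert res.Q == pytest.approx(2.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_rejects_fewer_than_two_estimates(self):
        with pytest.raises(ValueError):
            cochran_q([rd(0.1, 0.05)])

    def test_rejects_zero_standard_error(self):
        with pytest.raises(ValueError):
            cochran_q([rd(0.1, 0.0), rd(0.2, 0.1)])


class TestBootstrapCovariance:
    def test_deterministic_given_seed(self, sat_100_50):
        arms = [make_arm("a", 100, 45), make_arm("b", 100, 55)]
        c1 = bootstrap_covariance(sat_100_50, arms, B=200, seed=11)
        c2 = bootstrap_covariance(sat_100_50, arms, B=200, seed=11)
        assert np.array_equal(c1.matrix, c2.matrix)

    def test_identical_cohorts_have_matching_variances(self, sat_100_50):
        arms = [make_arm("a", 100, 40), make_arm("b", 100, 40)]
        cov = bootstrap_covariance(sat_100_50, arms, B=4000, seed=5)
        v1, v2 = np.diag(cov.matrix)
        # exchangeable cohorts: diagonal entries agree within 3 MC SEs
        mc = np.sqrt(2.0 / 4000) * max(v1, v2)
        assert abs(v1 - v2) < 3 * np.sqrt(2) * mc

    def test_off_diagonal_is_shared_sat_variance(self, sat_100_50):
        """cov(theta_1, theta_2) = Var(p_hat_SAT) = p(1-p)/n for risk differences."""
        arms = [make_arm("a", 100, 45), make_arm("b", 100, 60)]
        cov = bootstrap_covariance(sat_100_50, arms, B=4000, seed=7)
        target = 0.5 * 0.5 / 100
        mcse = np.sqrt(2.0 / 4000) * 0.005  # rough MC error of a covariance entry
        assert cov.matrix[0, 1] == pytest.approx(target, abs=4 * mcse)

    def test_matches_analytic_covariance(self, sat_100_50):
        arms = [make_arm("a", 100, 45), make_arm("b", 100, 60)]
        boot = bootstrap_covariance(sat_100_50, arms, B=4000, seed=9).matrix
        exact = analytic_covariance_risk_difference(sat_100_50, arms).matrix
        assert boot == pytest.approx(exact, abs=0.001)

    def test_requires_seed_and_two_rwccs(self, sat_100_50):
        arms = [make_arm("a", 100, 45), make_arm("b", 100, 60)]
        with pytest.raises(ValueError):
            bootstrap_covariance(sat_100_50, arms, B=100)
        with pytest.raises(ValueError):
            bootstrap_covariance(sat_100_50, arms[:1], B=100, seed=1)

    def test_log_odds_ratio_measure_is_finite(self):
        sat = make_arm("s", 20, 1)  # zero cells will occur in resamples
        arms = [make_arm("a", 20, 10), make_arm("b", 20, 8)]
        cov = bootstrap_covariance(sat, arms, "log_odds_ratio", B=500, seed=3)
        assert np.all(np.isfinite(cov.matrix))


class TestWhiten:
    def test_identity_covariance_is_a_no_op(self):
        theta = np.array([0.3, -0.2, 0.1])
        out = whiten(theta, CovMatrix(np.eye(3), list("abc")))
        assert out == pytest.approx(theta, rel=1e-6)

    def test_diagonal_covariance_scales_by_sd(self):
        out = whiten([2.0, 3.0], CovMatrix(np.diag([4.0, 9.0]), ["a", "b"]))
        assert out == pytest.approx([1.0, 1.0], rel=1e-6)

    def test_whitening_transforms_covariance_to_identity(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        cols = [whiten(S[:, j], CovMatrix(S, ["a", "b"])) for j in range(2)]
        # L^-1 S L^-T = I, column by column
        recovered = np.column_stack(cols)
        L = np.linalg.cholesky(S)
        assert recovered == pytest.approx(np.linalg.solve(L, S), abs=1e-8)

    def test_whitened_draws_have_identity_covariance(self, rng):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        cov = CovMatrix(S, ["a", "b"])
        # whiten() is linear: recover its matrix from the basis vectors,
        # then check the empirical covariance of whitened gaussian draws
        W = np.column_stack([whiten(np.eye(2)[:, j], cov) for j in range(2)])
        draws = rng.multivariate_normal([0, 0], S, size=40_000)
        emp = np.cov(draws @ W.T, rowvar=False)
        assert emp == pytest.approx(np.eye(2), abs=0.03)

    def test_singular_covariance_names_the_offending_pair(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularCovarianceError, match="compA.*compB"):
            whiten([0.1, 0.2], CovMatrix(S, ["compA", "compB"]))


class TestAdjustedQ:
    def test_constant_estimates_show_no_heterogeneity(self, rng):
        S = np.array([[2.0, 0.5, 0.1], [0.5, 1.0, 0.2], [0.1, 0.2, 1.5]])
        res = adjusted_q([0.7, 0.7, 0.7], CovMatrix(S, list("abc")))
        assert res.Q == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_direct_quadratic_form_evaluation(self):
        res = adjusted_q([0.0, 1.0], CovMatrix(np.eye(2), ["a", "b"]))
        assert res.Q == pytest.approx(0.5, rel=1e-6)
        assert res.df == 1

    def test_compound_symmetry_equals_contrast_z_squared(self):
        # k=2, S = [[v,c],[c,v]]: Q = (t1-t2)^2 / (2(v-c)), the squared
        # z-statistic of the contrast t1-t2 whose variance is 2(v-c)
        v, c = 0.01, 0.004
        t = np.array([0.05, 0.19])
        res = adjusted_q(t, CovMatrix(np.array([[v, c], [c, v]]), ["a", "b"]))
        assert res.Q == pytest.approx((t[0] - t[1]) ** 2 / (2 * (v - c)), rel=1e-6)

    def test_matches_brute_force_gls_minimum(self, rng):
        """Q equals min_mu (theta-mu 1)' S^-1 (theta-mu 1) on random instances."""
        for _ in range(20):
            k = int(rng.integers(2, 5))
            A = rng.normal(size=(k, k + 2))
            S = A @ A.T / (k + 2) + 0.1 * np.eye(k)
            theta = rng.normal(size=k)
            res = adjusted_q(theta, CovMatrix(S, [f"c{i}" for i in range(k)]))
            Sinv = np.linalg.inv(S)
            grid = np.linspace(theta.min() - 2, theta.max() + 2, 20001)
            brute = min(
                float((theta - m) @ Sinv @ (theta - m)) for m in grid
            )
            assert res.Q == pytest.approx(brute, abs=1e-4)

    def test_reduces_to_cochran_q_for_diagonal_covariance(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            se = rng.uniform(0.02, 0.3, size=k)
            theta = rng.normal(0, 0.2, size=k)
            classic = cochran_q([rd(t, s) for t, s in zip(theta, se)])
            adj = adjusted_q(theta, CovMatrix(np.diag(se**2), [str(i) for i in range(k)]))
            assert adj.Q == pytest.approx(classic.Q, rel=1e-6, abs=1e-9)
            assert adj.p_value == pytest.approx(classic.p_value, rel=1e-6, abs=1e-9)

    def test_invariant_to_relabeling_and_location_shift(self, rng):
        k = 4
        A = rng.normal(size=(k, k + 3))
        S = A @ A.T / (k + 3) + 0.05 * np.eye(k)
        theta = rng.normal(size=k)
        base = adjusted_q(theta, CovMatrix(S, list("abcd")))
        perm = rng.permutation(k)
        permuted = adjusted_q(
            theta[perm], CovMatrix(S[np.ix_(perm, perm)], [list("abcd")[i] for i in perm])
        )
        shifted = adjusted_q(theta + 5.0, CovMatrix(S, list("abcd")))
        assert permuted.Q == pytest.approx(base.Q, rel=1e-8)
        assert shifted.Q == pytest.approx(base.Q, rel=1e-6, abs=1e-8)


class TestGlsPooledEstimate:
    def test_symmetric_average_under_identity(self):
        est = gls_pooled_estimate([0.4, 0.4], CovMatrix(np.eye(2), ["a", "b"]))
        assert est.value == pytest.approx(0.4)
        assert est.se == pytest.approx(np.sqrt(0.5))

    def test_diagonal_equals_inverse_variance_pooling(self, rng):
        se = np.array([0.05, 0.12, 0.08])
        theta = np.array([0.1, 0.3, 0.2])
        w = 1 / se**2
        est = gls_pooled_estimate(theta, CovMatrix(np.diag(se**2), list("abc")))
        assert est.value == pytest.approx(float(w @ theta / w.sum()), rel=1e-6)
        assert est.se == pytest.approx(float(np.sqrt(1 / w.sum())), rel=1e-6)

    def test_exchangeable_covariance_gives_equal_weights(self):
        S = np.array([[0.01, 0.005], [0.005, 0.01]])
        est = gls_pooled_estimate([0.2, 0.4], CovMatrix(S, ["a", "b"]))
        assert est.value == pytest.approx(0.3, rel=1e-6)
        assert est.se == pytest.approx(np.sqrt(0.0075), rel=1e-6)

    def test_shared_sat_widens_pooled_se(self):
        """Positive covariance from the shared SAT must inflate the pooled SE
        relative to naive inverse-variance pooling."""
        v, c = 0.005, 0.0025
        dependent = gls_pooled_estimate([0.1, 0.2], CovMatrix([[v, c], [c, v]], ["a", "b"]))
        naive = gls_pooled_estimate([0.1, 0.2], CovMatrix(np.diag([v, v]), ["a", "b"]))
        assert dependent.se > naive.se


class TestJsonInterface:
    def test_estimates_and_covariance_from_json(self):
        payload = {"estimates": [0.1, 0.25], "cov": [[0.01, 0.002], [0.002, 0.015]]}
        theta, cov = estimates_from_json(payload)
        res = adjusted_q(theta, cov)
        assert res.df == 1 and 0 <= res.p_value <= 1
        parsed = __import__("json").loads(res.to_json())
        assert parsed["method"] == "adjusted_q"

    def test_covmatrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            CovMatrix(np.array([[1.0, 0.5], [0.1, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="semi-definite"):
            CovMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"])
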