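"""Firth score adjustment: closed forms, oracle assembly, and the solver."""

import numpy as np
import pytest

from emaxfit import (
    ThreePointDesign,
    SampleSummary,
    eta,
    expected_information,
    firth_terms,
    grad_eta,
    mle_original,
    modified_score,
    observed_information,
    score,
    solve_modified_score,
)

from conftest import exact_summary, make_summary, random_admissible_theta

THETA = (2.0, 0.467, 50.0)


def assemble_Qt(support, weights, theta, sigma=1.0, n=1.0):
    """Q_t matrices from their six nonzero moment entries ((2,3) symmetric)."""
    x = np.asarray(support, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    t1, t2 = theta[1], theta[2]
    M = lambda l1, l2: np.sum(w * x**l1 / (x + t2) ** l2)
    c = n / sigma**2
    Q = np.zeros((3, 3, 3))
    Q[0, 1, 2] = Q[0, 2, 1] = -c * M(1, 2)
    Q[0, 2, 2] = 2 * c * t1 * M(1, 3)
    Q[1, 1, 2] = Q[1, 2, 1] = -c * M(2, 3)
    Q[1, 2, 2] = 2 * c * t1 * M(2, 4)
    Q[2, 1, 2] = Q[2, 2, 1] = c * t1 * M(2, 4)
    Q[2, 2, 2] = -2 * c * t1**2 * M(2, 5)
    return Q


def adjustment_via_trace(support, weights, theta, sigma=1.0, n_total=7.0):
    """Independent oracle: A_t = 1/2 trace(I^-1 Q_t) by dense linear algebra."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    counts = n_total * w
    I = expected_information(support, counts, theta, sigma)
    Q = assemble_Qt(support, w, theta, sigma=sigma, n=n_total)
    Iinv = np.linalg.inv(I)
    return np.array([0.5 * np.trace(Iinv @ Q[t]) for t in range(3)])


class TestScore:
    def test_zero_at_residual_free_data(self):
        s = exact_summary(0.0, 150.0, 30.0, THETA)
        np.testing.assert_allclose(score(s, THETA), 0.0, atol=1e-12)

    def test_zero_at_analytic_mle(self, rng):
        x = np.array([0.5, 20.0, 90.0])
        y = np.sort(eta(x, THETA) + rng.normal(0, 0.01, 3))
        s = make_summary(x, y, (4, 4, 4), sigma=0.1)
        est = mle_original(s)
        assert np.max(np.abs(score(s, est))) < 1e-9

    def test_matches_finite_difference_gradient(self, rng):
        x = rng.uniform(1, 100, 4)
        y = eta(x, THETA) + rng.normal(0, 0.3, 4)
        sigma = 0.3

        def loglik(th):
            return -0.5 * np.sum((y - eta(x, th)) ** 2) / sigma**2

        U = score((x, y), THETA, sigma)
        h = 1e-6
        fd = np.array(
            [
                (loglik(np.asarray(THETA) + h * e) - loglik(np.asarray(THETA) - h * e))
                / (2 * h)
                for e in np.eye(3)
            ]
        )
        np.testing.assert_allclose(U, fd, rtol=1e-5, atol=1e-6)

    def test_summary_equals_raw_pathway(self, rng):
        x = np.repeat([0.0, 10.0, 80.0], 4)
        y = eta(x, THETA) + rng.normal(0, 0.2, 12)
        design = ThreePointDesign(0.0, 10.0, 80.0)
        from emaxfit import summarize

        s = summarize(np.column_stack([x, y]), design, 0.2)
        np.testing.assert_allclose(
            score(s, THETA), score((x, y), THETA, 0.2), rtol=1e-10
        )


class TestFirthTerms:
    def test_single_point_design_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            firth_terms([30.0], [1.0], THETA)

    def test_theta1_scaling(self):
        sup, w = [0.0, 30.0, 150.0], [1 / 3] * 3
        A1 = firth_terms(sup, w, (2.0, 1.0, 50.0)).A
        A2 = firth_terms(sup, w, (2.0, 2.0, 50.0)).A
        np.testing.assert_allclose(A2[:2] * 2, A1[:2], rtol=1e-12)
        assert A2[2] == pytest.approx(A1[2], rel=1e-12)

    def test_D_positive_cauchy_schwarz(self, rng):
        for th in random_admissible_theta(rng, n=20):
            sup = np.sort(rng.uniform(0, 100, 3))
            terms = firth_terms(sup, [0.2, 0.5, 0.3], th)
            assert terms.D > 0
            assert terms.V11 >= 0 and terms.V12 >= 0

    def test_matches_half_trace_oracle(self, rng):
        """Closed-form A equals 1/2 trace(I^-1 Q_t) from the Q_t assembly.

        Designs anchor the lowest dose near placebo, as dose-finding
        designs do; with all doses far above theta2 the information matrix
        is near-singular (D -> 0) and neither route retains precision.
        """
        for th in random_admissible_theta(rng, n=25):
            a = rng.uniform(0, 5)
            x2 = a + rng.uniform(2, 100)
            sup = np.array([a, x2, x2 + rng.uniform(10, 200)])
            w = rng.dirichlet([3, 3, 3])
            if w.min() < 0.02:
                continue
            A = firth_terms(sup, w, th).A
            oracle = adjustment_via_trace(sup, w, th, sigma=0.4, n_total=11.0)
            np.testing.assert_allclose(A, oracle, rtol=1e-8)

    def test_Qt_sparsity_from_gaussian_expectation(self):
        """Q_t = E(-O U_t) via the linear-in-y structure: only the
        (2,3)/(3,2)/(3,3) entries are nonzero, and they match the assembly."""
        sup = np.array([0.001, 10.716, 150.0])
        w = np.ones(3) / 3
        sigma, n_total = 0.7, 3.0
        mu = eta(sup, THETA)
        # O is affine in y: coefficient of y_k in O_ij by differencing
        O0 = observed_information(sup, mu, THETA, sigma)
        beta = np.empty((3, 3, 3))
        for k in range(3):
            yk = mu.copy()
            yk[k] += 1.0
            beta[k] = observed_information(sup, yk, THETA, sigma) - O0
        gamma = grad_eta(sup, THETA) / sigma**2  # gamma[t, k]: coeff of (y_k - mu_k) in U_t
        # E(-O U_t) = -sigma^2 sum_k beta_k,ij gamma_t,k (exact Gaussian identity)
        Q_indep = -np.einsum("kij,tk->tij", beta, gamma) * sigma**2
        Q_ref = assemble_Qt(sup, w, THETA, sigma=sigma, n=n_total)
        np.testing.assert_allclose(Q_indep, Q_ref, rtol=1e-9, atol=1e-12)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = mask[2, 1] = mask[2, 2] = True
        for t in range(3):
            assert np.allclose(Q_indep[t][~mask], 0.0, atol=1e-10)

    def test_invariant_to_counts_and_sigma(self, rng):
        """A depends only on design weights and (theta1, theta2)."""
        s1 = exact_summary(0.0, 150.0, 30.0, THETA, counts=(2, 2, 2), sigma=0.1)
        s2 = exact_summary(0.0, 150.0, 30.0, THETA, counts=(20, 20, 20), sigma=0.9)
        th = (1.5, 0.6, 20.0)
        A1 = modified_score(s1, th) - score(s1, th)
        A2 = modified_score(s2, th) - score(s2, th)
        np.testing.assert_allclose(A1, A2, rtol=1e-12)


class TestModifiedScore:
    def test_equals_A_at_truth_with_clean_data(self):
        s = exact_summary(0.0, 150.0, 30.0, THETA)
        Ustar = modified_score(s, THETA)
        A = firth_terms(s.x, s.n, THETA).A
        np.testing.assert_allclose(Ustar, A, rtol=1e-12)

    def test_jacobian_is_asymmetric(self, rng):
        """No penalized likelihood: dU*/dtheta is not a symmetric matrix."""
        s = exact_summary(0.001, 150.0, 20.0, THETA, counts=(6, 6, 6), sigma=0.1)
        th0 = np.array([1.8, 0.5, 30.0])
        h = 1e-5
        J = np.empty((3, 3))
        for j, e in enumerate(np.eye(3)):
            J[:, j] = (modified_score(s, th0 + h * e) - modified_score(s, th0 - h * e)) / (2 * h)
        assert np.max(np.abs(J - J.T)) > 1e-3 * np.max(np.abs(J))


class TestSolver:
    def test_approaches_mle_as_n_grows(self, rng):
        """Firth root is within O(1/n) of the analytic MLE on concave data."""
        x = np.array([0.001, 30.0, 150.0])
        mu = eta(x, THETA)
        dist = []
        for npp in (6, 60, 600):
            ybar = mu + np.array([0.01, 0.02, 0.05])  # fixed concave offset
            s = make_summary(x, ybar, (npp,) * 3, sigma=0.1)
            mle = mle_original(s).as_array()
            sol = solve_modified_score(s)
            assert sol.admissible
            dist.append(np.linalg.norm(sol.params.as_array() - mle))
        # O(1/n): each tenfold n cuts the distance about tenfold
        assert dist[1] < 0.2 * dist[0]
        assert dist[2] < 0.2 * dist[1]

    def test_case2_data_usually_solvable(self, rng):
        """Convex samples near the true curve get admissible Firth roots."""
        from emaxfit import classify, d_optimal_x2

        a, b = 0.001, 150.0
        x = np.array([a, d_optimal_x2(a, b, 12.5), b])
        mu = eta(x, THETA)
        n_c2 = n_ok = 0
        while n_c2 < 30:
            ybar = mu + 0.1 / np.sqrt(6) * rng.standard_normal(3)
            s = make_summary(x, ybar, (6, 6, 6), sigma=0.1)
            if classify(s).label.is_case2:
                n_c2 += 1
                n_ok += solve_modified_score(s).admissible
        assert n_ok >= 29

    def test_case1_data_usually_unsolvable(self, rng):
        from emaxfit import classify

        x = np.array([0.001, 74.0, 150.0])
        mu = eta(x, THETA)
        n_c1 = n_ok = 0
        while n_c1 < 20:
            ybar = mu + 0.1 / np.sqrt(6) * rng.standard_normal(3)
            s = make_summary(x, ybar, (6, 6, 6), sigma=0.1)
            if classify(s).label.is_case1:
                n_c1 += 1
                n_ok += solve_modified_score(s).admissible
        assert n_ok <= 1

    def test_failure_is_reported_not_raised(self):
        s = make_summary([0.0, 1.0, 2.0], (5.0, 3.0, 1.0), (2, 2, 2), sigma=0.1)
        sol = solve_modified_score(s)
        assert not sol.admissible
        assert sol.params is None
        assert sol.n_starts_used >= 1

    def test_bias_reduction_on_concave_conditioned_samples(self, rng):
        """Firth's theta2 bias is no larger than the MLE's, within MC error."""
        from emaxfit import classify, ShapeLabel, d_optimal_x2

        a, b = 0.001, 150.0
        x = np.array([a, d_optimal_x2(a, b, 50.0), b])
        mu = eta(x, THETA)
        ml2, fi2 = [], []
        while len(ml2) < 300:
            ybar = mu + 0.1 / np.sqrt(6) * rng.standard_normal(3)
            s = make_summary(x, ybar, (6, 6, 6), sigma=0.1)
            if classify(s).label is not ShapeLabel.INCREASING_CONCAVE:
                continue
            sol = solve_modified_score(s)
            if not sol.admissible:
                continue
            ml2.append(mle_original(s).theta2)
            fi2.append(sol.params.theta2)
        ml2, fi2 = np.array(ml2), np.array(fi2)
        se = ml2.std(ddof=1) / np.sqrt(len(ml2))
        bias_ml = abs(ml2.mean() - THETA[2])
        bias_fi = abs(fi2.mean() - THETA[2])
        assert bias_fi <= bias_ml + 3 * se
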