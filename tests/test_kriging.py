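"""Profile likelihood, ML fitting, and the universal-kriging predictor."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal

from airlur.kriging import (UniversalKriging, exponential_covariance, fit_uk,
                            negative_log_likelihood)


def simulate_uk_data(n, nugget, sill, range_km, beta, rng, domain=100.0):
    coords = rng.uniform(0, domain, (n, 2))
    F = rng.normal(size=(n, len(beta) - 1))
    D = cdist(coords, coords)
    cov = exponential_covariance(D, sill, range_km) + nugget * np.eye(n)
    mean = beta[0] + F @ beta[1:]
    y = mean + np.linalg.cholesky(cov) @ rng.standard_normal(n)
    return coords, F, y


class TestNegativeLogLikelihood:
    def test_matches_dense_mvn_density_n3(self):
        """Hand-built 3-site system vs. direct multivariate-normal evaluation
        (beta fixed at its GLS value, which the profile NLL uses)."""
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 20.0]])
        F = np.array([[0.5], [-1.0], [2.0]])
        y = np.array([1.0, 2.0, 0.5])
        theta = (0.3, 1.2, 15.0)
        got = negative_log_likelihood(theta, F, y, coords)
        # oracle: explicit GLS beta, then the dense normal density
        D = cdist(coords, coords)
        sigma = 1.2 * np.exp(-D / 15.0) + 0.3 * np.eye(3)
        Fd = np.hstack([np.ones((3, 1)), F])
        si = np.linalg.inv(sigma)
        beta = np.linalg.solve(Fd.T @ si @ Fd, Fd.T @ si @ y)
        expected = -multivariate_normal(mean=Fd @ beta, cov=sigma).logpdf(y)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_sigma2_zero_reduces_to_ols_gaussian_nll(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 50, (20, 2))
        F = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        tau2 = 0.7
        got = negative_log_likelihood((tau2, 0.0, 5.0), F, y, coords)
        Fd = np.hstack([np.ones((20, 1)), F])
        beta = np.linalg.lstsq(Fd, y, rcond=None)[0]
        r = y - Fd @ beta
        expected = 0.5 * (20 * np.log(2 * np.pi * tau2) + r @ r / tau2)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_location_scale_equivariance(self):
        """Scaling y and F by c shifts the minimised NLL by n log c and
        scales the variance estimates by c^2."""
        rng = np.random.default_rng(3)
        coords, F, y = simulate_uk_data(60, 0.2, 0.8, 20.0, np.array([1.0, 0.5]), rng)
        X = np.hstack([coords, F])
        m1 = UniversalKriging().fit(X, y)
        c = 3.0
        m2 = UniversalKriging().fit(X, c * y)
        assert m2.nll_ == pytest.approx(m1.nll_ + 60 * np.log(c), rel=1e-6)
        total1 = m1.nugget_ + m1.partial_sill_
        total2 = m2.nugget_ + m2.partial_sill_
        assert total2 == pytest.approx(c**2 * total1, rel=0.02)
        assert m2.range_km_ == pytest.approx(m1.range_km_, rel=0.02)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood((-0.1, 1.0, 5.0), np.ones((5, 1)),
                                    np.ones(5), np.random.rand(5, 2))


class TestFitUK:
    def test_duplicate_coordinates_rejected(self):
        coords = np.zeros((12, 2))
        with pytest.raises(ValueError, match="duplicate"):
            UniversalKriging().fit(np.hstack([coords, np.random.rand(12, 1)]),
                                   np.random.rand(12))

    def test_too_few_sites_rejected(self):
        rng = np.random.default_rng(0)
        X = np.hstack([rng.uniform(0, 10, (5, 2)), rng.normal(size=(5, 1))])
        with pytest.raises(ValueError, match="at least 10"):
            UniversalKriging().fit(X, rng.normal(size=5))

    def test_null_field_gives_small_spatial_fraction(self):
        """With iid data (sigma2 = 0 truth) the fitted spatial fraction
        sigma2 / (sigma2 + nugget) stays small (median over replicates)."""
        fractions = []
        for seed in range(7):
            rng = np.random.default_rng(100 + seed)
            coords = rng.uniform(0, 100, (80, 2))
            F = rng.normal(size=(80, 1))
            y = 1.0 + 0.5 * F[:, 0] + rng.normal(0, 1.0, 80)
            m = UniversalKriging().fit(np.hstack([coords, F]), y)
            fractions.append(m.partial_sill_ / (m.partial_sill_ + m.nugget_))
        assert np.median(fractions) < 0.2

    def test_fitted_nll_not_worse_than_truth_nll(self):
        """Optimiser sanity: NLL at the fitted theta <= NLL at the simulation
        truth in at least 90% of replicates."""
        wins = 0
        reps = 10
        truth = (0.2, 1.0, 20.0)
        for seed in range(reps):
            rng = np.random.default_rng(500 + seed)
            coords, F, y = simulate_uk_data(80, *truth, np.array([1.0, 0.5]), rng)
            m = UniversalKriging().fit(np.hstack([coords, F]), y)
            nll_truth = negative_log_likelihood(truth, F, y, coords)
            if m.nll_ <= nll_truth + 1e-6:
                wins += 1
        assert wins >= 0.9 * reps


class TestPredict:
    def test_noiseless_interpolation_at_training_sites(self):
        rng = np.random.default_rng(8)
        coords, F, y = simulate_uk_data(30, 0.0, 1.0, 15.0, np.array([2.0, 0.7]), rng)
        X = np.hstack([coords, F])
        m = UniversalKriging(theta=(0.0, 1.0, 15.0)).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-6)

    def test_far_point_reverts_to_mean_with_full_variance(self):
        rng = np.random.default_rng(12)
        coords, F, y = simulate_uk_data(30, 0.1, 1.0, 10.0, np.array([2.0, 0.7]), rng)
        m = UniversalKriging(theta=(0.1, 1.0, 10.0)).fit(np.hstack([coords, F]), y)
        far = np.array([[1e6, 1e6, 0.3]])
        pred, std = m.predict(far, return_std=True)
        expected_mean = m.beta_[0] + 0.3 * m.beta_[1]
        assert pred[0] == pytest.approx(expected_mean, rel=1e-8)
        # variance reverts to sill + nugget plus the mean-estimation term
        assert std[0] ** 2 >= 1.1 - 1e-8

    def test_constant_response_reproduced_everywhere(self):
        rng = np.random.default_rng(13)
        coords = rng.uniform(0, 50, (25, 2))
        X = np.hstack([coords, rng.normal(size=(25, 2))])
        y = np.full(25, 4.2)
        m = UniversalKriging(theta=(0.2, 0.5, 8.0)).fit(X, y)
        Xnew = np.hstack([rng.uniform(0, 50, (10, 2)), rng.normal(size=(10, 2))])
        np.testing.assert_allclose(m.predict(Xnew), 4.2, atol=1e-8)

    def test_prediction_invariant_to_training_order(self):
        rng = np.random.default_rng(14)
        coords, F, y = simulate_uk_data(40, 0.1, 0.8, 12.0, np.array([1.0, -0.4]), rng)
        X = np.hstack([coords, F])
        perm = rng.permutation(40)
        Xnew = np.hstack([rng.uniform(0, 100, (5, 2)), rng.normal(size=(5, 1))])
        p1 = UniversalKriging(theta=(0.1, 0.8, 12.0)).fit(X, y).predict(Xnew)
        p2 = UniversalKriging(theta=(0.1, 0.8, 12.0)).fit(X[perm], y[perm]).predict(Xnew)
        np.testing.assert_allclose(p1, p2, rtol=1e-8)

    def test_matches_dense_kriging_oracle(self):
        """10 new points vs. the textbook universal-kriging equations
        assembled with dense linear algebra."""
        rng = np.random.default_rng(30)
        coords, F, y = simulate_uk_data(30, 0.15, 0.9, 18.0, np.array([1.0, 0.6]), rng)
        theta = (0.15, 0.9, 18.0)
        m = UniversalKriging(theta=theta).fit(np.hstack([coords, F]), y)
        new_coords = rng.uniform(0, 100, (10, 2))
        new_F = rng.normal(size=(10, 1))
        pred = m.predict(np.hstack([new_coords, new_F]))
        # oracle
        D = cdist(coords, coords)
        sigma = 0.9 * np.exp(-D / 18.0) + 0.15 * np.eye(30)
        si = np.linalg.inv(sigma)
        Fd = np.hstack([np.ones((30, 1)), F])
        beta = np.linalg.solve(Fd.T @ si @ Fd, Fd.T @ si @ y)
        c = 0.9 * np.exp(-cdist(new_coords, coords) / 18.0)
        Fd_new = np.hstack([np.ones((10, 1)), new_F])
        expected = Fd_new @ beta + c @ si @ (y - Fd @ beta)
        np.testing.assert_allclose(pred, expected, rtol=1e-8)

    def test_functional_wrapper_equivalent(self):
        rng = np.random.default_rng(31)
        coords, F, y = simulate_uk_data(25, 0.1, 0.5, 10.0, np.array([1.0, 0.3]), rng)
        m1 = fit_uk(F, y, coords, theta=(0.1, 0.5, 10.0))
        m2 = UniversalKriging(theta=(0.1, 0.5, 10.0)).fit(np.hstack([coords, F]), y)
        Xn = np.hstack([rng.uniform(0, 100, (5, 2)), rng.normal(size=(5, 1))])
        np.testing.assert_allclose(m1.predict(Xn), m2.predict(Xn))
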