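"""Personalized GP: kernel, predictive equations, marginal likelihood, fitting."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pbostim.design import UnitCoordinates
from pbostim.errors import (
    DegenerateDataError,
    InvalidHyperparameterError,
    InvalidInputError,
)
from pbostim.pgp import (
    GPHyperparameters,
    PersonalizedGP,
    _lml_and_grad,
    fit_hyperparameters,
    kernel_value,
    log_marginal_likelihood,
    predict,
)


def _dense_oracle(Z, y, hyper, Zq, jitter=1e-8):
    """Brute-force GP predictive equations via explicit matrix inversion."""
    n = Z.shape[0]
    def k(A, B):
        out = np.exp(-cdist(A[:, :2], B[:, :2], "sqeuclidean") / (2 * hyper.sigma_l**2))
        out *= np.exp(-cdist(A[:, 2:], B[:, 2:], "sqeuclidean") / (2 * hyper.sigma_p**2))
        return out
    K = k(Z, Z) + (hyper.sigma_n2 + jitter) * np.eye(n)
    Kinv = np.linalg.inv(K)
    ks = k(Zq, Z)
    mu = ks @ Kinv @ y
    var = 1.0 - np.sum((ks @ Kinv) * ks, axis=1)
    lml = (
        -0.5 * y @ Kinv @ y
        - 0.5 * np.linalg.slogdet(K)[1]
        - 0.5 * n * np.log(2 * np.pi)
    )
    return mu, var, lml


class TestKernelValue:
    H = GPHyperparameters(sigma_l=0.2, sigma_p=0.3, sigma_n2=0.3)

    def test_identical_points_distinct_indices(self):
        c = UnitCoordinates(x=(0.4, 0.6), p=0.5)
        assert kernel_value(c, c, self.H) == pytest.approx(1.0)

    def test_identical_points_same_index_adds_noise(self):
        c = UnitCoordinates(x=(0.4, 0.6), p=0.5)
        assert kernel_value(c, c, self.H, same_index=True) == pytest.approx(1.3)

    def test_one_length_scale_offset(self):
        ci = UnitCoordinates(x=(0.5, 0.5), p=0.5)
        cj = UnitCoordinates(x=(0.5 + self.H.sigma_l, 0.5), p=0.5)
        assert kernel_value(ci, cj, self.H) == pytest.approx(np.exp(-0.5))

    def test_product_structure(self):
        ci = UnitCoordinates(x=(0.2, 0.2), p=0.1)
        cj = UnitCoordinates(x=(0.6, 0.4), p=0.7)
        kx = np.exp(-((0.4**2 + 0.2**2)) / (2 * 0.2**2))
        kp = np.exp(-(0.6**2) / (2 * 0.3**2))
        assert kernel_value(ci, cj, self.H) == pytest.approx(kx * kp, rel=1e-12)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(InvalidHyperparameterError):
            GPHyperparameters(sigma_l=0.0, sigma_p=0.3, sigma_n2=0.1)


class TestPredict:
    def test_noiseless_interpolation_single_point(self):
        model = PersonalizedGP(jitter=0.0)
        model.fit(
            np.array([[0.5, 0.5, 0.5]]),
            np.array([2.0]),
            hyper=GPHyperparameters(0.2, 0.3, 1e-300),
        )
        mu, var = model.predict(np.array([[0.5, 0.5, 0.5]]), raw=True)
        assert mu[0] == pytest.approx(2.0)
        assert var[0] == pytest.approx(0.0, abs=1e-10)

    def test_prior_reversion_far_from_data(self, small_gp):
        # all distances >> length scales: standardized prior N(0, 1)
        mu, var = small_gp.predict(np.array([[50.0, 50.0, 50.0]]))
        assert mu[0] == pytest.approx(0.0, abs=1e-8)
        assert var[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_dense_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 11))
            Z = rng.random((n, 3))
            y = rng.standard_normal(n)
            hyper = GPHyperparameters(
                float(rng.uniform(0.1, 1.0)),
                float(rng.uniform(0.1, 1.0)),
                float(rng.uniform(0.01, 0.5)),
            )
            model = PersonalizedGP()
            model.fit(Z, y, hyper=hyper)
            Zq = rng.random((4, 3))
            mu, var = model.predict(Zq)
            mu_o, var_o, _ = _dense_oracle(Z, model.y, hyper, Zq)
            np.testing.assert_allclose(mu, mu_o, atol=1e-8)
            np.testing.assert_allclose(var, np.clip(var_o, 0, None), atol=1e-8)

    def test_posterior_variance_below_prior(self, small_gp, rng):
        _, var = small_gp.predict(rng.random((200, 3)))
        assert np.all(var <= 1.0 + 1e-12)
        assert np.all(var >= 0.0)

    def test_covariance_matrix_symmetric_psd(self, rng):
        from pbostim.pgp import _kernel_matrix

        Z = rng.random((30, 3))
        K = _kernel_matrix(Z, Z, GPHyperparameters(0.2, 0.3, 0.1), d_x=2)
        np.testing.assert_allclose(K, K.T, atol=1e-14)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_unfitted_model_rejected(self):
        with pytest.raises(InvalidInputError):
            PersonalizedGP().predict(np.zeros((1, 3)))


class TestLogMarginalLikelihood:
    def test_single_zero_observation_closed_form(self):
        lml = log_marginal_likelihood(
            np.array([[0.5, 0.5, 0.5]]),
            np.array([0.0]),
            GPHyperparameters(0.2, 0.3, 1e-300),
            jitter=0.0,
        )
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_matches_dense_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 9))
            Z = rng.random((n, 3))
            y = rng.standard_normal(n)
            hyper = GPHyperparameters(0.3, 0.4, 0.2)
            _, _, lml_o = _dense_oracle(Z, y, hyper, Z)
            assert log_marginal_likelihood(Z, y, hyper) == pytest.approx(lml_o, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        Z = rng.random((12, 3))
        y = rng.standard_normal(12)
        log_theta = np.log([0.25, 0.35, 0.08])
        _, grad = _lml_and_grad(log_theta, Z, y, 2, 1e-8)
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1e-6
            fp, _ = _lml_and_grad(log_theta + e, Z, y, 2, 1e-8)
            fm, _ = _lml_and_grad(log_theta - e, Z, y, 2, 1e-8)
            assert grad[i] == pytest.approx((fp - fm) / 2e-6, abs=1e-4)


class TestFitHyperparameters:
    def test_within_bounds_and_reproducible(self, rng):
        Z = rng.random((25, 3))
        y = np.sin(4 * Z[:, 0]) + 0.1 * rng.standard_normal(25)
        h1 = fit_hyperparameters(Z, y, restarts=3, seed=7)
        h2 = fit_hyperparameters(Z, y, restarts=3, seed=7)
        assert (h1.sigma_l, h1.sigma_p, h1.sigma_n2) == (h2.sigma_l, h2.sigma_p, h2.sigma_n2)
        for val, (lo, hi) in zip(h1.as_array(), h1.bounds):
            assert lo <= val <= hi

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_hyperparameters(np.random.rand(5, 3), np.ones(5))
        with pytest.raises(DegenerateDataError):
            fit_hyperparameters(np.random.rand(2, 3), np.array([0.0, 1.0]))

    def test_generative_recovery_single_instance(self, rng):
        """Data sampled from the model recovers hyperparameters to a factor 2."""
        true = GPHyperparameters(0.2, 0.3, 0.05)
        Z = rng.random((200, 3))
        K = np.exp(-cdist(Z[:, :2], Z[:, :2], "sqeuclidean") / (2 * true.sigma_l**2))
        K *= np.exp(-cdist(Z[:, 2:], Z[:, 2:], "sqeuclidean") / (2 * true.sigma_p**2))
        K += true.sigma_n2 * np.eye(200)
        y = np.linalg.cholesky(K + 1e-10 * np.eye(200)) @ rng.standard_normal(200)
        fit = fit_hyperparameters(Z, (y - y.mean()) / y.std(), restarts=5, seed=0)
        for est, tru in zip(fit.as_array(), true.as_array()):
            assert tru / 2 <= est <= tru * 2


class TestModelBehaviour:
    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against scikit-learn's GP regressor."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF

        Z = rng.random((15, 3))
        y = rng.standard_normal(15)
        hyper = GPHyperparameters(sigma_l=0.3, sigma_p=0.45, sigma_n2=0.12)
        model = PersonalizedGP()
        model.fit(Z, y, hyper=hyper)
        ref = GaussianProcessRegressor(
            kernel=RBF(length_scale=[0.3, 0.3, 0.45]),
            alpha=hyper.sigma_n2 + model.jitter,
            optimizer=None,
        )
        ref.fit(Z, model.y)
        Zq = rng.random((6, 3))
        mu, var = model.predict(Zq)
        mu_ref, sd_ref = ref.predict(Zq, return_std=True)
        np.testing.assert_allclose(mu, mu_ref, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(var), sd_ref, atol=1e-6)

    def test_large_sigma_p_reduces_to_standard_bo(self, rng):
        """A huge baseline length scale makes the covariate irrelevant."""
        Z = rng.random((20, 3))
        y = np.cos(3 * Z[:, 0]) + 0.05 * rng.standard_normal(20)
        flat = PersonalizedGP()
        flat.fit(Z, y, hyper=GPHyperparameters(0.25, 1e6, 0.05))
        std = PersonalizedGP(personalized=False)
        std.fit(Z[:, :2], y, hyper=GPHyperparameters(0.25, 1.0, 0.05))
        Zq = rng.random((10, 3))
        mu_f, var_f = flat.predict(Zq)
        mu_s, var_s = std.predict(Zq[:, :2])
        np.testing.assert_allclose(mu_f, mu_s, atol=1e-6)
        np.testing.assert_allclose(var_f, var_s, atol=1e-6)

    def test_snapshot_round_trip(self, small_gp, tmp_path):
        path = tmp_path / "model.json"
        small_gp.save(path)
        back = PersonalizedGP.load(path)
        Zq = np.array([[0.2, 0.8, 0.5], [0.9, 0.1, 0.3]])
        np.testing.assert_allclose(back.predict(Zq)[0], small_gp.predict(Zq)[0], atol=1e-12)
        np.testing.assert_allclose(back.predict(Zq)[1], small_gp.predict(Zq)[1], atol=1e-12)

    def test_predict_single_query_helper(self, small_gp):
        mu, var = predict(small_gp, UnitCoordinates(x=(0.5, 0.5), p=0.5))
        mu2, var2 = small_gp.predict(np.array([[0.5, 0.5, 0.5]]))
        assert mu == pytest.approx(mu2[0]) and var == pytest.approx(var2[0])
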