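"""GL operator, order estimators, network fit, eigenmode summaries."""

import numpy as np
import pytest

from adsuppress.errors import ParameterError
from adsuppress.fodn import (
    FodnConfig,
    dominant_eigvec,
    estimate_alpha,
    estimate_alpha_regression,
    fit_fodn,
    gl_coefficients,
    gl_derivative,
    windowed_fodn,
)
from adsuppress.io import make_windows
from adsuppress.synthetic import (
    gen_arfima,
    random_skew_coupling,
    simulate_fodn,
)


class TestGlCoefficients:
    def test_half_order_hand_values(self):
        np.testing.assert_allclose(
            gl_coefficients(0.5, 3), [1.0, -0.5, -0.125, -0.0625]
        )

    def test_vector_orders_columnwise(self):
        c = gl_coefficients(np.array([0.0, 1.0]), 2)
        np.testing.assert_allclose(c[:, 0], [1.0, 0.0, 0.0])   # identity
        np.testing.assert_allclose(c[:, 1], [1.0, -1.0, 0.0])  # first difference

    def test_coefficients_sum_to_near_zero_for_alpha_one(self):
        c = gl_coefficients(1.0, 50)
        assert abs(c.sum()) < 1e-12

    def test_rejects_negative_depth(self):
        with pytest.raises(ParameterError):
            gl_coefficients(0.5, -1)


class TestGlDerivative:
    def test_alpha_zero_identity(self):
        x = np.random.default_rng(0).standard_normal(200)
        np.testing.assert_allclose(gl_derivative(x, 0.0), x)

    def test_alpha_one_first_difference(self):
        x = np.random.default_rng(1).standard_normal(200)
        z = gl_derivative(x, 1.0)
        np.testing.assert_allclose(z[1:], np.diff(x))
        assert z[0] == pytest.approx(x[0])

    def test_multichannel_orders(self):
        x = np.random.default_rng(2).standard_normal((100, 2))
        z = gl_derivative(x, np.array([0.0, 1.0]))
        np.testing.assert_allclose(z[:, 0], x[:, 0])
        np.testing.assert_allclose(z[1:, 1], np.diff(x[:, 1]))


class TestAlphaEstimators:
    def test_haar_white_noise_zero(self):
        x = np.random.default_rng(3).standard_normal(4096)
        a, _ = estimate_alpha(x)
        assert abs(a) < 0.1

    def test_haar_recovers_arfima_order(self):
        for d in (0.2, 0.4):
            x = gen_arfima(d, 8192, seed=int(d * 10))
            a, _ = estimate_alpha(x)
            assert abs(a - d) < 0.12

    def test_haar_too_short_rejected(self):
        with pytest.raises(ParameterError):
            estimate_alpha(np.zeros(16), levels=4)

    def test_regression_recovers_coupled_orders(self):
        rng = np.random.default_rng(6)
        A = random_skew_coupling(5, 0.8, rng)
        alpha = rng.uniform(0.3, 0.7, 5)
        sim = simulate_fodn(A, alpha, 1500, 0.1, rng)
        a_hat = estimate_alpha_regression(sim.signals)
        assert np.abs(a_hat - alpha).max() < 0.15

    def test_regression_needs_enough_samples(self):
        with pytest.raises(ParameterError):
            estimate_alpha_regression(np.zeros((80, 3)))


class TestFitFodn:
    def test_noiseless_known_input_round_trip(self):
        rng = np.random.default_rng(7)
        n, t = 6, 4000
        A = random_skew_coupling(n, 0.6, rng)
        alpha = rng.uniform(0.2, 0.8, n)
        u = rng.standard_normal((t, n))
        sim = simulate_fodn(A, alpha, t, 0.0, rng, u=u)
        model = fit_fodn(sim.signals, FodnConfig(lambda_ridge=0.0),
                         alpha=alpha, known_u=u)
        assert np.linalg.norm(model.A - A) / np.linalg.norm(A) < 1e-3

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(8)
        A = random_skew_coupling(5, 0.5, rng)
        sim = simulate_fodn(A, np.full(5, 0.4), 800, 0.5, rng)
        model = fit_fodn(sim.signals, FodnConfig(n_alt_iters=5))
        h = model.objective_history
        assert len(h) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))

    def test_lasso_zeroes_inputs_under_large_penalty(self):
        rng = np.random.default_rng(9)
        A = random_skew_coupling(4, 0.5, rng)
        sim = simulate_fodn(A, np.full(4, 0.4), 600, 0.5, rng)
        model = fit_fodn(sim.signals, FodnConfig(lambda_lasso=1e6))
        assert np.all(model.u == 0)

    def test_rejects_bad_shape(self):
        with pytest.raises(ParameterError):
            fit_fodn(np.zeros(100))


class TestEigenMode:
    def test_known_diagonal_matrix(self):
        A = np.diag([0.9, 0.2, -0.1])
        mode = dominant_eigvec(A)
        assert mode.eigenvalue == pytest.approx(0.9)
        np.testing.assert_allclose(mode.weights, [1.0, 0.0, 0.0], atol=1e-12)
        assert mode.max_weight == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        A = np.array([[0.5, 0.4], [0.4, 0.5]])
        mode = dominant_eigvec(A)
        assert np.all(mode.vector > 0)  # largest entry forced positive

    def test_participation_ratio_limits(self):
        uniform = dominant_eigvec(np.ones((4, 4)) / 4.0)
        assert uniform.participation_ratio == pytest.approx(1.0)
        single = dominant_eigvec(np.diag([1.0, 0.0, 0.0, 0.0]))
        assert single.participation_ratio == pytest.approx(0.25)

    def test_weights_unit_norm_complex_case(self):
        A = np.array([[0.0, -0.8], [0.8, 0.0]])  # rotation: complex pair
        mode = dominant_eigvec(A)
        assert np.linalg.norm(mode.weights) == pytest.approx(1.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ParameterError):
            dominant_eigvec(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestWindowedFodn:
    def test_track_shapes_and_no_failures(self, simple_recording):
        rec, tl = simple_recording
        grid = make_windows(rec, tl, "W1", "nonoverlap")
        track = windowed_fodn(rec, grid, FodnConfig())
        assert track.alpha.shape == (rec.n_channels, len(grid))
        assert not track.failed.any()
        assert np.isfinite(track.spectral_radius).all()

    def test_stability_is_cosine_in_unit_interval(self, simple_recording):
        rec, tl = simple_recording
        grid = make_windows(rec, tl, "W2", "nonoverlap")
        track = windowed_fodn(rec, grid, FodnConfig())
        assert 0.0 <= track.stability <= 1.0
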