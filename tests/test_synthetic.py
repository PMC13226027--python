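"""Generators: determinism, known-exponent signals, network simulation, cohorts."""

import numpy as np
import pytest

from adsuppress.errors import ParameterError
from adsuppress.fractal import ScalingConfig, dfa_hurst
from adsuppress.synthetic import (
    CohortSpec,
    binomial_cascade_hq,
    gen_arfima,
    gen_binomial_cascade,
    gen_cohort,
    gen_fgn,
    random_skew_coupling,
    random_stable_coupling,
    simulate_fodn,
)


class TestDeterminism:
    def test_fgn_same_seed_identical(self):
        a = gen_fgn(0.7, 2048, seed=42)
        b = gen_fgn(0.7, 2048, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, gen_fgn(0.7, 2048, seed=43))

    def test_arfima_same_seed_identical(self):
        np.testing.assert_array_equal(gen_arfima(0.3, 1024, 7), gen_arfima(0.3, 1024, 7))

    def test_simulate_fodn_same_seed_identical(self):
        A = random_stable_coupling(4, 0.5, 0.3, seed=1)
        s1 = simulate_fodn(A, np.full(4, 0.4), 500, 0.5, seed=2)
        s2 = simulate_fodn(A, np.full(4, 0.4), 500, 0.5, seed=2)
        np.testing.assert_array_equal(s1.signals, s2.signals)

    def test_cohort_same_seed_identical(self):
        spec = CohortSpec(n_trials=2, n_success=1, n_channels=4,
                          w1_duration_s=(3.0, 3.0), w2_duration_s=(4.0, 4.0), seed=9)
        c1, c2 = gen_cohort(spec), gen_cohort(spec)
        for t1, t2 in zip(c1, c2):
            np.testing.assert_array_equal(t1.recording.signals, t2.recording.signals)
            assert t1.timeline.markers == t2.timeline.markers


class TestFgn:
    def test_fgn_mean_and_autocorr_sign(self):
        x = gen_fgn(0.8, 8192, seed=0)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 > 0.2  # persistent increments
        y = gen_fgn(0.3, 8192, seed=0)
        assert np.corrcoef(y[:-1], y[1:])[0, 1] < 0.0  # anti-persistent

    def test_fgn_h_half_is_white(self):
        x = gen_fgn(0.5, 8192, seed=3)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.05

    def test_fgn_rejects_bad_h(self):
        with pytest.raises(ParameterError):
            gen_fgn(1.2, 256)
        with pytest.raises(ParameterError):
            gen_fgn(0.0, 256)


class TestArfima:
    def test_d_zero_is_white_noise(self):
        x, eps = gen_arfima(0.0, 512, seed=1, return_noise=True)
        np.testing.assert_allclose(x, eps)

    def test_rejects_d_out_of_range(self):
        with pytest.raises(ParameterError):
            gen_arfima(0.5, 256)

    def test_positive_d_long_memory(self):
        x = gen_arfima(0.4, 8192, seed=2)
        h, _ = dfa_hurst(x)
        assert h > 0.7  # H = d + 0.5 up to estimation error


class TestCascade:
    def test_length_and_positivity(self):
        x = gen_binomial_cascade(0.75, 10)
        assert x.shape == (1024,)
        assert np.all(x > 0)

    def test_mass_conservation(self):
        # each split preserves total mass: a + (1 - a) = 1
        np.testing.assert_allclose(gen_binomial_cascade(0.7, 8).sum(), 1.0)

    def test_closed_form_hq_limits(self):
        # a = 0.5 degenerates to uniform mass: h(q) = 1 for all q
        hq = binomial_cascade_hq(0.5, np.array([-3.0, 1.0, 4.0]))
        np.testing.assert_allclose(hq, 1.0)

    def test_hq_monotone_decreasing(self):
        q = np.array([-5.0, -2.0, -0.5, 0.5, 2.0, 5.0])
        hq = binomial_cascade_hq(0.75, q)
        assert np.all(np.diff(hq) < 0)


class TestSimulateFodn:
    def test_null_model_returns_noise(self):
        # A = 0, alpha = 0, u = 0: output is the innovation noise itself
        sim = simulate_fodn(np.zeros((3, 3)), np.zeros(3), 400, 1.0, seed=8)
        np.testing.assert_allclose(sim.signals, sim.eps)

    def test_rejects_unstable_coupling(self):
        A = np.eye(2) * 1.1
        with pytest.raises(ParameterError, match="unstable"):
            simulate_fodn(A, np.full(2, 0.3), 100, 1.0, seed=0)

    def test_known_input_enters_dynamics(self):
        u = np.zeros((300, 2))
        u[100, 0] = 5.0
        A = np.zeros((2, 2))
        sim = simulate_fodn(A, np.zeros(2), 300, 0.0, seed=0, u=u)
        assert sim.signals[100, 0] == pytest.approx(5.0)
        assert np.all(sim.signals[:100] == 0)


class TestCouplings:
    def test_stable_coupling_radius(self):
        A = random_stable_coupling(12, 0.2, 0.35, seed=4)
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        assert rho == pytest.approx(0.35, rel=1e-6)

    def test_skew_coupling_properties(self):
        A = random_skew_coupling(10, 0.85, seed=4)
        np.testing.assert_allclose(A, -A.T, atol=1e-12)
        assert np.all(np.diag(A) == 0)
        assert np.max(np.abs(np.linalg.eigvals(A))) == pytest.approx(0.85, rel=1e-6)

    def test_skew_coupling_stable_under_fractional_dynamics(self):
        A = random_skew_coupling(6, 0.85, seed=5)
        sim = simulate_fodn(A, np.full(6, 0.5), 2000, 0.1, seed=5)
        assert np.all(np.isfinite(sim.signals))
        assert np.abs(sim.signals).max() < 100


class TestCohort:
    def test_counts_and_outcomes(self, small_cohort):
        outcomes = [t.recording.outcome for t in small_cohort]
        assert len(small_cohort) == 6
        assert outcomes.count("success") == 3

    def test_recordings_validate(self, small_cohort):
        for t in small_cohort:
            t.recording.validate()
            t.timeline.validate(t.recording.duration_s)

    def test_ground_truth_effect_direction(self, small_cohort):
        for t in small_cohort:
            if t.recording.outcome == "success":
                assert t.truth.alpha_w2.mean() < t.truth.alpha_w1.mean() + 0.2

    def test_null_effect_same_marginals(self):
        spec = CohortSpec(n_trials=4, n_success=2, n_channels=4,
                          w1_duration_s=(3.0, 3.0), w2_duration_s=(4.0, 4.0),
                          effect_delta=0.0, seed=21)
        trials = gen_cohort(spec)
        a2 = {o: [] for o in ("success", "failure")}
        for t in trials:
            a2[t.recording.outcome].extend(t.truth.alpha_w2)
        # with no effect both outcome groups draw W2 orders from the W1 law
        assert abs(np.mean(a2["success"]) - np.mean(a2["failure"])) < 0.5

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            CohortSpec(n_trials=3, n_success=5).validate()
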