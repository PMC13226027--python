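"""DFA / MFDFA estimators: analytic small cases, oracles, windowed tracks."""

import numpy as np
import pytest

from adsuppress.errors import ParameterError
from adsuppress.fractal import (
    ScalingConfig,
    detrended_variance,
    dfa_hurst,
    mfdfa_h,
    profile,
    windowed_scan,
)
from adsuppress.io import EventTimeline, Recording, make_windows
from adsuppress.synthetic import gen_fgn


class TestProfile:
    def test_profile_is_centered_cumsum(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(profile(x), np.cumsum(x - 2.0))

    def test_profile_last_value_zero(self):
        x = np.random.default_rng(1).standard_normal(100)
        assert profile(x)[-1] == pytest.approx(0.0, abs=1e-10)


class TestDetrendedVariance:
    def test_exact_line_gives_zero(self):
        # a perfectly linear profile segment detrends to nothing
        Y = 3.0 * np.arange(64, dtype=float) + 2.0
        assert detrended_variance(Y, 16, 0) == pytest.approx(0.0, abs=1e-18)

    def test_hand_computed_parabola(self):
        # profile 0,1,4,9 over s=4: residual variance of t^2 on a linear fit
        Y = np.array([0.0, 1.0, 4.0, 9.0])
        t = np.arange(4.0)
        coef = np.polyfit(t, Y, 1)
        expected = np.mean((Y - np.polyval(coef, t)) ** 2)
        assert detrended_variance(Y, 4, 0) == pytest.approx(expected)


class TestDfa:
    def test_white_noise_h_half(self):
        x = np.random.default_rng(0).standard_normal(8192)
        h, r2 = dfa_hurst(x)
        assert abs(h - 0.5) < 0.08
        assert r2 > 0.95

    def test_integrated_noise_h_above_one(self):
        x = np.cumsum(np.random.default_rng(0).standard_normal(8192))
        h, _ = dfa_hurst(x)
        assert h > 1.2  # random walk: H ~ 1.5

    def test_rejects_short_signal(self):
        with pytest.raises(ParameterError):
            dfa_hurst(np.zeros(20))

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            ScalingConfig(scales=(2, 3, 4))   # too small for linear detrending
        with pytest.raises(ParameterError):
            ScalingConfig(scales=(16, 32))    # too few scales for a log-log fit
        with pytest.raises(ParameterError):
            ScalingConfig(q_grid=(1.0, 3.0))  # must include q = 2


class TestMfdfa:
    def test_monofractal_flat_in_q(self):
        x = gen_fgn(0.7, 4096, seed=1)
        hq = mfdfa_h(x)
        vals = np.array(list(hq.values()))
        assert vals.max() - vals.min() < 0.15

    def test_h2_matches_dfa_order(self):
        x = gen_fgn(0.6, 4096, seed=2)
        h2 = mfdfa_h(x)[2.0]
        h, _ = dfa_hurst(x)
        assert abs(h2 - h) < 0.1

    def test_q_zero_included_and_finite(self):
        hq = mfdfa_h(gen_fgn(0.5, 2048, seed=3))
        assert 0.0 in hq
        assert np.isfinite(hq[0.0])


class TestWindowedScan:
    def test_track_shapes(self, simple_recording):
        rec, tl = simple_recording
        grid = make_windows(rec, tl, "W1", "overlap50")
        htr, mtr = windowed_scan(rec, grid, ScalingConfig())
        assert htr.h.shape == (rec.n_channels, len(grid))
        assert mtr.hq.shape[0] == rec.n_channels
        assert htr.windows == grid.windows

    def test_constant_window_flagged_missing(self):
        rng = np.random.default_rng(4)
        sig = rng.standard_normal((6000, 2))
        sig[500:1000, 1] = 0.25  # one channel flat inside the first window
        rec = Recording(signals=sig, fs_hz=1000.0, channel_labels=["a", "b"],
                        trial_id="t", outcome="failure")
        tl = EventTimeline([("AD_Start", 0.5), ("Qes_Start", 2.5), ("AD_End", 5.5)])
        grid = make_windows(rec, tl, "W1", "nonoverlap")
        htr, _ = windowed_scan(rec, grid, ScalingConfig())
        assert htr.missing[1, 0]
        assert np.isnan(htr.h[1, 0])
        assert not htr.missing[0].any()

    def test_channel_mean_skips_missing(self, simple_recording):
        rec, tl = simple_recording
        grid = make_windows(rec, tl, "W1", "nonoverlap")
        htr, _ = windowed_scan(rec, grid, ScalingConfig())
        assert np.isfinite(htr.channel_mean).all()
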