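"""Feature extraction and leave-one-trial-out classification."""

import numpy as np
import pytest

from adsuppress.classify import (
    FEATURE_MODES,
    extract_features,
    feature_names,
    loocv_logistic,
)
from adsuppress.errors import ParameterError
from adsuppress.fodn import FodnTrack
from adsuppress.fractal import MFDFATrack


def _tracks(n_ch=4, n_w=5, seed=0):
    rng = np.random.default_rng(seed)
    q_grid = (-5.0, -2.0, 0.0, 2.0, 5.0)
    out = {}
    for phase in ("W1", "W2"):
        fodn = FodnTrack(
            alpha=rng.uniform(0.2, 0.8, (n_ch, n_w)),
            weights=np.abs(rng.standard_normal((n_ch, n_w))),
            eigenvalues=rng.uniform(0.1, 0.5, n_w).astype(complex),
            spectral_radius=rng.uniform(0.1, 0.5, n_w),
            failed=np.zeros(n_w, dtype=bool),
            windows=[(i * 500, (i + 1) * 500) for i in range(n_w)],
        )
        mfdfa = MFDFATrack(
            hq=rng.uniform(0.3, 0.9, (n_ch, n_w, len(q_grid))),
            q_grid=q_grid,
            missing=np.zeros((n_ch, n_w), dtype=bool),
            windows=fodn.windows,
        )
        out[phase] = (fodn, mfdfa)
    fodn_tracks = {p: out[p][0] for p in out}
    mfdfa_tracks = {p: out[p][1] for p in out}
    return fodn_tracks, mfdfa_tracks


class TestFeatures:
    def test_modes_and_lengths(self):
        fodn, mfdfa = _tracks()
        for mode in FEATURE_MODES:
            vec = extract_features(fodn, mfdfa, mode)
            assert vec.shape == (len(feature_names(mode)),)
            assert np.isfinite(vec).all()

    def test_length_independent_of_channel_count(self):
        v4 = extract_features(*_tracks(n_ch=4))
        v9 = extract_features(*_tracks(n_ch=9))
        assert v4.shape == v9.shape

    def test_delta_is_w2_minus_w1(self):
        fodn, mfdfa = _tracks(seed=3)
        w2 = extract_features(fodn, mfdfa, "absolute_w2")
        concat = extract_features(fodn, mfdfa, "concat")
        delta = extract_features(fodn, mfdfa, "delta_w2_minus_w1")
        np.testing.assert_allclose(delta, w2 - concat[: len(w2)])

    def test_width_feature_optional(self):
        fodn, mfdfa = _tracks()
        v = extract_features(fodn, mfdfa, "absolute_w2", include_width=True)
        assert v.shape == (7,)
        assert feature_names("absolute_w2", include_width=True)[-1] == "h_width_w2"

    def test_missing_phase_rejected(self):
        fodn, mfdfa = _tracks()
        del fodn["W2"]
        with pytest.raises(ParameterError):
            extract_features(fodn, mfdfa)


def _separable(n=24, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-2.0, 0.4, (n // 2, 3)),
                   rng.normal(2.0, 0.4, (n - n // 2, 3))])
    y = np.array(["failure"] * (n // 2) + ["success"] * (n - n // 2))
    return X, y


class TestLoocv:
    def test_separable_data_perfect(self):
        X, y = _separable()
        cv = loocv_logistic(X, y, seed=0)
        assert cv.accuracy == 1.0
        assert cv.auc == 1.0
        assert cv.confusion == {"TP": 12, "FP": 0, "TN": 12, "FN": 0}

    def test_confusion_sums_to_n(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 4))
        y = np.array(["success"] * 9 + ["failure"] * 11)
        cv = loocv_logistic(X, y, seed=1)
        assert sum(cv.confusion.values()) == 20

    def test_constant_features_chance(self):
        X = np.ones((30, 3))
        y = np.array(["success"] * 12 + ["failure"] * 18)
        cv = loocv_logistic(X, y, seed=0)
        assert cv.auc == pytest.approx(0.5)
        assert cv.accuracy == pytest.approx(18 / 30)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((16, 3))
        y = np.array(["success", "failure"] * 8)
        cv1 = loocv_logistic(X, y, seed=5)
        cv2 = loocv_logistic(X, y, seed=5)
        np.testing.assert_array_equal(cv1.proba, cv2.proba)

    def test_scaler_fit_on_training_fold_only(self):
        """No-leakage assertion: perturbing only the held-out trial must not
        change the standardization statistics of its training fold."""
        X, y = _separable(n=12, seed=6)
        cv = loocv_logistic(X, y, seed=0)
        X2 = X.copy()
        X2[3] += 100.0  # massive change to trial 3 only
        cv2 = loocv_logistic(X2, y, seed=0)
        np.testing.assert_allclose(cv.fold_scaler_mean[3], cv2.fold_scaler_mean[3])
        np.testing.assert_allclose(cv.fold_scaler_scale[3], cv2.fold_scaler_scale[3])
        # sanity: every other fold's scaler does see the perturbed trial
        assert not np.allclose(cv.fold_scaler_mean[0], cv2.fold_scaler_mean[0])

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X, y = _separable(n=20, seed=7)
        accs = []
        for _ in range(50):
            accs.append(loocv_logistic(X, rng.permutation(y), seed=0).accuracy)
        maj = 0.5
        assert abs(np.mean(accs) - maj) < 0.12

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            loocv_logistic(np.zeros((5, 2)), ["success"] * 5)
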