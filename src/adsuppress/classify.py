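"""Trial-level features and leave-one-trial-out outcome classification.

Each trial is reduced to a fixed-length descriptor vector built from four
ingredients: the mean and variance (across time windows and all channels) of
the network fractional orders, scalar summaries of the dominant eigenvector
(max weight, participation ratio, consecutive-window cosine stability — the
eigenvector itself varies in length across patients, so permutation-stable
scalars stand in for it), and the generalized Hurst exponent (mean h(2), with
the multifractal width h(-5) - h(5) optional).  Features are computed per
phase; the default mode feeds the W2 - W1 contrast to the classifier, with
absolute-W2 and concatenated modes available.

Evaluation is leave-one-trial-out logistic regression with a fixed L2 penalty
(no tuning: the cohort is far too small for nested selection).  Feature
standardization uses training-fold statistics only, so the held-out trial
never leaks into the scaler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError
from .fodn import FodnTrack
from .fractal import MFDFATrack

__all__ = ["FEATURE_MODES", "extract_features", "feature_names", "loocv_logistic",
           "CVReport"]

FEATURE_MODES = ("absolute_w2", "delta_w2_minus_w1", "concat")

_BASE_NAMES = (
    "mean_alpha",
    "var_alpha",
    "eig_max_weight",
    "eig_participation",
    "eig_stability",
    "gen_hurst_h2",
)


def _phase_vector(
    fodn: FodnTrack, mfdfa: MFDFATrack, include_width: bool
) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alpha = fodn.alpha[:, ~fodn.failed]
        mean_alpha = np.nanmean(alpha) if alpha.size else np.nan
        var_alpha = np.nanvar(alpha) if alpha.size else np.nan
        h2 = np.nanmean(mfdfa.h_of(2))
        vec = [
            mean_alpha,
            var_alpha,
            fodn.max_weight_mean,
            fodn.participation_mean,
            fodn.stability,
            h2,
        ]
        if include_width:
            width = np.nanmean(mfdfa.h_of(-5) - mfdfa.h_of(5))
            vec.append(width)
    return np.asarray(vec, dtype=float)


def feature_names(mode: str = "delta_w2_minus_w1", include_width: bool = False) -> list[str]:
    base = list(_BASE_NAMES) + (["h_width"] if include_width else [])
    if mode == "absolute_w2":
        return [f"{n}_w2" for n in base]
    if mode == "delta_w2_minus_w1":
        return [f"{n}_delta" for n in base]
    if mode == "concat":
        return [f"{n}_w1" for n in base] + [f"{n}_w2" for n in base]
    raise ParameterError(f"unknown feature mode {mode!r}")


def extract_features(
    fodn_tracks: Mapping[str, FodnTrack],
    mfdfa_tracks: Mapping[str, MFDFATrack],
    mode: str = "delta_w2_minus_w1",
    *,
    include_width: bool = False,
) -> np.ndarray:
    """Fixed-length trial descriptor vector; independent of channel count.

    Non-finite summaries (e.g. cosine stability of a single-window phase) are
    replaced by zero so that degenerate trials remain classifiable.
    """
    for phase in ("W1", "W2"):
        if phase not in fodn_tracks or phase not in mfdfa_tracks:
            raise ParameterError(f"missing phase {phase!r} in trial outputs")
    w1 = _phase_vector(fodn_tracks["W1"], mfdfa_tracks["W1"], include_width)
    w2 = _phase_vector(fodn_tracks["W2"], mfdfa_tracks["W2"], include_width)
    if mode == "absolute_w2":
        vec = w2
    elif mode == "delta_w2_minus_w1":
        vec = w2 - w1
    elif mode == "concat":
        vec = np.concatenate([w1, w2])
    else:
        raise ParameterError(f"unknown feature mode {mode!r}")
    return np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)


@dataclass
class CVReport:
    """Leave-one-trial-out evaluation: per-fold outputs and pooled metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray            # out-of-fold P(success)
    accuracy: float
    confusion: dict[str, int]    # TP/FP/TN/FN with "success" positive
    precision: dict[str, float]
    recall: dict[str, float]
    auc: float
    roc: tuple[np.ndarray, np.ndarray]
    flagged_folds: list[int] = field(default_factory=list)
    fold_scaler_mean: list[np.ndarray] = field(default_factory=list)
    fold_scaler_scale: list[np.ndarray] = field(default_factory=list)

    @property
    def n_correct(self) -> int:
        return int(np.sum(self.y_true == self.y_pred))


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[dict, dict, dict]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    conf = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}

    def safe(num, den):
        return float(num / den) if den else float("nan")

    precision = {"success": safe(tp, tp + fp), "failure": safe(tn, tn + fn)}
    recall = {"success": safe(tp, tp + fn), "failure": safe(tn, tn + fp)}
    return conf, precision, recall


def loocv_logistic(
    features: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    seed: int = 0,
    *,
    C: float = 1.0,
    threshold: float = 0.5,
) -> CVReport:
    """Leave-one-trial-out logistic regression with within-fold standardization.

    ``labels`` are "success"/"failure" strings (or a boolean/0-1 array with 1
    meaning success).  Per fold the scaler and the L2-penalized logistic model
    (fixed ``C``) are fit on the training trials only; the held-out trial is
    predicted at the given probability threshold.  A training fold with a
    single class is flagged and predicted as its majority class.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ParameterError("features must be (n_trials, n_features)")
    lab = np.asarray(labels)
    if lab.dtype.kind in "USO":
        y = (lab == "success").astype(int)
    else:
        y = lab.astype(int)
    n = X.shape[0]
    if n != y.size:
        raise ParameterError("features and labels disagree on trial count")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ParameterError("need at least 2 trials per class for LOOCV")

    preds = np.empty(n, dtype=int)
    proba = np.empty(n)
    flagged: list[int] = []
    scaler_means: list[np.ndarray] = []
    scaler_scales: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        scaler = StandardScaler().fit(Xtr)
        scaler_means.append(scaler.mean_.copy())
        scaler_scales.append(scaler.scale_.copy())
        if len(np.unique(ytr)) < 2:
            flagged.append(i)
            maj = int(np.round(ytr.mean()))
            preds[i] = maj
            proba[i] = float(ytr.mean())
            continue
        if not np.any(Xtr.std(axis=0) > 0):
            # uninformative fold: an intercept-only model would leak the
            # held-out label through the training base rate (anti-correlated
            # probabilities), so emit a flat 0.5 and the majority class
            flagged.append(i)
            preds[i] = int(np.round(ytr.mean()))
            proba[i] = 0.5
            continue
        clf = LogisticRegression(
            C=C, solver="lbfgs", max_iter=2000,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit(scaler.transform(Xtr), ytr)
        p = clf.predict_proba(scaler.transform(X[i][None]))[0]
        p_success = float(p[list(clf.classes_).index(1)])
        proba[i] = p_success
        preds[i] = int(p_success >= threshold)

    conf, precision, recall = _prf(y, preds)
    accuracy = float(np.mean(preds == y))
    if np.unique(proba).size > 1:
        auc = float(roc_auc_score(y, proba))
        fpr, tpr, _ = roc_curve(y, proba)
    else:
        auc = 0.5
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    return CVReport(
        y_true=y,
        y_pred=preds,
        proba=proba,
        accuracy=accuracy,
        confusion=conf,
        precision=precision,
        recall=recall,
        auc=auc,
        roc=(fpr, tpr),
        flagged_folds=flagged,
        fold_scaler_mean=scaler_means,
        fold_scaler_scale=scaler_scales,
    )
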