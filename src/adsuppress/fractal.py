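"""Windowed monofractal (DFA) and multifractal (MFDFA) scaling estimation.

Detrended fluctuation analysis integrates the mean-removed signal, removes a
local polynomial trend from segments of length ``s`` and measures the RMS
residual fluctuation F(s); the scaling law F(s) ~ s^H yields the Hurst
exponent.  MFDFA generalizes this with a moment order q, F_q(s) ~ s^{h(q)}:
for a monofractal signal h(q) is flat, and a q-dependence of h(q) indicates
multifractality.

Two segmentations coexist deliberately: plain DFA averages the Ns = int(N/s)
segments taken forward from the start of the profile, while MFDFA averages 2Ns
segments taken from both the start and the end (so that the trailing partial
segment is not discarded asymmetrically under q-weighting).  ĥ(2) therefore
agrees with the DFA Hurst exponent only up to the segmentation difference.

Estimates on 500-sample windows with scales up to 128 rest on as few as
Ns = 3 segments at the largest scale; the four scale points keep the log-log
fit defined but individual window estimates are noisy by construction — the
pipeline works with distributions and time averages of them, never single
windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io import Recording, WindowGrid

__all__ = [
    "ScalingConfig",
    "profile",
    "detrended_variance",
    "dfa_hurst",
    "mfdfa_h",
    "windowed_scan",
    "HurstTrack",
    "MFDFATrack",
]

DEFAULT_SCALES = (16, 32, 64, 128)
DEFAULT_Q = (-5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ScalingConfig:
    """Scales, detrending order and moment grid for DFA/MFDFA fits."""

    scales: tuple[int, ...] = DEFAULT_SCALES
    detrend_order: int = 1
    q_grid: tuple[float, ...] = DEFAULT_Q
    log_base: float = 2.0

    def __post_init__(self):
        if len(self.scales) < 3:
            raise ParameterError("need at least 3 scales for a log-log fit")
        if min(self.scales) < self.detrend_order + 2:
            raise ParameterError(
                f"min scale {min(self.scales)} too small for order-"
                f"{self.detrend_order} detrending"
            )
        if 2 not in self.q_grid:
            raise ParameterError("q_grid must contain q = 2")

    def check_window(self, n: int) -> None:
        if max(self.scales) > n // 2:
            warnings.warn(
                f"max scale {max(self.scales)} exceeds half the window length {n}",
                RuntimeWarning,
            )


def profile(x: np.ndarray) -> np.ndarray:
    """Integrated (cumulative-sum) profile Y(i) = sum_{k<=i} (x(k) - mean(x)).

    Works columnwise on a 2-D samples x channels array.  The final value is
    zero up to float round-off (the mean-removed terms telescope).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ParameterError("profile needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ParameterError("profile input must be finite")
    return np.cumsum(x - x.mean(axis=0), axis=0)


def _design(s: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    V = np.vander(np.arange(s, dtype=float), order + 1, increasing=True)
    P = np.linalg.pinv(V)
    return V, P


def _segment_f2(Y: np.ndarray, s: int, order: int, both_ends: bool) -> np.ndarray:
    """Detrended variances of all length-``s`` segments of a profile.

    Y is (n, C); returns (Ns, C) for forward segmentation or (2 Ns, C) with the
    segments taken from both the start and the end of the profile.
    """
    n = Y.shape[0]
    ns = n // s
    if ns < 1:
        raise ParameterError(f"scale {s} exceeds series length {n}")
    V, P = _design(s, order)

    def f2_of(block: np.ndarray) -> np.ndarray:
        segs = block.reshape(ns, s, -1)
        coef = np.einsum("ps,vsc->vpc", P, segs)
        resid = segs - np.einsum("sp,vpc->vsc", V, coef)
        return np.mean(resid**2, axis=1)

    out = f2_of(Y[: ns * s])
    if both_ends:
        out = np.concatenate([out, f2_of(Y[n - ns * s:])], axis=0)
    return out


def detrended_variance(Y: np.ndarray, s: int, nu: int, order: int = 1) -> float:
    """F^2(nu, s): mean squared residual of an order-``order`` polynomial fit
    over forward segment ``nu`` (0-based) of the profile ``Y``."""
    Y = np.asarray(Y, dtype=float)
    if s <= order + 1:
        raise ParameterError(f"scale {s} must exceed detrend order + 1")
    ns = Y.shape[0] // s
    if not 0 <= nu < ns:
        raise ParameterError(f"segment {nu} out of range (Ns = {ns})")
    seg = Y[nu * s:(nu + 1) * s]
    V, P = _design(s, order)
    resid = seg - V @ (P @ seg)
    return float(np.mean(resid**2))


def _log_slope(logs: np.ndarray, logF: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope (and R^2) of logF against logs, vectorized over columns."""
    X = np.column_stack([logs, np.ones_like(logs)])
    with np.errstate(divide="ignore", invalid="ignore"):
        coef, *_ = np.linalg.lstsq(X, logF, rcond=None)
        fitted = X @ coef
        ss_res = np.sum((logF - fitted) ** 2, axis=0)
        ss_tot = np.sum((logF - logF.mean(axis=0)) ** 2, axis=0)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    slope = np.where(np.isfinite(logF).all(axis=0), coef[0], np.nan)
    return slope, r2


def _dfa_multi(x: np.ndarray, config: ScalingConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DFA per column of (n, C) data: returns H (C,), R^2 (C,), F (S, C)."""
    n, n_ch = x.shape
    sd = x.std(axis=0)
    ok = sd > 0
    H = np.full(n_ch, np.nan)
    r2 = np.full(n_ch, np.nan)
    Fmat = np.full((len(config.scales), n_ch), np.nan)
    if not ok.any():
        return H, r2, Fmat
    Y = profile(x[:, ok])
    for i, s in enumerate(config.scales):
        f2 = _segment_f2(Y, s, config.detrend_order, both_ends=False)
        Fmat[i, ok] = np.sqrt(np.mean(f2, axis=0))
    logs = np.log(np.asarray(config.scales, float)) / np.log(config.log_base)
    with np.errstate(divide="ignore"):
        logF = np.log(Fmat[:, ok]) / np.log(config.log_base)
    H[ok], r2[ok] = _log_slope(logs, logF)
    return H, r2, Fmat


def dfa_hurst(x: np.ndarray, config: ScalingConfig = ScalingConfig()) -> tuple[float, float]:
    """Hurst exponent of a 1-D signal via DFA; returns ``(H, fit_r2)``.

    A zero-variance signal is flagged with ``(nan, nan)`` rather than raising:
    windowed scans must tolerate flat channels.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("dfa_hurst expects a 1-D signal; see windowed_scan")
    if x.shape[0] < 2 * max(config.scales):
        raise ParameterError(
            f"signal length {x.shape[0]} < 2 * max scale {max(config.scales)}"
        )
    H, r2, _ = _dfa_multi(x[:, None], config)
    return float(H[0]), float(r2[0])


def _mfdfa_multi(x: np.ndarray, config: ScalingConfig) -> np.ndarray:
    """MFDFA per column of (n, C) data: returns h(q) with shape (Q, C)."""
    n, n_ch = x.shape
    q_grid = np.asarray(config.q_grid, dtype=float)
    hq = np.full((len(q_grid), n_ch), np.nan)
    ok = x.std(axis=0) > 0
    if not ok.any():
        return hq
    Y = profile(x[:, ok])
    S = len(config.scales)
    logFq = np.full((S, len(q_grid), ok.sum()), np.nan)
    warned = False
    for i, s in enumerate(config.scales):
        f2 = _segment_f2(Y, s, config.detrend_order, both_ends=True)  # (2Ns, C')
        if np.any(f2 == 0):
            if not warned:
                warnings.warn(
                    "zero detrended variance in some segments; "
                    "excluded from moment averages",
                    RuntimeWarning,
                )
                warned = True
            f2 = np.where(f2 == 0, np.nan, f2)
        with np.errstate(divide="ignore"):
            lf2 = np.log(f2)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            with np.errstate(divide="ignore", invalid="ignore"):
                for j, q in enumerate(q_grid):
                    if q == 0:
                        # log-averaging limit: F_0(s) = exp(mean of (1/2) ln F^2)
                        logFq[i, j] = 0.5 * np.nanmean(lf2, axis=0)
                    else:
                        m = np.nanmean(np.exp(0.5 * q * lf2), axis=0)
                        logFq[i, j] = np.log(m) / q
    logs = np.log(np.asarray(config.scales, float))
    flat = logFq.reshape(S, -1)
    slope, _ = _log_slope(logs, flat)
    hq[:, ok] = slope.reshape(len(q_grid), ok.sum())
    return hq


def mfdfa_h(x: np.ndarray, config: ScalingConfig = ScalingConfig()) -> dict[float, float]:
    """Generalized Hurst exponent h(q) of a 1-D signal for each q in the grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("mfdfa_h expects a 1-D signal; see windowed_scan")
    if x.shape[0] < 2 * max(config.scales):
        raise ParameterError(
            f"signal length {x.shape[0]} < 2 * max scale {max(config.scales)}"
        )
    hq = _mfdfa_multi(x[:, None], config)[:, 0]
    return {float(q): float(h) for q, h in zip(config.q_grid, hq)}


@dataclass
class HurstTrack:
    """Per-channel-per-window DFA estimates for one trial phase."""

    h: np.ndarray        # (n_channels, n_windows)
    r2: np.ndarray       # (n_channels, n_windows)
    missing: np.ndarray  # (n_channels, n_windows) bool
    windows: list[tuple[int, int]]

    @property
    def channel_mean(self) -> np.ndarray:
        """Time-averaged Hurst exponent per channel (missing windows excluded)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(np.where(self.missing, np.nan, self.h), axis=1)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


@dataclass
class MFDFATrack:
    """Per-channel-per-window generalized Hurst exponents for one trial phase."""

    hq: np.ndarray       # (n_channels, n_windows, n_q)
    q_grid: tuple[float, ...]
    missing: np.ndarray  # (n_channels, n_windows) bool
    windows: list[tuple[int, int]]

    def h_of(self, q: float) -> np.ndarray:
        """The (n_channels, n_windows) slice at moment order q."""
        j = list(self.q_grid).index(q)
        return np.where(self.missing, np.nan, self.hq[:, :, j])

    @property
    def channel_mean(self) -> np.ndarray:
        """Time-averaged h(q) per channel, shape (n_channels, n_q)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(
                np.where(self.missing[:, :, None], np.nan, self.hq), axis=1
            )


def windowed_scan(
    rec: Recording,
    grid: WindowGrid,
    config: ScalingConfig = ScalingConfig(),
) -> tuple[HurstTrack, MFDFATrack]:
    """DFA and MFDFA estimates for every channel in every window of a grid.

    Channels with zero variance in a window are flagged missing for that
    window (and excluded from channel time averages) rather than raising.
    """
    sig = np.asarray(rec.signals, dtype=float)
    n_ch = sig.shape[1]
    n_w = len(grid.windows)
    if n_w:
        config.check_window(grid.windows[0][1] - grid.windows[0][0])
    h = np.full((n_ch, n_w), np.nan)
    r2 = np.full((n_ch, n_w), np.nan)
    hq = np.full((n_ch, n_w, len(config.q_grid)), np.nan)
    for w, (a, b) in enumerate(grid.windows):
        xw = sig[a:b]
        Hw, r2w, _ = _dfa_multi(xw, config)
        h[:, w] = Hw
        r2[:, w] = r2w
        hq[:, w, :] = _mfdfa_multi(xw, config).T
    missing = ~np.isfinite(h)
    return (
        HurstTrack(h=h, r2=r2, missing=missing, windows=list(grid.windows)),
        MFDFATrack(hq=hq, q_grid=tuple(config.q_grid), missing=missing,
                   windows=list(grid.windows)),
    )


def tracks_to_frame(trial_id: str, segment: str, track: HurstTrack, mfdfa: MFDFATrack):
    """Tidy long-format table of per-window estimates (one row per channel-window)."""
    import pandas as pd

    rows = []
    h2 = mfdfa.h_of(2)
    for c in range(track.h.shape[0]):
        for w in range(track.h.shape[1]):
            rows.append({
                "trial": trial_id,
                "segment": segment,
                "channel": c,
                "window_index": w,
                "H": track.h[c, w],
                "fit_r2": track.r2[c, w],
                "h_q2": h2[c, w],
                "missing": bool(track.missing[c, w]),
            })
    return pd.DataFrame(rows)
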