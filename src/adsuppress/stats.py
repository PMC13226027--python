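"""Pooling of scaling exponents by trial phase and W1-vs-W2 distribution tests.

The unit of pooling is one channel of one trial: its time-averaged exponent
over the windows of a phase.  Distributions are compared with the two-sample
Kolmogorov–Smirnov test using the asymptotic p-value; channelwise comparisons
use the window-level exponents of a single trial.  Channelwise p-values are
reported raw, with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError
from .fractal import HurstTrack

__all__ = ["PooledDistribution", "KSResult", "pool_exponents", "ks_two_sample",
           "channelwise_ks"]


@dataclass
class PooledDistribution:
    """Per-channel time-averaged exponents pooled over the trials of one class."""

    values: np.ndarray
    phase: str
    outcome: str

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    D: float
    p: float
    n1: int
    n2: int
    channel: int | None = None
    flagged: bool = False


def pool_exponents(
    trial_tracks: Sequence[tuple[str, Mapping[str, HurstTrack]]],
    phase: str,
    outcome: str,
) -> PooledDistribution:
    """Pool channel time-averaged exponents across all trials of one outcome.

    ``trial_tracks`` holds ``(trial_outcome, {"W1": track, "W2": track})``
    pairs.  One value enters the pool per (trial, channel); channels whose
    every window is flagged missing are excluded.
    """
    vals = []
    for trial_outcome, tracks in trial_tracks:
        if trial_outcome != outcome:
            continue
        cm = tracks[phase].channel_mean
        vals.append(cm[np.isfinite(cm)])
    if not vals or sum(v.size for v in vals) == 0:
        raise ParameterError(
            f"empty pool for phase={phase!r}, outcome={outcome!r}"
        )
    return PooledDistribution(values=np.concatenate(vals), phase=phase, outcome=outcome)


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| with asymptotic p-value."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ParameterError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return KSResult(D=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                    n1=a.size, n2=b.size)


def channelwise_ks(
    track_w1: HurstTrack, track_w2: HurstTrack, min_windows: int = 2
) -> list[KSResult]:
    """Per-channel KS test of W1 window-level exponents against W2's.

    Channels with fewer than ``min_windows`` usable windows in either phase
    are returned flagged (D, p = nan) rather than dropped, preserving channel
    indexing.
    """
    n_ch = track_w1.h.shape[0]
    if track_w2.h.shape[0] != n_ch:
        raise ParameterError("phase tracks have different channel counts")
    out: list[KSResult] = []
    for c in range(n_ch):
        a = track_w1.h[c][~track_w1.missing[c]]
        b = track_w2.h[c][~track_w2.missing[c]]
        if a.size < min_windows or b.size < min_windows:
            out.append(KSResult(D=float("nan"), p=float("nan"), n1=a.size,
                                n2=b.size, channel=c, flagged=True))
            continue
        r = ks_two_sample(a, b)
        out.append(KSResult(D=r.D, p=r.p, n1=r.n1, n2=r.n2, channel=c))
    return out
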