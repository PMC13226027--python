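"""Synthetic signal and cohort generators with known ground truth.

Everything the analysis pipeline assumes about its inputs is produced here with
controlled parameters: exact fractional Gaussian noise (long-range dependence
with a known Hurst exponent), fractionally integrated noise (known spectral
slope, hence known wavelet-regression order), the binomial multiplicative
cascade (closed-form generalized Hurst exponent), forward simulation of the
fractional-order network model, and full stimulation-trial cohorts with an
injectable suppression effect.

The cohort generator emulates functional-mapping sessions in which cortical
electrical stimulation evokes epileptiform after-discharges and the patient is
engaged in an arithmetic/spelling task: each trial is a multichannel recording
(1000 Hz) split by event markers into a pre-question phase (W1) and a
question-to-offset phase (W2).  In trials labelled "success" the W2 phase has
reduced dispersion of the channelwise fractional orders and attenuated spike
transients — the signature the downstream classifier is meant to detect.  With
``effect_delta = 0`` success and failure trials are exchangeable (null cohort).
Signals are generated in z-score-like units; amplitude calibration of real
intracranial recordings is not emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .fodn import gl_coefficients
from .io import EventTimeline, Recording

__all__ = [
    "gen_fgn",
    "gen_arfima",
    "gen_binomial_cascade",
    "binomial_cascade_hq",
    "simulate_fodn",
    "FodnSimResult",
    "CohortSpec",
    "GroundTruth",
    "Trial",
    "gen_cohort",
    "random_stable_coupling",
    "random_skew_coupling",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise — exact synthesis by circulant embedding


def _fgn_autocov(hurst: float, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )


def gen_fgn(hurst: float, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Exact fractional Gaussian noise of length ``n`` with Hurst exponent ``hurst``.

    Uses Davies–Harte circulant embedding of the fGn autocovariance, which is
    positive semi-definite for all ``hurst`` in (0, 1); if the embedding
    eigenvalues nevertheless come out numerically negative the routine falls
    back to Cholesky factorization of the Toeplitz covariance, with a warning.
    At ``hurst = 0.5`` the output is white noise (unit variance).
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)

    g = _fgn_autocov(hurst, n + 1)
    # circulant first row: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([g, g[-2:0:-1]])
    m = row.size  # 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        warnings.warn(
            "circulant embedding not positive semi-definite; "
            "falling back to Cholesky synthesis",
            RuntimeWarning,
        )
        from scipy.linalg import cholesky, toeplitz

        L = cholesky(toeplitz(_fgn_autocov(hurst, n)), lower=True)
        return L @ rng.standard_normal(n)
    lam = np.clip(lam, 0.0, None)

    # Hermitian-symmetric spectral sample -> real Gaussian series
    v = np.empty(m, dtype=complex)
    half = m // 2
    v[0] = np.sqrt(lam[0]) * rng.standard_normal()
    a = rng.standard_normal(half - 1)
    b = rng.standard_normal(half - 1)
    v[1:half] = np.sqrt(lam[1:half] / 2.0) * (a + 1j * b)
    v[half] = np.sqrt(lam[half]) * rng.standard_normal()
    v[half + 1:] = np.conj(v[1:half][::-1])
    x = np.fft.fft(v) / np.sqrt(m)
    return x.real[:n]


# ---------------------------------------------------------------------------
# fractionally integrated noise


def _fi_weights(d: float, n: int) -> np.ndarray:
    """MA(inf) weights of (1-B)^{-d}: psi_0 = 1, psi_j = psi_{j-1} (j-1+d)/j."""
    psi = np.empty(n)
    psi[0] = 1.0
    j = np.arange(1, n, dtype=float)
    psi[1:] = np.cumprod((j - 1.0 + d) / j)
    return psi


def _fractional_integrate(
    eps: np.ndarray, d: float, burn_in: int
) -> np.ndarray:
    """Apply the truncated MA(inf) filter of (1-B)^{-d} to a noise series.

    ``eps`` has length n + burn_in; the first ``burn_in`` output samples are
    discarded so the returned series of length n carries a full filter history.
    Valid for any d < 1.5 (the weights decay for d < 1 and grow sub-linearly
    up to d = 1.5, where the series is non-stationary by construction).
    """
    from scipy.signal import fftconvolve

    total = eps.size
    psi = _fi_weights(d, total)
    x = fftconvolve(eps, psi)[:total]
    return x[burn_in:]


def gen_arfima(
    d: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    *,
    burn_in: int | None = None,
    return_noise: bool = False,
):
    """Fractionally integrated white noise ARFIMA(0, d, 0) of length ``n``.

    The driving white noise is passed through the truncated MA(inf) expansion
    of :math:`(1-B)^{-d}` (weights by the stable recursion
    ``psi_j = psi_{j-1} (j-1+d)/j``), with a burn-in prefix discarded so that
    every returned sample sees an effectively full history.  The spectral
    density behaves as :math:`f^{-2d}` at low frequency, so a wavelet
    log-scale regression recovers a fractional order of ``d``.

    With ``return_noise=True`` also returns the aligned driving noise (at
    ``d = 0`` the output equals it exactly).
    """
    if not abs(d) < 0.5:
        raise ParameterError(f"d must satisfy |d| < 0.5, got {d}")
    if n < 1:
        raise ParameterError("n must be positive")
    rng = np.random.default_rng(seed)
    if burn_in is None:
        burn_in = min(n, 4096)
    eps = rng.standard_normal(n + burn_in)
    x = _fractional_integrate(eps, d, burn_in)
    if return_noise:
        return x, eps[burn_in:]
    return x


# ---------------------------------------------------------------------------
# binomial multiplicative cascade


def gen_binomial_cascade(a: float, n_levels: int) -> np.ndarray:
    """Deterministic binomial multiplicative cascade series of length 2**n_levels.

    Starting from a unit mass, each cell is repeatedly split in two, the left
    child receiving fraction ``a`` and the right ``1 - a``.  The resulting
    series is the canonical multifractal benchmark: its generalized Hurst
    exponent has the closed form given by :func:`binomial_cascade_hq`.
    """
    if not 0.5 < a < 1.0:
        raise ParameterError(f"multiplier a must be in (0.5, 1), got {a}")
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    x = np.array([1.0])
    for _ in range(n_levels):
        x = np.stack([a * x, (1.0 - a) * x], axis=1).ravel()
    return x


def binomial_cascade_hq(a: float, q) -> np.ndarray:
    """Exact generalized Hurst exponent of the binomial cascade.

    h(q) = 1/q - log2(a^q + (1-a)^q)/q, with the q -> 0 limit
    h(0) = -log2(a(1-a))/2.
    """
    q = np.asarray(q, dtype=float)
    out = np.empty_like(q)
    nz = q != 0
    qq = q[nz]
    out[nz] = 1.0 / qq - np.log2(a**qq + (1.0 - a) ** qq) / qq
    out[~nz] = -np.log2(a * (1.0 - a)) / 2.0
    return out


# ---------------------------------------------------------------------------
# forward simulation of the fractional-order network model


@dataclass
class FodnSimResult:
    """Output of :func:`simulate_fodn`: signals plus the realized inputs and noise."""

    signals: np.ndarray  # (t, n_channels)
    u: np.ndarray        # (t, n_channels) inputs as injected
    eps: np.ndarray      # (t, n_channels) innovation noise


def simulate_fodn(
    A: np.ndarray,
    alpha: np.ndarray,
    t_samples: int,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
    *,
    u: np.ndarray | None = None,
    J: int = 50,
) -> FodnSimResult:
    """Iterate the fractional-order network model forward in time.

    The model is ``z[k] = A x[k-1] + u[k] + eps[k]`` where
    ``z[k] = sum_j c_j(alpha) x[k-j]`` is the channelwise Grünwald–Letnikov
    fractional derivative (expanding history, truncated at ``J`` lags).  Since
    ``c_0 = 1`` the recursion is inverted step by step:

    ``x[k] = A x[k-1] + u[k] + eps[k] - sum_{j>=1} c_j x[k-j]``.

    With ``A = 0``, ``alpha = 0`` and ``u = 0`` the output is the innovation
    noise itself.
    """
    A = np.asarray(A, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    n = A.shape[0]
    if A.shape != (n, n):
        raise ParameterError(f"A must be square, got shape {A.shape}")
    if alpha.shape != (n,):
        raise ParameterError(
            f"alpha length {alpha.shape[0]} does not match {n} channels"
        )
    eigvals = np.linalg.eigvals(A)
    rho_idx = int(np.argmax(np.abs(eigvals)))
    if np.abs(eigvals[rho_idx]) >= 1.0:
        raise ParameterError(
            f"coupling matrix is unstable: eigenvalue {eigvals[rho_idx]:.4g} "
            f"has modulus {np.abs(eigvals[rho_idx]):.4g} >= 1"
        )
    rng = np.random.default_rng(seed)
    eps = noise_sd * rng.standard_normal((t_samples, n))
    if u is None:
        u_arr = np.zeros((t_samples, n))
    else:
        u_arr = np.asarray(u, dtype=float)
        if u_arr.shape != (t_samples, n):
            raise ParameterError(f"u must have shape {(t_samples, n)}, got {u_arr.shape}")

    C = gl_coefficients(alpha, J)  # (J+1, n)
    x = np.zeros((t_samples, n))
    for k in range(t_samples):
        drive = u_arr[k] + eps[k]
        if k > 0:
            drive = drive + A @ x[k - 1]
            jmax = min(k, J)
            hist = x[k - jmax:k][::-1]          # x[k-1], x[k-2], ...
            drive = drive - np.einsum("jc,jc->c", C[1:jmax + 1], hist)
        x[k] = drive
    return FodnSimResult(signals=x, u=u_arr, eps=eps)


def random_stable_coupling(
    n: int,
    density: float = 0.05,
    spectral_radius: float = 0.35,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sparse random directed coupling matrix rescaled to a target spectral radius.

    The spectrum is shifted into the closed left half-plane before rescaling
    (a uniform self-damping diagonal), because the fractional integrator has a
    pole at zero frequency: coupling eigenvalues with positive real part feed
    it back explosively, while left-half-plane spectra keep the simulated
    network stable for any fractional order used here.
    """
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n)) * (rng.random((n, n)) < density)
    if not A.any():  # fully empty draw; plant a single edge
        A[0, min(1, n - 1)] = 1.0
    ev = np.linalg.eigvals(A)
    shift = max(float(ev.real.max()), 0.0) + 0.1 * max(float(np.abs(ev).max()), 1e-6)
    A = A - shift * np.eye(n)
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    return A * (spectral_radius / rho)


def random_skew_coupling(
    n: int,
    spectral_radius: float = 0.85,
    seed: int | np.random.Generator | None = None,
    density: float = 1.0,
) -> np.ndarray:
    """Random skew-symmetric coupling matrix rescaled to a target spectral radius.

    Skew symmetry forces a purely imaginary spectrum and a zero diagonal.  For
    fractional orders below one such rotational coupling is stable under the
    fractional integrator (the characteristic roots 1 + (i mu)^(1/alpha) have
    negative real part), so the radius can be pushed much higher than with
    generic matrices — giving a strongly coupled yet stable planted network.
    The zero diagonal also makes the fractional orders identifiable by
    :func:`adsuppress.fodn.estimate_alpha_regression`, which attributes all
    self-history to the fractional operator.
    """
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((n, n)) * (rng.random((n, n)) < density)
    A = (B - B.T) / 2.0
    if not A.any():
        j = min(1, n - 1)
        A[0, j], A[j, 0] = 1.0, -1.0
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    return A * (spectral_radius / rho)


# ---------------------------------------------------------------------------
# trial cohorts


@dataclass
class CohortSpec:
    """Parameters of a synthetic stimulation-trial cohort.

    Defaults reproduce the reference cohort structure: 43 trials of which 20
    are successful suppressions, 60 channels at 1000 Hz.  Channelwise
    fractional orders are drawn per phase; in success trials the W2 orders are
    pulled toward a tighter distribution and spike transients are attenuated,
    both in proportion to ``effect_delta`` (0 disables the effect entirely,
    1 applies the full stated W2 success distribution).
    """

    n_trials: int = 43
    n_success: int = 20
    n_channels: int = 60
    fs_hz: float = 1000.0
    w1_duration_s: tuple[float, float] = (3.0, 5.0)
    w2_duration_s: tuple[float, float] = (4.0, 7.0)
    alpha_mean_w1: float = 0.55
    alpha_sd_w1: float = 0.25
    alpha_mean_w2_success: float = 0.40
    alpha_sd_w2_success: float = 0.10
    spike_rate_hz: float = 3.0
    spike_amp: float = 4.0
    effect_delta: float = 1.0
    coupling_density: float = 0.05
    coupling_radius: float = 0.35
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_success > self.n_trials:
            raise ParameterError("n_success cannot exceed n_trials")
        if min(self.n_trials, self.n_channels) < 1:
            raise ParameterError("n_trials and n_channels must be positive")
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be positive")
        for name in ("w1_duration_s", "w2_duration_s"):
            lo, hi = getattr(self, name)
            if not (1.0 < lo <= hi):
                raise ParameterError(f"{name} must satisfy 1 < lo <= hi, got {(lo, hi)}")
        if self.effect_delta < 0:
            raise ParameterError("effect_delta must be >= 0")
        if not 2.0 <= self.spike_rate_hz <= 4.0:
            raise ParameterError("spike_rate_hz must lie in the after-discharge band [2, 4] Hz")
        return self


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic trial (enables recovery testing)."""

    A: np.ndarray
    alpha_w1: np.ndarray
    alpha_w2: np.ndarray
    u: np.ndarray              # additive spike waveform actually injected (t, C)
    outcome: str
    spike_channels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class Trial:
    recording: Recording
    timeline: EventTimeline
    truth: GroundTruth


_ALPHA_MAX = 1.3  # keep planted orders below the strongly non-stationary regime


def _biphasic_kernel(fs_hz: float) -> np.ndarray:
    """One cycle of a tapered sine: sharp up-down transient (~60 ms)."""
    width = int(round(0.06 * fs_hz))
    t = np.linspace(0.0, 1.0, width, endpoint=False)
    return np.sin(2 * np.pi * t) * np.hanning(width)


def _spike_waveform(
    n_samples: int,
    n_channels: int,
    fs_hz: float,
    rate_hz: float,
    amp: float,
    channels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quasi-periodic biphasic spike train on a subset of channels."""
    out = np.zeros((n_samples, n_channels))
    if amp == 0 or channels.size == 0:
        return out
    kern = _biphasic_kernel(fs_hz)
    period = fs_hz / rate_hz
    times = []
    t = rng.uniform(0, period)
    while t < n_samples - kern.size:
        times.append(int(t))
        t += period * rng.uniform(0.85, 1.15)  # jittered periodicity
    train = np.zeros(n_samples)
    for t0 in times:
        train[t0:t0 + kern.size] += kern
    for ch in channels:
        out[:, ch] = amp * rng.uniform(0.7, 1.3) * train
    return out


def gen_cohort(spec: CohortSpec) -> list[Trial]:
    """Generate a full cohort of trials with ground truth.

    Each trial: channelwise long-memory background with phase-specific
    fractional orders, sparse directed coupling (one planted A per trial,
    shared by both phases), and a 2–4 Hz biphasic spike train on a subset of
    channels throughout the after-discharge period.  Success trials draw their
    W2 orders from a tighter distribution and attenuate W2 spikes; the
    strength of both is scaled by ``effect_delta``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outcomes = np.array(
        ["success"] * spec.n_success + ["failure"] * (spec.n_trials - spec.n_success)
    )
    rng.shuffle(outcomes)

    e = min(spec.effect_delta, 1.5)
    mean2 = spec.alpha_mean_w1 + e * (spec.alpha_mean_w2_success - spec.alpha_mean_w1)
    sd2 = max(spec.alpha_sd_w1 + e * (spec.alpha_sd_w2_success - spec.alpha_sd_w1), 0.01)
    spike_atten = max(1.0 - 0.8 * min(spec.effect_delta, 1.0), 0.0)

    trials: list[Trial] = []
    for i, outcome in enumerate(outcomes):
        n_ch = spec.n_channels
        w1_s = rng.uniform(*spec.w1_duration_s)
        w2_s = rng.uniform(*spec.w2_duration_s)
        n1 = int(round(w1_s * spec.fs_hz))
        n2 = int(round(w2_s * spec.fs_hz))

        alpha1 = np.clip(
            rng.normal(spec.alpha_mean_w1, spec.alpha_sd_w1, n_ch), 0.0, _ALPHA_MAX
        )
        if outcome == "success":
            alpha2 = np.clip(rng.normal(mean2, sd2, n_ch), 0.0, _ALPHA_MAX)
        else:
            alpha2 = np.clip(
                rng.normal(spec.alpha_mean_w1, spec.alpha_sd_w1, n_ch), 0.0, _ALPHA_MAX
            )

        A = random_stable_coupling(
            n_ch, spec.coupling_density, spec.coupling_radius, rng
        )
        sim1 = simulate_fodn(A, alpha1, n1, spec.noise_sd, rng)
        sim2 = simulate_fodn(A, alpha2, n2, spec.noise_sd, rng)
        sig = np.vstack([sim1.signals, sim2.signals])

        spike_channels = rng.choice(n_ch, size=max(1, n_ch // 3), replace=False)
        amp2 = spec.spike_amp * (spike_atten if outcome == "success" else 1.0)
        spikes = np.vstack([
            _spike_waveform(n1, n_ch, spec.fs_hz, spec.spike_rate_hz,
                            spec.spike_amp, spike_channels, rng),
            _spike_waveform(n2, n_ch, spec.fs_hz, spec.spike_rate_hz,
                            amp2, spike_channels, rng),
        ])
        sig = sig + spikes

        q_start = n1 / spec.fs_hz
        ad_end = (n1 + n2) / spec.fs_hz
        markers = [("AD_Start", 0.0), ("Qes_Start", q_start)]
        if w2_s > 3.0:  # annotate question/answer timing when the phase is long enough
            markers += [
                ("Qes_End", q_start + 1.0),
                ("Ans_Start", q_start + 1.5),
                ("Ans_End", q_start + 2.5),
            ]
        markers.append(("AD_End", ad_end))

        rec = Recording(
            signals=sig,
            fs_hz=spec.fs_hz,
            channel_labels=[f"ch{c:03d}" for c in range(n_ch)],
            patient_id="synthetic",
            trial_id=f"trial{i:03d}",
            outcome=str(outcome),
        ).validate()
        timeline = EventTimeline(markers=markers).validate(rec.duration_s)
        truth = GroundTruth(
            A=A,
            alpha_w1=alpha1,
            alpha_w2=alpha2,
            u=spikes,
            outcome=str(outcome),
            spike_channels=np.sort(spike_channels),
        )
        trials.append(Trial(recording=rec, timeline=timeline, truth=truth))
    return trials
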