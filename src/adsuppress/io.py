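"""Trial recording bundles, event timelines, channel normalization and analysis windows.

A trial is stored on disk as a signals file (``<trial>.tsv``, delimited text with a
header row of channel labels, samples down the rows; or ``<trial>.bin``, flat
float64 binary with the shape recorded in the metadata) plus a JSON sidecar
``<trial>.meta.json`` carrying the sampling rate, the event markers, the outcome
label and an optional list of channels to exclude (artifact / noise-dominated
channels identified during preprocessing).

Trial phases are delimited by event markers: W1 runs from after-discharge onset
(``AD_Start``) to question onset (``Qes_Start``); W2 runs from question onset to
after-discharge end (``AD_End``).  Optional intermediate markers (``Qes_End``,
``Ans_Start``, ``Ans_End``) restart the analysis windowing wherever they fall.

Conventions: 0-based sample indices, half-open ``[start, end)`` intervals,
marker times in seconds converted to samples by rounding to nearest sample.
Signals are stored samples x channels (long axis first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError

MANDATORY_MARKERS = ("AD_Start", "Qes_Start", "AD_End")
KNOWN_MARKERS = ("AD_Start", "Qes_Start", "Qes_End", "Ans_Start", "Ans_End", "AD_End")

#: analysis window length in seconds (500 ms)
WINDOW_S = 0.5

Outcome = Literal["success", "failure", "unknown"]


@dataclass
class Recording:
    """One trial's multichannel signals plus identifying metadata.

    ``signals`` is a samples x channels float matrix; after :func:`zscore_channels`
    each column has zero mean and unit variance.
    """

    signals: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    patient_id: str = ""
    trial_id: str = ""
    outcome: Outcome = "unknown"

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def validate(self) -> "Recording":
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2:
            raise ValidationError("signals must be a 2-D samples x channels matrix")
        if not np.all(np.isfinite(sig)):
            bad = np.where(~np.isfinite(sig).all(axis=0))[0]
            names = [self.channel_labels[i] for i in bad[:5]]
            raise ValidationError(f"non-finite samples in channel(s) {names}")
        if self.fs_hz <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs_hz}")
        if len(self.channel_labels) != sig.shape[1]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {sig.shape[1]} signal columns"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels are not unique")
        return self


@dataclass
class EventTimeline:
    """Ordered event markers, each a ``(name, time_s)`` pair."""

    markers: list[tuple[str, float]]

    def time_of(self, name: str) -> float:
        for m, t in self.markers:
            if m == name:
                return t
        raise KeyError(name)

    def validate(self, duration_s: float | None = None) -> "EventTimeline":
        names = [m for m, _ in self.markers]
        for m in names:
            if m not in KNOWN_MARKERS:
                raise ValidationError(f"unknown event marker {m!r}")
        for m in MANDATORY_MARKERS:
            if m not in names:
                raise ValidationError(f"mandatory event marker {m!r} missing")
        times = [t for _, t in self.markers]
        for (m0, t0), (m1, t1) in zip(self.markers, self.markers[1:]):
            if not t1 > t0:
                raise ValidationError(
                    f"event times not strictly increasing at marker {m1!r} "
                    f"({m0!r}@{t0} -> {m1!r}@{t1})"
                )
        if duration_s is not None:
            if times[0] < 0 or times[-1] > duration_s + 1e-9:
                raise ValidationError(
                    f"event times [{times[0]}, {times[-1]}] outside recording span "
                    f"[0, {duration_s}]"
                )
        return self


@dataclass(frozen=True)
class TrialSegments:
    """Half-open sample intervals for the two trial phases (w1.end == w2.start)."""

    w1: tuple[int, int]
    w2: tuple[int, int]


@dataclass
class WindowGrid:
    """Fixed-length analysis windows laid within the marker-delimited spans."""

    windows: list[tuple[int, int]]
    mode: Literal["nonoverlap", "overlap50"]
    window_s: float = WINDOW_S

    def __len__(self) -> int:
        return len(self.windows)


def _to_sample(time_s: float, fs_hz: float) -> int:
    return int(round(time_s * fs_hz))


def segments(timeline: EventTimeline, fs_hz: float) -> TrialSegments:
    """Sample intervals of W1 = [AD_Start, Qes_Start) and W2 = [Qes_Start, AD_End)."""
    a = _to_sample(timeline.time_of("AD_Start"), fs_hz)
    q = _to_sample(timeline.time_of("Qes_Start"), fs_hz)
    e = _to_sample(timeline.time_of("AD_End"), fs_hz)
    if not a < q < e:
        raise ValidationError(f"degenerate trial segments (samples {a}, {q}, {e})")
    return TrialSegments(w1=(a, q), w2=(q, e))


def make_windows(
    rec: Recording,
    timeline: EventTimeline,
    segment: Literal["W1", "W2"],
    mode: Literal["nonoverlap", "overlap50"] = "nonoverlap",
) -> WindowGrid:
    """Lay 500 ms windows within each inter-marker span of a trial phase.

    Any marker falling strictly inside the phase restarts the windowing at its
    sample (experimental timing markers interrupt the grid).  Trailing partial
    windows shorter than the window length are dropped; a span shorter than one
    window simply contributes no windows.
    """
    seg = segments(timeline, rec.fs_hz)
    lo, hi = seg.w1 if segment == "W1" else seg.w2
    wlen = int(round(WINDOW_S * rec.fs_hz))
    step = wlen if mode == "nonoverlap" else wlen // 2
    if mode not in ("nonoverlap", "overlap50"):
        raise ValueError(f"unknown windowing mode {mode!r}")

    cuts = sorted(
        {lo, hi}
        | {
            _to_sample(t, rec.fs_hz)
            for _, t in timeline.markers
            if lo < _to_sample(t, rec.fs_hz) < hi
        }
    )
    windows: list[tuple[int, int]] = []
    for a, b in zip(cuts, cuts[1:]):
        start = a
        while start + wlen <= b:
            windows.append((start, start + wlen))
            start += step
    return WindowGrid(windows=windows, mode=mode)


def zscore_channels(rec: Recording) -> Recording:
    """Z-score each channel over the full trial (per-trial normalization)."""
    sig = np.asarray(rec.signals, dtype=float)
    sd = sig.std(axis=0, ddof=0)
    # max == min is an exact constancy test; a constant column's floating-point
    # std can come out as a tiny nonzero value and slip past an sd == 0 check
    zero = np.where((sd == 0) | (sig.max(axis=0) == sig.min(axis=0)))[0]
    if zero.size:
        names = [rec.channel_labels[i] for i in zero]
        raise ValidationError(f"zero-variance channel(s) cannot be z-scored: {names}")
    out = (sig - sig.mean(axis=0)) / sd
    return replace(rec, signals=out)


# ---------------------------------------------------------------------------
# bundle serialization


def write_bundle(
    rec: Recording,
    timeline: EventTimeline,
    out_dir: str | Path,
    *,
    binary: bool = False,
    exclude_channels: Sequence[str] = (),
    fmt: str = "%.6f",
) -> tuple[Path, Path]:
    """Write a trial bundle (signals file + JSON sidecar); returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = rec.trial_id or "trial"
    meta_path = out_dir / f"{stem}.meta.json"
    meta = {
        "fs_hz": rec.fs_hz,
        "patient_id": rec.patient_id,
        "trial_id": rec.trial_id,
        "outcome": rec.outcome,
        "channel_labels": rec.channel_labels,
        "events": [[m, t] for m, t in timeline.markers],
        "exclude_channels": list(exclude_channels),
        "orientation": "samples_x_channels",
    }
    if binary:
        sig_path = out_dir / f"{stem}.bin"
        np.asarray(rec.signals, dtype="<f8").tofile(sig_path)
        meta["shape"] = list(rec.signals.shape)
        meta["dtype"] = "<f8"
    else:
        sig_path = out_dir / f"{stem}.tsv"
        header = "\t".join(rec.channel_labels)
        np.savetxt(sig_path, rec.signals, fmt=fmt, delimiter="\t",
                   header=header, comments="")
    meta_path.write_text(json.dumps(meta, indent=1))
    return sig_path, meta_path


def read_bundle(
    signals_path: str | Path, meta_path: str | Path | None = None
) -> tuple[Recording, EventTimeline]:
    """Read and validate a trial bundle; excluded channels are dropped."""
    signals_path = Path(signals_path)
    if meta_path is None:
        meta_path = signals_path.with_suffix("").with_suffix(".meta.json")
        if not Path(meta_path).exists():  # <stem>.tsv -> <stem>.meta.json
            meta_path = signals_path.parent / (signals_path.stem + ".meta.json")
    meta = json.loads(Path(meta_path).read_text())

    labels = list(meta["channel_labels"])
    if signals_path.suffix == ".bin":
        shape = tuple(meta["shape"])
        sig = np.fromfile(signals_path, dtype=meta.get("dtype", "<f8")).reshape(shape)
    else:
        sig = np.loadtxt(signals_path, delimiter="\t", skiprows=1, ndmin=2)

    if np.isnan(sig).any():
        raise ValidationError(f"NaN cells in signals file {signals_path.name}")

    exclude = set(meta.get("exclude_channels", ()))
    unknown = exclude - set(labels)
    if unknown:
        raise ValidationError(f"exclude_channels not present in bundle: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(labels) if lab not in exclude]
    rec = Recording(
        signals=sig[:, keep],
        fs_hz=float(meta["fs_hz"]),
        channel_labels=[labels[i] for i in keep],
        patient_id=str(meta.get("patient_id", "")),
        trial_id=str(meta.get("trial_id", "")),
        outcome=meta.get("outcome", "unknown"),
    ).validate()
    timeline = EventTimeline(
        markers=[(m, float(t)) for m, t in meta["events"]]
    ).validate(rec.duration_s)
    return rec, timeline


def validate_bundle_dir(bundle_dir: str | Path) -> list[str]:
    """Validate every bundle in a directory; returns the list of trial stems.

    Raises :class:`ValidationError` naming the first offending file.
    """
    bundle_dir = Path(bundle_dir)
    stems = []
    metas = sorted(bundle_dir.glob("*.meta.json"))
    if not metas:
        raise ValidationError(f"no *.meta.json bundles found in {bundle_dir}")
    for meta_path in metas:
        stem = meta_path.name[: -len(".meta.json")]
        sig_path = None
        for ext in (".tsv", ".bin"):
            cand = bundle_dir / f"{stem}{ext}"
            if cand.exists():
                sig_path = cand
                break
        if sig_path is None:
            raise ValidationError(f"no signals file for bundle {meta_path.name}")
        try:
            read_bundle(sig_path, meta_path)
        except ValidationError as err:
            raise ValidationError(f"{sig_path.name}: {err}") from err
        stems.append(stem)
    return stems
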