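"""End-to-end orchestration: windows -> fractal -> network -> stats -> LOOCV.

The pipeline runs per trial (validate, z-score, lay windows, scaling scans,
network fits), then pools exponents by phase and outcome class, tests W1
against W2, builds trial feature vectors and evaluates leave-one-trial-out
classification.  A run directory archives the configuration verbatim next to
the outputs; identical seed and configuration reproduce identical metrics.

The 50%-overlap window grid contains the non-overlapping grid as a subset
(every other window start), so the scaling scan is computed once on the
overlapped grid and the non-overlapping track is obtained by column selection.
Pooled W1-vs-W2 statistics are reported for both windowing schemes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as rio
from .classify import CVReport, extract_features, feature_names, loocv_logistic
from .errors import AdsuppressError
from .fodn import FodnConfig, FodnTrack, windowed_fodn
from .fractal import HurstTrack, MFDFATrack, ScalingConfig, windowed_scan
from .stats import KSResult, channelwise_ks, ks_two_sample, pool_exponents

__all__ = ["RunConfig", "TrialAnalysis", "CohortReport", "analyze_trial",
           "analyze_cohort", "run_pipeline", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Named deterministic substream seed derived from one root seed (< 2^31)."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything a run depends on; archived verbatim alongside outputs."""

    window_mode: str = "nonoverlap"        # grid used for features / network fits
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    fodn: FodnConfig = field(default_factory=FodnConfig)
    feature_mode: str = "delta_w2_minus_w1"
    include_width: bool = False
    seed: int = 0
    make_figures: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrialAnalysis:
    """All per-trial outputs of the analysis stages."""

    trial_id: str
    outcome: str
    hurst: dict[str, HurstTrack]           # per phase, overlap50 grid
    hurst_nonoverlap: dict[str, HurstTrack]
    mfdfa: dict[str, MFDFATrack]
    fodn: dict[str, FodnTrack]
    features: np.ndarray
    channel_ks: list[KSResult] = field(default_factory=list)


@dataclass
class CohortReport:
    trials: list[TrialAnalysis]
    pooled_ks: dict[str, dict]             # "<outcome>/<mode>" -> stats
    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    cv: CVReport | None
    config: RunConfig
    timings_s: dict[str, float] = field(default_factory=dict)


def _subset_nonoverlap(track: HurstTrack, grid_non: rio.WindowGrid) -> HurstTrack:
    index = {w: i for i, w in enumerate(track.windows)}
    cols = [index[w] for w in grid_non.windows if w in index]
    return HurstTrack(
        h=track.h[:, cols],
        r2=track.r2[:, cols],
        missing=track.missing[:, cols],
        windows=[track.windows[i] for i in cols],
    )


def analyze_trial(
    rec: rio.Recording,
    timeline: rio.EventTimeline,
    config: RunConfig = RunConfig(),
    *,
    features_only: bool = False,
) -> TrialAnalysis:
    """Run the per-trial stages on one validated recording.

    With ``features_only`` the scan covers just the feature grid and the
    per-channel KS stage is skipped; the descriptor vector (and hence any
    downstream classification) is identical to a full run, only the
    diagnostic tracks on the other grid are absent.
    """
    rec = rio.zscore_channels(rec.validate())
    timeline.validate(rec.duration_s)
    hurst, hurst_non, mfdfa, fodn = {}, {}, {}, {}
    for phase in ("W1", "W2"):
        grid_non = rio.make_windows(rec, timeline, phase, "nonoverlap")
        grid_feat = grid_non if config.window_mode == "nonoverlap" else \
            rio.make_windows(rec, timeline, phase, "overlap50")
        if features_only:
            htr, mtr = windowed_scan(rec, grid_feat, config.scaling)
            hurst[phase] = hurst_non[phase] = htr if grid_feat is grid_non \
                else _subset_nonoverlap(htr, grid_non)
            mfdfa[phase] = mtr
        else:
            grid_ov = rio.make_windows(rec, timeline, phase, "overlap50")
            htr, mtr = windowed_scan(rec, grid_ov, config.scaling)
            hurst[phase] = htr
            hurst_non[phase] = _subset_nonoverlap(htr, grid_non)
            # MFDFA features read from the same grid convention as the network fits
            if config.window_mode == "nonoverlap":
                cols = [i for i, w in enumerate(htr.windows)
                        if w in set(grid_non.windows)]
                mfdfa[phase] = MFDFATrack(
                    hq=mtr.hq[:, cols], q_grid=mtr.q_grid,
                    missing=mtr.missing[:, cols],
                    windows=[mtr.windows[i] for i in cols],
                )
            else:
                mfdfa[phase] = mtr
        fodn[phase] = windowed_fodn(rec, grid_feat, config.fodn)
    features = extract_features(fodn, mfdfa, config.feature_mode,
                                include_width=config.include_width)
    channel_ks = [] if features_only else \
        channelwise_ks(hurst_non["W1"], hurst_non["W2"])
    return TrialAnalysis(
        trial_id=rec.trial_id,
        outcome=rec.outcome,
        hurst=hurst,
        hurst_nonoverlap=hurst_non,
        mfdfa=mfdfa,
        fodn=fodn,
        features=features,
        channel_ks=channel_ks,
    )


def _pooled_stats(trials: list[TrialAnalysis]) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for outcome in ("success", "failure"):
        if not any(t.outcome == outcome for t in trials):
            continue
        for mode, attr in (("nonoverlap", "hurst_nonoverlap"), ("overlap50", "hurst")):
            items = [(t.outcome, getattr(t, attr)) for t in trials]
            p1 = pool_exponents(items, "W1", outcome)
            p2 = pool_exponents(items, "W2", outcome)
            ks = ks_two_sample(p1.values, p2.values)
            out[f"{outcome}/{mode}"] = {
                "D": ks.D, "p": ks.p, "n_w1": ks.n1, "n_w2": ks.n2,
                "w1_mean": float(np.mean(p1.values)),
                "w2_mean": float(np.mean(p2.values)),
                "w1_var": float(np.var(p1.values)),
                "w2_var": float(np.var(p2.values)),
            }
    return out


def analyze_cohort(
    trials: Sequence[tuple[rio.Recording, rio.EventTimeline]],
    config: RunConfig = RunConfig(),
    *,
    run_cv: bool = True,
    features_only: bool = False,
    log: list | None = None,
) -> CohortReport:
    """Run the full pipeline on an in-memory cohort.

    ``trials`` may also hold :class:`~adsuppress.synthetic.Trial` objects.
    ``features_only`` forwards to :func:`analyze_trial` and also skips the
    pooled group statistics; classification output is unchanged.
    """
    analyses: list[TrialAnalysis] = []
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    for item in trials:
        if hasattr(item, "recording"):  # synthetic.Trial
            rec, timeline = item.recording, item.timeline
        else:
            rec, timeline = item
        t1 = time.perf_counter()
        try:
            analyses.append(
                analyze_trial(rec, timeline, config, features_only=features_only)
            )
        except AdsuppressError as err:
            raise AdsuppressError(
                f"stage 'analyze_trial' failed on trial {rec.trial_id!r}: {err}"
            ) from err
        if log is not None:
            n_missing = sum(tr.n_missing for tr in analyses[-1].hurst.values())
            log.append({
                "stage": "trial", "trial_id": rec.trial_id,
                "elapsed_s": round(time.perf_counter() - t1, 4),
                "flagged_windows": int(n_missing),
            })
    timings["trials"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    pooled = {} if features_only else _pooled_stats(analyses)
    timings["group_stats"] = time.perf_counter() - t1

    X = np.vstack([a.features for a in analyses])
    y = np.asarray([a.outcome for a in analyses])
    cv = None
    if run_cv:
        t1 = time.perf_counter()
        counts = [np.sum(y == c) for c in ("success", "failure")]
        if min(counts) >= 2:
            cv = loocv_logistic(X, y, seed=substream_seed(config.seed, "loocv"))
        timings["loocv"] = time.perf_counter() - t1
    return CohortReport(
        trials=analyses,
        pooled_ks=pooled,
        features=X,
        labels=y,
        feature_names=feature_names(config.feature_mode, config.include_width),
        cv=cv,
        config=config,
        timings_s=timings,
    )


# ---------------------------------------------------------------------------
# disk-oriented run


def report_metrics(report: CohortReport) -> dict:
    """JSON-serializable metrics summary of a cohort run."""
    out: dict = {
        "n_trials": len(report.trials),
        "pooled_ks": report.pooled_ks,
    }
    if report.cv is not None:
        cv = report.cv
        out["loocv"] = {
            "accuracy": cv.accuracy,
            "n_correct": cv.n_correct,
            "auc": cv.auc,
            "confusion": cv.confusion,
            "precision": cv.precision,
            "recall": cv.recall,
            "folds": [
                {
                    "trial_id": t.trial_id,
                    "truth": int(yt),
                    "pred": int(yp),
                    "p_success": round(float(pp), 6),
                }
                for t, yt, yp, pp in zip(
                    report.trials, cv.y_true, cv.y_pred, cv.proba
                )
            ],
        }
    return out


def _write_tables(report: CohortReport, out_dir: Path) -> None:
    import pandas as pd

    rows = []
    for t in report.trials:
        for mode, attr in (("nonoverlap", "hurst_nonoverlap"), ("overlap50", "hurst")):
            for phase in ("W1", "W2"):
                cm = getattr(t, attr)[phase].channel_mean
                for c, v in enumerate(cm):
                    rows.append({
                        "trial": t.trial_id, "outcome": t.outcome, "mode": mode,
                        "phase": phase, "channel": c, "H_mean": v,
                    })
    pd.DataFrame(rows).to_csv(out_dir / "hurst_pooled.tsv", sep="\t", index=False)

    feats = pd.DataFrame(report.features, columns=report.feature_names)
    feats.insert(0, "trial", [t.trial_id for t in report.trials])
    feats.insert(1, "outcome", report.labels)
    feats.to_csv(out_dir / "features.tsv", sep="\t", index=False)

    ks_rows = []
    for t in report.trials:
        for r in t.channel_ks:
            ks_rows.append({
                "trial": t.trial_id, "channel": r.channel, "D": r.D, "p_raw": r.p,
                "n_w1": r.n1, "n_w2": r.n2, "flagged": r.flagged,
            })
    pd.DataFrame(ks_rows).to_csv(out_dir / "channelwise_ks.tsv", sep="\t", index=False)


def _write_figures(report: CohortReport, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, outcome in zip(axes, ("success", "failure")):
        for phase, color in (("W1", "C0"), ("W2", "C1")):
            vals = np.concatenate([
                t.hurst_nonoverlap[phase].channel_mean
                for t in report.trials if t.outcome == outcome
            ]) if any(t.outcome == outcome for t in report.trials) else np.array([])
            vals = vals[np.isfinite(vals)]
            if vals.size:
                ax.hist(vals, bins=30, alpha=0.5, color=color, label=phase, density=True)
        ax.set_title(f"{outcome} trials")
        ax.set_xlabel("channel time-averaged H")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "hurst_distributions.png", dpi=120)
    plt.close(fig)

    if report.cv is not None:
        fpr, tpr = report.cv.roc
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fpr, tpr, "-o", ms=3)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"LOOCV ROC (AUC = {report.cv.auc:.2f})")
        fig.tight_layout()
        fig.savefig(out_dir / "roc.png", dpi=120)
        plt.close(fig)

    if report.trials:
        t = report.trials[0]
        fig, ax = plt.subplots(figsize=(6, 4))
        track = np.hstack([t.fodn["W1"].weights, t.fodn["W2"].weights])
        im = ax.imshow(track, aspect="auto", interpolation="nearest")
        ax.axvline(t.fodn["W1"].weights.shape[1] - 0.5, color="w", lw=1)
        ax.set_xlabel("time window")
        ax.set_ylabel("channel")
        ax.set_title(f"dominant-mode weights, trial {t.trial_id}")
        fig.colorbar(im, ax=ax, label="|weight|")
        fig.tight_layout()
        fig.savefig(out_dir / "eigvec_heatmap.png", dpi=120)
        plt.close(fig)


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    *,
    input_dir: str | Path | None = None,
    trials: Sequence | None = None,
) -> Path:
    """Execute the full pipeline and write tables, metrics and logs.

    Inputs come either from a bundle directory (``input_dir``) or an in-memory
    trial sequence.  Returns the run directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    if trials is None:
        if input_dir is None:
            raise AdsuppressError("run_pipeline needs input_dir or trials")
        stems = rio.validate_bundle_dir(input_dir)
        loaded = []
        for stem in stems:
            base = Path(input_dir) / stem
            sig = base.with_suffix(".tsv")
            if not sig.exists():
                sig = base.with_suffix(".bin")
            loaded.append(rio.read_bundle(sig, Path(input_dir) / f"{stem}.meta.json"))
        trials = loaded

    report = analyze_cohort(trials, config, log=log)
    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True)
    )
    (out_dir / "metrics.json").write_text(
        json.dumps(report_metrics(report), indent=1, sort_keys=True)
    )
    _write_tables(report, out_dir)
    if config.make_figures:
        _write_figures(report, out_dir)
    with (out_dir / "log.jsonl").open("w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        fh.write(json.dumps(
            {"stage": "done", **{k: round(v, 3) for k, v in report.timings_s.items()}},
            sort_keys=True) + "\n")
    return out_dir
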