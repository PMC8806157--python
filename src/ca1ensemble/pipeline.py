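"""End-to-end per-session analysis and cohort summaries.

``run_session`` composes the stages: detrend -> baseline -> event
detection -> activity filter -> LFP measures -> 2 kHz alignment ->
threshold normalisation -> ensemble trace -> sweeps -> epochs -> ensemble
fractions -> Hamming distances -> shuffle null.  Sessions with fewer than
the minimum number of active ROIs are marked invalid and the ensemble
stages are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import alignment, ensemble, events, lfp, similarity
from .config import AnalysisConfig
from .io import RoiTraceSet, SessionBundle

log = logging.getLogger("ca1ensemble")


@dataclass
class SessionResult:
    session_id: str
    group: str
    valid: bool
    exclusion_reasons: list[str]
    n_active_rois: int
    features: list[events.EventFeatures]
    events_per_roi: list[list[events.CalciumEvent]]
    epochs: ensemble.EpochSet | None = None
    pattern: str | None = None
    fractions: dict[str, list[float | None]] = field(default_factory=dict)
    distances: dict[str, float] = field(default_factory=dict)
    null: similarity.ShuffleNull | None = None
    fepsp: list[lfp.FepspMeasure] = field(default_factory=list)
    pairwise_corr: float | None = None
    n_sweeps: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)

    def event_table(self) -> pd.DataFrame:
        rows = []
        for i, evs in enumerate(self.events_per_roi):
            for e in evs:
                rows.append(
                    {
                        "session_id": self.session_id,
                        "roi_id": self.features[i].roi_id,
                        "start_s": e.start_s,
                        "peak_s": e.peak_s,
                        "end_s": e.end_s,
                        "amplitude": e.amplitude,
                        "duration_s": e.duration_s,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "session_id", "roi_id", "start_s", "peak_s", "end_s",
                "amplitude", "duration_s",
            ],
        )

    def feature_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"session_id": self.session_id, "group": self.group, **f.__dict__}
                for f in self.features
            ]
        )


def run_session(
    bundle: SessionBundle,
    config: AnalysisConfig | None = None,
    run_null: bool = True,
    n_shuffles: int | None = None,
    redetect_epochs: bool = False,
) -> SessionResult:
    """Run the full analysis on one session bundle."""
    cfg = config or AnalysisConfig()
    tr = bundle.roi_traces
    sid = str(bundle.metadata.get("session_id", "session"))
    group = str(bundle.metadata.get("group", ""))
    log.info("session %s: %d ROIs x %d frames", sid, tr.n_rois, tr.n_frames)

    # 1. detrend + baseline + events, per ROI, at the native frame rate
    detrended = np.empty_like(tr.dff)
    baselines: list[events.Baseline] = []
    events_per_roi: list[list[events.CalciumEvent]] = []
    features: list[events.EventFeatures] = []
    for i in range(tr.n_rois):
        detrended[i] = events.detrend(tr.dff[i], cfg.detrend_span_frames)
        b = events.fit_baseline(
            detrended[i],
            event_peak_sd=cfg.event_peak_sd,
            event_bound_sd=cfg.event_bound_sd,
        )
        baselines.append(b)
        evs = events.detect_events(detrended[i], b, cfg.frame_rate_hz)
        events_per_roi.append(evs)
        features.append(events.summarize_events(evs, tr.duration_s, tr.roi_ids[i]))

    n_active = sum(f.active for f in features)
    valid = events.session_activity_filter(features, cfg)
    reasons = [] if valid else [f"active_rois<{cfg.min_active_rois}"]

    # 2. LFP: stimulus detection check + fEPSP measures
    noise_sd = float(
        1.4826 * np.median(np.abs(bundle.lfp.samples - np.median(bundle.lfp.samples)))
    )
    thr = max(8.0 * noise_sd, 1e-6)
    stim_events = lfp.detect_stimuli(
        bundle.lfp, thr, expected_count=bundle.stimulus_onsets_s.size or None
    )
    fepsp_measures = []
    for i, s in enumerate(stim_events):
        try:
            fepsp_measures.append(lfp.measure_fepsp(bundle.lfp, s, stimulus_index=i))
        except ValueError:
            log.warning("session %s: fEPSP window past end for stimulus %d", sid, i)

    result = SessionResult(
        session_id=sid,
        group=group,
        valid=valid,
        exclusion_reasons=reasons,
        n_active_rois=n_active,
        features=features,
        events_per_roi=events_per_roi,
        fepsp=fepsp_measures,
        metadata=dict(bundle.metadata),
    )
    corr, _ = (
        similarity.pairwise_correlation(detrended) if tr.n_rois >= 2 else (None, 0)
    )
    result.pairwise_corr = corr
    if not valid:
        log.info("session %s invalid (%d active ROIs); ensemble stages skipped", sid, n_active)
        return result

    # 3. alignment and ensemble stages
    offset = float(bundle.metadata.get("alignment_offset_s", 0.0))
    aligned = alignment.align_session(
        RoiTraceSet(detrended, tr.frame_rate_hz, tr.roi_ids),
        bundle.lfp,
        bundle.stimulus_onsets_s,
        cfg.aligned_rate_hz,
        offset_s=offset,
    )
    norm = ensemble.threshold_normalize(aligned.calcium, baselines)
    ens_trace = ensemble.compute_ensemble_trace(norm)
    sweeps = alignment.bin_sweeps(
        ens_trace, aligned.stimulus_onsets_s, cfg.sweep_period_s, cfg.aligned_rate_hz
    )
    result.n_sweeps = sweeps.n_sweeps
    avg = ensemble.average_sweeps(sweeps)
    epochs = ensemble.detect_epochs(avg, cfg.aligned_rate_hz, cfg)
    result.epochs = epochs
    result.pattern = ensemble.classify_pattern(epochs)
    result.fractions = ensemble.per_stimulus_fractions(
        events_per_roi, aligned.stimulus_onsets_s, epochs, cfg.epoch_window_s
    )

    half = cfg.epoch_window_s / 2
    for name, lat in (
        ("epoch1", epochs.t1_s), ("epoch2", epochs.t2_s), ("epoch3", epochs.t3_s)
    ):
        if lat is None:
            continue
        pats = [
            similarity.active_pattern(
                [], (s + lat - half, s + lat + half), per_roi=events_per_roi
            )
            for s in aligned.stimulus_onsets_s
        ]
        if len(pats) >= 2:
            d, _ = similarity.epoch_distance(np.array(pats))
            result.distances[name] = d

    if run_null:
        result.null = similarity.build_null(
            events_per_roi,
            aligned.stimulus_onsets_s,
            epochs,
            duration_s=min(tr.duration_s, aligned.duration_s),
            config=cfg,
            matrix2k=norm.values if redetect_epochs else None,
            redetect_epochs=redetect_epochs,
            n_shuffles=n_shuffles,
            seed=cfg.rng_seed,
        )
    return result


def _tukey_quartiles(x: np.ndarray) -> tuple[float, float]:
    """Inclusive-median (Tukey hinge) quartiles."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half :]))


def flag_outliers(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier flags: outside [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use the inclusive-median method.  Fewer than 4 values give no
    flags (with a warning in the log).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        log.warning("flag_outliers: need >= 4 values, got %d; no flags", values.size)
        return np.zeros(values.size, dtype=bool)
    q1, q3 = _tukey_quartiles(values)
    iqr = q3 - q1
    return (values < q1 - multiplier * iqr) | (values > q3 + multiplier * iqr)


def summarize_cohort(
    results: list[SessionResult], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Tidy long-format cohort table: one row per session x metric, with
    per-group Tukey outlier flags.  Group means +- SEM are descriptive;
    inferential statistics are left to external tools.
    """
    if not results:
        raise ValueError("need >= 1 session result")
    cfg = config or AnalysisConfig()
    rows = []
    for r in results:
        feats = [f for f in r.features]
        mean_or_nan = lambda xs: float(np.mean(xs)) if xs else np.nan
        metrics = {
            "n_active_rois": float(r.n_active_rois),
            "events_per_roi": mean_or_nan([f.n_events for f in feats]),
            "mean_amplitude": mean_or_nan(
                [f.mean_amplitude for f in feats if f.mean_amplitude is not None]
            ),
            "mean_duration_s": mean_or_nan(
                [f.mean_duration_s for f in feats if f.mean_duration_s is not None]
            ),
            "mean_iei_s": mean_or_nan(
                [f.mean_iei_s for f in feats if f.mean_iei_s is not None]
            ),
            "pairwise_corr": r.pairwise_corr if r.pairwise_corr is not None else np.nan,
            "fepsp_peak_mV": mean_or_nan([m.peak_amplitude_mV for m in r.fepsp]),
        }
        for name, vals in r.fractions.items():
            good = [v for v in vals if v is not None]
            metrics[f"fraction_{name}"] = mean_or_nan(good)
        for name, d in r.distances.items():
            metrics[f"distance_{name}"] = d
        if r.null is not None:
            for name, arr in r.null.fractions.items():
                obs = r.null.observed_fractions.get(name)
                if obs is not None and np.isfinite(arr).any():
                    metrics[f"null_pct_{name}"] = similarity.percentile_of(
                        obs, arr[np.isfinite(arr)]
                    )
        for metric, value in metrics.items():
            rows.append(
                {
                    "session_id": r.session_id,
                    "group": r.group,
                    "valid": r.valid,
                    "pattern": r.pattern,
                    "metric": metric,
                    "value": value,
                }
            )
    df = pd.DataFrame(rows)
    df["outlier"] = False
    for (grp, metric), sub in df.groupby(["group", "metric"]):
        vals = sub["value"].to_numpy()
        finite = np.isfinite(vals)
        if finite.sum() >= 4:
            flags = np.zeros(len(sub), dtype=bool)
            flags[finite] = flag_outliers(vals[finite], cfg.outlier_iqr_mult)
            df.loc[sub.index, "outlier"] = flags
    return df


def group_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-group mean +- SEM per metric (SEM missing for n=1)."""
    def sem(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    return (
        cohort.groupby(["group", "metric"])["value"]
        .agg(n="count", mean="mean", sem=sem)
        .reset_index()
    )
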