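"""Ensemble trace, post-stimulus epochs, ensemble fraction, pattern type.

Per-ROI activity is thresholded at the 4 SD event level, scaled to the
ROI's session maximum (so values live in [0, 1] and sub-threshold noise
contributes nothing), and averaged across ROIs into a single ensemble
trace: the instantaneous fraction-weighted activity of the ensemble.
Averaged inter-stimulus sweeps of this trace show up to three epochs —
a first maximum (< 1 s), an ensemble minimum (1-3 s) and a second maximum
(< 5 s) — which classify a slice as Type A, B or C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .alignment import SweepSet
from .config import AnalysisConfig
from .events import Baseline, CalciumEvent


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # (n_roi, T) in [0, 1]
    session_max: np.ndarray  # per-ROI scaling maximum (0 when never active)


@dataclass(frozen=True)
class EpochSet:
    """Per-session epoch latencies on the stimulus-relative axis."""

    t1_s: float | None
    t2_s: float | None
    t3_s: float | None
    amp1: float | None
    amp2: float | None
    amp3: float | None

    @property
    def present(self) -> dict[str, bool]:
        return {
            "epoch1": self.t1_s is not None,
            "epoch2": self.t2_s is not None,
            "epoch3": self.t3_s is not None,
        }


def threshold_normalize(
    traces: np.ndarray, baselines: list[Baseline]
) -> NormalizedMatrix:
    """Zero everything below each ROI's 4 SD event threshold, then divide by
    that ROI's session maximum; ROIs that never cross threshold stay all-zero.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] != len(baselines):
        raise ValueError("one baseline per ROI required")
    out = np.zeros_like(traces)
    maxima = np.zeros(traces.shape[0])
    for i, b in enumerate(baselines):
        row = np.where(traces[i] >= b.thr_event, traces[i], 0.0)
        m = row.max()
        maxima[i] = m
        if m > 0:
            out[i] = row / m
    return NormalizedMatrix(values=out, session_max=maxima)


def compute_ensemble_trace(matrix: NormalizedMatrix | np.ndarray) -> np.ndarray:
    """Across-ROI mean of normalized activity: the active fraction-weighted
    ensemble signal through time, in [0, 1]."""
    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else np.asarray(matrix)
    if vals.shape[0] < 1:
        raise ValueError("need at least one ROI")
    return vals.mean(axis=0)


def average_sweeps(sweepset: SweepSet | np.ndarray) -> np.ndarray:
    """Pointwise mean of the inter-stimulus sweeps."""
    sweeps = sweepset.sweeps if isinstance(sweepset, SweepSet) else np.asarray(sweepset)
    if sweeps.ndim != 2 or sweeps.shape[0] < 1:
        raise ValueError("sweeps must be a non-empty 2-D (n_sweeps, n_samples) array")
    return sweeps.mean(axis=0)


def _smooth(x: np.ndarray, rate_hz: float, smooth_s: float) -> np.ndarray:
    w = max(1, int(round(smooth_s * rate_hz)))
    return uniform_filter1d(x, size=w, mode="nearest")


def detect_epochs(
    avg_sweep: np.ndarray,
    rate_hz: float = 2000.0,
    config: AnalysisConfig | None = None,
) -> EpochSet:
    """Locate the three post-stimulus epochs on an averaged ensemble sweep.

    The sweep is smoothed (50 ms default) before extremum search.  Epoch 1
    is the most prominent local maximum within the first second; epoch 2
    the minimum of the 1-3 s range (starting no earlier than epoch 1);
    epoch 3 the most prominent local maximum after the minimum and within
    5 s.  Maxima must clear a prominence floor (a fraction of the sweep's
    dynamic range); ties break to the earliest candidate.  Absent epochs
    are reported as ``None``, never as zero times.
    """
    cfg = config or AnalysisConfig()
    x = np.asarray(avg_sweep, dtype=float)
    t = (np.arange(x.size) + 0.5) / rate_hz
    xs = _smooth(x, rate_hz, cfg.epoch_smooth_s)
    dyn = float(np.ptp(xs))
    if dyn == 0:
        return EpochSet(None, None, None, None, None, None)
    p_min = cfg.epoch_prominence_frac * dyn

    def best_peak(lo_s: float, hi_s: float) -> tuple[float, float] | None:
        sel = (t > lo_s) & (t <= hi_s)
        if not sel.any():
            return None
        idx = np.flatnonzero(sel)
        seg = xs[idx[0] : idx[-1] + 1]
        peaks, props = signal.find_peaks(seg, prominence=p_min)
        # an interior monotone maximum at the segment edge is not a peak;
        # also admit the segment endpoint when it dominates (plateau edge)
        if peaks.size == 0:
            return None
        order = np.lexsort((peaks, -props["prominences"]))
        k = peaks[order[0]]
        return float(t[idx[0] + k]), float(xs[idx[0] + k])

    e1 = best_peak(0.0, cfg.epoch1_limit_s)
    t1, a1 = e1 if e1 else (None, None)

    lo2 = max(t1 if t1 is not None else 0.0, cfg.epoch2_range_s[0])
    hi2 = cfg.epoch2_range_s[1]
    sel2 = (t >= lo2) & (t <= hi2)
    t2 = a2 = None
    if sel2.any():
        idx2 = np.flatnonzero(sel2)
        seg2 = xs[idx2]
        k2 = int(np.argmin(seg2))
        t2, a2 = float(t[idx2[k2]]), float(seg2[k2])

    t3 = a3 = None
    if t2 is not None:
        e3 = best_peak(t2, cfg.epoch3_limit_s)
        if e3:
            t3, a3 = e3
    return EpochSet(t1, t2, t3, a1, a2, a3)


def roi_active_in_window(
    events: list[CalciumEvent], window: tuple[float, float]
) -> bool:
    """True when any event interval [start, end] intersects the window."""
    lo, hi = window
    return any(e.start_s <= hi and e.end_s >= lo for e in events)


def ensemble_fraction(
    events_per_roi: list[list[CalciumEvent]],
    epoch_time_s: float | None,
    window_s: float = 0.010,
) -> float | None:
    """Fraction of ROIs with a transient overlapping the +-window/2 interval
    around the epoch time.  Absent epoch -> missing value (None)."""
    if epoch_time_s is None:
        return None
    half = window_s / 2.0
    win = (epoch_time_s - half, epoch_time_s + half)
    n = len(events_per_roi)
    if n == 0:
        raise ValueError("need at least one ROI")
    return sum(roi_active_in_window(ev, win) for ev in events_per_roi) / n


def per_stimulus_fractions(
    events_per_roi: list[list[CalciumEvent]],
    stimulus_onsets_s: np.ndarray,
    epochs: EpochSet,
    window_s: float = 0.010,
) -> dict[str, list[float | None]]:
    """Ensemble fraction per stimulus x epoch, applying the session-level
    epoch latency at each stimulus onset."""
    out: dict[str, list[float | None]] = {}
    for name, lat in (("epoch1", epochs.t1_s), ("epoch2", epochs.t2_s), ("epoch3", epochs.t3_s)):
        if lat is None:
            out[name] = [None] * len(stimulus_onsets_s)
        else:
            out[name] = [
                ensemble_fraction(events_per_roi, float(s) + lat, window_s)
                for s in stimulus_onsets_s
            ]
    return out


def classify_pattern(epochs: EpochSet) -> str:
    """Session pattern type from the highest-intensity session's epochs.

    A: first maximum (dominant) plus minimum; B: second maximum plus
    minimum without a dominant first maximum; C: minimum only; 'none'
    otherwise.
    """
    has1, has2, has3 = (
        epochs.t1_s is not None,
        epochs.t2_s is not None,
        epochs.t3_s is not None,
    )
    if not has2:
        return "none"
    a1 = epochs.amp1 if epochs.amp1 is not None else 0.0
    a3 = epochs.amp3 if epochs.amp3 is not None else 0.0
    if has1 and a1 >= a3:
        return "A"
    if has3 and (not has1 or a3 > a1):
        return "B"
    if not has1 and not has3:
        return "C"
    return "none"
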