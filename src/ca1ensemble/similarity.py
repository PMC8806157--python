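"""Pattern similarity and the circular-shift shuffle null.

Per-stimulus activity is reduced to a binary vector over ROIs (active in
the 10 ms epoch window or not); overlap across stimulations is the mean
normalized Hamming distance over stimulus pairs.  Hamming is used because,
unlike Jaccard or cosine similarity, it is well defined between two
all-zero patterns — the common case during the ensemble minimum.

The chance level of every epoch metric comes from a surrogate ensemble:
each ROI's time series is circularly rotated by an independent random
amount (preserving its autocorrelation and event content but destroying
stimulus locking), the metrics are recomputed, and the rotation is repeated
``n_shuffles`` times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .ensemble import EpochSet, detect_epochs
from .events import CalciumEvent


def hamming(p: np.ndarray, q: np.ndarray) -> float:
    """Normalized Hamming distance between two binary patterns.

    Defined for all inputs, including two zero vectors (distance 0).
    """
    p = np.asarray(p).astype(bool)
    q = np.asarray(q).astype(bool)
    if p.shape != q.shape:
        raise ValueError(f"pattern lengths differ: {p.shape} vs {q.shape}")
    return float(np.mean(p != q))


def active_pattern(
    event_intervals: list[tuple[float, float]] | list[CalciumEvent],
    window: tuple[float, float],
    per_roi: list[list] | None = None,
) -> np.ndarray:
    """Binary over-ROIs activity vector for one epoch window.

    ``per_roi`` is a list of per-ROI event (or interval) lists; an ROI is
    active when any of its event intervals intersects the window.
    """
    rois = per_roi if per_roi is not None else [event_intervals]
    lo, hi = window
    out = np.zeros(len(rois), dtype=bool)
    for i, evs in enumerate(rois):
        for e in evs:
            s, t = (e.start_s, e.end_s) if isinstance(e, CalciumEvent) else (e[0], e[1])
            if s <= hi and t >= lo:
                out[i] = True
                break
    return out


def epoch_distance(patterns: np.ndarray | list[np.ndarray]) -> tuple[float, int]:
    """Mean normalized Hamming distance over all unordered stimulus pairs.

    Returns ``(mean_distance, n_pairs)``.
    """
    mat = np.asarray(patterns, dtype=bool)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 patterns")
    k, n = mat.shape
    f = mat.astype(float)
    g = f @ f.T  # pairwise co-active counts
    ones = f.sum(axis=1)
    diff = ones[:, None] + ones[None, :] - 2 * g  # pairwise differing counts
    iu = np.triu_indices(k, 1)
    return float(diff[iu].mean() / n), len(iu[0])


def pairwise_correlation(matrix: np.ndarray) -> tuple[float | None, int]:
    """Mean Pearson correlation over all ROI pairs.

    Pairs involving a constant row have undefined correlation; they are
    skipped and counted.  Returns ``(mean_r, n_skipped_pairs)``; the mean is
    ``None`` when every pair is undefined.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    if m.shape[0] < 2:
        raise ValueError("need >= 2 ROIs")
    sd = m.std(axis=1)
    ok = sd > 0
    n = m.shape[0]
    n_pairs = n * (n - 1) // 2
    k = int(ok.sum())
    n_ok_pairs = k * (k - 1) // 2
    if n_ok_pairs == 0:
        return None, n_pairs
    c = np.corrcoef(m[ok])
    iu = np.triu_indices(k, 1)
    return float(c[iu].mean()), n_pairs - n_ok_pairs


def circular_shuffle(matrix: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Rotate each row independently by its shift (samples).

    Conserves each row's value multiset exactly.
    """
    matrix = np.atleast_2d(np.asarray(matrix))
    shifts = np.asarray(shifts, dtype=int)
    if shifts.size != matrix.shape[0]:
        raise ValueError("one shift per row required")
    out = np.empty_like(matrix)
    for i, s in enumerate(shifts):
        out[i] = np.roll(matrix[i], s)
    return out


def ensemble_time_average(matrix: np.ndarray) -> float:
    """Time average of the ensemble trace, via exactly rounded summation.

    ``math.fsum`` is order-independent, so this value is bit-identical
    before and after any circular shuffle of the rows.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    row_sums = [math.fsum(row.tolist()) for row in matrix]
    return math.fsum(row_sums) / matrix.size


# ---------------------------------------------------------------------------
# shuffle null


@dataclass
class ShuffleNull:
    """Null distributions of epoch metrics under circular shifting."""

    fractions: dict[str, np.ndarray]  # epoch -> (n_shuffles,)
    distances: dict[str, np.ndarray]
    observed_fractions: dict[str, float]
    observed_distances: dict[str, float]
    seed: int
    n_shuffles: int


def percentile_of(observed: float, null: np.ndarray) -> float:
    """Percentile rank of the observed value within its null (midrank ties)."""
    null = np.asarray(null, dtype=float)
    less = np.sum(null < observed)
    ties = np.sum(null == observed)
    return float((less + 0.5 * ties) / null.size * 100.0)


def _event_arrays(
    events_per_roi: list[list[CalciumEvent]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts, ends, rois = [], [], []
    for i, evs in enumerate(events_per_roi):
        for e in evs:
            starts.append(e.start_s)
            ends.append(e.end_s)
            rois.append(i)
    return (
        np.asarray(starts, dtype=float),
        np.asarray(ends, dtype=float),
        np.asarray(rois, dtype=int),
    )


def _window_patterns(
    starts: np.ndarray,
    ends: np.ndarray,
    rois: np.ndarray,
    n_roi: int,
    windows: np.ndarray,  # (n_windows, 2)
    duration_s: float,
) -> np.ndarray:
    """(n_windows, n_roi) activity with circular wrap-around handling."""
    pat = np.zeros((windows.shape[0], n_roi), dtype=bool)
    if starts.size == 0:
        return pat
    s = np.mod(starts, duration_s)
    d = ends - starts
    e = s + d
    for w, (lo, hi) in enumerate(windows):
        hit = (s <= hi) & (e >= lo)
        wrap = e > duration_s
        if np.any(wrap):
            hit |= wrap & ((e - duration_s) >= lo)
        pat[w, rois[hit]] = True
    return pat


def _epoch_metrics(
    starts: np.ndarray,
    ends: np.ndarray,
    rois: np.ndarray,
    n_roi: int,
    onsets: np.ndarray,
    epoch_times: dict[str, float | None],
    window_s: float,
    duration_s: float,
) -> tuple[dict[str, float], dict[str, float]]:
    half = window_s / 2.0
    fr: dict[str, float] = {}
    di: dict[str, float] = {}
    for name, lat in epoch_times.items():
        if lat is None:
            continue
        wins = np.column_stack((onsets + lat - half, onsets + lat + half))
        pats = _window_patterns(starts, ends, rois, n_roi, wins, duration_s)
        fr[name] = float(pats.mean(axis=1).mean())
        if pats.shape[0] >= 2:
            di[name], _ = epoch_distance(pats)
    return fr, di


class _SweepAverager:
    """Precomputed per-ROI sweep averages for fast epoch re-detection.

    For ROI i with normalized trace x_i of length T, the averaged-sweep
    contribution after a circular shift by s samples is a contiguous slice
    of the (precomputed, doubled) sweep-sum array — so each shuffle costs
    one slice per ROI instead of a full re-binning.
    """

    def __init__(self, matrix: np.ndarray, onsets: np.ndarray, rate_hz: float, period_s: float):
        n_roi, T = matrix.shape
        W = int(round(period_s * rate_hz))
        idx0 = np.round(onsets[:-1] * rate_hz).astype(int)
        self.W, self.T, self.rate_hz = W, T, rate_hz
        y = np.zeros((n_roi, T))
        for i0 in idx0:
            shifted = np.roll(matrix, -i0, axis=1) if i0 else matrix
            y += shifted
        y /= idx0.size
        self.y2 = np.concatenate([y, y], axis=1)

    def averaged_sweep(self, shifts: np.ndarray) -> np.ndarray:
        """Ensemble averaged sweep when each ROI is rolled by ``shifts``."""
        n_roi = self.y2.shape[0] // 1
        acc = np.zeros(self.W)
        for i in range(self.y2.shape[0]):
            s = int(shifts[i]) % self.T
            start = (self.T - s) % self.T
            acc += self.y2[i, start : start + self.W]
        return acc / self.y2.shape[0]


def build_null(
    events_per_roi: list[list[CalciumEvent]],
    stimulus_onsets_s: np.ndarray,
    epochs: EpochSet,
    duration_s: float,
    config: AnalysisConfig | None = None,
    matrix2k: np.ndarray | None = None,
    redetect_epochs: bool = False,
    n_shuffles: int | None = None,
    seed: int | None = None,
) -> ShuffleNull:
    """Circular-shift shuffle null for ensemble fraction and epoch distance.

    Each iteration rotates every ROI (its events, and its normalized trace
    when re-detection is on) by an independent uniform shift, then
    recomputes the per-epoch mean ensemble fraction and mean Hamming
    distance.  By default epoch times stay fixed at the observed values;
    with ``redetect_epochs=True`` the epochs are re-detected on each
    surrogate's averaged ensemble sweep (requires ``matrix2k``), so the
    null inherits the same extremum-selection step as the observation.
    """
    cfg = config or AnalysisConfig()
    n_sh = n_shuffles if n_shuffles is not None else cfg.n_shuffles
    master = seed if seed is not None else cfg.rng_seed
    rng = np.random.default_rng(master)
    n_roi = len(events_per_roi)
    onsets = np.asarray(stimulus_onsets_s, dtype=float)
    starts, ends, rois = _event_arrays(events_per_roi)
    # shifts are whole frames of the native series: event boundaries live on
    # the frame-centre lattice, and with the stimulus period a whole number
    # of frames, so do the detected epoch windows — surrogates must share
    # that alignment or the null under-counts boundary overlaps
    n_frames = max(1, int(round(duration_s * cfg.frame_rate_hz)))
    frame_dt = 1.0 / cfg.frame_rate_hz
    epoch_times = {"epoch1": epochs.t1_s, "epoch2": epochs.t2_s, "epoch3": epochs.t3_s}

    obs_fr, obs_di = _epoch_metrics(
        starts, ends, rois, n_roi, onsets, epoch_times, cfg.epoch_window_s, duration_s
    )

    averager = None
    if redetect_epochs:
        if matrix2k is None:
            raise ValueError("redetect_epochs requires the normalized 2 kHz matrix")
        averager = _SweepAverager(matrix2k, onsets, cfg.aligned_rate_hz, cfg.sweep_period_s)

    present = [k for k, v in epoch_times.items() if v is not None]
    null_fr = {k: np.full(n_sh, np.nan) for k in present}
    null_di = {k: np.full(n_sh, np.nan) for k in present}
    T = averager.T if averager is not None else None

    for it in range(n_sh):
        shift_s = rng.integers(0, n_frames, size=n_roi) * frame_dt
        if averager is not None:
            shifts = np.round(shift_s * cfg.aligned_rate_hz).astype(int)
            avg = averager.averaged_sweep(shifts)
            ep = detect_epochs(avg, cfg.aligned_rate_hz, cfg)
            times = {"epoch1": ep.t1_s, "epoch2": ep.t2_s, "epoch3": ep.t3_s}
        else:
            times = epoch_times
        sh_starts = starts + shift_s[rois] if starts.size else starts
        fr, di = _epoch_metrics(
            sh_starts,
            ends + shift_s[rois] if ends.size else ends,
            rois,
            n_roi,
            onsets,
            times,
            cfg.epoch_window_s,
            duration_s,
        )
        for k in present:
            if k in fr:
                null_fr[k][it] = fr[k]
            if k in di:
                null_di[k][it] = di[k]

    return ShuffleNull(
        fractions=null_fr,
        distances=null_di,
        observed_fractions=obs_fr,
        observed_distances=obs_di,
        seed=master,
        n_shuffles=n_sh,
    )
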