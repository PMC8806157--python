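"""Calcium transient detection from ΔF/F traces.

Pipeline per ROI: remove slow fluorescence drift with locally weighted
regression (LOWESS), estimate the noise baseline by iteratively fitting a
Gaussian to the histogram of all samples, then call events as excursions
whose peak reaches ``mu + 4*sigma`` with start/end at the ``mu + 2*sigma``
crossings.  The iterative fit matters: transients contaminate the upper
tail, so a naive whole-trace SD overestimates the noise and moves the
thresholds; censoring suprathreshold samples between refits converges on
the noise component alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import AnalysisConfig


class DegenerateTraceError(ValueError):
    """Raised when a trace carries no usable noise information."""


@dataclass(frozen=True)
class Baseline:
    """Per-ROI noise model and the derived detection thresholds."""

    mu: float
    sigma: float
    event_peak_sd: float = 4.0
    event_bound_sd: float = 2.0
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateTraceError("baseline sigma must be positive")

    @property
    def thr_event(self) -> float:
        """Peak threshold: a run must reach this to count as an event."""
        return self.mu + self.event_peak_sd * self.sigma

    @property
    def thr_bound(self) -> float:
        """Boundary threshold: event start/end crossings."""
        return self.mu + self.event_bound_sd * self.sigma


@dataclass(frozen=True)
class CalciumEvent:
    start_s: float
    peak_s: float
    end_s: float
    #: peak ΔF/F minus the baseline mean
    amplitude: float

    def __post_init__(self) -> None:
        if not self.start_s <= self.peak_s <= self.end_s:
            raise ValueError("event times must satisfy start <= peak <= end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EventFeatures:
    roi_id: str
    n_events: int
    frequency_hz: float
    mean_iei_s: float | None
    mean_amplitude: float | None
    mean_duration_s: float | None
    active: bool


def detrend(trace: np.ndarray, span_frames: int = 100) -> np.ndarray:
    """Subtract a LOWESS trend; the trend is recentred so the detrended
    trace has exactly zero mean (the baseline fit estimates any offset).

    The trace is odd-extended (mirrored about its endpoints) by one span on
    each side before smoothing, so every sample sees a full symmetric
    neighbourhood: boundary samples are treated like interior ones, and a
    straight line is still removed exactly.
    """
    trace = np.asarray(trace, dtype=float)
    if span_frames < 10:
        raise ValueError(f"span_frames must be >= 10, got {span_frames}")
    if span_frames > trace.size:
        raise ValueError(
            f"span_frames={span_frames} longer than trace ({trace.size} frames)"
        )
    n = trace.size
    pad = span_frames
    left = 2 * trace[0] - trace[pad:0:-1]
    right = 2 * trace[-1] - trace[-2 : -pad - 2 : -1]
    padded = np.concatenate([left, trace, right])
    x = np.arange(padded.size, dtype=float)
    frac = span_frames / padded.size
    trend = lowess(padded, x, frac=frac, it=2, return_sorted=False)[pad : pad + n]
    trend = trend + (trace.mean() - trend.mean())
    return trace - trend


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_histogram(samples: np.ndarray, mu0: float, sigma0: float) -> tuple[float, float]:
    """Least-squares Gaussian fit to a Freedman-Diaconis histogram."""
    counts, edges = np.histogram(samples, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gauss,
            centers,
            counts,
            p0=(counts.max(), mu0, sigma0),
            maxfev=2000,
        )
        mu, sigma = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        # fall back to robust moments of the censored sample
        mu, sigma = float(np.median(samples)), float(samples.std())
    if sigma <= 0 or not np.isfinite(sigma):
        mu, sigma = float(np.median(samples)), float(samples.std())
    return mu, sigma


def fit_baseline(
    trace: np.ndarray,
    event_peak_sd: float = 4.0,
    event_bound_sd: float = 2.0,
    censor_sd: float = 2.0,
    rel_tol: float = 1e-3,
    max_iter: int = 20,
) -> Baseline:
    """Iterative Gaussian fit to the sample histogram.

    Fit a Gaussian to the histogram of all samples, censor samples above
    ``mu + censor_sd*sigma``, refit on the censored data, and iterate until
    the relative change in sigma drops below ``rel_tol`` (or ``max_iter``).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise ValueError(f"need >= 100 samples to fit a baseline, got {trace.size}")
    if np.ptp(trace) == 0:
        raise DegenerateTraceError("constant trace has no noise baseline")

    samples = trace
    mu, sigma = float(np.median(trace)), float(trace.std())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu_new, sigma_new = _fit_histogram(samples, mu, sigma)
        if sigma_new <= 0:
            raise DegenerateTraceError("baseline fit collapsed to zero variance")
        done = abs(sigma_new - sigma) / sigma < rel_tol
        mu, sigma = mu_new, sigma_new
        censored = trace[trace <= mu + censor_sd * sigma]
        if censored.size >= 50:
            samples = censored
        if done:
            converged = True
            break
    return Baseline(
        mu=mu,
        sigma=sigma,
        event_peak_sd=event_peak_sd,
        event_bound_sd=event_bound_sd,
        n_iterations=it,
        converged=converged,
    )


def detect_events(
    trace: np.ndarray,
    baseline: Baseline,
    frame_rate_hz: float = 7.5,
) -> list[CalciumEvent]:
    """Call transients: maximal runs above the 2 SD boundary threshold that
    contain at least one sample at or above the 4 SD peak threshold.

    Start is the first sample of the run; end is the first sample after the
    run drops back below the boundary; peak is the run's argmax.  Times are
    sample-centre timestamps in seconds.
    """
    trace = np.asarray(trace, dtype=float)
    above = trace > baseline.thr_bound
    if not above.any():
        return []
    dt = 1.0 / frame_rate_hz
    t = (np.arange(trace.size) + 0.5) * dt
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    out: list[CalciumEvent] = []
    for s, e in zip(run_starts, run_ends):
        seg = trace[s:e]
        if seg.max() < baseline.thr_event:
            continue
        p = s + int(np.argmax(seg))
        end_t = t[e] if e < trace.size else t[-1] + dt
        out.append(
            CalciumEvent(
                start_s=float(t[s]),
                peak_s=float(t[p]),
                end_s=float(end_t),
                amplitude=float(trace[p] - baseline.mu),
            )
        )
    return out


def summarize_events(
    events: list[CalciumEvent], duration_s: float, roi_id: str = ""
) -> EventFeatures:
    """Per-ROI event features: count, frequency, mean IEI (onset-to-onset),
    mean amplitude and duration.  IEI is undefined below 2 events.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = len(events)
    ieis = [b.start_s - a.start_s for a, b in zip(events, events[1:])]
    return EventFeatures(
        roi_id=roi_id,
        n_events=n,
        frequency_hz=n / duration_s,
        mean_iei_s=float(np.mean(ieis)) if n >= 2 else None,
        mean_amplitude=float(np.mean([e.amplitude for e in events])) if n else None,
        mean_duration_s=float(np.mean([e.duration_s for e in events])) if n else None,
        active=n >= 1,
    )


def session_activity_filter(
    features: list[EventFeatures], config: AnalysisConfig | None = None
) -> bool:
    """A session is valid iff at least ``min_active_rois`` ROIs are active
    (inclusive: exactly the minimum passes).
    """
    min_active = config.min_active_rois if config is not None else 3
    return sum(f.active for f in features) >= min_active
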