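"""Field-potential analysis: stimulus detection, fEPSP measurement,
input/output curves and LTP normalisation.

Responses are taken as negative-going (stratum radiatum convention);
magnitudes are reported as positive mV.  The response window (default
2-50 ms post-stimulus, blanking the first 2 ms of artifact) replaces the
manual cursor placement used at the rig.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LfpRecording


@dataclass(frozen=True)
class StimulusEvent:
    start_s: float
    peak_s: float
    end_s: float
    intensity_mA: float | None = None

    def __post_init__(self) -> None:
        if not self.start_s <= self.peak_s <= self.end_s:
            raise ValueError("stimulus times must satisfy start <= peak <= end")


@dataclass(frozen=True)
class FepspMeasure:
    stimulus_index: int
    #: magnitude of the extremal deflection in the response window, mV
    peak_amplitude_mV: float
    #: 20-80% rise slope toward the peak, signed, mV/ms
    slope_mV_per_ms: float


@dataclass(frozen=True)
class HfsProtocol:
    """High-frequency stimulation bookkeeping (recorded, not delivered)."""

    n_trains: int = 4
    train_freq_hz: float = 100.0
    train_duration_s: float = 1.0
    inter_train_interval_s: float = 10.0

    def validate(self) -> None:
        expected = HfsProtocol()
        for f in ("n_trains", "train_freq_hz", "train_duration_s", "inter_train_interval_s"):
            if getattr(self, f) != getattr(expected, f):
                raise ValueError(
                    f"non-standard HFS protocol: {f}={getattr(self, f)} "
                    f"(expected {getattr(expected, f)})"
                )


@dataclass(frozen=True)
class LtpResult:
    """Normalised post-HFS responses (post peak / mean baseline peak)."""

    normalized: dict[str, list[float]]  # session label -> per-stimulus values
    session_means: dict[str, float]
    excluded: bool


class StimulusDetectionWarning(UserWarning):
    pass


def detect_stimuli(
    lfp: LfpRecording,
    threshold_mV: float,
    refractory_s: float = 0.050,
    expected_count: int | None = None,
) -> list[StimulusEvent]:
    """Threshold search for stimulus artifacts.

    Maximal excursions of |voltage - median| above ``threshold_mV`` become
    events (start / peak / end); crossings closer than ``refractory_s`` are
    merged into one event.
    """
    v = lfp.samples
    dev = np.abs(v - np.median(v))
    above = dev > threshold_mV
    t = lfp.times()
    if not above.any():
        if expected_count:
            warnings.warn(
                f"expected {expected_count} stimuli, found none",
                StimulusDetectionWarning,
            )
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    # refractory merge
    merged: list[tuple[int, int]] = [(int(starts[0]), int(ends[0]))]
    gap = int(round(refractory_s * lfp.rate_hz))
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], int(e))
        else:
            merged.append((int(s), int(e)))
    events = []
    for s, e in merged:
        p = s + int(np.argmax(dev[s:e]))
        events.append(
            StimulusEvent(start_s=float(t[s]), peak_s=float(t[p]), end_s=float(t[e - 1]))
        )
    if expected_count is not None and len(events) != expected_count:
        warnings.warn(
            f"expected {expected_count} stimuli, detected {len(events)}",
            StimulusDetectionWarning,
        )
    return events


def measure_fepsp(
    lfp: LfpRecording,
    stim: StimulusEvent,
    window_s: tuple[float, float] = (0.002, 0.050),
    baseline_s: float = 0.010,
    stimulus_index: int = 0,
    polarity: int = -1,
) -> FepspMeasure:
    """Peak amplitude and 20-80% rise slope of the fEPSP after a stimulus.

    Deflections are referenced to the mean of ``baseline_s`` seconds of
    pre-stimulus signal, so a constant offset on the LFP changes nothing.
    """
    rate = lfp.rate_hz
    i_stim = int(round(stim.start_s * rate))
    i0 = i_stim + int(round(window_s[0] * rate))
    i1 = i_stim + int(round(window_s[1] * rate))
    if i1 > lfp.samples.size:
        raise ValueError("response window extends past the recording end")
    b0 = max(0, i_stim - int(round(baseline_s * rate)) - 1)
    baseline = float(np.mean(lfp.samples[b0 : max(b0 + 1, i_stim - 1)]))
    defl = (lfp.samples[i0:i1] - baseline) * polarity  # response-positive
    ipk = int(np.argmax(defl))
    peak = float(defl[ipk])
    if peak <= 0:
        return FepspMeasure(stimulus_index, 0.0, 0.0)

    # rising phase: from the last sub-20% sample before the peak, to the peak
    lo, hi = 0.2 * peak, 0.8 * peak
    below = np.flatnonzero(defl[: ipk + 1] <= lo)
    j = int(below[-1]) if below.size else 0
    rise = defl[j : ipk + 1]
    sel = np.flatnonzero((rise >= lo) & (rise <= hi))
    if sel.size >= 2:
        tt = sel / rate * 1000.0  # ms
        slope = float(np.polyfit(tt, rise[sel], 1)[0]) * polarity
    else:
        slope = 0.0
    return FepspMeasure(stimulus_index, peak, slope)


def measure_session(
    lfp: LfpRecording,
    stimuli: list[StimulusEvent],
    window_s: tuple[float, float] = (0.002, 0.050),
) -> list[FepspMeasure]:
    return [
        measure_fepsp(lfp, s, window_s=window_s, stimulus_index=i)
        for i, s in enumerate(stimuli)
    ]


def build_io_curve(measures_by_intensity: dict[float, list[FepspMeasure]]) -> dict[float, float]:
    """Input/output curve: mean fEPSP peak per stimulus intensity (mA)."""
    if len(measures_by_intensity) < 2:
        raise ValueError("need measures at >= 2 intensities for an I/O curve")
    return {
        float(i): float(np.mean([m.peak_amplitude_mV for m in ms]))
        for i, ms in sorted(measures_by_intensity.items())
    }


def pick_test_intensity(io_curve: dict[float, float]) -> float:
    """Smallest intensity whose mean response is 30-50% of the maximum.

    When no intensity lands in the band, fall back to the one nearest 40%
    of maximum, with a warning.
    """
    peaks = np.array(list(io_curve.values()))
    intensities = np.array(list(io_curve.keys()))
    vmax = peaks.max()
    if vmax <= 0:
        raise ValueError("all-zero I/O curve: cannot select a test intensity")
    rel = peaks / vmax
    in_band = np.flatnonzero((rel >= 0.3) & (rel <= 0.5))
    if in_band.size:
        return float(intensities[in_band[np.argmin(intensities[in_band])]])
    warnings.warn(
        "no intensity in the 30-50% band; choosing the nearest to 40% of maximum",
        UserWarning,
    )
    return float(intensities[np.argmin(np.abs(rel - 0.4))])


def normalize_ltp(
    baseline_measures: list[FepspMeasure],
    post_sessions: dict[str, list[FepspMeasure]],
) -> LtpResult:
    """Normalise post-HFS responses to the baseline-session mean peak.

    A slice is flagged excluded when the mean normalised amplitude across
    the post-HFS sessions falls below 1 (depression instead of LTP).
    """
    base = [m.peak_amplitude_mV for m in baseline_measures]
    if not base:
        raise ValueError("baseline session has no measures")
    base_mean = float(np.mean(base))
    if base_mean == 0:
        raise ZeroDivisionError("baseline mean peak is zero; cannot normalise")
    normalized = {
        label: [m.peak_amplitude_mV / base_mean for m in ms]
        for label, ms in post_sessions.items()
    }
    session_means = {label: float(np.mean(v)) for label, v in normalized.items()}
    overall = float(np.mean(list(session_means.values())))
    return LtpResult(
        normalized=normalized,
        session_means=session_means,
        excluded=overall < 1.0,
    )
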