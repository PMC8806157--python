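"""Shared 2 kHz timebase: calcium upsampling, LFP decimation, sweep binning.

Calcium traces acquired at 7.5 Hz are linearly interpolated onto the
aligned grid; the 20 kHz LFP is anti-alias filtered and decimated by 10.
The recording is then segmented into inter-stimulus sweeps (stimulus onset
to next onset), so 10 stimuli give 9 sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import LfpRecording, RoiTraceSet


@dataclass
class AlignedSession:
    """Calcium matrix and LFP on a common clock."""

    calcium: np.ndarray  # (n_roi, T)
    lfp: np.ndarray  # (T,)
    rate_hz: float
    stimulus_onsets_s: np.ndarray
    #: original frame timestamps, for mapping native-rate features back
    frame_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.calcium.shape[1] != self.lfp.size:
            raise ValueError(
                f"calcium ({self.calcium.shape[1]}) and LFP ({self.lfp.size}) "
                "must share one timebase"
            )

    @property
    def duration_s(self) -> float:
        return self.lfp.size / self.rate_hz

    def times(self) -> np.ndarray:
        return (np.arange(self.lfp.size) + 0.5) / self.rate_hz


@dataclass
class SweepSet:
    """Stimulus-onset-to-next-onset segments of one aligned channel."""

    sweeps: np.ndarray  # (n_sweeps, n_samples)
    rate_hz: float
    period_s: float

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def rel_times(self) -> np.ndarray:
        """Stimulus-relative time axis (sample centres), seconds."""
        return (np.arange(self.sweeps.shape[1]) + 0.5) / self.rate_hz


def upsample_calcium(
    traces: RoiTraceSet | np.ndarray,
    frame_rate_hz: float | None = None,
    target_rate_hz: float = 2000.0,
    t_target: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of frame-rate traces onto a fast grid.

    Values at the original frame times are preserved exactly; beyond the
    first/last frame the edge value is held (no extrapolation).  Returns
    ``(matrix, t_target)``.
    """
    if isinstance(traces, RoiTraceSet):
        dff = traces.dff
        frame_rate_hz = traces.frame_rate_hz
    else:
        dff = np.atleast_2d(np.asarray(traces, dtype=float))
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz required for bare arrays")
    n_frames = dff.shape[1]
    if n_frames < 2:
        raise ValueError("need >= 2 frames to interpolate")
    t_frames = (np.arange(n_frames) + 0.5) / frame_rate_hz
    if t_target is None:
        n_t = int(round(n_frames / frame_rate_hz * target_rate_hz))
        t_target = (np.arange(n_t) + 0.5) / target_rate_hz
    out = np.empty((dff.shape[0], t_target.size))
    for i in range(dff.shape[0]):
        out[i] = np.interp(t_target, t_frames, dff[i])
    return out, t_target


def downsample_lfp(lfp: LfpRecording, target_rate_hz: float = 2000.0) -> LfpRecording:
    """Anti-alias filter and decimate the LFP to the aligned rate.

    Uses a zero-phase FIR decimator (cutoff below the output Nyquist), so
    stimulus timing is preserved to within half an output sample.
    """
    factor = lfp.rate_hz / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"rate ratio {lfp.rate_hz}/{target_rate_hz} must be an integer"
        )
    q = int(round(factor))
    if q == 1:
        return LfpRecording(samples=lfp.samples.copy(), rate_hz=target_rate_hz)
    out = signal.decimate(lfp.samples, q, ftype="fir", zero_phase=True)
    return LfpRecording(samples=out, rate_hz=target_rate_hz)


def align_session(
    traces: RoiTraceSet,
    lfp: LfpRecording,
    stimulus_onsets_s: np.ndarray,
    aligned_rate_hz: float = 2000.0,
    offset_s: float = 0.0,
) -> AlignedSession:
    """Build the shared-timebase session (optionally shifting the LFP clock
    by an explicit ``offset_s`` to model acquisition-sync offsets), trimming
    both channels to the overlapping span.
    """
    lfp2k = downsample_lfp(lfp, aligned_rate_hz)
    n_t = lfp2k.samples.size
    t_target = (np.arange(n_t) + 0.5) / aligned_rate_hz
    ca2k, _ = upsample_calcium(traces, t_target=t_target)
    n = min(ca2k.shape[1], n_t)
    onsets = np.asarray(stimulus_onsets_s, dtype=float) + offset_s
    return AlignedSession(
        calcium=ca2k[:, :n],
        lfp=lfp2k.samples[:n],
        rate_hz=aligned_rate_hz,
        stimulus_onsets_s=onsets,
        frame_times_s=traces.frame_times(),
    )


def bin_sweeps(
    channel: np.ndarray,
    onsets_s: np.ndarray,
    sweep_period_s: float = 10.0,
    rate_hz: float = 2000.0,
    jitter_tol_s: float = 0.1,
) -> SweepSet:
    """Segment a channel into inter-stimulus sweeps.

    One sweep per interval between consecutive onsets, truncated to a
    common grid of at most ``sweep_period_s``; n onsets give n-1 sweeps.
    """
    channel = np.asarray(channel, dtype=float)
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.size < 2:
        raise ValueError("need >= 2 stimulus onsets to form sweeps")
    intervals = np.diff(onsets)
    if np.any(intervals < sweep_period_s - jitter_tol_s):
        raise ValueError(
            f"inter-onset interval {intervals.min():.3f} s shorter than "
            f"sweep period {sweep_period_s} s minus tolerance"
        )
    n_common = int(np.floor(min(intervals.min(), sweep_period_s) * rate_hz))
    rows = []
    for s in onsets[:-1]:
        i0 = int(round(s * rate_hz))
        seg = channel[i0 : i0 + n_common]
        if seg.size < n_common:
            seg = np.pad(seg, (0, n_common - seg.size), mode="edge")
        rows.append(seg)
    return SweepSet(sweeps=np.vstack(rows), rate_hz=rate_hz, period_s=n_common / rate_hz)
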