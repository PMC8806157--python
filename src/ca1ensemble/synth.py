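"""Seeded synthetic session generator.

Emulates the recordings the pipeline targets: ~100 somatic ROIs imaged at
7.5 Hz for 720 frames while Schaffer-collateral stimuli (10 pulses, 10 s
apart) evoke a structured CA1 ensemble response, recorded simultaneously
with a 20 kHz field potential.  Each ΔF/F trace is Gaussian baseline noise
plus a slow additive drift plus GCaMP6f-like double-exponential transients;
the LFP is baseline noise plus a one-sample stimulus artifact plus a
negative-going alpha-function fEPSP.

The evoked structure follows the three-epoch phenomenology the analysis
must detect: a first ensemble maximum shortly after the stimulus, an
ensemble minimum (spontaneous-rate suppression) 1-3 s post-stimulus, and a
weaker second maximum within 5 s.  Ensemble membership repeats across
stimuli with reliability ``p_repeat``, so pattern-similarity recovery is
testable against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import LfpRecording, RoiTraceSet, SessionBundle


class SynthValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class TransientKernelParams:
    """GCaMP6f-like transient shape: difference of exponentials."""

    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.30
    #: peak ΔF/F amplitude, in multiples of noise_sd
    amplitude_sd: float = 6.0


@dataclass(frozen=True)
class DriftParams:
    """Slow additive baseline component (bleaching-like)."""

    #: amplitude of a decaying-exponential component, ΔF/F units
    exp_amplitude: float = 0.01
    #: its time constant, seconds
    exp_tau_s: float = 40.0
    #: optional linear term, ΔF/F per second
    linear_per_s: float = 0.0


@dataclass(frozen=True)
class StimulusParams:
    count: int = 10
    period_s: float = 10.0
    first_onset_s: float = 2.0


@dataclass(frozen=True)
class EpochStructureParams:
    """Programmed post-stimulus ensemble structure.

    ``pattern`` selects which epochs are present: Type A has a dominant
    first maximum plus the minimum (and a weak second maximum), Type B a
    second maximum plus the minimum, Type C the minimum only, and ``none``
    disables all evoked structure.  Latencies are the target times of the
    ensemble-trace extrema relative to stimulus onset; evoked event onsets
    are placed so that the transient peak lands at the programmed latency.
    """

    pattern: Literal["A", "B", "C", "none"] = "A"
    epoch1_latency_s: float = 0.4
    #: ensemble-minimum time; suppression ramps linearly to zero rate here
    epoch2_latency_s: float = 1.8
    #: suppression window bounds, seconds post-stimulus
    suppression_window_s: tuple[float, float] = (1.0, 3.0)
    epoch3_latency_s: float = 3.5
    #: fraction of ROIs in the epoch-1 / epoch-3 core sets
    epoch1_core_frac: float = 0.40
    epoch3_core_frac: float = 0.15
    #: onset jitter SD for evoked events, seconds
    jitter_sd_s: float = 0.03
    #: how far the rate-suppression vertex leads the programmed activity
    #: minimum: the ensemble trace is the event rate convolved with the
    #: supra-threshold transient profile, so the activity minimum trails
    #: the rate minimum by about half a transient's persistence
    rate_min_lead_s: float = 0.2


@dataclass(frozen=True)
class MembershipParams:
    """How consistently the same ROIs participate across stimuli."""

    #: probability a core-set ROI participates in its epoch on a stimulus
    p_repeat: float = 0.90
    #: probability a non-core ROI participates anyway
    p_leak: float = 0.02


@dataclass(frozen=True)
class FepspParams:
    #: fEPSP peak magnitude, mV (negative-going response)
    amplitude_mV: float = 0.5
    #: alpha-function time constant, seconds
    alpha_tau_s: float = 0.005
    #: synaptic onset latency after the stimulus artifact, seconds
    onset_latency_s: float = 0.003
    #: one-sample stimulus-artifact amplitude, mV
    artifact_mV: float = 5.0
    #: LFP baseline noise SD, mV
    noise_sd_mV: float = 0.01


@dataclass(frozen=True)
class GroupProfile:
    """Group-level modifiers (sham-like vs HFHI-like)."""

    name: str = "sham"
    spont_rate_mult: float = 1.0
    p_repeat_mult: float = 1.0


SHAM_PROFILE = GroupProfile("sham", 1.0, 1.0)
HFHI_PROFILE = GroupProfile("hfhi", 1.5, 0.72)


@dataclass(frozen=True)
class SyntheticParams:
    n_rois: int = 50
    n_frames: int = 720
    frame_rate_hz: float = 7.5
    lfp_rate_hz: float = 20_000.0
    #: ΔF/F baseline noise SD
    noise_sd: float = 0.02
    drift: DriftParams = field(default_factory=DriftParams)
    transient_kernel: TransientKernelParams = field(default_factory=TransientKernelParams)
    #: per-ROI spontaneous event rate, Hz
    spont_rate_hz: float = 0.20
    stimuli: StimulusParams = field(default_factory=StimulusParams)
    epoch_structure: EpochStructureParams = field(default_factory=EpochStructureParams)
    membership: MembershipParams = field(default_factory=MembershipParams)
    group_profile: GroupProfile = field(default_factory=lambda: SHAM_PROFILE)
    fepsp: FepspParams = field(default_factory=FepspParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1 or self.n_frames < 2:
            raise SynthValidationError("need at least 1 ROI and 2 frames")
        if self.noise_sd <= 0:
            raise SynthValidationError("noise_sd must be positive")
        if self.spont_rate_hz < 0:
            raise SynthValidationError("spont_rate_hz must be non-negative")
        for p in (self.membership.p_repeat, self.membership.p_leak):
            if not 0.0 <= p <= 1.0:
                raise SynthValidationError("membership probabilities must be in [0, 1]")
        dur = self.n_frames / self.frame_rate_hz
        last = self.stimuli.first_onset_s + (self.stimuli.count - 1) * self.stimuli.period_s
        if self.stimuli.count and not 0 < self.stimuli.first_onset_s < last < dur:
            raise SynthValidationError(
                f"stimuli must fit inside the {dur:.1f} s recording (last onset {last:.1f} s)"
            )

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    #: per-ROI list of (onset_s, amplitude) for every planted transient
    events: list[list[tuple[float, float]]]
    #: per-stimulus, per-epoch ("epoch1"/"epoch3") participating ROI index sets
    participants: list[dict[str, set[int]]]
    #: programmed epoch latencies, seconds post-stimulus (None when absent)
    epoch_latencies_s: dict[str, float | None]
    #: programmed fEPSP peak amplitudes per stimulus, mV
    fepsp_amplitudes_mV: list[float]

    def event_count(self, roi: int) -> int:
        return len(self.events[roi])

    def total_events(self) -> int:
        return sum(len(e) for e in self.events)


# ---------------------------------------------------------------------------
# kernel


def _validate_taus(rise_tau: float, decay_tau: float) -> None:
    if rise_tau <= 0 or decay_tau <= 0:
        raise SynthValidationError("time constants must be positive")
    if rise_tau >= decay_tau:
        raise SynthValidationError("require 0 < rise_tau < decay_tau")


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the difference-of-exponentials maximum."""
    _validate_taus(rise_tau, decay_tau)
    return math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def transient_shape(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Peak-normalised double-exponential transient evaluated at times ``t``.

    Zero for t < 0; maximum value exactly 1 at the analytic peak time.
    """
    _validate_taus(rise_tau, decay_tau)
    t = np.asarray(t, dtype=float)
    tc = np.where(t >= 0, t, 0.0)
    raw = np.where(t >= 0, np.exp(-tc / decay_tau) - np.exp(-tc / rise_tau), 0.0)
    tp = kernel_peak_time(rise_tau, decay_tau)
    peak = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
    return raw / peak


def make_transient_kernel(
    rise_tau: float, decay_tau: float, frame_rate: float
) -> np.ndarray:
    """Discrete peak-normalised transient kernel at the given sampling rate.

    Length covers at least five decay constants past the peak so the tail
    is negligible; the discrete maximum equals 1 exactly.
    """
    if frame_rate <= 0:
        raise SynthValidationError("frame_rate must be positive")
    tp = kernel_peak_time(rise_tau, decay_tau)
    n = int(np.ceil((tp + 5.0 * decay_tau) * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    k = transient_shape(t, rise_tau, decay_tau)
    return k / k.max()  # discrete-grid renormalisation


# ---------------------------------------------------------------------------
# session generation


def _suppression_multiplier(
    t_rel: np.ndarray, ep: EpochStructureParams
) -> np.ndarray:
    """Spontaneous-rate multiplier as a function of time since stimulus.

    V-shaped: 1 outside the suppression window, ramping linearly to 0 at the
    programmed ensemble-minimum time, so the minimum has a recoverable
    location rather than a flat zero plateau.
    """
    lo, hi = ep.suppression_window_s
    t2 = ep.epoch2_latency_s - ep.rate_min_lead_s
    half = min(t2 - lo, hi - t2)
    m = np.ones_like(t_rel)
    inside = (t_rel >= lo) & (t_rel <= hi)
    m[inside] = np.minimum(1.0, np.abs(t_rel[inside] - t2) / half)
    return m


def _spontaneous_onsets(
    rng: np.random.Generator, params: SyntheticParams, onsets: np.ndarray
) -> np.ndarray:
    """Poisson onsets over the recording, thinned by the suppression profile."""
    rate = params.spont_rate_hz * params.group_profile.spont_rate_mult
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * params.duration_s)
    t = np.sort(rng.uniform(0.0, params.duration_s, size=n))
    ep = params.epoch_structure
    if ep.pattern == "none" or t.size == 0 or onsets.size == 0:
        return t
    keep = np.ones(t.size, dtype=bool)
    for s in onsets:
        rel = t - s
        in_win = (rel >= 0) & (rel <= ep.suppression_window_s[1])
        if np.any(in_win):
            m = _suppression_multiplier(rel[in_win], ep)
            keep[in_win] &= rng.uniform(size=m.size) < m
    return t[keep]


def generate_session(params: SyntheticParams) -> tuple[SessionBundle, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Identical ``params.seed`` gives bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    kp = params.transient_kernel
    ep = params.epoch_structure
    mem = params.membership
    st = params.stimuli
    n_roi, n_frames = params.n_rois, params.n_frames
    frame_t = (np.arange(n_frames) + 0.5) / params.frame_rate_hz
    onsets = st.first_onset_s + st.period_s * np.arange(st.count)

    # evoked membership core sets (fixed per session)
    roi_order = rng.permutation(n_roi)
    n1 = int(round(ep.epoch1_core_frac * n_roi))
    n3 = int(round(ep.epoch3_core_frac * n_roi))
    core1 = set(roi_order[:n1].tolist())
    core3 = set(roi_order[n1 : n1 + n3].tolist())
    has_e1 = ep.pattern == "A"
    has_e3 = ep.pattern in ("A", "B")
    has_e2 = ep.pattern in ("A", "B", "C")
    p_rep = min(1.0, mem.p_repeat * params.group_profile.p_repeat_mult)

    tpk = kernel_peak_time(kp.rise_tau_s, kp.decay_tau_s)
    events: list[list[tuple[float, float]]] = [[] for _ in range(n_roi)]
    participants: list[dict[str, set[int]]] = []

    for s in onsets:
        part: dict[str, set[int]] = {"epoch1": set(), "epoch3": set()}
        for name, flag, core, lat in (
            ("epoch1", has_e1, core1, ep.epoch1_latency_s),
            ("epoch3", has_e3, core3, ep.epoch3_latency_s),
        ):
            if not flag:
                continue
            for roi in range(n_roi):
                p = p_rep if roi in core else mem.p_leak
                if rng.uniform() < p:
                    part[name].add(roi)
                    onset = s + lat - tpk + rng.normal(0.0, ep.jitter_sd_s)
                    onset = min(max(onset, s + 0.02), params.duration_s - 0.1)
                    amp = kp.amplitude_sd * params.noise_sd * rng.uniform(1.0, 1.5)
                    events[roi].append((onset, amp))
        participants.append(part)

    # spontaneous events, suppressed around the ensemble minimum
    for roi in range(n_roi):
        for onset in _spontaneous_onsets(rng, params, onsets if has_e2 else np.empty(0)):
            amp = kp.amplitude_sd * params.noise_sd * rng.uniform(1.0, 1.5)
            events[roi].append((float(onset), float(amp)))
        events[roi].sort()

    # ΔF/F = drift + noise + sum of transients (evaluated in continuous time)
    dff = rng.normal(0.0, params.noise_sd, size=(n_roi, n_frames))
    dr = params.drift
    dff += dr.exp_amplitude * np.exp(-frame_t / dr.exp_tau_s) + dr.linear_per_s * frame_t
    for roi in range(n_roi):
        for onset, amp in events[roi]:
            j0 = int(np.searchsorted(frame_t, onset))
            j1 = min(n_frames, j0 + int((tpk + 5 * kp.decay_tau_s) * params.frame_rate_hz) + 2)
            if j0 < n_frames:
                dff[roi, j0:j1] += amp * transient_shape(
                    frame_t[j0:j1] - onset, kp.rise_tau_s, kp.decay_tau_s
                )

    # LFP: noise + per-stimulus artifact + negative alpha-function fEPSP
    fp = params.fepsp
    n_lfp = int(round(params.duration_s * params.lfp_rate_hz))
    lfp = rng.normal(0.0, fp.noise_sd_mV, size=n_lfp)
    lfp_t = (np.arange(n_lfp) + 0.5) / params.lfp_rate_hz
    fepsp_amps: list[float] = []
    for s in onsets:
        i = int(round(s * params.lfp_rate_hz))
        if 0 <= i < n_lfp:
            lfp[i] += fp.artifact_mV
        a = fp.amplitude_mV
        fepsp_amps.append(a)
        t0 = s + fp.onset_latency_s
        j0 = int(np.searchsorted(lfp_t, t0))
        j1 = min(n_lfp, j0 + int(10 * fp.alpha_tau_s * params.lfp_rate_hz))
        if j0 < n_lfp:
            tr = (lfp_t[j0:j1] - t0) / fp.alpha_tau_s
            lfp[j0:j1] -= a * tr * np.exp(1.0 - tr)

    bundle = SessionBundle(
        roi_traces=RoiTraceSet(dff=dff, frame_rate_hz=params.frame_rate_hz),
        lfp=LfpRecording(samples=lfp, rate_hz=params.lfp_rate_hz),
        stimulus_onsets_s=onsets,
        metadata={
            "session_id": f"synth-{params.seed}",
            "group": params.group_profile.name,
            "session_type": "baseline",
            "pattern": ep.pattern,
            "alignment_offset_s": 0.0,
        },
    )
    truth = GroundTruth(
        events=events,
        participants=participants,
        epoch_latencies_s={
            "epoch1": ep.epoch1_latency_s if has_e1 else None,
            "epoch2": ep.epoch2_latency_s if has_e2 else None,
            "epoch3": ep.epoch3_latency_s if has_e3 else None,
        },
        fepsp_amplitudes_mV=fepsp_amps,
    )
    return bundle, truth


def generate_cohort(
    n_sham: int,
    n_hfhi: int,
    base_params: SyntheticParams | None = None,
    seed: int = 0,
    hfhi_profile: GroupProfile = HFHI_PROFILE,
) -> list[tuple[SessionBundle, GroundTruth]]:
    """Generate a two-group cohort with deterministically derived seeds.

    Sham-like sessions use the base parameters; HFHI-like sessions apply the
    profile's spontaneous-rate and membership-reliability multipliers.
    """
    if n_sham < 1 or n_hfhi < 1:
        raise SynthValidationError("need at least one session per group")
    base = base_params or SyntheticParams()
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_sham + n_hfhi)
    out = []
    for i in range(n_sham):
        out.append(
            generate_session(
                replace(base, seed=int(child[i]), group_profile=SHAM_PROFILE)
            )
        )
    for i in range(n_hfhi):
        out.append(
            generate_session(
                replace(base, seed=int(child[n_sham + i]), group_profile=hfhi_profile)
            )
        )
    return out
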