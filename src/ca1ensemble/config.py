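"""Analysis configuration.

All tunable constants of the pipeline live in :class:`AnalysisConfig` so a
run is fully described by one small document plus a seed.  Defaults encode
the recording protocol and detection rules of the slice experiments this
package analyses: 720 imaging frames at 7.5 Hz, LFP digitised at 20 kHz and
aligned at 2 kHz, calcium events thresholded at 4 SD with 2 SD boundaries,
10 s inter-stimulus sweeps, a 10 ms epoch window, and a 1,000-iteration
circular-shift null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass(frozen=True)
class AnalysisConfig:
    #: imaging frame rate, Hz
    frame_rate_hz: float = 7.5
    #: frames per imaging session
    n_frames: int = 720
    #: native LFP sampling rate, Hz
    lfp_rate_hz: float = 20_000.0
    #: shared timebase for calcium/LFP alignment, Hz
    aligned_rate_hz: float = 2_000.0
    #: event peak threshold, in baseline SDs above the baseline mean
    event_peak_sd: float = 4.0
    #: event start/end boundary threshold, in baseline SDs
    event_bound_sd: float = 2.0
    #: window around an epoch time for the ensemble fraction, seconds
    epoch_window_s: float = 0.010
    #: inter-stimulus sweep length, seconds
    sweep_period_s: float = 10.0
    #: circular-shift iterations for the shuffle null
    n_shuffles: int = 1000
    #: sessions with fewer active ROIs than this are invalid
    min_active_rois: int = 3
    #: epoch 1 (first ensemble maximum) must occur within this many seconds
    epoch1_limit_s: float = 1.0
    #: epoch 2 (ensemble minimum) search range, seconds post-stimulus
    epoch2_range_s: tuple[float, float] = (1.0, 3.0)
    #: epoch 3 (second ensemble maximum) must occur within this many seconds
    epoch3_limit_s: float = 5.0
    #: Tukey-fence multiplier for outlier flagging
    outlier_iqr_mult: float = 1.5
    #: LOWESS detrending span, frames
    detrend_span_frames: int = 100
    #: smoothing window applied to averaged sweeps before extremum search, s
    epoch_smooth_s: float = 0.050
    #: minimum peak prominence, as a fraction of the sweep's dynamic range
    epoch_prominence_frac: float = 0.10
    #: master seed for every randomised step
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "lfp_rate_hz", "aligned_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.event_peak_sd > self.event_bound_sd > 0:
            raise ConfigError(
                "thresholds must satisfy event_peak_sd > event_bound_sd > 0, got "
                f"event_peak_sd={self.event_peak_sd}, event_bound_sd={self.event_bound_sd}"
            )
        lo, hi = self.epoch2_range_s
        if not (self.epoch1_limit_s < hi <= self.epoch3_limit_s < self.sweep_period_s):
            raise ConfigError(
                "epoch timing must satisfy epoch1_limit_s < epoch2_range_s[1] "
                "<= epoch3_limit_s < sweep_period_s"
            )
        if lo >= hi:
            raise ConfigError("epoch2_range_s must be an increasing interval")
        if self.n_shuffles < 1:
            raise ConfigError(f"n_shuffles must be >= 1, got {self.n_shuffles}")
        if self.n_frames < 2:
            raise ConfigError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.min_active_rois < 0:
            raise ConfigError("min_active_rois must be non-negative")

    def with_overrides(self, **kwargs: Any) -> "AnalysisConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value document.

    Missing keys take the documented defaults; an empty file yields the
    default configuration.  Unknown keys and invariant violations raise
    :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "epoch2_range_s" in raw:
        raw["epoch2_range_s"] = tuple(raw["epoch2_range_s"])
    return AnalysisConfig(**raw)
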