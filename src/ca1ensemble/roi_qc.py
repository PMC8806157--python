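"""ROI refinement: shape and trace-stability criteria with reason codes.

Somatic ROIs from semi-automatic extraction are filtered on geometry
(roundness, oblongness, area), baseline behaviour (drift, stability) and
saturation.  Skewness and kurtosis are computed and recorded but never used
in the decision.  All thresholds are inclusive: a feature exactly at its
bound passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure


@dataclass(frozen=True)
class QCCriteria:
    max_drift_pct: float = 25.0
    #: minimum inverse-CV of sliding-window baseline medians
    stability_threshold: float = 1000.0
    max_roundness: float = 2.2
    max_oblongness: float = 3.6
    area_range: tuple[float, float] = (5.0, 500.0)
    max_saturated_frames: int = 0

    def __post_init__(self) -> None:
        if self.area_range[0] >= self.area_range[1]:
            raise ValueError("area_range must be increasing")


@dataclass(frozen=True)
class RoiFeatures:
    area: float
    roundness: float
    oblongness: float
    baseline_drift_pct: float
    baseline_stability: float
    n_saturated_frames: int
    skewness: float = 0.0  # recorded, not used
    kurtosis: float = 0.0  # recorded, not used


@dataclass(frozen=True)
class QCDecision:
    include: bool
    reasons: tuple[str, ...] = ()


def compute_shape_features(mask: np.ndarray) -> tuple[float, float, float]:
    """Area, roundness and oblongness of a binary ROI mask.

    area: pixel count.  roundness: perimeter^2 / (4*pi*area), 1 for a
    perfect circle, larger = less round.  oblongness: major/minor axis
    ratio of the second-moment ellipse (inf for degenerate 1-pixel-wide
    masks).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    area = float(mask.sum())
    perimeter = float(measure.perimeter(mask))
    roundness = perimeter**2 / (4.0 * np.pi * area) if perimeter > 0 else 1.0
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    minor = rp.axis_minor_length
    oblongness = float(rp.axis_major_length / minor) if minor > 0 else float("inf")
    if area == 1:
        roundness, oblongness = 1.0, 1.0
    return area, roundness, max(oblongness, 1.0)


def compute_trace_qc(
    trace: np.ndarray,
    frame_rate: float = 7.5,
    window_frames: int = 100,
    saturation_value: float | None = None,
) -> tuple[float, float, int, float, float]:
    """Trace-stability metrics over sliding 100-frame windows.

    drift: worst-window |endpoint difference of a linear fit| relative to
    the window median, percent.  stability: mean of window medians divided
    by their SD (inverse CV; large = stable, infinite for a constant
    baseline).  A frame is saturated when it sits at the representable
    maximum of the source data (``saturation_value``; none assumed when
    not given).
    """
    trace = np.asarray(trace, dtype=float)
    w = window_frames
    if trace.size < w:
        raise ValueError(f"trace must have >= {w} frames, got {trace.size}")
    x = np.arange(w, dtype=float)
    sw = np.lib.stride_tricks.sliding_window_view(trace, w)
    # linear-fit endpoint difference = slope * (w - 1); slope via closed form
    xc = x - x.mean()
    slopes = sw @ xc / (xc @ xc)
    medians = np.median(sw, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = np.abs(slopes * (w - 1)) / np.abs(medians) * 100.0
    drift = float(np.nanmax(np.where(medians == 0, np.nan, drift)))
    if not np.isfinite(drift):
        drift = 0.0 if np.allclose(slopes, 0) else float("inf")
    med_sd = float(medians.std())
    stability = float(np.abs(medians.mean()) / med_sd) if med_sd > 0 else float("inf")
    n_sat = int(np.sum(trace >= saturation_value)) if saturation_value is not None else 0
    return (
        drift,
        stability,
        n_sat,
        float(stats.skew(trace)),
        float(stats.kurtosis(trace)),
    )


def apply_qc(features: RoiFeatures, criteria: QCCriteria = QCCriteria()) -> QCDecision:
    """Pure inclusion decision; every failing criterion is reason-coded."""
    reasons: list[str] = []
    if features.baseline_drift_pct > criteria.max_drift_pct:
        reasons.append("drift")
    if features.baseline_stability < criteria.stability_threshold:
        reasons.append("stability")
    if features.roundness > criteria.max_roundness:
        reasons.append("roundness")
    if features.oblongness > criteria.max_oblongness:
        reasons.append("oblongness")
    lo, hi = criteria.area_range
    if not lo <= features.area <= hi:
        reasons.append("area")
    if features.n_saturated_frames > criteria.max_saturated_frames:
        reasons.append("saturation")
    return QCDecision(include=not reasons, reasons=tuple(reasons))


def qc_table(
    feature_list: list[RoiFeatures],
    criteria: QCCriteria = QCCriteria(),
    include_list: list[int] | None = None,
):
    """Apply QC to many ROIs; ``include_list`` models the manual anatomical
    pass (ROIs outside it are excluded with reason 'manual').
    """
    import pandas as pd

    rows = []
    for i, f in enumerate(feature_list):
        d = apply_qc(f, criteria)
        reasons = list(d.reasons)
        if include_list is not None and i not in include_list:
            reasons.append("manual")
        rows.append(
            {
                "roi_index": i,
                "include": not reasons,
                "reasons": ";".join(reasons),
                **f.__dict__,
            }
        )
    return pd.DataFrame(rows)
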