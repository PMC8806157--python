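"""Reading and writing session artifacts.

On-disk formats are deliberately plain: UTF-8 comma-delimited tables with a
mandatory header row, or a single HDF5 container with fixed dataset names
(``/dff``, ``/lfp``, ``/stimuli``).  Times are seconds from recording start,
with sample timestamps at sample centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an on-disk table is malformed."""


class SessionValidationError(ValueError):
    """Raised when session components are mutually inconsistent."""


@dataclass
class RoiTraceSet:
    """Per-ROI ΔF/F traces at the imaging frame rate."""

    dff: np.ndarray  # (n_rois, n_frames)
    frame_rate_hz: float
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise SessionValidationError("dff must be a 2-D (n_rois, n_frames) array")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.dff.shape[0])]
        if len(self.roi_ids) != self.dff.shape[0]:
            raise SessionValidationError("roi_ids length must match trace count")

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        """Frame timestamps (sample centres), seconds."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate_hz


@dataclass
class LfpRecording:
    """Extracellular voltage trace, mV."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate_hz <= 0:
            raise SessionValidationError("LFP rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise SessionValidationError("LFP contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def times(self) -> np.ndarray:
        return (np.arange(self.samples.size) + 0.5) / self.rate_hz


@dataclass
class SessionBundle:
    """One recording session: traces, LFP, stimulus table, metadata."""

    roi_traces: RoiTraceSet
    lfp: LfpRecording
    stimulus_onsets_s: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stimulus_onsets_s = np.asarray(self.stimulus_onsets_s, dtype=float).ravel()
        if self.stimulus_onsets_s.size and np.any(np.diff(self.stimulus_onsets_s) <= 0):
            raise SessionValidationError("stimulus onsets must be strictly increasing")
        dur = min(self.roi_traces.duration_s, self.lfp.duration_s)
        if self.stimulus_onsets_s.size and (
            self.stimulus_onsets_s[0] < 0 or self.stimulus_onsets_s[-1] > dur
        ):
            raise SessionValidationError(
                f"stimulus onsets must lie within the recording (0, {dur:.3f}) s"
            )


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed table {path}: {exc}") from exc
    return df


def read_session(
    trace_path: str | Path,
    lfp_path: str | Path,
    stim_path: str | Path,
    meta: dict[str, Any] | None = None,
    frame_rate_hz: float = 7.5,
    lfp_rate_hz: float = 20_000.0,
) -> SessionBundle:
    """Assemble a :class:`SessionBundle` from delimited tables.

    The trace table may be ROIs x frames (one row per ROI, first column the
    ROI id) or frames x ROIs (one column per ROI); orientation is detected
    from the header and recorded in the metadata.  The LFP table has a
    single ``voltage_mV`` column; the stimulus table an ``onset_s`` column.
    """
    meta = dict(meta or {})
    tdf = _read_table(Path(trace_path))
    first = tdf.columns[0]
    if first.lower() in ("roi_id", "roi"):
        roi_ids = tdf[first].astype(str).tolist()
        dff = tdf.drop(columns=[first]).to_numpy(dtype=float)
        meta["trace_orientation"] = "rois_x_frames"
    else:
        roi_ids = [str(c) for c in tdf.columns]
        dff = tdf.to_numpy(dtype=float).T
        meta["trace_orientation"] = "frames_x_rois"
    if np.any(np.isnan(dff)):
        raise FormatError(f"trace table {trace_path} has missing values (ragged rows?)")

    ldf = _read_table(Path(lfp_path))
    if "voltage_mV" not in ldf.columns:
        raise FormatError(f"LFP table {lfp_path} needs a 'voltage_mV' column")
    sdf = _read_table(Path(stim_path))
    if "onset_s" not in sdf.columns:
        raise FormatError(f"stimulus table {stim_path} needs an 'onset_s' column")

    return SessionBundle(
        roi_traces=RoiTraceSet(dff=dff, frame_rate_hz=frame_rate_hz, roi_ids=roi_ids),
        lfp=LfpRecording(samples=ldf["voltage_mV"].to_numpy(float), rate_hz=lfp_rate_hz),
        stimulus_onsets_s=sdf["onset_s"].to_numpy(float),
        metadata=meta,
    )


def write_session(bundle: SessionBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as CSV tables; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "dff.csv",
        "lfp": out / "lfp.csv",
        "stimuli": out / "stimuli.csv",
        "metadata": out / "metadata.json",
    }
    tr = bundle.roi_traces
    tdf = pd.DataFrame(tr.dff, columns=[f"f{j}" for j in range(tr.n_frames)])
    tdf.insert(0, "roi_id", tr.roi_ids)
    tdf.to_csv(paths["traces"], index=False, float_format="%.17g")
    pd.DataFrame({"voltage_mV": bundle.lfp.samples}).to_csv(
        paths["lfp"], index=False, float_format="%.17g"
    )
    pd.DataFrame({"onset_s": bundle.stimulus_onsets_s}).to_csv(
        paths["stimuli"], index=False, float_format="%.17g"
    )
    meta = dict(bundle.metadata)
    meta.update(
        frame_rate_hz=tr.frame_rate_hz,
        lfp_rate_hz=bundle.lfp.rate_hz,
        n_rois=tr.n_rois,
        n_frames=tr.n_frames,
    )
    paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
    return paths


def read_session_dir(session_dir: str | Path) -> SessionBundle:
    """Read a bundle previously written by :func:`write_session`."""
    d = Path(session_dir)
    meta = json.loads((d / "metadata.json").read_text())
    return read_session(
        d / "dff.csv",
        d / "lfp.csv",
        d / "stimuli.csv",
        meta={k: v for k, v in meta.items() if k not in ("frame_rate_hz", "lfp_rate_hz")},
        frame_rate_hz=meta.get("frame_rate_hz", 7.5),
        lfp_rate_hz=meta.get("lfp_rate_hz", 20_000.0),
    )


def write_session_hdf5(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a bundle into one HDF5 file with fixed dataset names."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=bundle.roi_traces.dff)
        f.create_dataset("lfp", data=bundle.lfp.samples)
        f.create_dataset("stimuli", data=bundle.stimulus_onsets_s)
        f.attrs["frame_rate_hz"] = bundle.roi_traces.frame_rate_hz
        f.attrs["lfp_rate_hz"] = bundle.lfp.rate_hz
        f.attrs["roi_ids"] = [s.encode() for s in bundle.roi_traces.roi_ids]
        f.attrs["metadata_json"] = json.dumps(bundle.metadata, default=str)
    return path


def read_session_hdf5(path: str | Path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        return SessionBundle(
            roi_traces=RoiTraceSet(
                dff=f["dff"][()],
                frame_rate_hz=float(f.attrs["frame_rate_hz"]),
                roi_ids=[s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["roi_ids"]],
            ),
            lfp=LfpRecording(samples=f["lfp"][()], rate_hz=float(f.attrs["lfp_rate_hz"])),
            stimulus_onsets_s=f["stimuli"][()],
            metadata=json.loads(f.attrs["metadata_json"]),
        )


def write_results(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: Any = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write per-session result tables plus a machine-readable run manifest.

    ``results`` maps table names to DataFrames; each is written as
    ``<name>.csv``.  The manifest records the configuration, the seed and
    package versions so a run can be reproduced exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc
    paths: dict[str, Path] = {}
    for name, df in results.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    import ca1ensemble

    manifest = {
        "package": "ca1ensemble",
        "version": ca1ensemble.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config.to_dict() if hasattr(config, "to_dict") else config,
        "tables": sorted(results),
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = mp
    return paths
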