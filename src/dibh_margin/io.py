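"""Disk formats: tidy trace CSV, TIFF frame stacks with JSON sidecars,
and an optional DICOM portal-image reading path.

The tidy CSV schema (columns ``patient_id, fraction, field, frame, time_s,
error_mm``; units in the column names) is shared between the synthetic
generator, the edge tracker and the variance-component fit.  Frame stacks
travel as multi-page 16-bit TIFF plus a ``<name>.json`` sidecar carrying
the acquisition geometry and the reference edge position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .epid_edge import FrameStack
from .synth import TRACE_COLUMNS


class TraceSchemaError(ValueError):
    """A trace file does not conform to the tidy schema."""


def write_trace_csv(trace: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise TraceSchemaError(f"trace is missing columns {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.loc[:, TRACE_COLUMNS].to_csv(path, index=False, float_format="%.6g")
    return path


def read_trace_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in TRACE_COLUMNS]
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise TraceSchemaError(
            f"{path.name}: expected columns {TRACE_COLUMNS}; "
            f"missing {missing or 'none'}, unknown {unknown or 'none'}")
    if not np.all(np.isfinite(df["error_mm"].to_numpy(dtype=float))):
        raise TraceSchemaError(f"{path.name}: error_mm contains non-finite values")
    return df


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

_SIDECAR_KEYS = ("sid_cm", "detector_pitch_mm", "field_long_axis", "roi",
                 "reference_position_mm", "inspiration_sign",
                 "patient_id", "fraction", "field_label")


def write_stack(stack: FrameStack, path) -> Path:
    """Write a multi-page TIFF plus its JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.uint16),
                     photometric="minisblack")
    meta = {k: getattr(stack, k) for k in _SIDECAR_KEYS}
    meta["roi"] = list(stack.roi) if stack.roi is not None else None
    meta["timestamps_s"] = (stack.timestamps_s.tolist()
                            if stack.timestamps_s is not None else None)
    meta["coordinate_convention"] = ("0-based pixel indices, positions at pixel "
                                     "centres; mm origin at frame centre along the "
                                     "measurement axis, deep inspiration positive")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> FrameStack:
    """Read a TIFF stack and its sidecar back into a :class:`FrameStack`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar metadata {sidecar.name} not found next to {path.name}; "
            "stacks need their geometry (SID, pitch, ROI, reference) to be tracked")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(
        frames=frames,
        sid_cm=float(meta["sid_cm"]),
        detector_pitch_mm=float(meta["detector_pitch_mm"]),
        field_long_axis=meta.get("field_long_axis", "rows"),
        roi=tuple(meta["roi"]) if meta.get("roi") else None,
        reference_position_mm=float(meta.get("reference_position_mm", 0.0)),
        timestamps_s=(np.asarray(meta["timestamps_s"], dtype=float)
                      if meta.get("timestamps_s") else None),
        inspiration_sign=int(meta.get("inspiration_sign", 1)),
        patient_id=int(meta.get("patient_id", 0)),
        fraction=int(meta.get("fraction", 0)),
        field_label=int(meta.get("field_label", 1)),
    )


def read_dicom_frame(path, sid_cm: float | None = None,
                     detector_pitch_mm: float | None = None) -> FrameStack:
    """Read a single portal image from DICOM into a one-frame stack.

    Geometry is taken from RT Image tags (RTImageSID, ImagePlanePixelSpacing)
    when present; explicit arguments override and are required when the
    tags are absent.
    """
    import pydicom

    ds = pydicom.dcmread(Path(path))
    frames = np.asarray(ds.pixel_array)
    if frames.ndim == 2:
        frames = frames[None]
    if sid_cm is None:
        sid_mm = getattr(ds, "RTImageSID", None)
        if sid_mm is None:
            raise ValueError(f"{path}: no RTImageSID tag; pass sid_cm explicitly")
        sid_cm = float(sid_mm) / 10.0
    if detector_pitch_mm is None:
        spacing = getattr(ds, "ImagePlanePixelSpacing", None) or \
            getattr(ds, "PixelSpacing", None)
        if spacing is None:
            raise ValueError(f"{path}: no pixel-spacing tag; pass detector_pitch_mm")
        detector_pitch_mm = float(spacing[1])
    return FrameStack(frames=frames, sid_cm=sid_cm,
                      detector_pitch_mm=detector_pitch_mm)


def write_json_report(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))
    return path
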