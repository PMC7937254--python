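"""Chest-wall edge tracking on cine portal-image frames.

Each frame of a cine EPID stack shows the chest wall as a dominant
intensity step between lung and soft tissue.  Within a region of interest
placed at isocenter level, a Canny-style pipeline (Gaussian smoothing,
gradient, non-maximum suppression, hysteresis — via scikit-image) gates
edge presence; the edge coordinate is then measured along the direction
perpendicular to the field's long axis from the smoothed 1-D gradient
profile, refined to sub-pixel precision by a parabolic fit to the gradient
peak.  Detected positions are projected to millimetres at the isocenter
plane and referenced to the DRR-derived chest-wall position, with the
deep-inspiration direction signed positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks
from skimage.feature import canny

FLAG_DETECTED = "detected"
FLAG_NO_EDGE = "no-edge"
FLAG_MULTI = "multi-edge-resolved"


def pixels_to_isocenter_mm(pixels, detector_pitch_mm: float, sid_cm: float):
    """Project a detector-plane pixel displacement to mm at the isocenter.

    ``mm = pixels * detector_pitch_mm * 100 / sid_cm`` — the divergent-beam
    back-projection from imager to isocenter plane.  Linear and
    sign-preserving.
    """
    if sid_cm <= 0:
        raise ValueError(f"sid_cm must be > 0, got {sid_cm}")
    if detector_pitch_mm <= 0:
        raise ValueError(f"detector_pitch_mm must be > 0, got {detector_pitch_mm}")
    return np.asarray(pixels, dtype=float) * detector_pitch_mm * (100.0 / sid_cm)


@dataclass(frozen=True)
class FrameStack:
    """Ordered cine frames for one field of one fraction, with geometry.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in 0-based pixel
    coordinates (stop exclusive); positions are reported at pixel centres.
    ``reference_position_mm`` is the DRR chest-wall position that defines
    zero error, on the isocenter-plane mm axis whose origin is the frame
    centre and whose positive direction is deep inspiration.
    """

    frames: np.ndarray                   # (n_frames, rows, cols)
    sid_cm: float
    detector_pitch_mm: float
    field_long_axis: str = "rows"        # "rows" | "cols"
    roi: tuple[int, int, int, int] | None = None
    reference_position_mm: float = 0.0
    timestamps_s: np.ndarray | None = None
    inspiration_sign: int = 1            # +1: deeper inspiration = increasing measurement axis
    patient_id: int = 0
    fraction: int = 0
    field_label: int = 1

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, rows, cols) array")
        if min(frames.shape[1:]) < 2:
            raise ValueError(f"frame shape {frames.shape[1:]} is degenerate")
        if self.sid_cm <= 0 or self.detector_pitch_mm <= 0:
            raise ValueError("sid_cm and detector_pitch_mm must be > 0")
        if self.field_long_axis not in ("rows", "cols"):
            raise ValueError(f"field_long_axis must be 'rows' or 'cols', got {self.field_long_axis!r}")
        object.__setattr__(self, "frames", frames)
        if self.roi is not None:
            r0, r1, c0, c1 = self.roi
            rows, cols = frames.shape[1:]
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError(f"roi {self.roi} does not lie inside frames of shape {frames.shape[1:]}")
        if self.timestamps_s is not None:
            ts = np.asarray(self.timestamps_s, dtype=float)
            if ts.size != frames.shape[0]:
                raise ValueError("timestamps_s length must match the number of frames")
            object.__setattr__(self, "timestamps_s", ts)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def isocenter_pixel_mm(self) -> float:
        """Pixel size at the isocenter plane (mm/pixel)."""
        return float(pixels_to_isocenter_mm(1.0, self.detector_pitch_mm, self.sid_cm))


@dataclass(frozen=True)
class EdgeParams:
    """Detector settings.

    ``sigma`` is the Gaussian smoothing width (pixels) used both by the
    Canny gate and the measurement profile.  Hysteresis thresholds are
    absolute gradient-magnitude values on the smoothed image; the defaults
    suit portal-image-like 16-bit data with a soft-tissue/lung step of a
    few hundred counts.
    """

    sigma: float = 2.0
    low_threshold: float = 20.0
    high_threshold: float = 60.0
    peak_rel_height: float = 0.5    # candidate peaks >= this fraction of the max
    tie_rel_height: float = 0.95    # peaks within this fraction of max are ties

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 < self.low_threshold <= self.high_threshold):
            raise ValueError("need 0 < low_threshold <= high_threshold")


def _parabolic_refine(profile: np.ndarray, idx: int) -> float:
    """Sub-pixel peak position from a 3-point parabola through the maximum."""
    if idx <= 0 or idx >= profile.size - 1:
        return float(idx)
    g0, g1, g2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = g0 - 2.0 * g1 + g2
    if denom >= 0:  # not a strict local max; keep integer position
        return float(idx)
    return float(idx + 0.5 * (g0 - g2) / denom)


def detect_edge(
    frame: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    params: EdgeParams | None = None,
    reference_px: float | None = None,
    prev_px: float | None = None,
) -> tuple[float, str]:
    """Locate the chest-wall edge in one frame.

    Returns ``(position, flag)`` with the position in full-frame pixel
    coordinates along the measurement (column) axis, or NaN with flag
    ``"no-edge"`` when nothing survives hysteresis.  When several edges
    compete (e.g. a rib), the one with the largest integrated gradient
    magnitude wins; near-ties are broken toward ``prev_px`` (the previous
    frame's edge), else toward ``reference_px``, and the frame is flagged
    ``"multi-edge-resolved"``.
    """
    params = params or EdgeParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D array")
    if roi is None:
        roi = (0, img.shape[0], 0, img.shape[1])
    r0, r1, c0, c1 = roi
    if r1 - r0 < 2 or c1 - c0 < 3:
        raise ValueError(f"roi {roi} is degenerate")
    sub = img[r0:r1, c0:c1]

    if np.ptp(sub) == 0:
        return float("nan"), FLAG_NO_EDGE
    edge_mask = canny(sub, sigma=params.sigma,
                      low_threshold=params.low_threshold,
                      high_threshold=params.high_threshold)
    if not edge_mask.any():
        return float("nan"), FLAG_NO_EDGE

    grad = np.gradient(gaussian_filter(sub, params.sigma), axis=1)
    profile = np.mean(np.abs(grad), axis=0)
    peaks, props = find_peaks(profile, height=params.peak_rel_height * profile.max())
    if peaks.size == 0:
        # Profile maximal at the ROI boundary: no interior peak to refine.
        peaks = np.array([int(np.argmax(profile))])
        heights = profile[peaks]
    else:
        heights = props["peak_heights"]

    flag = FLAG_DETECTED
    best = peaks[int(np.argmax(heights))]
    if peaks.size > 1:
        ties = peaks[heights >= params.tie_rel_height * heights.max()]
        if ties.size > 1:
            anchor = prev_px if prev_px is not None else reference_px
            if anchor is not None:
                best = ties[int(np.argmin(np.abs(ties + c0 - anchor)))]
        flag = FLAG_MULTI
    return c0 + _parabolic_refine(profile, int(best)), flag


@dataclass(frozen=True)
class EdgeTrace:
    """Per-frame edge positions and signed errors for one stack.

    ``data`` columns: frame, time_s, detected_px, detected_position_mm,
    error_mm, quality_flag.  Frames flagged no-edge carry NaN positions and
    are excluded from error statistics; ``report`` counts them.
    """

    data: pd.DataFrame
    report: dict
    patient_id: int = 0
    fraction: int = 0
    field_label: int = 1

    def detected(self) -> pd.DataFrame:
        return self.data[self.data["quality_flag"] != FLAG_NO_EDGE]

    def to_tidy(self) -> pd.DataFrame:
        """Detected frames in the shared tidy trace schema."""
        det = self.detected()
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "fraction": self.fraction,
            "field": self.field_label,
            "frame": det["frame"].to_numpy(),
            "time_s": det["time_s"].to_numpy(),
            "error_mm": det["error_mm"].to_numpy(),
        })


def extract_trace(
    stack: FrameStack,
    params: EdgeParams | None = None,
    no_edge_warn_fraction: float = 0.5,
) -> EdgeTrace:
    """Track the chest wall through a stack and return signed errors.

    Runs :func:`detect_edge` on every frame, converts detector pixels to mm
    at the isocenter plane, subtracts the reference (DRR) position and
    applies the inspiration sign convention.  The mm origin is the frame
    centre along the measurement axis.
    """
    params = params or EdgeParams()
    frames = stack.frames
    roi = stack.roi or (0, frames.shape[1], 0, frames.shape[2])
    if stack.field_long_axis == "cols":
        frames = frames.transpose(0, 2, 1)
        r0, r1, c0, c1 = roi
        roi = (c0, c1, r0, r1)

    iso = stack.isocenter_pixel_mm
    centre = (frames.shape[2] - 1) / 2.0
    ref_px = centre + stack.inspiration_sign * stack.reference_position_mm / iso

    rows = []
    prev: float | None = None
    for k in range(frames.shape[0]):
        pos_px, flag = detect_edge(frames[k], roi, params,
                                   reference_px=ref_px, prev_px=prev)
        if flag == FLAG_NO_EDGE:
            pos_mm = err_mm = float("nan")
        else:
            pos_mm = stack.inspiration_sign * (pos_px - centre) * iso
            err_mm = pos_mm - stack.reference_position_mm
            prev = pos_px
        t = stack.timestamps_s[k] if stack.timestamps_s is not None else float(k)
        rows.append((k, t, pos_px, pos_mm, err_mm, flag))

    data = pd.DataFrame(rows, columns=["frame", "time_s", "detected_px",
                                       "detected_position_mm", "error_mm",
                                       "quality_flag"])
    n = len(data)
    n_no_edge = int((data["quality_flag"] == FLAG_NO_EDGE).sum())
    report = {
        "n_frames": n,
        "n_detected": n - n_no_edge,
        "n_no_edge": n_no_edge,
        "n_multi_edge_resolved": int((data["quality_flag"] == FLAG_MULTI).sum()),
        "no_edge_fraction": n_no_edge / n,
        "warning": n_no_edge / n > no_edge_warn_fraction,
        "isocenter_pixel_mm": iso,
        "reference_position_mm": stack.reference_position_mm,
        "coordinate_convention": "0-based pixel indices, positions at pixel centres; "
                                 "mm origin at frame centre, deep inspiration positive",
    }
    return EdgeTrace(data=data, report=report, patient_id=stack.patient_id,
                     fraction=stack.fraction, field_label=stack.field_label)
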