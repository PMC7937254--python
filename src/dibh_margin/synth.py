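"""Synthetic data for the breath-hold error pipeline.

Generates (a) tidy positional-error traces drawn from the nested Gaussian
model ``y = M + a_patient + b_fraction(patient) + e``, (b) RPM-like
abdominal-wall traces shaped as a breath-hold plateau, and (c) portal-image
frame stacks containing an oriented chest-wall-like step edge at a known
isocenter-plane position.  Every generator is seeded and bit-reproducible,
so the downstream edge detector, variance-component fit and margin recipe
can all be tested against known ground truth.

Defaults reproduce the study conditions: 25 patients x 16 fractions x 2
tangential fields, breath-holds of 20.4 +/- 1.7 s, nested SDs
(0.82, 1.19, 1.63) mm around an overall mean of 0.30 mm, and a cine frame
rate chosen so the cohort totals ~3.1e5 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .epid_edge import FrameStack

#: Column schema shared by every tidy error trace in the package.
TRACE_COLUMNS = ["patient_id", "fraction", "field", "frame", "time_s", "error_mm"]

#: Default cine acquisition rate (Hz).  The study reports 309,609 frames over
#: 25 patients x 16 fractions x 2 fields with ~20.4 s breath-holds; 19 Hz
#: reproduces that total to ~0.15%.
DEFAULT_FRAME_RATE_HZ = 19.0


class SimulationSpecError(ValueError):
    """A simulation parameter violates its constraints."""


@dataclass(frozen=True)
class SimulationSpec:
    """Design and ground truth for a synthetic error-trace cohort.

    ``frames_per_field=None`` draws the per-field frame count as
    ``round(breath_hold_s * frame_rate_hz)`` with one breath-hold per field,
    giving the unbalanced design the model expects; an integer fixes the
    count for balanced test designs.
    """

    n_patients: int = 25
    n_fractions: int = 16
    n_fields: int = 2
    frames_per_field: int | None = None
    mean_m: float = 0.30        # mm, overall mean M
    sigma_pt: float = 0.82      # mm, inter-patient SD
    sigma_fr: float = 1.19      # mm, inter-fraction SD
    sigma_intra: float = 1.63   # mm, intra-fraction (residual) SD
    breath_hold_mean_s: float = 20.4
    breath_hold_sd_s: float = 1.7
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_fractions", "n_fields"):
            if int(getattr(self, name)) < 1:
                raise SimulationSpecError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.frames_per_field is not None and int(self.frames_per_field) < 1:
            raise SimulationSpecError(f"frames_per_field must be >= 1, got {self.frames_per_field}")
        for name in ("sigma_pt", "sigma_fr", "sigma_intra", "breath_hold_sd_s"):
            if getattr(self, name) < 0:
                raise SimulationSpecError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.frame_rate_hz <= 0:
            raise SimulationSpecError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.breath_hold_mean_s <= 0:
            raise SimulationSpecError(f"breath_hold_mean_s must be > 0, got {self.breath_hold_mean_s}")

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=int(seed))


def _frames_for_field(spec: SimulationSpec, rng: np.random.Generator) -> int:
    if spec.frames_per_field is not None:
        return int(spec.frames_per_field)
    hold_s = rng.normal(spec.breath_hold_mean_s, spec.breath_hold_sd_s)
    return max(1, int(round(hold_s * spec.frame_rate_hz)))


def simulate_errors(spec: SimulationSpec) -> pd.DataFrame:
    """Draw a tidy error trace from the nested random-effect model.

    Returns a DataFrame with columns ``patient_id, fraction, field, frame,
    time_s, error_mm``.  Patient effects are shared across the patient's
    fractions; fraction effects are shared across the two fields of that
    fraction (fields are labels, not a variance level); residuals are
    independent per frame.
    """
    rng = np.random.default_rng(spec.seed)
    chunks: list[pd.DataFrame] = []
    for p in range(spec.n_patients):
        a_p = rng.normal(0.0, spec.sigma_pt)
        for f in range(spec.n_fractions):
            b_pf = rng.normal(0.0, spec.sigma_fr)
            for fld in range(spec.n_fields):
                k = _frames_for_field(spec, rng)
                e = rng.normal(0.0, spec.sigma_intra, size=k)
                frames = np.arange(k)
                chunks.append(pd.DataFrame({
                    "patient_id": np.full(k, p + 1, dtype=np.int64),
                    "fraction": np.full(k, f + 1, dtype=np.int64),
                    "field": np.full(k, fld + 1, dtype=np.int64),
                    "frame": frames,
                    "time_s": frames / spec.frame_rate_hz,
                    "error_mm": spec.mean_m + a_p + b_pf + e,
                }))
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# RPM-like abdominal-wall traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RpmTrace:
    """Abdominal AP wall position during one breath-hold.

    The motion amplitude statistic is ``max(position) - min(position)``,
    the range of the wall position over the hold.
    """

    time_s: np.ndarray
    position_mm: np.ndarray
    gate_upper_mm: float
    gate_lower_mm: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.position_mm, dtype=float)
        if t.size != p.size:
            raise ValueError("time_s and position_mm must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "position_mm", p)


def compute_amplitude(trace: RpmTrace) -> float:
    """Amplitude of a trace: max minus min of the wall position (mm)."""
    pos = np.asarray(trace.position_mm, dtype=float)
    if pos.size == 0:
        raise ValueError("cannot compute the amplitude of an empty trace")
    return float(pos.max() - pos.min())


def simulate_rpm_trace(
    duration_s: float,
    amplitude_mm: float,
    baseline_mm: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 25.0,
) -> RpmTrace:
    """Generate a breath-hold-plateau trace with an exact target amplitude.

    The waveform is a plateau carrying a two-tone sinusoidal ripple plus a
    slow drift, rescaled so that ``max - min`` equals ``amplitude_mm``
    exactly (to float precision).  Gate thresholds bracket the plateau with
    a small guard band.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if amplitude_mm < 0:
        raise ValueError(f"amplitude_mm must be >= 0, got {amplitude_mm}")
    if sample_rate_hz <= 0:
        raise ValueError(f"sample_rate_hz must be > 0, got {sample_rate_hz}")
    rng = np.random.default_rng(seed)
    n = max(2, int(round(duration_s * sample_rate_hz)))
    t = np.arange(n) / sample_rate_hz
    # Cardiac-ish ripple + slower wander; phases randomised per seed.
    ph1, ph2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    raw = (np.sin(2.0 * np.pi * 1.1 * t + ph1)
           + 0.4 * np.sin(2.0 * np.pi * 0.23 * t + ph2)
           + 0.15 * (t / t[-1]))
    span = raw.max() - raw.min()
    if amplitude_mm == 0.0 or span == 0.0:
        pos = np.full(n, baseline_mm)
    else:
        pos = baseline_mm + amplitude_mm * (raw - raw.min()) / span
    guard = max(0.25, 0.25 * amplitude_mm)
    return RpmTrace(
        time_s=t,
        position_mm=pos,
        gate_upper_mm=float(pos.max() + guard),
        gate_lower_mm=float(pos.min() - guard),
    )


# ---------------------------------------------------------------------------
# Portal-image-like frame stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Geometry and appearance of rendered portal-image frames.

    The detector is square (``detector_size_cm`` per side); pixel pitch
    follows from the frame shape, and the pixel size at the isocenter plane
    is pitch scaled by 100/SID.  The rendered edge is a smooth intensity
    step (an erf profile of width ``blur_sigma_px``) from lung-side low to
    tissue-side high running along the field's long axis (image rows),
    optionally tilted by ``edge_angle_deg``.
    """

    frame_shape: tuple[int, int] = (192, 256)   # rows, cols
    detector_size_cm: float = 43.0
    sid_cm: float = 160.0
    edge_position_mm: float = 0.0   # true edge at isocenter plane, 0 = frame centre
    edge_angle_deg: float = 0.0
    contrast: float = 1200.0        # intensity step height (16-bit counts)
    base_level: float = 400.0
    noise_sd: float = 40.0          # additive Gaussian noise (counts)
    blur_sigma_px: float = 1.5

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"frame_shape must be positive, got {self.frame_shape}")
        if self.sid_cm <= 0:
            raise ValueError(f"sid_cm must be > 0, got {self.sid_cm}")
        if self.detector_size_cm <= 0:
            raise ValueError(f"detector_size_cm must be > 0, got {self.detector_size_cm}")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")

    @property
    def detector_pitch_mm(self) -> float:
        """Pixel pitch at the detector along the measurement (column) axis."""
        return self.detector_size_cm * 10.0 / self.frame_shape[1]

    @property
    def isocenter_pixel_mm(self) -> float:
        """Pixel size projected to the isocenter plane."""
        return self.detector_pitch_mm * 100.0 / self.sid_cm


def render_frames(
    spec: SyntheticImageSpec,
    per_frame_offsets_mm,
    seed: int = 0,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    roi_half_width_px: int | None = None,
    patient_id: int = 0,
    fraction: int = 0,
    field_label: int = 1,
) -> FrameStack:
    """Render a stack of frames with the edge at known per-frame positions.

    Frame ``k`` carries the edge at ``spec.edge_position_mm + offsets[k]``
    (mm at isocenter, positive toward increasing column index — the deep-
    inspiration direction).  The stack's reference position is
    ``spec.edge_position_mm``, so a perfect detector recovers exactly the
    offsets as errors.
    """
    offsets = np.atleast_1d(np.asarray(per_frame_offsets_mm, dtype=float))
    if offsets.size == 0:
        raise ValueError("per_frame_offsets_mm must contain at least one frame")
    if not np.all(np.isfinite(offsets)):
        raise ValueError("per_frame_offsets_mm must be finite")
    rows, cols = spec.frame_shape
    rng = np.random.default_rng(seed)
    iso_px = spec.isocenter_pixel_mm
    centre_col = (cols - 1) / 2.0
    r = np.arange(rows, dtype=float)[:, None]
    c = np.arange(cols, dtype=float)[None, :]
    tilt = np.tan(np.deg2rad(spec.edge_angle_deg))
    width = max(spec.blur_sigma_px, 1e-6)

    frames = np.empty((offsets.size, rows, cols), dtype=np.uint16)
    for k, off in enumerate(offsets):
        edge_col = centre_col + (spec.edge_position_mm + off) / iso_px + tilt * (r - (rows - 1) / 2.0)
        img = spec.base_level + spec.contrast * 0.5 * (1.0 + erf((c - edge_col) / (np.sqrt(2.0) * width)))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[k] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    if roi_half_width_px is None:
        roi_half_width_px = cols // 4
    c0 = max(0, int(np.floor(centre_col)) - roi_half_width_px)
    c1 = min(cols, int(np.ceil(centre_col)) + roi_half_width_px + 1)
    roi = (rows // 4, rows - rows // 4, c0, c1)

    return FrameStack(
        frames=frames,
        sid_cm=spec.sid_cm,
        detector_pitch_mm=spec.detector_pitch_mm,
        field_long_axis="rows",
        roi=roi,
        reference_position_mm=spec.edge_position_mm,
        timestamps_s=np.arange(offsets.size) / frame_rate_hz,
        patient_id=patient_id,
        fraction=fraction,
        field_label=field_label,
    )
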