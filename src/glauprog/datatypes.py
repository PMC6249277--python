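"""Core per-visit record types: one perimetry exam, one OCT circle scan.

Both types validate their invariants on construction and are plain frozen
dataclasses so that equality and hashing behave predictably in tests and
round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .grids import GRID_24_2

#: Number of thickness samples along the 3.46 mm circle scan.
N_PROFILE_SAMPLES = 768

#: Circle-scan diameter in millimetres (Spectralis cpRNFL protocol).
SCAN_DIAMETER_MM = 3.46

LATERALITIES = ("OD", "OS")


@dataclass(frozen=True)
class VisualFieldExam:
    """One 24-2 standard automated perimetry test for one eye.

    ``points`` maps the 52 non-blind-spot grid locations (OD-frame signed
    degrees) to ``(threshold_dB, total_deviation_dB)`` pairs.  Reliability
    indices are proportions in [0, 1].
    """

    eye_id: str
    subject_id: str
    laterality: str
    time_years: float
    points: dict = field(default_factory=dict)
    md_dB: float = float("nan")
    psd_dB: float = float("nan")
    fixation_loss: float = 0.0
    false_pos: float = 0.0
    false_neg: float = 0.0

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"unknown laterality {self.laterality!r}")
        expected = set(GRID_24_2) if self.laterality == "OD" else {
            (-x, y) for x, y in GRID_24_2}
        if set(self.points) != expected:
            raise ValidationError(
                f"exam must cover exactly the 52 analyzed 24-2 points in the "
                f"{self.laterality} frame (got {len(self.points)})")
        for name in ("fixation_loss", "false_pos", "false_neg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.time_years < 0:
            raise ValidationError("time_years must be >= 0")

    def values(self, kind: str = "threshold") -> dict:
        """Per-point dB values, ``kind`` in {'threshold', 'total_deviation'}."""
        idx = {"threshold": 0, "total_deviation": 1}[kind]
        return {p: v[idx] for p, v in self.points.items()}

    def is_reliable(self, fl_max=0.20, fp_max=1.0 / 3.0, fn_max=1.0 / 3.0) -> bool:
        """Apply the standard reliability rule (strict upper bounds)."""
        return (self.fixation_loss < fl_max
                and self.false_pos < fp_max
                and self.false_neg < fn_max)


@dataclass(frozen=True)
class CpRNFLProfile:
    """One circumpapillary RNFL thickness profile (768 samples, um).

    ``thickness_um`` runs around the full circle in the instrument's export
    order; in this package's canonical convention sample ``k`` is centred at
    angle ``(k + 0.5) * 360/768`` degrees from the temporal meridian,
    increasing through superior, in the right-eye frame.
    """

    eye_id: str
    subject_id: str
    laterality: str
    time_years: float
    thickness_um: tuple = ()
    fovea_onh_angle_deg: float = float("nan")
    scan_diameter_mm: float = SCAN_DIAMETER_MM

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"unknown laterality {self.laterality!r}")
        arr = np.asarray(self.thickness_um, dtype=float)
        if arr.shape != (N_PROFILE_SAMPLES,):
            raise ValidationError(
                f"profile must have exactly {N_PROFILE_SAMPLES} samples, got {arr.shape}")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr >= 300):
            raise ValidationError("thickness values must be finite and in [0, 300) um")
        object.__setattr__(self, "thickness_um", tuple(float(v) for v in arr))
        if self.time_years < 0:
            raise ValidationError("time_years must be >= 0")

    @property
    def thickness(self) -> np.ndarray:
        return np.asarray(self.thickness_um, dtype=float)

    def with_thickness(self, arr) -> "CpRNFLProfile":
        return replace(self, thickness_um=tuple(float(v) for v in arr))
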