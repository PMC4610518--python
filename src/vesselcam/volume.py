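"""Frustum volume computations for a conically shaped glass.

The liquid body between two horizontal sections of a cone is a conical
frustum with volume ``(pi/3) * h * (r1^2 + r2^2 + r1*r2)`` (mm^3; divided
by 1000 for mL).  Volumes are always referenced to a fixed section — by
default the section at the topmost calibrated level — so that differences
between two states of the glass estimate the consumed amount.

Two referencing conventions are exposed.  The default ``"table"``
convention (h = the row's own level, r1 = the reference radius, r2 = the
radius at the row's level) is the one that reproduces the bundled
calibration table's printed volume column; the literal ``"between_levels"``
convention (h = reference level minus row level) is kept for comparison and
for differencing two arbitrary measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import Exp2Model, Poly2Model, predict_area, predict_level
from .ellipse import Measurement

__all__ = [
    "VolumeEstimate",
    "frustum_volume",
    "radius_from_area",
    "ground_truth_volume",
    "inferred_volume",
    "volume_difference",
]


@dataclass(frozen=True)
class VolumeEstimate:
    volume_ml: float
    h_mm: float
    r1_mm: float
    r2_mm: float
    provenance: str  # "ground_truth" | "inferred"

    def __post_init__(self) -> None:
        if self.volume_ml < 0 or self.h_mm < 0:
            raise ValueError("volume and height must be non-negative")
        if self.r1_mm < 0 or self.r2_mm < 0:
            raise ValueError("radii must be non-negative")


def frustum_volume(h_mm: float, r1_mm: float, r2_mm: float) -> float:
    """Conical-frustum volume in mL: (pi/3) h (r1^2 + r2^2 + r1 r2) / 1000."""
    if h_mm < 0 or r1_mm < 0 or r2_mm < 0:
        raise ValueError("frustum arguments must be non-negative")
    return float(np.pi / 3.0 * h_mm * (r1_mm**2 + r2_mm**2 + r1_mm * r2_mm) / 1000.0)


def radius_from_area(area_mm2: float) -> float:
    """Radius of the circular section with the given area: sqrt(area/pi)."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return float(np.sqrt(area_mm2 / np.pi))


def _volume(h: float, r1: float, r2: float, provenance: str) -> VolumeEstimate:
    return VolumeEstimate(volume_ml=frustum_volume(h, r1, r2), h_mm=float(h),
                          r1_mm=float(r1), r2_mm=float(r2), provenance=provenance)


def ground_truth_volume(level_mm: float, radius_mm: float,
                        reference: tuple[float, float],
                        convention: str = "table") -> VolumeEstimate:
    """Volume of a table row from its measured level and wall radius.

    ``reference`` is the (level_mm, radius_mm) of the topmost calibrated
    row.  Under the default ``"table"`` convention the frustum height is the
    row's own level with r1 the reference radius — the convention that
    reproduces the calibration table's printed volume column.  Under
    ``"between_levels"`` the height is the drop from the reference level.
    """
    ref_level, ref_radius = reference
    if level_mm < 0 or radius_mm <= 0 or ref_radius <= 0:
        raise ValueError("levels must be non-negative and radii positive")
    if convention == "table":
        h = level_mm
    elif convention == "between_levels":
        h = ref_level - level_mm
        if h < 0:
            raise ValueError("row level above the reference level")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return _volume(h, ref_radius, radius_mm, "ground_truth")


def inferred_volume(m: Measurement, level_model: Poly2Model, area_model: Exp2Model,
                    reference: tuple[float, float],
                    convention: str = "table") -> VolumeEstimate:
    """Volume from a pixel measurement via the calibrated conversions."""
    level_mm = float(predict_level(level_model, m.level_px))
    radius_mm = radius_from_area(float(predict_area(area_model, m.area_px2)))
    est = ground_truth_volume(level_mm, radius_mm, reference, convention)
    return VolumeEstimate(volume_ml=est.volume_ml, h_mm=est.h_mm, r1_mm=est.r1_mm,
                          r2_mm=est.r2_mm, provenance="inferred")


def volume_difference(m1: Measurement, m2: Measurement, level_model: Poly2Model,
                      area_model: Exp2Model) -> float:
    """Consumed volume between two measurements, in mL.

    The two pixel measurements are converted to (level mm, radius mm) with
    the calibration models and the frustum between the two sections is
    evaluated with h = |l1 - l2|.  Symmetric in its arguments.
    """
    l1 = float(predict_level(level_model, m1.level_px))
    l2 = float(predict_level(level_model, m2.level_px))
    r1 = radius_from_area(float(predict_area(area_model, m1.area_px2)))
    r2 = radius_from_area(float(predict_area(area_model, m2.area_px2)))
    return frustum_volume(abs(l1 - l2), r1, r2)
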