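"""Baseplate planning geometry for RSA angle correction.

Inclination of the glenoid face is corrected to a 0° RSA angle either by
eccentric reaming (medializing the centre of rotation) or by a full wedge —
metallic (MA) or autologous bone graft (BIO) — under the baseplate. For a
full wedge hinged at one rim of a circular baseplate of diameter ``D`` and
wedge angle ``theta``, the far rim is raised by ``D * tan(theta)`` and the
joint line is lateralized relative to the hinged edge by the full-wedge rim
height ``(D / 2) * tan(theta)`` at the baseplate centre axis. For the 24 mm
baseplate this yields 2.1 mm at 10° and 4.4 mm at 20°. Corrective reaming
removes the same wedge of bone instead, so the centre of rotation medializes
by the same magnitude.

Seating quality is expressed as a contact fraction: the share of footprint
sample points where the gap between the seated wedge underside and the
prepared bone surface is within a contact tolerance. The wedge may be
rotated about the implant axis to reach the 80% minimum contact threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BASEPLATE_DIAMETER_MM",
    "DEFAULT_CONTACT_TOLERANCE_MM",
    "MIN_CONTACT_FRACTION",
    "PlanningError",
    "BaseplatePlan",
    "wedge_lateral_offset",
    "reaming_medialization",
    "disc_sample_points",
    "contact_fraction",
    "optimize_wedge_rotation",
]

DEFAULT_BASEPLATE_DIAMETER_MM: float = 24.0
DEFAULT_CONTACT_TOLERANCE_MM: float = 0.1
MIN_CONTACT_FRACTION: float = 0.8


class PlanningError(ValueError):
    pass


@dataclass
class BaseplatePlan:
    """Resolved placement plan for one specimen.

    ``method`` is ``ream`` (reference group), ``MA`` (metallic augment) or
    ``BIO`` (bone graft). ``lateral_offset_mm`` is signed: positive lateral
    (augments), negative medial (reaming). The 3 mm inferior-rim offset and
    glenosphere inferior overhang are placement rules recorded as-is.
    """

    correction_deg: float
    method: str
    baseplate_diameter_mm: float = DEFAULT_BASEPLATE_DIAMETER_MM
    inferior_rim_offset_mm: float = 3.0
    target_inclination_deg: float = 0.0
    target_retroversion_deg: float = 5.0
    glenosphere_inferior_overhang_mm: float = 3.0
    wedge_rotation_deg: float | None = None
    lateral_offset_mm: float = field(init=False)
    contact_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("ream", "MA", "BIO"):
            raise PlanningError(f"unknown correction method {self.method!r}")
        if self.correction_deg not in (0.0, 10.0, 20.0):
            raise PlanningError("correction angle must be 0, 10 or 20 degrees")
        if self.method == "ream":
            self.lateral_offset_mm = reaming_medialization(
                self.correction_deg, self.baseplate_diameter_mm
            )
        else:
            self.lateral_offset_mm = wedge_lateral_offset(
                self.correction_deg, self.baseplate_diameter_mm
            )
        if self.contact_fraction is not None and not (0 <= self.contact_fraction <= 1):
            raise PlanningError("contact fraction must lie in [0, 1]")


def wedge_lateral_offset(
    correction_deg: float,
    baseplate_diameter_mm: float = DEFAULT_BASEPLATE_DIAMETER_MM,
) -> float:
    """Additional lateral offset of a full-wedge augment, in mm (0.1 mm).

    Full-wedge rim height at the baseplate radius: ``(D/2) * tan(theta)``.
    """
    if not 0 <= correction_deg < 90:
        raise PlanningError("correction angle must lie in [0, 90) degrees")
    if baseplate_diameter_mm <= 0:
        raise PlanningError("baseplate diameter must be positive")
    offset = (baseplate_diameter_mm / 2.0) * math.tan(math.radians(correction_deg))
    return round(offset, 1)


def reaming_medialization(
    correction_deg: float,
    baseplate_diameter_mm: float = DEFAULT_BASEPLATE_DIAMETER_MM,
) -> float:
    """COR medialization from corrective reaming: same magnitude as the
    wedge lateral offset at equal angle, signed medial (negative)."""
    return -wedge_lateral_offset(correction_deg, baseplate_diameter_mm)


def disc_sample_points(
    diameter_mm: float = DEFAULT_BASEPLATE_DIAMETER_MM, spacing_mm: float = 0.5
) -> np.ndarray:
    """Regular-grid sample points (x, y) covering the baseplate footprint."""
    r = diameter_mm / 2.0
    ax = np.arange(-r, r + spacing_mm / 2, spacing_mm)
    xx, yy = np.meshgrid(ax, ax)
    keep = xx**2 + yy**2 <= r**2
    return np.column_stack([xx[keep], yy[keep]])


def _wedge_underside(
    points_xy: np.ndarray, wedge_angle_deg: float, rotation_deg: float
) -> np.ndarray:
    """Height of the wedge underside above its hinged edge, at each (x, y).

    The underside is a plane inclined by the wedge angle; ``rotation_deg``
    rotates the downhill direction about the implant axis.
    """
    phi = math.radians(rotation_deg)
    along = points_xy[:, 0] * math.cos(phi) + points_xy[:, 1] * math.sin(phi)
    return along * math.tan(math.radians(wedge_angle_deg))


def contact_fraction(
    surface_heights: np.ndarray,
    points_xy: np.ndarray,
    wedge_angle_deg: float,
    rotation_deg: float = 0.0,
    tolerance_mm: float = DEFAULT_CONTACT_TOLERANCE_MM,
) -> float:
    """Fraction of footprint points in contact after seating the wedge.

    ``surface_heights`` are prepared-bone heights (mm, any datum) sampled at
    ``points_xy`` over the footprint. The wedge is translated along the
    implant axis until it first touches the surface (minimum gap zero);
    contact holds wherever the remaining gap is within ``tolerance_mm``.
    """
    surface_heights = np.asarray(surface_heights, dtype=float)
    points_xy = np.asarray(points_xy, dtype=float)
    if surface_heights.shape[0] != points_xy.shape[0] or surface_heights.size == 0:
        raise PlanningError("surface must be sampled at every footprint point")
    underside = _wedge_underside(points_xy, wedge_angle_deg, rotation_deg)
    # seat: raise the wedge until nothing penetrates the bone
    gap = (underside - surface_heights) - (underside - surface_heights).min()
    return float(np.mean(gap <= tolerance_mm))


def optimize_wedge_rotation(
    surface_heights: np.ndarray,
    points_xy: np.ndarray,
    wedge_angle_deg: float,
    tolerance_mm: float = DEFAULT_CONTACT_TOLERANCE_MM,
    threshold: float = MIN_CONTACT_FRACTION,
    grid_deg: float = 1.0,
) -> tuple[float | None, float]:
    """Smallest-magnitude wedge rotation reaching the contact threshold.

    Searches a uniform grid over [−180°, 180°) ordered by absolute rotation
    and returns ``(rotation_deg, fraction)`` for the first angle whose
    contact fraction reaches ``threshold``. If no rotation achieves it,
    returns ``(None, best_fraction)`` — a valid, flagged outcome.
    """
    angles = np.arange(-180.0, 180.0, grid_deg)
    order = np.lexsort((angles < 0, np.abs(angles)))  # |angle| asc, +ve first
    best = 0.0
    for ang in angles[order]:
        frac = contact_fraction(
            surface_heights, points_xy, wedge_angle_deg, ang, tolerance_mm
        )
        if frac >= threshold:
            return float(ang), frac
        best = max(best, frac)
    return None, best
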