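"""Anatomical volumes of interest on the glenoid.

Three VOIs drive the density analysis: the global glenoid mask (supplied as a
label map, not computed here), and two coaxial cylinders along the scapular
axis — the glenoid-vault cylinder spanning from the articular surface to the
medial cortex, and the subchondral cylinder, one third of the vault depth,
starting just medial to the articular cortex so that a superficial layer of
(potentially necrotic) bone is excluded.

Construction rules
------------------
* axis: through the glenoid centre and the root of the scapular spine,
  oriented lateral→medial;
* cylinder diameter: 50% of the 3-to-9 o'clock glenoid width measured at the
  articular surface;
* vault depth: articular surface to medial cortex along the axis;
* subchondral depth: one third of the vault depth, offset medially past the
  articular cortex by a configurable necrosis margin (default 2 mm).

Rasterization uses a voxel-centre-in-solid rule (pure pixel counting, no
partial volumes). Depth intervals are half-open ``[start, start + depth)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .volume import CtVolume, voxel_centers

__all__ = [
    "DEFAULT_NECROSIS_OFFSET_MM",
    "GeometryError",
    "GlenoidLandmarks",
    "CylinderVoi",
    "derive_scapular_axis",
    "cylinder_diameter",
    "construct_vault_cylinder",
    "construct_subchondral_cylinder",
    "rasterize_voi",
    "load_landmarks",
    "save_landmarks",
]

#: Margin past the articular cortex at which the subchondral cylinder starts.
DEFAULT_NECROSIS_OFFSET_MM: float = 2.0


class GeometryError(ValueError):
    """Degenerate or inconsistent landmark geometry."""


@dataclass(frozen=True)
class GlenoidLandmarks:
    """Named glenoid landmarks in world millimetres.

    ``articular_cortex_level`` and ``medial_cortex_level`` are scalar
    positions along the scapular axis measured from the glenoid centre
    (positive medially); the medial cortex must lie medial to the articular
    surface.
    """

    glenoid_center: np.ndarray
    spine_root: np.ndarray
    inferior_rim: np.ndarray
    clock3: np.ndarray
    clock9: np.ndarray
    articular_cortex_level: float
    medial_cortex_level: float

    def __post_init__(self) -> None:
        for f in ("glenoid_center", "spine_root", "inferior_rim", "clock3", "clock9"):
            object.__setattr__(self, f, np.asarray(getattr(self, f), dtype=float))
        if np.allclose(self.clock3, self.clock9):
            raise GeometryError("3 and 9 o'clock landmarks coincide")
        if np.allclose(self.spine_root, self.glenoid_center):
            raise GeometryError("spine root coincides with glenoid centre")
        if not self.medial_cortex_level > self.articular_cortex_level:
            raise GeometryError(
                "medial cortex must lie medial to the articular surface "
                "(axis oriented lateral→medial)"
            )


@dataclass(frozen=True)
class CylinderVoi:
    """Finite right cylinder: base point, unit axis (lateral→medial),
    diameter, depth, and a start offset along the axis from the base point."""

    base_point: np.ndarray
    axis: np.ndarray
    diameter_mm: float
    depth_mm: float
    start_offset_mm: float = 0.0
    name: str = "cylinder"

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_point", np.asarray(self.base_point, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise GeometryError("cylinder axis must be non-zero")
        object.__setattr__(self, "axis", axis / n)
        if self.diameter_mm <= 0 or self.depth_mm <= 0:
            raise GeometryError("diameter and depth must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def analytic_volume_mm3(self) -> float:
        return float(np.pi * self.radius_mm**2 * self.depth_mm)


def derive_scapular_axis(lm: GlenoidLandmarks) -> tuple[np.ndarray, np.ndarray]:
    """Scapular axis: glenoid centre → root of the scapular spine.

    Returns ``(anchor_point, unit_axis)`` anchored at the glenoid centre and
    oriented medially (towards the spine root).
    """
    d = lm.spine_root - lm.glenoid_center
    n = np.linalg.norm(d)
    if n == 0:
        raise GeometryError("axis degenerate: spine root equals glenoid centre")
    return lm.glenoid_center.copy(), d / n


def cylinder_diameter(lm: GlenoidLandmarks) -> float:
    """Cylinder diameter: 50% of the 3-to-9 o'clock glenoid distance."""
    width = float(np.linalg.norm(lm.clock3 - lm.clock9))
    if width == 0:
        raise GeometryError("zero 3-9 o'clock distance")
    return 0.5 * width


def construct_vault_cylinder(
    lm: GlenoidLandmarks, axis: tuple[np.ndarray, np.ndarray] | None = None
) -> CylinderVoi:
    """Glenoid-vault cylinder: articular surface down to the medial cortex."""
    point, direction = axis if axis is not None else derive_scapular_axis(lm)
    depth = lm.medial_cortex_level - lm.articular_cortex_level
    if depth <= 0:
        raise GeometryError("non-positive vault depth")
    return CylinderVoi(
        base_point=point + direction * lm.articular_cortex_level,
        axis=direction,
        diameter_mm=cylinder_diameter(lm),
        depth_mm=float(depth),
        start_offset_mm=0.0,
        name="glenoid_vault",
    )


def construct_subchondral_cylinder(
    vault: CylinderVoi,
    necrosis_offset_mm: float = DEFAULT_NECROSIS_OFFSET_MM,
) -> CylinderVoi:
    """Subchondral cylinder: one third of the vault depth, starting medial to
    the articular cortex by ``necrosis_offset_mm``."""
    if necrosis_offset_mm < 0:
        raise GeometryError("necrosis offset must be non-negative")
    depth = vault.depth_mm / 3.0
    start = vault.start_offset_mm + necrosis_offset_mm
    if start + depth > vault.start_offset_mm + vault.depth_mm + 1e-9:
        raise GeometryError("subchondral cylinder would exceed the vault depth")
    return replace(vault, start_offset_mm=start, depth_mm=depth, name="subchondral")


def rasterize_voi(voi: CylinderVoi, grid: CtVolume) -> np.ndarray:
    """Boolean mask of grid voxels whose centres lie inside the cylinder.

    Axial inclusion is half-open ``[start, start + depth)``; radial inclusion
    is ``<= radius``. Raises :class:`GeometryError` when no voxel centre
    falls inside the cylinder.
    """
    xs, ys, zs = voxel_centers(grid)
    dx = xs - voi.base_point[0]
    dy = ys - voi.base_point[1]
    dz = zs - voi.base_point[2]
    a = voi.axis
    t = dx * a[0] + dy * a[1] + dz * a[2]  # coordinate along the axis
    r2 = (dx * dx + dy * dy + dz * dz) - t * t
    lo = voi.start_offset_mm
    mask = (t >= lo) & (t < lo + voi.depth_mm) & (r2 <= voi.radius_mm**2 + 1e-12)
    if not mask.any():
        raise GeometryError("VOI does not intersect the voxel grid")
    return mask


# -- landmark file I/O: simple "name: x y z" / "name: value" text format ----


def save_landmarks(lm: GlenoidLandmarks, path: str | Path) -> None:
    lines = []
    for f in ("glenoid_center", "spine_root", "inferior_rim", "clock3", "clock9"):
        p = getattr(lm, f)
        lines.append(f"{f}: {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    lines.append(f"articular_cortex_level: {lm.articular_cortex_level:.6f}")
    lines.append(f"medial_cortex_level: {lm.medial_cortex_level:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_landmarks(path: str | Path) -> GlenoidLandmarks:
    fields: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, rest = line.partition(":")
        vals = [float(v) for v in rest.split()]
        fields[key.strip()] = vals[0] if len(vals) == 1 else np.array(vals)
    return GlenoidLandmarks(**fields)  # type: ignore[arg-type]
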