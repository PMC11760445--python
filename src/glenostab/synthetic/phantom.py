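"""Glenoid-like CT voxel phantoms with exact ground truth.

The phantom emulates what the densitometry pipeline consumes from a clinical
scan of a scapula: a grayscale voxel grid (default 0.6 mm isotropic)
containing a glenoid-shaped bone body plus internal air/fat/muscle reference
regions for patient-specific calibration. The glenoid is a capped elliptical
cylinder along a configurable medial axis: a thin cortical shell of high
density encloses a trabecular interior in which voxels are assigned to bone
or marrow by thresholding smooth spatial noise so that a target bone volume
fraction is hit exactly (to one voxel). Scanner behaviour is an affine
grayscale distortion (gain/offset) plus i.i.d. voxel noise.

Anatomical landmarks (glenoid centre, spine root, inferior rim, 3/9 o'clock
points, cortex levels) are emitted analytically with the ground truth —
landmark detection is out of scope, and downstream geometry needs exact
truth. Realistic scapular shape, beam hardening and scatter are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ..densitometry import (
    TISSUE_BMD_ANCHORS_MGHA,
    CalibrationModel,
    CalibrationSample,
)
from ..voi import GlenoidLandmarks
from ..volume import CtVolume, voxel_centers

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom_ct", "reference_samples"]


class PhantomSizingError(ValueError):
    """Grid too small to contain the glenoid body and reference regions."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic glenoid CT phantom.

    Densities are in mgHA/cm^3; the trabecular mean/SD describe bone-labelled
    voxels only, marrow voxels sit near the fat anchor. ``bone_fraction`` is
    the target true BV/TV of the trabecular compartment.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.6
    trabecular_bmd_mean: float = 220.0
    trabecular_bmd_sd: float = 30.0
    cortical_bmd: float = 800.0
    marrow_bmd_mean: float = TISSUE_BMD_ANCHORS_MGHA["fat"]
    marrow_bmd_sd: float = 15.0
    bone_fraction: float = 0.65
    reference_tissue_grayscales: dict[str, float] = field(
        default_factory=lambda: {"air": -1000.0, "fat": -95.0, "muscle": 45.0}
    )
    scanner_gain: float = 1.0
    scanner_offset: float = 0.0
    noise_sd: float = 5.0
    cortical_shell_mm: float = 1.2
    #: optional low-density pocket (centre offset from the glenoid centre in
    #: mm along (axis, width, height), radius mm, bmd) emulating necrosis
    necrotic_pocket: tuple[tuple[float, float, float], float, float] | None = None
    texture_smoothness_vox: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if not 0 < self.bone_fraction <= 1:
            raise ValueError("bone_fraction must lie in (0, 1]")
        if not self.cortical_bmd > self.trabecular_bmd_mean:
            raise ValueError("cortical BMD must exceed trabecular mean")
        missing = {"air", "fat", "muscle"} - set(self.reference_tissue_grayscales)
        if missing:
            raise ValueError(f"reference grayscales missing {sorted(missing)}")


@dataclass
class GroundTruth:
    """Noise-free truth accompanying a generated phantom."""

    bmd: CtVolume
    glenoid_mask: np.ndarray
    trabecular_mask: np.ndarray
    bone_mask: np.ndarray
    tissue_masks: dict[str, np.ndarray]
    landmarks: GlenoidLandmarks
    medial_axis: np.ndarray
    vault_depth_mm: float
    clock_distance_mm: float
    calibration: CalibrationModel
    spec: PhantomSpec

    @property
    def trabecular_bvtv(self) -> float:
        tv = int(self.trabecular_mask.sum())
        return int((self.bone_mask & self.trabecular_mask).sum()) / tv

    def save_sidecar(self, path: str | Path) -> None:
        """Write the scalar ground truth as a small structured text file."""
        lm = self.landmarks
        lines = [
            f"vault_depth_mm: {self.vault_depth_mm:.6f}",
            f"clock_distance_mm: {self.clock_distance_mm:.6f}",
            f"trabecular_bvtv: {self.trabecular_bvtv:.6f}",
            f"medial_axis: {self.medial_axis[0]:.6f} {self.medial_axis[1]:.6f} "
            f"{self.medial_axis[2]:.6f}",
            f"glenoid_center: {lm.glenoid_center[0]:.6f} {lm.glenoid_center[1]:.6f} "
            f"{lm.glenoid_center[2]:.6f}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def generate_phantom_ct(spec: PhantomSpec) -> tuple[CtVolume, GroundTruth]:
    """Generate one phantom: observed grayscale volume plus ground truth.

    The observed grayscale is ``gain * true_grayscale + offset + noise``,
    where the true grayscale is the exact inverse of the phantom's own
    piecewise-linear calibration applied to the true BMD field — so with an
    identity scanner and zero noise, calibrating the phantom recovers the
    BMD field voxel-exactly.
    """
    shape = tuple(spec.grid_shape)
    if min(shape) < 24:
        raise PhantomSizingError(
            "grid too small: need >= 24 voxels per axis for glenoid + "
            "reference regions"
        )
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing_mm
    extent = np.array(shape) * sp
    grid = CtVolume(values=np.zeros(shape), spacing_mm=np.full(3, sp))
    xs, ys, zs = voxel_centers(grid)
    cy, cz = extent[1] / 2, extent[2] / 2

    # glenoid solid: elliptical cylinder along +x (the medial axis)
    x_face = 0.30 * extent[0]
    vault_depth = 0.45 * extent[0]
    ry = 0.28 * extent[1]
    rz = 0.32 * extent[2]
    ell = ((ys - cy) / ry) ** 2 + ((zs - cz) / rz) ** 2
    glenoid = (xs >= x_face) & (xs < x_face + vault_depth) & (ell <= 1.0)
    glenoid = np.broadcast_to(glenoid, shape).copy()
    if not glenoid.any():
        raise PhantomSizingError("glenoid solid is empty on this grid")

    # cortical shell: boundary layer of the solid, >= 1 voxel thick
    n_erode = max(int(round(spec.cortical_shell_mm / sp)), 1)
    interior = ndimage.binary_erosion(glenoid, iterations=n_erode)
    cortex = glenoid & ~interior

    # trabecular texture: thresholded smooth noise hits bone_fraction exactly
    noise_field = ndimage.gaussian_filter(
        rng.standard_normal(shape), spec.texture_smoothness_vox
    )
    trab_idx = np.flatnonzero(interior)
    n_trab = trab_idx.size
    n_bone = int(round(spec.bone_fraction * n_trab))
    order = np.argsort(noise_field.ravel()[trab_idx])
    bone_flat = trab_idx[order[n_trab - n_bone :]]
    bone = np.zeros(shape, dtype=bool)
    bone.ravel()[bone_flat] = True

    # assemble the true BMD field; background is soft tissue near fat
    bmd = np.full(shape, spec.marrow_bmd_mean, dtype=float)
    bmd[interior] = rng.normal(spec.marrow_bmd_mean, spec.marrow_bmd_sd, int(interior.sum()))
    bmd[bone] = rng.normal(spec.trabecular_bmd_mean, spec.trabecular_bmd_sd, int(bone.sum()))
    bmd[cortex] = spec.cortical_bmd

    if spec.necrotic_pocket is not None:
        (off_ax, off_y, off_z), radius, pocket_bmd = spec.necrotic_pocket
        pc = np.array([x_face + off_ax, cy + off_y, cz + off_z])
        pocket = (xs - pc[0]) ** 2 + (ys - pc[1]) ** 2 + (zs - pc[2]) ** 2 <= radius**2
        pocket = np.broadcast_to(pocket, shape) & interior
        bmd[pocket] = pocket_bmd
        bone[pocket] = False

    # reference tissue spheres in the lateral (pre-articular) space
    ref_r = min(2.5, 0.35 * x_face)
    if ref_r < 1.5 * sp:
        raise PhantomSizingError("no room for reference tissue regions")
    centers = {
        "air": np.array([x_face / 2, 0.25 * extent[1], 0.25 * extent[2]]),
        "fat": np.array([x_face / 2, 0.75 * extent[1], 0.25 * extent[2]]),
        "muscle": np.array([x_face / 2, 0.25 * extent[1], 0.75 * extent[2]]),
    }
    tissue_masks: dict[str, np.ndarray] = {}
    for tissue, c in centers.items():
        m = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= ref_r**2
        m = np.broadcast_to(m, shape).copy()
        if not m.any():
            raise PhantomSizingError(f"reference region {tissue!r} empty")
        bmd[m] = TISSUE_BMD_ANCHORS_MGHA[tissue]
        tissue_masks[tissue] = m

    # true calibration of this phantom's scanner, and the observed grayscale
    grays = spec.reference_tissue_grayscales
    model = CalibrationModel(
        anchor_grayscales=(grays["air"], grays["fat"], grays["muscle"])
    )
    true_gray = model.inverse(bmd)
    observed = spec.scanner_gain * true_gray + spec.scanner_offset
    if spec.noise_sd > 0:
        observed = observed + rng.normal(0.0, spec.noise_sd, shape)

    landmarks = GlenoidLandmarks(
        glenoid_center=np.array([x_face, cy, cz]),
        spine_root=np.array([x_face + vault_depth + 3 * sp, cy, cz]),
        inferior_rim=np.array([x_face, cy, cz - rz]),
        clock3=np.array([x_face, cy + ry, cz]),
        clock9=np.array([x_face, cy - ry, cz]),
        articular_cortex_level=0.0,
        medial_cortex_level=float(vault_depth),
    )
    truth = GroundTruth(
        bmd=grid.with_values(bmd, kind="bmd"),
        glenoid_mask=glenoid,
        trabecular_mask=interior,
        bone_mask=bone,
        tissue_masks=tissue_masks,
        landmarks=landmarks,
        medial_axis=np.array([1.0, 0.0, 0.0]),
        vault_depth_mm=float(vault_depth),
        clock_distance_mm=float(2 * ry),
        calibration=model,
        spec=spec,
    )
    return grid.with_values(observed, kind="grayscale"), truth


def reference_samples(ct: CtVolume, truth: GroundTruth) -> list[CalibrationSample]:
    """Sample the observed scan in the phantom's own reference regions —
    the input to per-scan calibration fitting."""
    return [
        CalibrationSample(
            tissue=t,
            mean_grayscale=float(ct.values[m].mean()),
            voxel_count=int(m.sum()),
        )
        for t, m in truth.tissue_masks.items()
    ]
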