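"""Voxel-grid containers and NIfTI I/O.

A :class:`CtVolume` is a plain 3-D scalar field on an axis-aligned grid with
isotropic-or-not voxel spacing in millimetres. The same container carries
either raw scanner grayscale or calibrated bone mineral density (mgHA/cm^3);
the ``kind`` tag records which. World coordinates are
``origin + index * spacing`` per axis (voxel centres), LPS-agnostic: the
``frame`` tag is carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CtVolume", "voxel_centers", "load_nifti", "save_nifti"]


@dataclass
class CtVolume:
    """A 3-D scalar volume with grid geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (grayscale or mgHA/cm^3, see ``kind``).
    spacing_mm : array-like of 3 floats
        Voxel edge lengths, strictly positive.
    origin : array-like of 3 floats
        World position (mm) of the centre of voxel (0, 0, 0).
    frame : str
        Axis-orientation tag, carried through unchanged.
    kind : str
        ``"grayscale"`` or ``"bmd"``.
    """

    values: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.full(3, 0.6))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = "xyz"
    kind: str = "grayscale"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3-D array")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be 3 strictly positive floats")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "CtVolume":
        """Same grid, new voxel data."""
        if np.shape(values) != self.values.shape:
            raise ValueError("replacement values must match the grid shape")
        return replace(self, values=np.asarray(values), kind=kind or self.kind)


def voxel_centers(vol: CtVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World-coordinate (mm) centre grids of every voxel, as a sparse meshgrid."""
    axes = [vol.origin[a] + np.arange(vol.shape[a]) * vol.spacing_mm[a] for a in range(3)]
    return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def save_nifti(vol: CtVolume, path: str | Path) -> None:
    affine = np.diag(np.append(vol.spacing_mm, 1.0))
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def load_nifti(path: str | Path, kind: str = "grayscale") -> CtVolume:
    img = nib.load(str(path))
    affine = img.affine
    return CtVolume(
        values=np.asarray(img.get_fdata()),
        spacing_mm=np.abs(np.diag(affine)[:3]),
        origin=affine[:3, 3].copy(),
        frame="nifti",
        kind=kind,
    )
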