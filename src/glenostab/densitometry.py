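"""Patient-specific grayscale-to-BMD calibration and density metrics.

Clinical CT grayscale is scanner- and protocol-dependent. Instead of a
physical density phantom, calibration is anchored on three internal reference
tissues sampled from the scan itself — air, subcutaneous fat and muscle —
which are assigned fixed hydroxyapatite-equivalent densities of −840, −80 and
+30 mgHA/cm^3. The grayscale→BMD map is the piecewise-linear interpolant
through those three anchors, continued with the terminal segment slopes
beyond them (bone lies above the muscle anchor). Because the anchors are
re-sampled per scan, any affine distortion of the scanner output (gain and
offset) cancels exactly.

Trabecular bone volume fraction (BV/TV) is computed by pixel counting: the
fraction of voxels inside a volume of interest whose calibrated density
reaches a global segmentation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .volume import CtVolume

if TYPE_CHECKING:  # pragma: no cover
    from .voi import CylinderVoi

__all__ = [
    "TISSUE_BMD_ANCHORS_MGHA",
    "DEFAULT_BVTV_THRESHOLD_MGHA",
    "CalibrationSample",
    "CalibrationModel",
    "CalibrationError",
    "DensityMetrics",
    "fit_calibration",
    "apply_calibration",
    "invert_calibration",
    "compute_bvtv",
    "compute_voi_metrics",
]

#: Hydroxyapatite-equivalent densities assigned to the reference tissues.
TISSUE_BMD_ANCHORS_MGHA: dict[str, float] = {"air": -840.0, "fat": -80.0, "muscle": 30.0}

#: Default global segmentation threshold for bone pixel counting. The
#: published pipeline uses a fixed global threshold without printing its
#: value; 100 mgHA/cm^3 sits between marrow/fat (~-80) and trabecular bone
#: (>150) and is overridable everywhere it is used.
DEFAULT_BVTV_THRESHOLD_MGHA: float = 100.0

_TISSUE_ORDER = ("air", "fat", "muscle")


class CalibrationError(ValueError):
    """Raised when reference samples cannot define a monotone calibration."""


@dataclass(frozen=True)
class CalibrationSample:
    """Mean grayscale of one reference tissue region.

    ``tissue`` must be one of ``air``, ``fat``, ``muscle``.
    """

    tissue: str
    mean_grayscale: float
    voxel_count: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in _TISSUE_ORDER:
            raise CalibrationError(f"unknown reference tissue {self.tissue!r}")
        if self.voxel_count <= 0:
            raise CalibrationError("voxel_count must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Monotone piecewise-linear grayscale→BMD map anchored on three tissues.

    ``anchor_grayscales`` and ``anchor_bmd`` are parallel, strictly increasing
    triples (air, fat, muscle). Outside the anchor range the terminal segment
    slopes are continued.
    """

    anchor_grayscales: tuple[float, float, float]
    anchor_bmd: tuple[float, float, float] = (
        TISSUE_BMD_ANCHORS_MGHA["air"],
        TISSUE_BMD_ANCHORS_MGHA["fat"],
        TISSUE_BMD_ANCHORS_MGHA["muscle"],
    )

    def __post_init__(self) -> None:
        g = np.asarray(self.anchor_grayscales, dtype=float)
        if g.shape != (3,) or not np.all(np.diff(g) > 0):
            raise CalibrationError(
                "anchor grayscales must be three strictly increasing values "
                "(air < fat < muscle)"
            )

    def __call__(self, grayscale):
        return _piecewise_linear(
            np.asarray(grayscale, dtype=float),
            np.asarray(self.anchor_grayscales),
            np.asarray(self.anchor_bmd),
        )

    def inverse(self, bmd):
        """Grayscale producing a given BMD (the map is strictly increasing)."""
        return _piecewise_linear(
            np.asarray(bmd, dtype=float),
            np.asarray(self.anchor_bmd),
            np.asarray(self.anchor_grayscales),
        )


def _piecewise_linear(x: np.ndarray, xp: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """np.interp with the terminal segment slopes continued beyond the knots."""
    y = np.interp(x, xp, yp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        slope = (yp[1] - yp[0]) / (xp[1] - xp[0])
        y = np.where(lo, yp[0] + slope * (x - xp[0]), y)
    if np.any(hi):
        slope = (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, yp[-1] + slope * (x - xp[-1]), y)
    return y


def fit_calibration(samples: Iterable[CalibrationSample]) -> CalibrationModel:
    """Fit the per-scan calibration from one sample per reference tissue.

    The fitted map sends each sample's mean grayscale exactly to its assigned
    anchor density. Raises :class:`CalibrationError` if a tissue is missing,
    duplicated, or the grayscales are not ordered air < fat < muscle.
    """
    by_tissue: dict[str, CalibrationSample] = {}
    for s in samples:
        if s.tissue in by_tissue:
            raise CalibrationError(f"duplicate reference tissue {s.tissue!r}")
        by_tissue[s.tissue] = s
    missing = [t for t in _TISSUE_ORDER if t not in by_tissue]
    if missing:
        raise CalibrationError(f"missing reference tissue(s): {missing}")
    grays = tuple(by_tissue[t].mean_grayscale for t in _TISSUE_ORDER)
    return CalibrationModel(anchor_grayscales=grays)


def apply_calibration(vol: CtVolume, model: CalibrationModel) -> CtVolume:
    """Voxel-wise conversion of a grayscale volume to BMD (mgHA/cm^3)."""
    return vol.with_values(model(vol.values), kind="bmd")


def invert_calibration(bmd_vol: CtVolume, model: CalibrationModel) -> CtVolume:
    """Voxel-wise grayscale volume whose calibration reproduces ``bmd_vol``."""
    return bmd_vol.with_values(model.inverse(bmd_vol.values), kind="grayscale")


@dataclass(frozen=True)
class DensityMetrics:
    """Summary density statistics of one volume of interest."""

    voi_name: str
    bmd_mean: float
    bmd_sd: float
    bvtv: float
    voxel_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.bvtv <= 1.0):
            raise ValueError("bvtv must lie in [0, 1]")
        if self.voxel_count <= 0:
            raise ValueError("voxel_count must be positive")


def compute_bvtv(
    vol: CtVolume,
    mask: np.ndarray,
    threshold: float = DEFAULT_BVTV_THRESHOLD_MGHA,
) -> float:
    """Bone volume fraction by pixel counting.

    BV/TV = (# masked voxels with BMD >= threshold) / (# masked voxels).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask shape must match the volume")
    tv = int(mask.sum())
    if tv == 0:
        raise ValueError("empty mask: BV/TV undefined")
    bv = int(np.count_nonzero(vol.values[mask] >= threshold))
    return bv / tv


def compute_voi_metrics(
    vol: CtVolume,
    voi: "CylinderVoi | np.ndarray",
    threshold: float = DEFAULT_BVTV_THRESHOLD_MGHA,
    name: str | None = None,
) -> DensityMetrics:
    """Mean/SD BMD and BV/TV over a cylindrical VOI or a precomputed mask."""
    if isinstance(voi, np.ndarray):
        mask = np.asarray(voi, dtype=bool)
        voi_name = name or "mask"
    else:
        from .voi import rasterize_voi

        mask = rasterize_voi(voi, vol)
        voi_name = name or voi.name
    vals = vol.values[mask]
    if vals.size == 0:
        raise ValueError("VOI does not intersect the volume")
    if vals.size == 1:
        warnings.warn("single-voxel VOI: SD reported as 0", stacklevel=2)
    return DensityMetrics(
        voi_name=voi_name,
        bmd_mean=float(vals.mean()),
        bmd_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        bvtv=compute_bvtv(vol, mask, threshold),
        voxel_count=int(vals.size),
    )
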