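"""Synthetic study cohorts with known density–micromotion structure.

A cohort mirrors the study design: a reference group treated by corrective
reaming (n = 10) and two augment groups — metallic (MA) and bone-graft
(BIO) — of n = 10 each, split into 10° and 20° corrections (n = 5 per cell).
Each specimen gets a subchondral trabecular density and a total micromotion
amplitude. In the BIO group the two are drawn from a bivariate normal with a
configurable negative correlation (default −0.63): grafted constructs move
more in low-density bone. MA and reference specimens draw the two
independently.

Group density means/SDs default to the subchondral-cylinder BMD statistics
of the study cohort; micromotion means/SDs are generator choices sized so
the reference group stays well below the 150 µm osseointegration limit.

The generator returns lightweight per-specimen simulation specs (phantom +
bench parameters, with per-specimen substreams derived from the master seed
by fixed increments); materialising voxel phantoms and marker recordings is
the pipeline's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bench import TestBenchSpec
from .phantom import PhantomSpec

__all__ = ["CohortSpec", "SpecimenSimulation", "generate_cohort", "GROUP_CELLS"]

#: study cells: (cell label, base group, correction degrees)
GROUP_CELLS: tuple[tuple[str, str, int], ...] = (
    ("Reference", "Reference", 0),
    ("MA10", "MA", 10),
    ("MA20", "MA", 20),
    ("BIO10", "BIO", 10),
    ("BIO20", "BIO", 20),
)

_DEF_N = {"Reference": 10, "MA10": 5, "MA20": 5, "BIO10": 5, "BIO20": 5}
#: subchondral-cylinder BMD (mgHA/cm^3) per base group, mean and SD
_DEF_DENSITY = {"Reference": (238.0, 37.0), "MA": (217.0, 34.0), "BIO": (211.0, 16.0)}
#: total pre-cyclic micromotion amplitude (µm) per base group, mean and SD
_DEF_MICROMOTION = {"Reference": (40.0, 10.0), "MA": (45.0, 12.0), "BIO": (60.0, 25.0)}

_MIN_MICROMOTION_UM = 1.0


@dataclass
class CohortSpec:
    """Cohort-level simulation parameters."""

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(_DEF_N))
    density_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEF_DENSITY)
    )
    micromotion_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEF_MICROMOTION)
    )
    bio_density_micromotion_rho: float = -0.63
    graft_split: float = 0.53
    phantom_grid_shape: tuple[int, int, int] = (48, 48, 48)
    marker_noise_um: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.bio_density_micromotion_rho) > 1:
            raise ValueError("|rho| must be <= 1")
        for cell, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(
                    f"cell {cell!r}: need >= 2 specimens for statistics, got {n}"
                )


@dataclass
class SpecimenSimulation:
    """Everything needed to materialise one synthetic specimen."""

    specimen_id: str
    group: str  # Reference | MA | BIO
    correction_deg: int
    subchondral_bmd_true: float
    micromotion_um_true: float
    phantom_spec: PhantomSpec
    bench_spec: TestBenchSpec


def generate_cohort(spec: CohortSpec) -> list[SpecimenSimulation]:
    """Draw a full cohort of specimen simulation specs.

    Deterministic for a fixed seed; per-specimen phantom/bench substream
    seeds are ``base + 2 i`` / ``base + 2 i + 1`` so cohort reproducibility
    does not depend on iteration order.
    """
    rng = np.random.default_rng(spec.seed)
    base = (int(spec.seed) * 100_003) % 2**30
    sims: list[SpecimenSimulation] = []
    i = 0
    for cell, group, correction in GROUP_CELLS:
        n = spec.n_per_group.get(cell, 0)
        if n == 0:
            continue
        d_mu, d_sd = spec.density_mean_sd[group]
        m_mu, m_sd = spec.micromotion_mean_sd[group]
        if group == "BIO":
            rho = spec.bio_density_micromotion_rho
            cov = np.array(
                [[d_sd**2, rho * d_sd * m_sd], [rho * d_sd * m_sd, m_sd**2]]
            )
            draws = rng.multivariate_normal([d_mu, m_mu], cov, size=n)
            density, motion = draws[:, 0], draws[:, 1]
        else:
            density = rng.normal(d_mu, d_sd, n)
            motion = rng.normal(m_mu, m_sd, n)
        motion = np.maximum(motion, _MIN_MICROMOTION_UM)
        for k in range(n):
            sims.append(
                SpecimenSimulation(
                    specimen_id=f"{cell}-{k + 1:02d}",
                    group=group,
                    correction_deg=correction,
                    subchondral_bmd_true=float(density[k]),
                    micromotion_um_true=float(motion[k]),
                    phantom_spec=PhantomSpec(
                        grid_shape=spec.phantom_grid_shape,
                        trabecular_bmd_mean=float(density[k]),
                        seed=base + 2 * i,
                    ),
                    bench_spec=TestBenchSpec(
                        elastic_amplitude_um=float(motion[k]),
                        graft_split=spec.graft_split if group == "BIO" else None,
                        marker_noise_um=spec.marker_noise_um,
                        seed=base + 2 * i + 1,
                    ),
                )
            )
            i += 1
    return sims
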