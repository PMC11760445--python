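"""Synthetic rocking-horse marker recordings.

Emulates the optical measurement of baseplate primary stability: a constant
compressive load with a sinusoidal superior–inferior shear force (350 N at
1/6 Hz, 25 cycles) while rings of six labelled markers on the glenosphere,
the glenoid rim and — for bone-graft constructs — the graft are tracked at
5 Hz with a given in-plane accuracy (default 2.8 µm, i.i.d. Gaussian per
coordinate).

Injected motion is exactly representable by the downstream estimators:

* the glenosphere translates relative to the (bench-fixed) glenoid rim along
  the shear axis by ``(A/2) * (1 − cos(2π f t))`` so that every full shear
  cycle spans a peak-to-peak relative displacement of exactly ``A``;
* it additionally oscillates about the implant axis through the baseplate
  centre (the glenosphere marker centroid) so rotation leaks nothing into
  the displacement at the reference point;
* post-fatigue recordings carry a constant permanent migration offset plus
  an elastic amplitude enlarged by ``post_added_um``;
* when a graft interface fraction is configured, the graft body carries
  ``(1 − graft_split)`` of the total relative motion, leaving ``graft_split``
  at the implant–graft interface.

The physical test rig (ASTM-style fixturing, actuator dynamics, camera
optics) is emulated at the level of its recorded output, not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..micromotion import MarkerRecording

__all__ = ["TestBenchSpec", "generate_marker_recording"]

_PHASES = ("pre", "post")


@dataclass
class TestBenchSpec:
    """Loading protocol and injected-motion parameters of one bench run."""

    n_cycles_pre: int = 25
    n_cycles_post: int = 25
    shear_freq_hz: float = 1.0 / 6.0
    sample_hz: float = 5.0
    compression_n: float = 430.0
    shear_n: float = 350.0
    fatigue_cycles: int = 10_000
    fatigue_freq_hz: float = 0.5
    abduction_range_deg: tuple[float, float] = (45.0, 93.0)
    #: peak-to-peak relative glenosphere–glenoid displacement per shear cycle
    elastic_amplitude_um: float = 40.0
    #: permanent migration plus added elastic amplitude after fatigue
    post_added_um: float = 15.0
    rot_amplitude_deg: float = 0.10
    rot_post_added_deg: float = 0.02
    #: fraction of the total motion at the implant–graft interface
    #: (bone-graft constructs only; None disables the graft body)
    graft_split: float | None = None
    marker_noise_um: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.graft_split is not None and not 0 <= self.graft_split <= 1:
            raise ValueError("graft_split must lie in [0, 1]")
        for name in ("elastic_amplitude_um", "post_added_um", "rot_amplitude_deg",
                     "rot_post_added_deg", "marker_noise_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sample_hz / self.shear_freq_hz < 10:
            raise ValueError("need >= 10 samples per shear cycle")


def _marker_ring(center: np.ndarray, radius_mm: float, n: int = 6) -> np.ndarray:
    """Ring of markers in the y-z plane around ``center``. All bodies use the
    same angular stations so first-to-last marker chords are parallel."""
    ang = 2 * np.pi * np.arange(n) / n
    pts = np.tile(center, (n, 1))
    pts[:, 1] += radius_mm * np.cos(ang)
    pts[:, 2] += radius_mm * np.sin(ang)
    return pts


def _rot_x(angle_rad: np.ndarray) -> np.ndarray:
    """Stack of rotations about the +x (implant) axis, shape (n, 3, 3)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.zeros((angle_rad.size, 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1] = c
    R[:, 1, 2] = -s
    R[:, 2, 1] = s
    R[:, 2, 2] = c
    return R


def generate_marker_recording(spec: TestBenchSpec, phase: str) -> MarkerRecording:
    """Generate one pre- or post-fatigue recording for the given bench spec.

    Deterministic for a fixed (spec.seed, phase): the post phase uses a fixed
    +1 increment of the seed so the two phases draw independent noise.
    """
    if phase not in _PHASES:
        raise ValueError(f"phase must be one of {_PHASES}, got {phase!r}")
    n_cycles = spec.n_cycles_pre if phase == "pre" else spec.n_cycles_post
    n_frames = int(round(n_cycles * spec.sample_hz / spec.shear_freq_hz))
    t = np.arange(n_frames) / spec.sample_hz
    omega = 2 * np.pi * spec.shear_freq_hz
    shear = spec.shear_n * np.sin(omega * t)

    amp_um = spec.elastic_amplitude_um
    rot_deg = spec.rot_amplitude_deg
    perm_um = 0.0
    if phase == "post":
        amp_um += spec.post_added_um
        rot_deg += spec.rot_post_added_deg
        perm_um = spec.post_added_um
    # raised-cosine drive: per-cycle peak-to-peak equals the amplitude
    drive = 0.5 * (1.0 - np.cos(omega * t))
    u_mm = (perm_um + amp_um * drive) / 1000.0  # along z (shear axis)
    phi = np.radians(rot_deg) * drive

    sphere_c = np.array([-5.0, 0.0, 0.0])  # baseplate centre proxy
    sphere0 = _marker_ring(sphere_c, 15.0)
    rim0 = _marker_ring(np.array([1.0, 0.0, 0.0]), 18.0)
    graft0 = _marker_ring(np.array([-2.0, 0.0, 0.0]), 16.0)

    R = _rot_x(phi)
    sphere = np.einsum("nij,mj->nmi", R, sphere0 - sphere_c) + sphere_c
    sphere[:, :, 2] += u_mm[:, None]
    bodies = {
        "glenosphere": sphere,
        "glenoid_rim": np.broadcast_to(rim0, (n_frames, *rim0.shape)).copy(),
    }
    if spec.graft_split is not None:
        graft = np.broadcast_to(graft0, (n_frames, *graft0.shape)).copy()
        graft[:, :, 2] += (1.0 - spec.graft_split) * u_mm[:, None]
        bodies["graft"] = graft

    rng = np.random.default_rng(spec.seed + (0 if phase == "pre" else 1))
    if spec.marker_noise_um > 0:
        sigma_mm = spec.marker_noise_um / 1000.0
        for tracks in bodies.values():
            tracks += rng.normal(0.0, sigma_mm, tracks.shape)

    return MarkerRecording(
        time_s=t,
        bodies=bodies,
        shear_n=shear,
        phase=phase,
        meta={
            "injected_amplitude_um": amp_um,
            "injected_rotation_deg": rot_deg,
            "permanent_offset_um": perm_um,
            "graft_split": spec.graft_split,
        },
    )
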