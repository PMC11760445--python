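"""Baseplate micromotion and rotational displacement from marker tracking.

During the rocking-horse test an optical system tracks labelled reflective
markers on the glenosphere, the glenoid rim and — for bone-graft constructs —
the graft, at 5 Hz while a sinusoidal shear load (1/6 Hz, 25 cycles) is
applied under constant compression. Primary stability is quantified as:

* **micromotion** — the relative displacement between glenosphere and glenoid
  rim, evaluated at a reference point (default: the glenosphere marker
  centroid of the first frame, a proxy for the baseplate centre, because the
  translation of a rigid body under rotation is point-dependent);
* **rotational displacement** — the angle between the first-to-last marker
  lines on the glenosphere and the glenoid, expressed as change from the
  first frame;

both summarised per recording as the mean of the per-shear-cycle
minimum-to-maximum range, before (pre) and after (post) fatigue loading.
Sustained micromotion above 150 µm is the conventional limit for bony
osseointegration.

Rigid-body poses are least-squares orthogonal (Kabsch) fits of each frame's
markers to the first frame; all relative measures are invariant to common
rigid motion of the whole scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OSSEOINTEGRATION_LIMIT_UM",
    "RecordingError",
    "MarkerRecording",
    "StabilityOutcome",
    "segment_cycles",
    "fit_rigid_body",
    "body_transforms",
    "relative_displacement_series",
    "rotation_series",
    "cycle_range_mean",
    "interface_split",
    "stability_outcome",
    "read_recording_csv",
    "write_recording_csv",
]

#: Conventional micromotion limit (µm) above which osseointegration is
#: considered impaired.
OSSEOINTEGRATION_LIMIT_UM: float = 150.0

#: Column order of the trajectory CSV dialect (long format, one row per
#: marker per frame).
TRAJECTORY_COLUMNS = [
    "time_s", "body", "marker_id", "x_mm", "y_mm", "z_mm", "shear_N", "phase",
]


class RecordingError(ValueError):
    pass


@dataclass
class MarkerRecording:
    """Labelled marker trajectories of one rocking-horse recording.

    ``bodies`` maps body name (``glenosphere``, ``glenoid_rim``, optionally
    ``graft``) to an array of shape ``(n_frames, n_markers, 3)`` in mm.
    ``shear_n`` is the per-frame shear load channel (N). ``phase`` is
    ``"pre"`` or ``"post"`` (relative to fatigue loading).
    """

    time_s: np.ndarray
    bodies: dict[str, np.ndarray]
    shear_n: np.ndarray
    phase: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.shear_n = np.asarray(self.shear_n, dtype=float)
        if self.phase not in ("pre", "post"):
            raise RecordingError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        n = self.time_s.shape[0]
        if self.shear_n.shape[0] != n:
            raise RecordingError("shear channel length differs from time base")
        if not self.bodies:
            raise RecordingError("recording contains no bodies")
        for name, tracks in self.bodies.items():
            tracks = np.asarray(tracks, dtype=float)
            self.bodies[name] = tracks
            if tracks.ndim != 3 or tracks.shape[0] != n or tracks.shape[2] != 3:
                raise RecordingError(f"body {name!r}: tracks must be (n_frames, m, 3)")
            if tracks.shape[1] < 2:
                raise RecordingError(f"body {name!r}: need at least 2 markers")
            if not np.isfinite(tracks).all():
                raise RecordingError(f"body {name!r}: missing frames not allowed")

    @property
    def n_frames(self) -> int:
        return self.time_s.shape[0]

    @property
    def sample_hz(self) -> float:
        dt = np.diff(self.time_s)
        return 1.0 / float(np.median(dt))

    def require(self, *names: str) -> None:
        missing = [b for b in names if b not in self.bodies]
        if missing:
            raise RecordingError(f"recording lacks body/bodies {missing}")


def segment_cycles(
    rec: MarkerRecording, expected_freq_hz: float = 1.0 / 6.0
) -> list[tuple[int, int]]:
    """Shear-cycle windows as half-open frame ranges ``(start, stop)``.

    Windows run between successive positive-going crossings of the shear
    channel through its mean, de-bounced to at least half the nominal cycle
    length. A head/tail window is kept only if it spans at least half a
    nominal cycle. If the channel is (near-)constant the recording is cut
    into fixed-length windows of ``sample_hz / expected_freq_hz`` frames.
    """
    s = rec.shear_n
    nominal = max(int(round(rec.sample_hz / expected_freq_hz)), 1)
    if np.ptp(s) < 1e-9 * max(1.0, abs(s).max()) or np.ptp(s) == 0:
        n_windows = rec.n_frames // nominal
        if n_windows < 1:
            raise RecordingError("recording shorter than one nominal cycle")
        return [(i * nominal, (i + 1) * nominal) for i in range(n_windows)]

    c = s - s.mean()
    tol = 1e-9 * max(1.0, float(np.abs(c).max()))  # absorbs sin(2*pi*k) round-off
    rising = np.flatnonzero((c[:-1] < -tol) & (c[1:] >= -tol)) + 1
    starts: list[int] = []
    for idx in rising:
        if not starts or idx - starts[-1] >= nominal // 2:
            starts.append(int(idx))
    # the recording may begin exactly on (or just after) a crossing
    if starts and starts[0] >= nominal // 2 and c[0] >= -tol:
        starts.insert(0, 0)
    if len(starts) >= 3:
        diffs = np.diff(starts)
        if abs(float(np.median(diffs)) - nominal) <= 0.2 * nominal:
            # channel runs at the commanded frequency: snap windows to the
            # nominal period at the (circular-median) observed phase, which
            # de-noises single-frame crossing jitter
            r = (np.asarray(starts) + nominal // 2) % nominal - nominal // 2
            offset = int(round(float(np.median(r)))) % nominal
            starts = list(range(offset, rec.n_frames - nominal + 1, nominal))
            return [(a, a + nominal) for a in starts]
    bounds = starts + [rec.n_frames]
    windows = [
        (a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= nominal // 2
    ]
    if len(windows) < 2:
        raise RecordingError("fewer than 2 shear cycles detected")
    return windows


def fit_rigid_body(
    ref_markers: np.ndarray, markers: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping ``ref_markers`` onto ``markers``.

    Kabsch alignment with a proper rotation (det +1). Returns
    ``(R, t, rms_mm)`` such that ``markers ≈ ref_markers @ R.T + t``.
    Requires at least 3 non-collinear markers.
    """
    ref = np.asarray(ref_markers, dtype=float)
    cur = np.asarray(markers, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[0] < 3:
        raise RecordingError("need matching sets of >= 3 markers")
    R, t = _kabsch(ref[None], cur[None])
    resid = cur - (ref @ R[0].T + t[0])
    return R[0], t[0], float(np.sqrt(np.mean(np.sum(resid**2, axis=-1))))


def _kabsch(ref: np.ndarray, cur: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Kabsch: ref (1 or n, m, 3), cur (n, m, 3) -> R (n,3,3), t (n,3)."""
    ref = np.broadcast_to(np.asarray(ref, dtype=float), cur.shape)
    ref_mean = ref.mean(axis=1)
    cur_mean = cur.mean(axis=1)
    ref_c = ref - ref_mean[:, None]
    if np.linalg.matrix_rank(ref_c[0], tol=1e-9) < 2:
        raise RecordingError("degenerate (collinear) marker set")
    cur_c = cur - cur_mean[:, None]
    H = np.einsum("nmi,nmj->nij", ref_c, cur_c)
    U, _, Vt = np.linalg.svd(H)
    V = Vt.transpose(0, 2, 1).copy()
    d = np.sign(np.linalg.det(V @ U.transpose(0, 2, 1)))
    d[d == 0] = 1.0
    # force proper rotations by flipping the smallest singular direction
    V[:, :, 2] *= d[:, None]
    R = V @ U.transpose(0, 2, 1)
    t = cur_mean - np.einsum("nij,nj->ni", R, ref_mean)
    return R, t


def body_transforms(tracks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rigid pose of a body relative to its first frame.

    ``tracks`` has shape ``(n_frames, m, 3)`` with m >= 3 non-collinear
    markers; returns ``(R, t)`` with ``R`` ``(n, 3, 3)`` and ``t`` ``(n, 3)``
    such that frame-0 coordinates map to frame ``i`` via ``R[i] x + t[i]``.
    """
    tracks = np.asarray(tracks, dtype=float)
    if tracks.shape[1] < 3:
        raise RecordingError("rigid fit needs >= 3 markers")
    return _kabsch(tracks[:1], tracks)


def relative_displacement_series(
    rec: MarkerRecording,
    moving: str = "glenosphere",
    fixed: str = "glenoid_rim",
    reference_point: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame relative displacement magnitude (µm) of ``moving`` vs
    ``fixed``, evaluated at ``reference_point`` (default: the moving body's
    first-frame marker centroid, i.e. the baseplate centre for the
    glenosphere ring).

    Both bodies' poses are taken relative to the first frame; the fixed
    body's motion is inverted and composed with the moving body's, so any
    common rigid motion of the whole scene cancels.
    """
    rec.require(moving, fixed)
    Rm, tm = body_transforms(rec.bodies[moving])
    Rf, tf = body_transforms(rec.bodies[fixed])
    p = (
        rec.bodies[moving][0].mean(axis=0)
        if reference_point is None
        else np.asarray(reference_point, dtype=float)
    )
    # world position of the reference point carried by the moving body
    p_m = np.einsum("nij,j->ni", Rm, p) + tm
    # pull back through the fixed body's motion: q = Rf^T (p_m - tf)
    q = np.einsum("nji,nj->ni", Rf, p_m - tf)
    return np.linalg.norm(q - p, axis=1) * 1000.0  # mm -> µm


def rotation_series(
    rec: MarkerRecording,
    body_a: str = "glenosphere",
    body_b: str = "glenoid_rim",
) -> np.ndarray:
    """Per-frame angle (deg) between the first-to-last marker lines of the
    two bodies, as change from the first frame."""
    rec.require(body_a, body_b)
    va = rec.bodies[body_a][:, -1] - rec.bodies[body_a][:, 0]
    vb = rec.bodies[body_b][:, -1] - rec.bodies[body_b][:, 0]
    na = np.linalg.norm(va, axis=1)
    nb = np.linalg.norm(vb, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise RecordingError("zero-length first-to-last marker line")
    cosang = np.clip(np.sum(va * vb, axis=1) / (na * nb), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return ang - ang[0]


def cycle_range_mean(series: np.ndarray, windows: list[tuple[int, int]]) -> float:
    """Mean over shear cycles of the within-cycle minimum-to-maximum range."""
    series = np.asarray(series, dtype=float)
    if not windows:
        raise RecordingError("no cycle windows")
    ranges = []
    for a, b in windows:
        if b <= a:
            raise RecordingError("empty cycle window")
        ranges.append(np.ptp(series[a:b]))
    return float(np.mean(ranges))


def interface_split(
    rec: MarkerRecording, expected_freq_hz: float = 1.0 / 6.0
) -> dict[str, float]:
    """Partition of total micromotion between the implant–graft and
    graft–glenoid interfaces, in percent (graft-tracked constructs only)."""
    rec.require("glenosphere", "graft", "glenoid_rim")
    windows = segment_cycles(rec, expected_freq_hz)
    ref_point = rec.bodies["glenosphere"][0].mean(axis=0)
    implant_graft = cycle_range_mean(
        relative_displacement_series(rec, "glenosphere", "graft", ref_point), windows
    )
    graft_glenoid = cycle_range_mean(
        relative_displacement_series(rec, "graft", "glenoid_rim", ref_point), windows
    )
    total = implant_graft + graft_glenoid
    if total == 0:
        raise RecordingError("no interface motion to partition")
    return {
        "implant_graft_pct": 100.0 * implant_graft / total,
        "graft_glenoid_pct": 100.0 * graft_glenoid / total,
    }


@dataclass(frozen=True)
class StabilityOutcome:
    """Pre-/post-fatigue primary-stability outcomes of one specimen."""

    micromotion_pre_um: float
    micromotion_post_um: float
    micromotion_delta_um: float
    rotation_pre_deg: float
    rotation_post_deg: float
    rotation_delta_deg: float
    exceeds_150um: bool
    graft_split: dict[str, float] | None = None
    threshold_um: float = OSSEOINTEGRATION_LIMIT_UM


def stability_outcome(
    pre_rec: MarkerRecording,
    post_rec: MarkerRecording,
    threshold_um: float = OSSEOINTEGRATION_LIMIT_UM,
    expected_freq_hz: float = 1.0 / 6.0,
) -> StabilityOutcome:
    """Assemble micromotion/rotation outcomes from a pre/post recording pair.

    The pair must share the bench configuration (same bodies and marker
    counts). ``exceeds_150um`` flags post-cyclic micromotion above the
    osseointegration threshold. The interface split is computed from the
    pre-fatigue recording when a graft body is tracked.
    """
    if pre_rec.phase != "pre" or post_rec.phase != "post":
        raise RecordingError("recordings must be a (pre, post) pair")
    if set(pre_rec.bodies) != set(post_rec.bodies) or any(
        pre_rec.bodies[b].shape[1] != post_rec.bodies[b].shape[1] for b in pre_rec.bodies
    ):
        raise RecordingError("pre/post recordings have mismatched configurations")

    def _metrics(rec: MarkerRecording) -> tuple[float, float]:
        windows = segment_cycles(rec, expected_freq_hz)
        mm = cycle_range_mean(relative_displacement_series(rec), windows)
        rot = cycle_range_mean(rotation_series(rec), windows)
        return mm, rot

    mm_pre, rot_pre = _metrics(pre_rec)
    mm_post, rot_post = _metrics(post_rec)
    split = interface_split(pre_rec, expected_freq_hz) if "graft" in pre_rec.bodies else None
    return StabilityOutcome(
        micromotion_pre_um=mm_pre,
        micromotion_post_um=mm_post,
        micromotion_delta_um=mm_post - mm_pre,
        rotation_pre_deg=rot_pre,
        rotation_post_deg=rot_post,
        rotation_delta_deg=rot_post - rot_pre,
        exceeds_150um=bool(mm_post > threshold_um),
        graft_split=split,
        threshold_um=threshold_um,
    )


def write_recording_csv(rec: MarkerRecording, path: str | Path) -> None:
    """Write the long-format trajectory CSV (one row per marker per frame)."""
    rows = []
    for body, tracks in rec.bodies.items():
        n, m, _ = tracks.shape
        rows.append(
            pd.DataFrame(
                {
                    "time_s": np.repeat(rec.time_s, m),
                    "body": body,
                    "marker_id": np.tile(np.arange(m), n),
                    "x_mm": tracks[:, :, 0].ravel(),
                    "y_mm": tracks[:, :, 1].ravel(),
                    "z_mm": tracks[:, :, 2].ravel(),
                    "shear_N": np.repeat(rec.shear_n, m),
                    "phase": rec.phase,
                }
            )
        )
    pd.concat(rows, ignore_index=True)[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_recording_csv(path: str | Path) -> MarkerRecording:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise RecordingError(f"trajectory CSV lacks columns {sorted(missing)}")
    phases = df["phase"].unique()
    if len(phases) != 1:
        raise RecordingError("trajectory CSV must contain a single phase")
    bodies: dict[str, np.ndarray] = {}
    time_s = None
    shear = None
    for body, sub in df.groupby("body", sort=False):
        piv = sub.sort_values(["time_s", "marker_id"])
        m = piv["marker_id"].nunique()
        n = len(piv) // m
        tracks = piv[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(n, m, 3)
        bodies[str(body)] = tracks
        if time_s is None:
            time_s = piv["time_s"].to_numpy()[::m]
            shear = piv["shear_N"].to_numpy()[::m]
    return MarkerRecording(time_s=time_s, bodies=bodies, shear_n=shear, phase=str(phases[0]))
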