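"""Marker-based micromotion and rotation outcomes."""

import numpy as np
import pytest

from glenostab.micromotion import (
    MarkerRecording,
    RecordingError,
    cycle_range_mean,
    fit_rigid_body,
    interface_split,
    read_recording_csv,
    relative_displacement_series,
    rotation_series,
    segment_cycles,
    stability_outcome,
    write_recording_csv,
)
from glenostab.synthetic import TestBenchSpec, generate_marker_recording


def _static_recording(n_frames=60, shear=None, extra_bodies=None):
    rng = np.random.default_rng(0)
    base = {name: rng.normal(0, 10, (1, 6, 3)) for name in ("glenosphere", "glenoid_rim")}
    if extra_bodies:
        base.update({n: rng.normal(0, 10, (1, 6, 3)) for n in extra_bodies})
    bodies = {n: np.repeat(b, n_frames, axis=0) for n, b in base.items()}
    t = np.arange(n_frames) / 5.0
    if shear is None:
        shear = 350.0 * np.sin(2 * np.pi * t / 6.0)
    return MarkerRecording(time_s=t, bodies=bodies, shear_n=shear, phase="pre")


class TestSegmentCycles:
    def test_clean_sinusoid_gives_25_windows_of_30_frames(self):
        rec = generate_marker_recording(TestBenchSpec(marker_noise_um=0.0), "pre")
        windows = segment_cycles(rec)
        assert len(windows) == 25
        assert all(b - a == 30 for a, b in windows)

    def test_constant_channel_falls_back_to_fixed_windows(self):
        rec = _static_recording(n_frames=90, shear=np.full(90, 430.0))
        windows = segment_cycles(rec)
        assert windows == [(0, 30), (30, 60), (60, 90)]

    def test_noisy_channel_matches_noiseless_segmentation(self):
        spec = TestBenchSpec(marker_noise_um=0.0, seed=2)
        clean = generate_marker_recording(spec, "pre")
        noisy = MarkerRecording(
            time_s=clean.time_s,
            bodies=dict(clean.bodies),
            shear_n=clean.shear_n + np.random.default_rng(7).normal(0, 5.0, clean.n_frames),
            phase="pre",
        )
        assert segment_cycles(noisy) == segment_cycles(clean)

    def test_too_short_recording_rejected(self):
        rec = _static_recording(n_frames=20)
        with pytest.raises(RecordingError):
            segment_cycles(rec)


class TestRigidFit:
    def test_pure_translation_recovered(self, rng):
        ref = rng.normal(0, 10, (6, 3))
        R, t, rms = fit_rigid_body(ref, ref + np.array([0.01, 0, 0]))
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, [0.01, 0, 0], atol=1e-12)
        assert rms < 1e-12

    def test_pure_rotation_recovered_exactly(self, rng):
        ref = rng.normal(0, 10, (6, 3))
        ang = np.radians(1.0)
        R_true = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        R, t, _ = fit_rigid_body(ref, ref @ R_true.T)
        recovered = np.degrees(np.arccos((np.trace(R) - 1) / 2))
        assert recovered == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_collinear_markers_rejected(self):
        ref = np.outer(np.arange(4.0), np.array([1.0, 0, 0]))
        with pytest.raises(RecordingError):
            fit_rigid_body(ref, ref)

    def test_translation_error_under_noise_within_monte_carlo_bound(self, rng):
        """Mean |t_err| over trials stays below 3*sigma/sqrt(m) per axis."""
        sigma = 2.8e-3  # mm
        m = 6
        ref = rng.normal(0, 10, (m, 3))
        errs = []
        for _ in range(300):
            cur = ref + np.array([0.05, 0, 0]) + rng.normal(0, sigma, (m, 3))
            _, t, _ = fit_rigid_body(ref, cur)
            errs.append(np.abs(t - [0.05, 0, 0]))
        assert np.mean(errs) < 3 * sigma / np.sqrt(m)


class TestSeries:
    def test_rigid_world_gives_zero_series(self):
        rec = _static_recording()
        assert np.allclose(relative_displacement_series(rec), 0.0, atol=1e-9)
        assert np.allclose(rotation_series(rec), 0.0, atol=1e-9)

    def test_injected_oscillation_amplitude_recovered(self):
        spec = TestBenchSpec(elastic_amplitude_um=50.0, marker_noise_um=0.0)
        rec = generate_marker_recording(spec, "pre")
        series = relative_displacement_series(rec)
        windows = segment_cycles(rec)
        for a, b in windows:
            assert np.ptp(series[a:b]) == pytest.approx(50.0, rel=1e-9)

    def test_injected_rotation_amplitude_recovered(self):
        spec = TestBenchSpec(rot_amplitude_deg=0.2, marker_noise_um=0.0)
        rec = generate_marker_recording(spec, "pre")
        got = cycle_range_mean(rotation_series(rec), segment_cycles(rec))
        assert got == pytest.approx(0.2, rel=1e-6)

    def test_common_mode_motion_cancels(self):
        """Applying one rigid motion to every body leaves both series zero."""
        rec = _static_recording()
        ang = np.radians(3.0)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        shift = np.array([5.0, -2.0, 1.0])
        bodies = {
            n: np.einsum("ij,nmj->nmi", R, b) + shift for n, b in rec.bodies.items()
        }
        moved = MarkerRecording(
            time_s=rec.time_s, bodies=bodies, shear_n=rec.shear_n, phase="pre"
        )
        assert np.allclose(relative_displacement_series(moved), 0.0, atol=1e-6)
        assert np.allclose(rotation_series(moved), 0.0, atol=1e-9)

    def test_missing_body_rejected(self):
        rec = _static_recording()
        with pytest.raises(RecordingError):
            relative_displacement_series(rec, "glenosphere", "graft")


class TestCycleRangeMean:
    def test_constant_series_zero(self):
        assert cycle_range_mean(np.full(60, 3.0), [(0, 30), (30, 60)]) == 0.0

    def test_sinusoid_range_is_twice_amplitude(self):
        t = np.arange(60)
        series = -5.0 * np.cos(2 * np.pi * t / 30)  # extrema fall on samples
        got = cycle_range_mean(series, [(0, 30), (30, 60)])
        assert got == pytest.approx(10.0, rel=1e-9)

    def test_matches_bruteforce_scan(self, rng):
        series = rng.normal(0, 1, 90)
        windows = [(0, 30), (30, 60), (60, 90)]
        brute = np.mean(
            [max(series[a:b]) - min(series[a:b]) for a, b in windows]
        )
        assert cycle_range_mean(series, windows) == pytest.approx(brute)

    def test_empty_window_rejected(self):
        with pytest.raises(RecordingError):
            cycle_range_mean(np.arange(10.0), [(3, 3)])


class TestInterfaceSplit:
    def test_default_split_recovered_noiselessly(self, noiseless_bench_pair):
        pre, _, _ = noiseless_bench_pair
        split = interface_split(pre)
        assert split["implant_graft_pct"] == pytest.approx(53.0, abs=1e-6)
        assert split["graft_glenoid_pct"] == pytest.approx(47.0, abs=1e-6)

    def test_graft_locked_to_glenoid_gives_100_0(self):
        spec = TestBenchSpec(graft_split=1.0, marker_noise_um=0.0)
        split = interface_split(generate_marker_recording(spec, "pre"))
        assert split["implant_graft_pct"] == pytest.approx(100.0)
        assert split["graft_glenoid_pct"] == pytest.approx(0.0)

    def test_even_split_symmetric(self):
        spec = TestBenchSpec(graft_split=0.5, marker_noise_um=0.0)
        split = interface_split(generate_marker_recording(spec, "pre"))
        assert split["implant_graft_pct"] == pytest.approx(50.0, abs=1e-6)

    def test_percentages_sum_to_100(self, noiseless_bench_pair):
        pre, _, _ = noiseless_bench_pair
        split = interface_split(pre)
        assert split["implant_graft_pct"] + split["graft_glenoid_pct"] == pytest.approx(100.0)

    def test_graft_absent_rejected(self):
        rec = _static_recording()
        with pytest.raises(RecordingError):
            interface_split(rec)


class TestStabilityOutcome:
    def test_deltas_and_flag(self, noiseless_bench_pair):
        pre, post, spec = noiseless_bench_pair
        out = stability_outcome(pre, post)
        assert out.micromotion_pre_um == pytest.approx(spec.elastic_amplitude_um, rel=1e-9)
        assert out.micromotion_delta_um == pytest.approx(spec.post_added_um, rel=1e-6)
        assert out.rotation_delta_deg == pytest.approx(spec.rot_post_added_deg, rel=1e-4)
        assert not out.exceeds_150um

    def test_identical_recordings_give_zero_delta(self, noiseless_bench_pair):
        pre, _, _ = noiseless_bench_pair
        post_like = MarkerRecording(
            time_s=pre.time_s, bodies=dict(pre.bodies), shear_n=pre.shear_n, phase="post"
        )
        out = stability_outcome(pre, post_like)
        assert out.micromotion_delta_um == 0.0

    def test_post_above_threshold_flagged(self):
        spec = TestBenchSpec(
            elastic_amplitude_um=150.0, post_added_um=10.0, marker_noise_um=0.0
        )
        out = stability_outcome(
            generate_marker_recording(spec, "pre"),
            generate_marker_recording(spec, "post"),
        )
        assert out.exceeds_150um

    def test_mismatched_configuration_rejected(self, noiseless_bench_pair):
        pre, _, _ = noiseless_bench_pair
        no_graft = TestBenchSpec(marker_noise_um=0.0)
        post = generate_marker_recording(no_graft, "post")
        with pytest.raises(RecordingError):
            stability_outcome(pre, post)


def test_trajectory_csv_roundtrip(tmp_path, noiseless_bench_pair):
    pre, _, _ = noiseless_bench_pair
    path = tmp_path / "pre.csv"
    write_recording_csv(pre, path)
    back = read_recording_csv(path)
    assert set(back.bodies) == set(pre.bodies)
    for name in pre.bodies:
        np.testing.assert_allclose(back.bodies[name], pre.bodies[name], atol=1e-9)
    np.testing.assert_allclose(back.shear_n, pre.shear_n, atol=1e-9)
    assert back.phase == "pre"
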