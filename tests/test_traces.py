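"""F/F_peak traces, peak-to-peak statistics, alignment, residency."""

import numpy as np
import pytest

import cistrack as ct
from cistrack.detect import Spot, Track
from cistrack.traces import CisternaTrace


def _track(frames, pos):
    return Track(
        track_id=0,
        spots=[
            Spot(frame=f, z_um=p[0], y_um=p[1], x_um=p[2], intensity=1.0, diameter_um=0.5)
            for f, p in zip(frames, pos)
        ],
    )


def _trace(times, green, red):
    return CisternaTrace(
        track_id=0,
        times=np.asarray(times, dtype=float),
        intensity=np.column_stack([green, red]).astype(float),
        roi_radius_um=0.35,
        background=np.zeros(2),
    )


class TestExtractTrace:
    def test_uniform_image_gives_constant_trace(self):
        stack = np.full((4, 2, 9, 20, 20), 37.0, dtype=np.float32)
        track = _track(range(4), [[0.8, 1.0, 1.0]] * 4)
        tr = ct.extract_trace(track, stack, (0.2, 0.1, 0.1), 5.0)
        np.testing.assert_allclose(tr.intensity, 37.0)
        np.testing.assert_allclose(tr.times, [0, 5, 10, 15])

    def test_zero_roi_radius_rejected(self):
        stack = np.zeros((1, 2, 5, 10, 10), dtype=np.float32)
        track = _track([0], [[0.4, 0.5, 0.5]])
        with pytest.raises(ValueError):
            ct.extract_trace(track, stack, (0.2, 0.1, 0.1), 5.0, roi_radius_um=0.0)

    def test_border_roi_truncated_with_warning(self):
        stack = np.full((1, 1, 9, 20, 20), 5.0, dtype=np.float32)
        track = _track([0], [[0.8, 0.05, 1.0]])
        with pytest.warns(UserWarning, match="truncated"):
            tr = ct.extract_trace(track, stack, (0.2, 0.1, 0.1), 5.0)
        assert tr.intensity[0, 0] == pytest.approx(5.0)

    def test_noiseless_trace_follows_kinetics(self, maturation_replicate):
        config, scene, stack, truth = maturation_replicate
        cis = scene[0]
        frames = np.arange(config.n_frames)
        track = _track(frames, cis.trajectory)
        tr = ct.extract_trace(
            track, stack, config.voxel_size, config.frame_interval,
            background=float(config.camera_offset),
        )
        for c in (0, 1):
            expected = ct.kinetic_profile(tr.times, cis.kinetics[c])
            r = np.corrcoef(tr.intensity[:, c], expected)[0, 1]
            assert r > 0.99

    def test_normalized_max_is_one_and_idempotent(self, maturation_replicate):
        config, scene, stack, _ = maturation_replicate
        track = _track(np.arange(config.n_frames), scene[0].trajectory)
        tr = ct.extract_trace(track, stack, config.voxel_size, config.frame_interval)
        norm = tr.normalized
        np.testing.assert_allclose(norm.max(axis=0), 1.0)
        renorm = norm / norm.max(axis=0)
        np.testing.assert_allclose(renorm, norm)


class TestFindPeak:
    def test_simple_maximum(self):
        assert ct.find_peak([0, 1, 3, 1, 0], [0, 5, 10, 15, 20], 1) == 10.0

    def test_plateau_takes_earliest(self):
        assert ct.find_peak([0, 3, 3, 0], [0, 5, 10, 15], 1) == 5.0

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="no unique peak"):
            ct.find_peak([2, 2, 2, 2], [0, 5, 10, 15], 1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ct.find_peak([0, 1], [0, 5], 1)

    def test_smoothing_rescues_noisy_pulse(self):
        rng = np.random.default_rng(4)
        times = np.arange(0, 200, 5.0)
        k = ct.MarkerKinetics(peak_time=95.0, rise_sigma=15.0, decay_sigma=20.0)
        noisy = ct.kinetic_profile(times, k) + rng.normal(0, 0.06, times.size)
        assert abs(ct.find_peak(noisy, times, 3) - 95.0) <= 5.0


class TestPeakToPeak:
    def test_arithmetic(self):
        tr = _trace([0, 5, 10, 41, 50], [0, 1, 3, 1, 0], [0, 0, 1, 3, 1])
        pair = ct.peak_to_peak(tr, smoothing_window=1)
        assert pair.t_green_peak == 10.0
        assert pair.t_red_peak == 41.0
        assert pair.delta == 31.0
        assert pair.midpoint == 25.5

    def test_identical_channels_delta_zero(self):
        tr = _trace([0, 5, 10, 15], [0, 3, 1, 0], [0, 3, 1, 0])
        assert ct.peak_to_peak(tr, smoothing_window=1).delta == 0.0

    def test_red_before_green_negative_delta(self):
        tr = _trace([0, 10, 20, 30, 40, 50], [0, 0, 0, 1, 3, 0], [0, 1, 3, 1, 0, 0])
        pair = ct.peak_to_peak(tr, smoothing_window=1)
        assert pair.delta == pytest.approx(-20.0)


class TestAlignAndAverage:
    def test_single_trace_peaks_at_plus_minus_half_delta(self):
        times = np.arange(0, 100, 5.0)
        g = ct.kinetic_profile(times, ct.MarkerKinetics(peak_time=30.0))
        r = ct.kinetic_profile(times, ct.MarkerKinetics(peak_time=60.0))
        tr = _trace(times, g, r)
        pair = ct.peak_to_peak(tr, smoothing_window=1)
        summary = ct.align_and_average([tr], [pair])
        grid = summary.grid_s
        assert grid[np.nanargmax(summary.mean_curves[:, 0])] == pytest.approx(-pair.delta / 2)
        assert grid[np.nanargmax(summary.mean_curves[:, 1])] == pytest.approx(+pair.delta / 2)

    def test_two_identical_traces_sem_zero(self):
        times = np.arange(0, 60, 5.0)
        g = ct.kinetic_profile(times, ct.MarkerKinetics(peak_time=20.0))
        r = ct.kinetic_profile(times, ct.MarkerKinetics(peak_time=40.0))
        traces = [_trace(times, g, r) for _ in range(2)]
        pairs = [ct.peak_to_peak(t, smoothing_window=1) for t in traces]
        summary = ct.align_and_average(traces, pairs)
        np.testing.assert_allclose(summary.sem_curves[summary.coverage == 2], 0.0, atol=1e-12)
        assert summary.n == 2
        assert summary.sem_delta_s == pytest.approx(summary.sd_delta_s / np.sqrt(2))

    def test_time_offset_invariance(self):
        times = np.arange(0, 80, 5.0)
        g = ct.kinetic_profile(times, ct.MarkerKinetics(peak_time=25.0))
        r = ct.kinetic_profile(times, ct.MarkerKinetics(peak_time=45.0))
        p0 = ct.peak_to_peak(_trace(times, g, r), smoothing_window=1)
        p1 = ct.peak_to_peak(_trace(times + 17.0, g, r), smoothing_window=1)
        assert p1.delta == p0.delta
        assert p1.midpoint == pytest.approx(p0.midpoint + 17.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ct.align_and_average([], [])


class TestResidencyInterval:
    def test_triangle_half_threshold(self):
        start, end = ct.residency_interval([0.0, 10.0, 20.0], [0.0, 1.0, 0.0], 0.5)
        assert (start, end) == (5.0, 15.0)

    def test_zero_threshold_full_support(self):
        start, end = ct.residency_interval([0.0, 10.0, 20.0], [0.0, 1.0, 0.0], 0.0)
        assert (start, end) == (0.0, 20.0)

    def test_unreachable_threshold_rejected(self):
        with pytest.raises(ValueError):
            ct.residency_interval([0, 10], [0.1, 0.2], 5.0)

    def test_asymmetric_pulse_brackets_peak(self):
        times = np.arange(0.0, 120.0, 2.0)
        k = ct.MarkerKinetics(peak_time=50.0, rise_sigma=10.0, decay_sigma=30.0)
        curve = ct.kinetic_profile(times, k)
        start, end = ct.residency_interval(times, curve, 0.2)
        assert start < 50.0 < end
        assert end - 50.0 > 50.0 - start  # slower decay -> longer tail


class TestSummarizeMaturation:
    def test_grid_quantization_bound_noiseless(self):
        """On effectively noiseless movies every recovered delta is on the
        frame grid and within one frame interval of that cisterna's truth."""
        import dataclasses

        config, scene = ct.maturation_scene(31.0, 15.0, 6, seed=13)
        config = dataclasses.replace(
            config, read_noise_sd=0.0, photons_per_unit=20000.0
        )
        stack, truth = ct.generate_movie(config, scene)
        spots = ct.detect_spots_movie(
            stack, config.voxel_size,
            psf_sigma_xy=config.psf_sigma_xy, psf_sigma_z=config.psf_sigma_z,
        )
        tracks = ct.link_tracks(spots)
        _, traces, pairs, _ = ct.summarize_maturation(
            tracks, stack, config.voxel_size, config.frame_interval
        )
        assert len(pairs) == len(scene)
        homes = {c.cisterna_id: c.trajectory.mean(axis=0) for c in scene}
        true_delta = truth.cisternae.set_index("cisterna_id")["delta_true_s"]
        for trace, pair in zip(traces, pairs):
            assert pair.delta % config.frame_interval == pytest.approx(0.0, abs=1e-9)
            track = next(t for t in tracks if t.track_id == trace.track_id)
            pos = track.positions.mean(axis=0)
            cid = min(homes, key=lambda k: np.linalg.norm(homes[k] - pos))
            assert abs(pair.delta - true_delta[cid]) <= config.frame_interval + 1e-9

    def test_noisy_deltas_on_frame_grid(self, maturation_replicate):
        config, scene, stack, truth = maturation_replicate
        spots = ct.detect_spots_movie(
            stack, config.voxel_size,
            psf_sigma_xy=config.psf_sigma_xy, psf_sigma_z=config.psf_sigma_z,
        )
        tracks = ct.link_tracks(spots)
        summary, *_ = ct.summarize_maturation(
            tracks, stack, config.voxel_size, config.frame_interval
        )
        assert summary.n >= 8  # most of the 10 cisternae usable
        np.testing.assert_allclose(
            np.mod(summary.deltas_s, config.frame_interval), 0.0, atol=1e-9
        )

    def test_exclusions_are_logged(self, maturation_replicate):
        config, _, stack, _ = maturation_replicate
        short = _track([0, 1], [[2.0, 2.0, 2.0]] * 2)
        usable = ct.link_tracks(
            ct.detect_spots_movie(
                stack, config.voxel_size,
                psf_sigma_xy=config.psf_sigma_xy, psf_sigma_z=config.psf_sigma_z,
            )
        )
        _, _, _, log = ct.summarize_maturation(
            [short] + usable, stack, config.voxel_size, config.frame_interval
        )
        assert any("excluded" in line for line in log)
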