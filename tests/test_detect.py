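"""Blob detection, track linking, and contact-event conventions."""

import numpy as np
import pytest

import cistrack as ct
from cistrack.detect import Spot
from conftest import static_cisterna


def _spot(frame, z, y, x):
    return Spot(frame=frame, z_um=z, y_um=y, x_um=x, intensity=1.0, diameter_um=0.5)


class TestDetectSpots:
    def test_requires_voxel_sizes(self):
        with pytest.raises(ValueError, match="voxel_size"):
            ct.detect_spots(np.zeros((5, 10, 10)), None)

    def test_blank_frame_yields_nothing(self, small_config):
        stack, _ = ct.generate_movie(small_config, [])
        assert ct.detect_spots(stack[0, 0], small_config.voxel_size) == []

    def test_single_spot_center_accuracy(self, noiseless_config):
        cis = static_cisterna([2.0, 2.13, 1.87])
        stack, _ = ct.generate_movie(noiseless_config, [cis])
        spots = ct.detect_spots(
            stack[0, 0],
            noiseless_config.voxel_size,
            threshold=100.0,
            threshold_mode="absolute",
            psf_sigma_xy=noiseless_config.psf_sigma_xy,
            psf_sigma_z=noiseless_config.psf_sigma_z,
        )
        assert len(spots) == 1
        s = spots[0]
        err = np.array([s.z_um - 2.0, s.y_um - 2.13, s.x_um - 1.87])
        # sub-voxel localization: better than half a voxel on each axis
        assert np.all(np.abs(err) < 0.5 * np.array(noiseless_config.voxel_size))

    def test_two_separated_spots_both_found(self, small_config):
        a = static_cisterna([2.0, 1.2, 1.2])
        b = static_cisterna([2.0, 2.8, 2.8])
        b.cisterna_id = 1
        stack, _ = ct.generate_movie(small_config, [a, b])
        spots = ct.detect_spots(
            stack[0, 0],
            small_config.voxel_size,
            psf_sigma_xy=small_config.psf_sigma_xy,
            psf_sigma_z=small_config.psf_sigma_z,
        )
        assert len(spots) == 2

    def test_translation_equivariance(self, noiseless_config):
        cis = static_cisterna([2.0, 1.6, 1.6])
        stack, _ = ct.generate_movie(noiseless_config, [cis])
        frame = stack[0, 0]
        shifted = np.roll(frame, shift=(3, 4), axis=(1, 2))
        kwargs = dict(threshold=100.0, threshold_mode="absolute")
        (s0,) = ct.detect_spots(frame, noiseless_config.voxel_size, **kwargs)
        (s1,) = ct.detect_spots(shifted, noiseless_config.voxel_size, **kwargs)
        vz, vy, vx = noiseless_config.voxel_size
        assert s1.y_um - s0.y_um == pytest.approx(3 * vy, abs=1e-6)
        assert s1.x_um - s0.x_um == pytest.approx(4 * vx, abs=1e-6)
        assert s1.diameter_um == pytest.approx(s0.diameter_um, abs=1e-6)

    def test_diameter_estimate_psf_corrected(self, noiseless_config):
        cis = static_cisterna([2.0, 2.0, 2.0])
        stack, _ = ct.generate_movie(noiseless_config, [cis])
        (s,) = ct.detect_spots(
            stack[0, 0],
            noiseless_config.voxel_size,
            threshold=100.0,
            threshold_mode="absolute",
            psf_sigma_xy=noiseless_config.psf_sigma_xy,
            psf_sigma_z=noiseless_config.psf_sigma_z,
        )
        assert s.diameter_um == pytest.approx(0.5, abs=0.05)


class TestLinkTracks:
    def test_empty_input(self):
        assert ct.link_tracks([]) == []

    def test_single_moving_spot_one_track(self):
        spots = [_spot(f, 2.0, 2.0 + 0.1 * f, 2.0) for f in range(10)]
        tracks = ct.link_tracks(spots, max_displacement=0.5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_two_stationary_spots_two_tracks(self):
        spots = []
        for f in range(8):
            spots.append(_spot(f, 2.0, 1.0, 1.0))
            spots.append(_spot(f, 2.0, 3.0, 3.0))
        tracks = ct.link_tracks(spots, max_displacement=0.5)
        assert len(tracks) == 2
        for t in tracks:
            pos = t.positions
            assert np.ptp(pos, axis=0).max() == 0.0  # no identity switches

    def test_gap_bridging(self):
        spots = [_spot(f, 2.0, 2.0, 2.0) for f in range(10) if f != 4]
        tracks = ct.link_tracks(spots, max_displacement=0.5, max_gap=2)
        assert len(tracks) == 1
        frames, pos = tracks[0].interpolated()
        assert list(frames) == list(range(10))

    def test_gap_larger_than_max_gap_splits(self):
        spots = [_spot(f, 2.0, 2.0, 2.0) for f in (0, 1, 2, 7, 8)]
        tracks = ct.link_tracks(spots, max_displacement=0.5, max_gap=2)
        assert len(tracks) == 2

    def test_jump_beyond_gate_starts_new_track(self):
        spots = [_spot(0, 2.0, 1.0, 1.0), _spot(1, 2.0, 3.0, 3.0)]
        tracks = ct.link_tracks(spots, max_displacement=0.5)
        assert len(tracks) == 2

    def test_never_two_spots_per_frame_in_one_track(self, maturation_replicate):
        config, _, stack, _ = maturation_replicate
        spots = ct.detect_spots_movie(
            stack,
            config.voxel_size,
            psf_sigma_xy=config.psf_sigma_xy,
            psf_sigma_z=config.psf_sigma_z,
        )
        for t in ct.link_tracks(spots):
            frames = t.frames
            assert len(np.unique(frames)) == len(frames)
            assert (np.diff(frames) > 0).all()

    def test_noiseless_track_rmse_below_half_voxel(self, noiseless_config):
        import dataclasses

        config = dataclasses.replace(noiseless_config, n_frames=8)
        rng = np.random.default_rng(3)
        traj = np.array([2.0, 2.0, 2.0]) + np.cumsum(
            rng.normal(0, 0.02, size=(8, 3)), axis=0
        )
        cis = ct.SimCisterna(
            cisterna_id=0,
            birth_time=0.0,
            death_time=100.0,
            trajectory=traj,
            kinetics=(
                ct.MarkerKinetics(peak_time=0.0, rise_sigma=1e4, decay_sigma=1e4),
                ct.MarkerKinetics(peak_time=0.0, amplitude=0.0),
            ),
        )
        stack, truth = ct.generate_movie(config, [cis])
        spots = ct.detect_spots_movie(
            stack, config.voxel_size, channel=0, threshold=100.0, threshold_mode="absolute"
        )
        (track,) = ct.link_tracks(spots)
        rmse = np.sqrt(np.mean((track.positions - traj) ** 2))
        assert rmse < 0.5 * max(config.voxel_size)


class TestDetectContacts:
    def test_duration_convention(self):
        # three consecutive close frames at 1.1 s spacing span 2.2 s
        spots = [
            _spot(f, 2.0, 2.0, 2.0 if f in (5, 6, 7) else 3.5) for f in range(10)
        ]
        (track,) = ct.link_tracks(spots, max_displacement=2.0)
        events = ct.detect_contacts(
            [track], [[2.0, 2.0, 2.0]], frame_interval=1.1, contact_distance=0.35, min_frames=2
        )
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(2.2)
        assert (events[0].start_frame, events[0].end_frame) == (5, 7)

    def test_never_close_is_empty(self):
        spots = [_spot(f, 2.0, 2.0, 3.5) for f in range(6)]
        (track,) = ct.link_tracks(spots)
        assert (
            ct.detect_contacts([track], [[2.0, 2.0, 2.0]], 1.1, 0.35, 2) == []
        )

    def test_single_frame_dip_below_min_frames(self):
        spots = [_spot(f, 2.0, 2.0, 2.0 if f == 3 else 3.5) for f in range(6)]
        (track,) = ct.link_tracks(spots, max_displacement=2.0)
        assert ct.detect_contacts([track], [[2.0, 2.0, 2.0]], 1.1, 0.35, 2) == []

    def test_frame_interval_required(self):
        with pytest.raises(ValueError, match="frame_interval"):
            ct.detect_contacts([], [[0, 0, 0]], None)

    def test_simulated_contacts_recovered_within_one_frame(self):
        events, truth = ct.contact_recovery_experiment(n_pairs=4, seed=5)
        assert len(events) == len(truth)
        merged = events.sort_values("eres_id").reset_index(drop=True)
        expected = truth.sort_values("eres_id").reset_index(drop=True)
        err = (merged["duration_s"] - expected["duration_s"]).abs()
        assert (err <= 1.1 + 1e-9).all()
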