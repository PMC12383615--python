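"""Kinematics: heading, angular velocity, rotation counting, turn detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lateralis import (
    AngularSeries,
    PoseTrack,
    angular_velocity,
    count_rotations,
    detect_turn_events,
    head_trunk_angle,
    heading_series,
    ipsi_percentage,
    mean_angular_velocity,
)
from lateralis.kinematics import read_pose_csv, write_pose_csv

from conftest import rigid_track


def make_series(velocity, frame_rate=30.0, valid=None):
    v = np.asarray(velocity, dtype=float)
    if valid is None:
        valid = np.isfinite(v)
    t = (np.arange(v.size) + 0.5) / frame_rate
    return AngularSeries(t, v, valid, frame_rate)


class TestHeading:
    def test_cardinal_directions(self):
        # nose east of tailbase -> 0 deg; nose north -> 90 deg
        n = 3
        track = PoseTrack(
            time=np.arange(n) / 30,
            nose=np.tile([2.0, 0.0], (n, 1)),
            left_ear=np.tile([0.0, 0.5], (n, 1)),
            right_ear=np.tile([0.0, -0.5], (n, 1)),
            tailbase=np.tile([-3.0, 0.0], (n, 1)),
            frame_rate=30,
            hemisphere="right",
        )
        assert np.allclose(heading_series(track), 0.0)
        track_north = PoseTrack(
            time=track.time,
            nose=np.tile([0.0, 2.0], (n, 1)),
            left_ear=np.tile([-0.5, 0.0], (n, 1)),
            right_ear=np.tile([0.5, 0.0], (n, 1)),
            tailbase=np.tile([0.0, -3.0], (n, 1)),
            frame_rate=30,
            hemisphere="right",
        )
        assert np.allclose(heading_series(track_north), 90.0)

    @pytest.mark.parametrize("delta", [7.3, -45.0, 120.0, 179.5])
    def test_rotation_matrix_oracle(self, delta):
        """Rotating all coordinates by delta shifts every heading by delta."""
        base = rigid_track(np.array([10.0, 40.0, 80.0]))
        h0 = heading_series(base)
        th = np.deg2rad(delta)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = PoseTrack(
            time=base.time,
            nose=base.nose @ R.T,
            left_ear=base.left_ear @ R.T,
            right_ear=base.right_ear @ R.T,
            tailbase=base.tailbase @ R.T,
            frame_rate=base.frame_rate,
            hemisphere=base.hemisphere,
        )
        diff = heading_series(rotated) - h0
        diff = (diff + 180) % 360 - 180
        assert np.allclose(diff, delta if delta <= 180 else delta - 360, atol=1e-9)

    def test_coincident_nose_tail_masked(self):
        track = rigid_track(np.zeros(3))
        track.nose[1] = track.tailbase[1]
        h = heading_series(track)
        assert np.isnan(h[1]) and np.isfinite(h[[0, 2]]).all()


class TestAngularVelocity:
    def test_stationary_track_is_zero(self):
        s = angular_velocity(rigid_track(np.full(30, 25.0)))
        assert np.allclose(s.velocity, 0.0)

    @pytest.mark.parametrize("hemisphere,sign", [("left", 1.0), ("right", -1.0)])
    def test_constant_rotation_closed_form(self, hemisphere, sign):
        """90 deg/s CCW rotation at 30 fps -> 90 deg/s everywhere, sign by side."""
        heading = 3.0 * np.arange(60)  # +90 deg/s at 30 fps
        s = angular_velocity(rigid_track(heading, hemisphere=hemisphere))
        assert np.allclose(s.velocity, sign * 90.0, atol=1e-9)

    def test_wrap_at_seam(self):
        """Heading crossing +/-180 must not produce |v| above the true rate."""
        heading = np.linspace(170, 190, 21)  # crosses the seam at 1 deg/frame
        s = angular_velocity(rigid_track(heading, frame_rate=30))
        assert np.all(np.abs(np.abs(s.velocity) - 30.0) < 1e-9)

    def test_translation_and_scale_invariance(self):
        heading = np.cumsum(np.linspace(0, 4, 50))
        a = angular_velocity(rigid_track(heading))
        b = angular_velocity(
            rigid_track(heading, center=np.array([123.4, -56.7]), scale=3.5)
        )
        assert np.allclose(a.velocity, b.velocity, atol=1e-8)

    def test_reflection_flips_sign(self):
        heading = np.cumsum(np.full(40, 2.0))
        base = rigid_track(heading)
        mirrored = PoseTrack(
            time=base.time,
            nose=base.nose * [1, -1],
            left_ear=base.left_ear * [1, -1],
            right_ear=base.right_ear * [1, -1],
            tailbase=base.tailbase * [1, -1],
            frame_rate=base.frame_rate,
            hemisphere=base.hemisphere,
        )
        assert np.allclose(
            angular_velocity(base).velocity,
            -angular_velocity(mirrored).velocity,
            atol=1e-8,
        )

    def test_smoothing_exact_on_constant_rate_interior(self):
        heading = 3.0 * np.arange(120)
        s = angular_velocity(rigid_track(heading, hemisphere="left"), smooth_s=0.2)
        assert np.allclose(s.velocity[s.valid], 90.0, atol=1e-8)


class TestMeanAngularVelocity:
    def test_constant_speed(self):
        assert mean_angular_velocity(make_series(np.full(60, 50.0))) == pytest.approx(50.0)

    def test_immobile_phase_excluded(self):
        v = np.concatenate([np.full(30, 100.0), np.zeros(30)])
        assert mean_angular_velocity(
            make_series(v), immobile_threshold=10
        ) == pytest.approx(100.0)

    def test_no_active_frames_is_nan(self):
        with pytest.warns(UserWarning):
            out = mean_angular_velocity(make_series(np.full(40, 5.0)))
        assert np.isnan(out)

    def test_short_bursts_below_min_bout_excluded(self):
        v = np.zeros(90)
        v[10:13] = 100.0  # 0.1 s burst at 30 fps < 0.5 s min bout
        with pytest.warns(UserWarning):
            assert np.isnan(mean_angular_velocity(make_series(v)))

    def test_signed_variant(self):
        v = np.concatenate([np.full(30, 50.0), np.full(30, -50.0)])
        assert mean_angular_velocity(make_series(v)) == pytest.approx(50.0)
        assert mean_angular_velocity(make_series(v), signed=True) == pytest.approx(0.0)


class TestHeadTrunkAngle:
    def test_straight_body_is_zero(self):
        assert np.allclose(head_trunk_angle(rigid_track(np.linspace(0, 90, 10))), 0.0)

    def test_perpendicular_nose_dot_product_oracle(self):
        """Nose displaced perpendicular to the trunk axis -> 90 deg."""
        n = 2
        track = PoseTrack(
            time=np.arange(n) / 30,
            nose=np.tile([0.0, 1.5], (n, 1)),  # straight up from ear midpoint
            left_ear=np.tile([-0.5, 0.0], (n, 1)),
            right_ear=np.tile([0.5, 0.0], (n, 1)),
            tailbase=np.tile([-3.0, 0.0], (n, 1)),  # trunk along +x
            frame_rate=30,
            hemisphere="right",
        )
        head = track.nose[0] - 0.5 * (track.left_ear[0] + track.right_ear[0])
        trunk = 0.5 * (track.left_ear[0] + track.right_ear[0]) - track.tailbase[0]
        expected = np.degrees(
            np.arccos(head @ trunk / np.linalg.norm(head) / np.linalg.norm(trunk))
        )
        assert expected == pytest.approx(90.0)
        assert np.allclose(head_trunk_angle(track), expected)

    def test_mirror_symmetry(self):
        track = rigid_track(np.zeros(3))
        track.nose[:, 1] += 0.8  # bend head leftward
        bent_left = head_trunk_angle(track)
        track.nose[:, 1] -= 1.6  # same bend rightward
        bent_right = head_trunk_angle(track)
        assert np.allclose(bent_left, bent_right)
        assert np.all(bent_left > 0)

    def test_degenerate_masked(self):
        track = rigid_track(np.zeros(3))
        track.nose[1] = 0.5 * (track.left_ear[1] + track.right_ear[1])
        assert np.isnan(head_trunk_angle(track)[1])


def brute_force_rotation_count(velocity, frame_rate):
    """Independent oracle: per-sample accumulator walked step by step."""
    n_ipsi = n_contra = 0
    acc = 0.0
    for v in velocity:
        acc += v / frame_rate
        while acc >= 360.0:
            n_ipsi += 1
            acc -= 360.0
        while acc <= -360.0:
            n_contra += 1
            acc += 360.0
    return n_ipsi, n_contra


class TestCountRotations:
    def test_two_full_ipsi_rotations(self):
        # 720 deg total at 60 deg/s
        v = np.full(12 * 30, 60.0)
        assert count_rotations(make_series(v)) == (2, 0)

    def test_partial_rotation_not_counted(self):
        v = np.full(int(350 / 60 * 30), 60.0)  # 350 deg total
        assert count_rotations(make_series(v)) == (0, 0)

    def test_reversal_hand_integrated(self):
        """+400 deg then -400 deg: one rotation counted in each direction."""
        fr = 30.0
        v = np.concatenate([np.full(int(400 / 100 * fr), 100.0),
                            np.full(int(400 / 100 * fr), -100.0)])
        assert count_rotations(make_series(v, fr)) == (1, 1)

    @pytest.mark.parametrize("omega,duration", [(45.0, 20.0), (-100.0, 30.0), (90.0, 3.0)])
    def test_floor_identity_constant_velocity(self, omega, duration):
        fr = 30.0
        v = np.full(int(duration * fr), omega)
        expected = int(abs(omega) * duration // 360)
        n_i, n_c = count_rotations(make_series(v, fr))
        assert (n_i, n_c) == ((expected, 0) if omega > 0 else (0, expected))

    def test_random_profiles_match_brute_force(self, rng):
        fr = 30.0
        for _ in range(200):
            v = rng.normal(0, 150, size=rng.integers(10, 400))
            s = make_series(v, fr)
            assert count_rotations(s) == brute_force_rotation_count(v, fr)

    def test_invalid_frames_warn_and_count_as_zero(self):
        v = np.full(360, 60.0)
        v[5] = np.nan
        with pytest.warns(UserWarning):
            n_i, n_c = count_rotations(make_series(v))
        assert n_c == 0 and n_i >= 1


class TestIpsiPercentage:
    @pytest.mark.parametrize("ni,nc,expected", [(8, 2, 80.0), (5, 5, 50.0), (0, 7, 0.0)])
    def test_values(self, ni, nc, expected):
        assert ipsi_percentage(ni, nc) == pytest.approx(expected)

    def test_no_rotations_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(ipsi_percentage(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ipsi_percentage(-1, 2)


class TestDetectTurnEvents:
    def test_immobile_track_empty(self):
        assert detect_turn_events(make_series(np.zeros(100))) == []

    def test_small_twitch_below_min_angle(self):
        v = np.zeros(120)
        v[30:45] = 90.0  # 45 deg total
        assert detect_turn_events(make_series(v), min_angle=60) == []

    def test_scheduled_bouts_recovered(self):
        """3 ipsi + 2 contra bouts of >= 90 deg -> 5 events at the right onsets."""
        fr = 30.0
        v = np.zeros(int(60 * fr))
        onsets, dirs = [], []
        for i, sign in enumerate([1, -1, 1, 1, -1]):
            start = int((5 + 10 * i) * fr)
            v[start : start + int(1.5 * fr)] = sign * 90.0  # 135 deg bouts
            onsets.append(start / fr)
            dirs.append("ipsi" if sign > 0 else "contra")
        evs = detect_turn_events(make_series(v, fr), min_angle=90, min_speed=20)
        assert [e.direction for e in evs] == dirs
        for e, t0 in zip(evs, onsets):
            assert abs(e.onset_s - t0) <= 2 / fr


class TestPoseCSV:
    def test_roundtrip(self, tmp_path):
        track = rigid_track(np.linspace(0, 90, 20))
        path = tmp_path / "pose.csv"
        write_pose_csv(track, path)
        back = read_pose_csv(path, frame_rate=30.0, hemisphere="right")
        assert np.allclose(back.nose, track.nose)
        assert np.allclose(
            heading_series(back), heading_series(track), equal_nan=True
        )

    def test_likelihood_cutoff_masks_frames(self, tmp_path):
        import pandas as pd

        track = rigid_track(np.zeros(10))
        path = tmp_path / "pose.csv"
        write_pose_csv(track, path)
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        col = [c for c in df.columns if c[1] == "nose" and c[2] == "likelihood"][0]
        df.loc[df.index[3], col] = 0.1
        df.to_csv(path)
        back = read_pose_csv(path, 30.0, "right", likelihood_cutoff=0.9)
        assert not back.valid[3] and back.valid.sum() == 9


@given(
    offset=st.floats(-1e3, 1e3),
    scale=st.floats(0.01, 100.0),
)
def test_rotation_counts_invariant_under_similarity_transform(offset, scale):
    """Translating or scaling coordinates leaves counts unchanged."""
    heading = np.cumsum(np.full(400, 4.0))  # 120 deg/s at 30 fps
    a = rigid_track(heading)
    b = rigid_track(heading, center=np.array([offset, -offset]), scale=scale)
    ca = count_rotations(angular_velocity(a))
    cb = count_rotations(angular_velocity(b))
    assert ca == cb


def test_reflection_swaps_rotation_counts():
    heading = np.concatenate([np.cumsum(np.full(200, 6.0)), np.cumsum(np.full(100, -6.0))])
    base = rigid_track(heading)
    mirrored = PoseTrack(
        time=base.time,
        nose=base.nose * [1, -1],
        left_ear=base.left_ear * [1, -1],
        right_ear=base.right_ear * [1, -1],
        tailbase=base.tailbase * [1, -1],
        frame_rate=base.frame_rate,
        hemisphere=base.hemisphere,
    )
    ni, nc = count_rotations(angular_velocity(base))
    mi, mc = count_rotations(angular_velocity(mirrored))
    assert (ni, nc) == (mc, mi) and ni > 0
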