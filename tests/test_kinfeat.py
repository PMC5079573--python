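"""Kinematic preprocessing: filtering, segmentation, features, resampling."""

import numpy as np
import pandas as pd
import pytest

from kinstyle import kinfeat, synthkin
from kinstyle.errors import (
    DegenerateFrameError,
    InvalidArgumentError,
    NoMovementError,
    TruncatedTrialError,
)


def _trial_from_wrist(positions, rate=100.0):
    """A trial whose six markers all follow the given wrist path."""
    T = len(positions)
    samples = np.tile(np.asarray(positions, float)[:, None, :], (1, 6, 1))
    # displace non-wrist markers so frames are non-degenerate
    offsets = np.array([[0, 0, 0], [80, 15, 0], [160, 25, 10],
                        [70, -40, 5], [25, 45, -5], [150, 5, 10]], float)
    samples += offsets[None, :, :]
    return kinfeat.MarkerTrial(samples, rate, "P", "pour", 2, "t0")


class TestLowpassFilter:
    def test_constant_trajectory_unchanged(self):
        trial = _trial_from_wrist(np.ones((50, 3)) * 7.0)
        out = kinfeat.lowpass_filter(trial, 6.0)
        assert np.allclose(out.samples, trial.samples, atol=1e-9)

    def test_stopband_sinusoid_attenuated(self):
        # 20 Hz tone at 100 Hz sampling; zero-phase order-2 Butterworth at
        # 6 Hz has squared magnitude ~0.008 there, i.e. > 90% attenuation
        t = np.arange(400) / 100.0
        path = np.zeros((400, 3))
        path[:, 0] = 10.0 * np.sin(2 * np.pi * 20.0 * t)
        out = kinfeat.lowpass_filter(_trial_from_wrist(path), 6.0)
        mid = slice(100, 300)  # avoid edge transients
        amp = np.ptp(out.samples[mid, 0, 0]) / 2.0
        assert amp < 0.1 * 10.0

    def test_second_pass_changes_less_than_first(self, clean_trial):
        noisy = clean_trial.with_samples(
            clean_trial.samples
            + np.random.default_rng(0).normal(0, 1.0, clean_trial.samples.shape))
        once = kinfeat.lowpass_filter(noisy, 6.0)
        twice = kinfeat.lowpass_filter(once, 6.0)
        d1 = np.abs(once.samples - noisy.samples).max()
        d2 = np.abs(twice.samples - once.samples).max()
        assert d2 < d1

    def test_cutoff_at_nyquist_rejected(self, clean_trial):
        with pytest.raises(InvalidArgumentError):
            kinfeat.lowpass_filter(clean_trial, 50.0)


class TestSegmentReach:
    def _speed_profile_trial(self, speed, rate=100.0):
        # integrate a prescribed speed profile along x
        x = np.concatenate([[0.0], np.cumsum(speed[:-1]) / rate])
        path = np.zeros((len(speed), 3))
        path[:, 0] = x
        return _trial_from_wrist(path, rate)

    def test_crossings_found_at_known_samples(self):
        # trapezoid speed: 0 until sample 12, high until 88, 0 after
        speed = np.zeros(120)
        speed[12:88] = 500.0
        trial = self._speed_profile_trial(speed)
        win = kinfeat.segment_reach(trial, threshold_mm_s=20.0)
        # brute-force crossings of the *computed* wrist speed
        s = kinfeat.wrist_speed(trial)
        above = s > 20.0
        expect_on = int(np.argmax(above))
        expect_off = int(np.argmax(~above[expect_on:])) + expect_on
        assert (win.onset, win.offset) == (expect_on, expect_off)
        assert abs(win.onset - 12) <= 1 and abs(win.offset - 88) <= 1

    def test_all_zero_velocity_raises_no_movement(self):
        trial = _trial_from_wrist(np.zeros((60, 3)))
        with pytest.raises(NoMovementError):
            kinfeat.segment_reach(trial)

    def test_never_dropping_speed_raises_truncated(self):
        speed = np.full(80, 400.0)  # moving at start and end
        trial = self._speed_profile_trial(speed)
        with pytest.raises(TruncatedTrialError):
            kinfeat.segment_reach(trial)

    def test_zero_threshold_spans_interior(self):
        # strictly positive interior speed, exactly zero at both ends
        speed = np.zeros(100)
        speed[5:95] = 300.0 * np.sin(np.linspace(0.05, np.pi - 0.05, 90))
        trial = self._speed_profile_trial(speed)
        s = kinfeat.wrist_speed(trial)
        win = kinfeat.segment_reach(trial, threshold_mm_s=0.0)
        interior = np.flatnonzero(s > 0)
        assert win.onset == interior[0]
        assert win.offset == interior[-1] + 1

    def test_window_shrinks_with_threshold(self, clean_trial):
        filt = kinfeat.lowpass_filter(clean_trial)
        lengths = [kinfeat.segment_reach(filt, thr).length
                   for thr in (5.0, 20.0, 100.0)]
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_interior_onset_offset_on_generated_trial(self, clean_trial):
        filt = kinfeat.lowpass_filter(clean_trial)
        win = kinfeat.segment_reach(filt)
        assert 0 < win.onset < win.offset < clean_trial.n_samples - 1


class TestGlobalFeatures:
    def test_stationary_wrist_zero_velocity(self):
        trial = _trial_from_wrist(np.zeros((40, 3)))
        win = kinfeat.ReachWindow(5, 30, 0.0)
        feats = kinfeat.global_features(trial, win)
        assert np.allclose(feats["wrist_velocity"], 0.0)

    def test_aperture_is_tip_distance(self):
        trial = _trial_from_wrist(np.zeros((10, 3)))
        s = trial.samples.copy()
        s[:, 5] = [0, 0, 0]      # thumb_tip
        s[:, 2] = [3, 4, 0]      # index_tip
        trial = trial.with_samples(s)
        feats = kinfeat.global_features(trial, kinfeat.ReachWindow(0, 9, 0.0))
        assert np.allclose(feats["grip_aperture"], 5.0)

    def test_translation_shifts_position_not_velocity_aperture(self, clean_trial):
        filt = kinfeat.lowpass_filter(clean_trial)
        win = kinfeat.segment_reach(filt)
        base = kinfeat.global_features(filt, win)
        moved = filt.with_samples(filt.samples + 10.0)
        shifted = kinfeat.global_features(moved, win)
        assert np.allclose(shifted["wrist_velocity"], base["wrist_velocity"],
                           atol=1e-9)
        assert np.allclose(shifted["grip_aperture"], base["grip_aperture"],
                           atol=1e-9)
        assert np.allclose(shifted["wrist_height"], base["wrist_height"] + 10)
        assert np.allclose(shifted["wrist_horizontal"],
                           base["wrist_horizontal"] + 10)

    def test_speed_and_aperture_nonnegative(self, clean_trial):
        filt = kinfeat.lowpass_filter(clean_trial)
        win = kinfeat.segment_reach(filt)
        feats = kinfeat.global_features(filt, win)
        assert (feats["wrist_velocity"] >= 0).all()
        assert (feats["grip_aperture"] >= 0).all()


def _random_rigid_motion(rng):
    # random rotation via QR, proper orientation
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-100, 100, 3)
    return q, t


class TestLocalFrame:
    def test_known_marker_layout(self):
        samples = np.zeros((2, 6, 3))
        samples[:, 1] = [80, 0, 0]   # index_mcp
        samples[:, 3] = [0, 60, 0]   # little_mcp
        samples[:, 2] = [160, 10, 10]
        samples[:, 4] = [25, 45, -5]
        samples[:, 5] = [150, -10, 10]
        trial = kinfeat.MarkerTrial(samples, 100.0, "P", "pour", 2, "t")
        origin, R = kinfeat.local_frame(trial, 0)
        assert np.allclose(origin, 0)
        assert np.allclose(R[0], [1, 0, 0], atol=1e-12)
        assert np.allclose(np.abs(R[2]), [0, 0, 1], atol=1e-12)
        assert np.allclose(np.cross(R[0], R[1]), R[2], atol=1e-12)

    def test_orthonormality_on_generated_trial(self, clean_trial):
        _, R = kinfeat.local_frame(clean_trial, 30)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_collinear_markers_degenerate(self):
        samples = np.zeros((2, 6, 3))
        samples[:, 1] = [80, 0, 0]
        samples[:, 3] = [40, 0, 0]   # little_mcp on the same line
        trial = kinfeat.MarkerTrial(samples, 100.0, "P", "pour", 2, "t")
        with pytest.raises(DegenerateFrameError):
            kinfeat.local_frame(trial, 0)


class TestLocalFeatures:
    def test_rigid_motion_invariance(self, clean_trial, rng):
        filt = kinfeat.lowpass_filter(clean_trial)
        win = kinfeat.segment_reach(filt)
        base = kinfeat.local_features(filt, win).to_numpy()
        q, t = _random_rigid_motion(rng)
        moved = filt.with_samples(filt.samples @ q.T + t)
        out = kinfeat.local_features(moved, win).to_numpy()
        assert np.allclose(out, base, atol=1e-6)

    def test_normals_unit_length(self, clean_trial):
        filt = kinfeat.lowpass_filter(clean_trial)
        win = kinfeat.segment_reach(filt)
        feats = kinfeat.local_features(filt, win)
        for prefix in ("finger_plane", "dorsum_plane"):
            n = feats[[f"{prefix}_{c}" for c in "xyz"]].to_numpy()
            assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)

    def test_dorsum_normal_is_frame_z(self, clean_trial):
        # the dorsum plane is spanned by the frame-defining markers, so its
        # normal in that frame must be exactly (0, 0, +-1)
        filt = kinfeat.lowpass_filter(clean_trial)
        win = kinfeat.segment_reach(filt)
        feats = kinfeat.local_features(filt, win)
        dz = feats[["dorsum_plane_x", "dorsum_plane_y"]].to_numpy()
        assert np.allclose(dz, 0.0, atol=1e-9)
        assert np.allclose(np.abs(feats["dorsum_plane_z"]), 1.0, atol=1e-9)


class TestNormalizeResample:
    def test_linear_ramp_hits_grid_values(self):
        series = np.linspace(0, 100, 51)  # ramp over the window
        out = kinfeat.normalize_resample(series, n_points=10)
        assert np.allclose(out, np.arange(10, 101, 10), atol=1e-9)

    def test_constant_series_constant_profile(self):
        out = kinfeat.normalize_resample(np.full(37, 4.2), n_points=10)
        assert np.allclose(out, 4.2)

    def test_idempotent_on_zero_inclusive_grid(self):
        series = np.sin(np.linspace(0, 3, 11))
        once = kinfeat.normalize_resample(series, 11, include_zero=True)
        twice = kinfeat.normalize_resample(once, 11, include_zero=True)
        assert np.allclose(once, twice, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kinfeat.normalize_resample(np.array([1.0]), 10)


class TestBuildFeatureMatrix:
    def test_dimensions(self, pour_features):
        fm = pour_features
        assert fm.X.shape == (fm.n_trials, 16 * 10)
        assert len(fm.columns) == 160

    def test_columns_standardized(self, pour_features):
        fm = pour_features
        varying = fm.col_sd > 0
        assert np.allclose(fm.X[:, varying].mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.X[:, varying].std(axis=0), 1.0, atol=1e-6)

    def test_failing_trials_dropped_with_reason(self, pour_trials):
        frozen = pour_trials[0].with_samples(
            np.tile(pour_trials[0].samples[:1], (40, 1, 1)))
        frozen.trial_id = "frozen"
        fm = kinfeat.build_feature_matrix(list(pour_trials[:3]) + [frozen])
        assert fm.n_trials == 3
        assert fm.dropped and fm.dropped[0][0] == "frozen"
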