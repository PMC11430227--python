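"""Online and offline trajectory metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hybridarm as ha
from hybridarm.metrics import (
    SAL_CUTOFF_HZ,
    curvature_of_trajectory,
    distance_index,
    shoulder_spread_volume,
    spectral_arc_length,
)
from hybridarm.synthetic import minimum_jerk_profile


def _sal_oracle(v, fs, cutoff=20.0, padding=4):
    """Independent spectral-arc-length computation: explicit DFT sum rather
    than an FFT call, same zero-padded frequency grid."""
    n_fft = int(2 ** np.ceil(np.log2(padding * len(v))))
    k = np.arange(n_fft // 2 + 1)
    freqs = k * fs / n_fft
    t = np.arange(len(v))
    mag = np.abs(np.exp(-2j * np.pi * np.outer(k, t) / n_fft) @ v)
    sel = freqs <= cutoff
    f, m = freqs[sel], mag[sel] / mag[0]
    return -np.sum(np.sqrt(np.diff(f / cutoff) ** 2 + np.diff(m) ** 2))


def _minimum_jerk_path(n=100, duration=1.0, length=0.3):
    t = np.linspace(0, duration, n)
    x = length * minimum_jerk_profile(t / duration)
    pos = np.column_stack([x, np.zeros(n), np.zeros(n)])
    return pos, t


class TestSuccessRateAndTimes:
    def test_success_rate_fractions(self):
        def rec(success):
            return type("R", (), {"success": success})()

        assert ha.success_rate([rec(True)] * 4) == 100.0
        assert ha.success_rate([rec(False)] * 4) == 0.0
        assert ha.success_rate([rec(True)] * 3 + [rec(False)]) == 75.0
        with pytest.raises(ValueError):
            ha.success_rate([])

    def test_movement_and_validation_times(self):
        rec = type(
            "R", (), {"success": True, "movement_time": 2.4, "validation_time": 0.3}
        )()
        from hybridarm.metrics import movement_time, validation_time

        assert movement_time(rec) == 2.4
        assert validation_time(rec) == 0.3
        assert movement_time(rec) >= validation_time(rec)
        rec.success = False
        with pytest.raises(ValueError):
            movement_time(rec)


class TestShoulderSpreadVolume:
    def test_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        sigma = 0.03
        pts = rng.normal(0.0, sigma, size=(10_000, 3))
        q = stats.chi2.ppf(0.97, df=3)
        expected = (4 / 3) * np.pi * (sigma * np.sqrt(q)) ** 3 * 1e3
        assert shoulder_spread_volume(pts) == pytest.approx(expected, rel=0.05)

    def test_homogeneous_of_degree_three(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(500, 3)) * [0.02, 0.05, 0.01]
        assert shoulder_spread_volume(2 * pts) == pytest.approx(
            8 * shoulder_spread_volume(pts), rel=1e-9
        )

    def test_stationary_cloud_has_zero_volume(self):
        assert shoulder_spread_volume(np.zeros((10, 3))) == 0.0

    def test_coplanar_cloud_rejected(self):
        rng = np.random.default_rng(2)
        flat = rng.normal(size=(100, 3))
        flat[:, 2] = 0.0
        with pytest.raises(ValueError):
            shoulder_spread_volume(flat)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(500, 3)) * 0.05
        assert shoulder_spread_volume(pts + [1.0, -2.0, 0.5]) == pytest.approx(
            shoulder_spread_volume(pts), rel=1e-9
        )


class TestSpectralArcLength:
    def test_matches_independent_dft_oracle_on_minimum_jerk(self):
        pos, t = _minimum_jerk_path()
        v = np.linalg.norm(np.diff(pos, axis=0), axis=1) / np.diff(t)
        fs = 1.0 / np.mean(np.diff(t))
        expected = _sal_oracle(v, fs, cutoff=SAL_CUTOFF_HZ)
        assert spectral_arc_length(pos, t) == pytest.approx(expected, abs=1e-9)

    def test_regression_locked_minimum_jerk_value(self):
        # value frozen from the DFT oracle at n=100, 1 s, 0.3 m
        pos, t = _minimum_jerk_path()
        assert spectral_arc_length(pos, t) == pytest.approx(-1.9298322, abs=1e-4)

    def test_high_frequency_perturbation_reduces_smoothness(self):
        pos, t = _minimum_jerk_path(n=200)
        smooth = spectral_arc_length(pos, t)
        wobble = pos.copy()
        wobble[:, 0] += 0.005 * np.sin(2 * np.pi * 3.0 * t)
        assert spectral_arc_length(wobble, t) < smooth

    def test_bounded_above_by_minus_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(16, 200)
            t = np.arange(n) / 90.0
            pos = np.cumsum(rng.normal(0, 0.002, size=(n, 3)), axis=0)
            assert spectral_arc_length(pos, t) <= -1.0 + 1e-12

    def test_motionless_and_nonuniform_inputs_rejected(self):
        n = 32
        t = np.arange(n) / 90.0
        with pytest.raises(ValueError):
            spectral_arc_length(np.zeros((n, 3)), t)
        pos, tt = _minimum_jerk_path(n=50)
        with pytest.raises(ValueError):
            spectral_arc_length(pos, tt**1.5 + tt)

    def test_translation_invariance(self):
        pos, t = _minimum_jerk_path()
        assert spectral_arc_length(pos + [0.3, -0.2, 1.0], t) == pytest.approx(
            spectral_arc_length(pos, t)
        )


class TestPathShapeMetrics:
    def test_straight_monotone_path(self):
        pos = np.linspace([0, 0, 0], [0.3, 0.1, -0.2], 50)
        assert distance_index(pos) == pytest.approx(1.0)
        assert curvature_of_trajectory(pos) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_curvature_equals_radius(self):
        r = 0.2
        theta = np.linspace(0, np.pi, 100)
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(100)])
        assert curvature_of_trajectory(pos) == pytest.approx(r, rel=1e-3)

    def test_out_and_back_path_lengthens_distance_index(self):
        # out to 0.4 m, back to 0.2 m: path 0.6 m over a 0.2 m chord
        x = np.concatenate([np.linspace(0, 0.4, 30), np.linspace(0.4, 0.2, 16)[1:]])
        pos = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        assert distance_index(pos) == pytest.approx(3.0, rel=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.normal(0, 0.01, size=(60, 3)), axis=0)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = R.apply(pos) + [0.5, 0.2, -0.1]
        assert distance_index(moved) == pytest.approx(distance_index(pos), rel=1e-9)
        assert curvature_of_trajectory(moved) == pytest.approx(
            curvature_of_trajectory(pos), rel=1e-9
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_distance_index_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 0.01, size=(20, 3)), axis=0)
        if np.linalg.norm(pos[-1] - pos[0]) > 1e-9:
            assert distance_index(pos) >= 1.0 - 1e-12
            assert curvature_of_trajectory(pos) >= 0.0


class TestOfflineDistances:
    def _traj(self, angles):
        n = angles.shape[0]
        return ha.Trajectory(np.arange(n) / 90.0, angles)

    def test_identity_reconstruction_scores_zero(self, geometry):
        rng = np.random.default_rng(6)
        a = self._traj(rng.uniform(-30, 60, size=(40, 7)))
        d = ha.offline_distances(a, self._traj(a.angles.copy()), geometry)
        assert all(v == 0.0 for v in d.values())

    def test_constant_distal_offset_recovered_exactly(self, geometry):
        base = np.tile(ha.joint_angles(sfe=20, efe=80), (30, 1))
        shifted = base.copy()
        shifted[:, 2:] += 2.0
        d = ha.offline_distances(self._traj(base), self._traj(shifted), geometry)
        assert d["mmae_distal_deg"] == pytest.approx(2.0)
        assert d["mmae_proximal_deg"] == 0.0

    def test_perpendicular_axes_give_ninety_degrees(self, geometry):
        base = np.tile(ha.joint_angles(), (20, 1))
        bent = base.copy()
        bent[:, 6] = 90.0  # wrist flexion turns the grasp axis by 90 degrees
        d = ha.offline_distances(self._traj(base), self._traj(bent), geometry)
        assert d["mhod_deg"] == pytest.approx(90.0)

    def test_length_mismatch_rejected(self, geometry):
        a = self._traj(np.zeros((10, 7)))
        b = self._traj(np.zeros((11, 7)))
        with pytest.raises(ValueError):
            ha.offline_distances(a, b, geometry)


class TestAggregation:
    def test_phase_medians_match_sorting_oracle(self, geometry, rom, oracle_setup):
        targets, postures, oracle = oracle_setup
        recs, report = ha.run_phase(
            targets[:8], postures[:8], "interpolation", oracle, geometry, rom,
            ha.TrialConfig.exp2_test(), seed=9,
        )
        mts = sorted(r.movement_time for r in recs if r.success)
        n = len(mts)
        naive = mts[n // 2] if n % 2 else 0.5 * (mts[n // 2 - 1] + mts[n // 2])
        assert report.medians["movement_time_s"] == pytest.approx(naive)
        assert 0.0 <= report.success_rate <= 100.0
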