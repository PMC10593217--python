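"""Angle computation, decomposition, anomaly masking and ROM extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from romkit import (
    DecompositionConfig,
    KinematicScenario,
    NoiseModel,
    compute_trial_rom,
    decompose_additive,
    detect_anomalies,
    extract_rom,
    movement_angles,
    segment_vectors,
    simulate_trial,
)
from romkit.rom_engine import AngleSeries
from romkit.trajectory_io import TrialTrajectory

from conftest import make_trial


class TestSegmentVectors:
    def test_axis_normalization(self):
        v, keep = segment_vectors(np.array([[0.0, 2, 0]]), np.array([[0.0, 0, 0]]))
        np.testing.assert_allclose(v, [[0, 1, 0]])
        assert keep.all()

    def test_diagonal_by_hand(self):
        v, _ = segment_vectors(np.array([[1.0, 1, 0]]), np.array([[0.0, 0, 0]]))
        np.testing.assert_allclose(v, [[0.7071, 0.7071, 0]], atol=1e-4)

    def test_coincident_frame_dropped(self):
        p1 = np.array([[0.0, 1, 0], [0.0, 0, 0], [1.0, 0, 0]])
        p2 = np.zeros((3, 3))
        v, keep = segment_vectors(p1, p2)
        assert keep.tolist() == [True, False, True]
        assert len(v) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_unit_norm_to_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.normal(size=(20, 3))
        p2 = rng.normal(size=(20, 3))
        v, _ = segment_vectors(p1, p2)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-9)


class TestMovementAngles:
    def test_identity_vectors_zero_angle(self):
        v = np.tile([0.0, 1, 0], (5, 1))
        series = movement_angles(np.arange(5.0), v)
        np.testing.assert_allclose(series.alpha, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "vt,expected", [((1.0, 0, 0), 90.0), ((0.0, -1, 0), 180.0)]
    )
    def test_orthogonal_and_antiparallel(self, vt, expected):
        v = np.array([[0.0, 1, 0], list(vt)])
        series = movement_angles(np.arange(2.0), v)
        assert series.alpha[0] == 0.0
        np.testing.assert_allclose(series.alpha[1], expected, atol=1e-9)

    def test_mean_first_n_reference(self):
        rng = np.random.default_rng(0)
        v = np.tile([0.0, 1, 0], (10, 1)) + rng.normal(0, 1e-3, (10, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        series = movement_angles(np.arange(10.0), v, reference="mean_first_n")
        np.testing.assert_allclose(np.linalg.norm(series.v0), 1.0, atol=1e-12)

    def test_noiseless_rotation_reaches_programmed_apex(self, back_flexion):
        traj = make_trial(back_flexion, true_rom=120.0)
        res = compute_trial_rom(traj, back_flexion)
        assert abs(res.rom - 120.0) < 1e-6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rigid_transform_and_scale_invariance(self, seed):
        """Angles are invariant to rotation + translation + positive scale."""
        rng = np.random.default_rng(seed)
        p1 = rng.normal(size=(15, 3)) + [0, 2, 0]
        p2 = rng.normal(scale=0.1, size=(15, 3))
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        shift = rng.normal(size=3)
        scale = float(rng.uniform(0.2, 5.0))
        v_a, _ = segment_vectors(p1, p2)
        alpha_a = movement_angles(np.arange(15.0), v_a).alpha
        q1 = scale * (p1 @ rot.T) + shift
        q2 = scale * (p2 @ rot.T) + shift
        v_b, _ = segment_vectors(q1, q2)
        alpha_b = movement_angles(np.arange(15.0), v_b).alpha
        np.testing.assert_allclose(alpha_a, alpha_b, atol=1e-7)


class TestDecomposition:
    def test_linear_ramp_has_no_seasonality(self):
        alpha = np.linspace(0, 90, 80)
        trend, seasonal, residual = decompose_additive(
            alpha, DecompositionConfig(period=10)
        )
        assert np.abs(seasonal).max() < 1e-9
        assert np.abs(residual[10:-10]).max() < 1e-9

    def test_constant_series_decomposes_trivially(self):
        alpha = np.full(60, 42.0)
        trend, seasonal, residual = decompose_additive(
            alpha, DecompositionConfig(period=12)
        )
        np.testing.assert_allclose(trend, 42.0)
        np.testing.assert_allclose(seasonal, 0.0, atol=1e-12)
        np.testing.assert_allclose(residual, 0.0, atol=1e-12)

    def test_pure_sine_lands_in_seasonal(self):
        period = 12
        n = 6 * period
        alpha = 5.0 * np.sin(2 * np.pi * np.arange(n) / period)
        trend, seasonal, residual = decompose_additive(
            alpha, DecompositionConfig(period=period)
        )
        interior = slice(period, n - period)
        assert np.abs(residual[interior]).max() < 1e-9
        assert np.abs(seasonal).max() > 4.0

    @given(st.integers(0, 2**31 - 1), st.integers(2, 15))
    @settings(max_examples=30, deadline=None)
    def test_additivity_exact_on_every_frame(self, seed, period):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2 * period, 6 * period))
        alpha = rng.normal(size=n).cumsum()
        trend, seasonal, residual = decompose_additive(
            alpha, DecompositionConfig(period=period)
        )
        np.testing.assert_allclose(trend + seasonal + residual, alpha, atol=1e-10)

    def test_short_series_falls_back_to_trend_only(self, caplog):
        import logging

        alpha = np.arange(10.0)
        with caplog.at_level(logging.WARNING):
            trend, seasonal, residual = decompose_additive(
                alpha, DecompositionConfig(period=8)
            )
        np.testing.assert_allclose(seasonal, 0.0)
        np.testing.assert_allclose(trend + residual, alpha, atol=1e-12)

    def test_interior_trend_matches_statsmodels(self):
        """Independent oracle: classical decomposition, interior frames."""
        from statsmodels.tsa.seasonal import seasonal_decompose

        rng = np.random.default_rng(5)
        period = 10
        n = 8 * period
        alpha = (
            np.linspace(0, 60, n)
            + 2 * np.sin(2 * np.pi * np.arange(n) / period)
            + rng.normal(0, 0.3, n)
        )
        trend, seasonal, residual = decompose_additive(
            alpha, DecompositionConfig(period=period)
        )
        ref = seasonal_decompose(alpha, model="additive", period=period)
        interior = slice(period, n - period)
        np.testing.assert_allclose(trend[interior], ref.trend[interior], atol=1e-8)
        np.testing.assert_allclose(
            seasonal[interior], ref.seasonal[interior], atol=0.2
        )


class TestAnomalyDetection:
    def test_constant_residuals_flag_nothing(self):
        assert not detect_anomalies(np.full(50, 1.3)).any()

    def test_single_spike_flagged_exactly(self):
        rng = np.random.default_rng(2)
        residual = rng.normal(0, 0.01, 101)
        residual[40] = 50.0
        mask = detect_anomalies(residual)
        assert mask[40] and mask.sum() == 1

    def test_three_spikes_flagged_and_max_angle_unaffected(self, back_flexion):
        """Three landmark-space glitches must not move the extracted ROM."""
        scenario = KinematicScenario(movement=back_flexion, true_rom=60.0)
        clean = simulate_trial(scenario, NoiseModel(landmark_sigma=0.002, seed=11))
        spiky = simulate_trial(
            scenario,
            NoiseModel(landmark_sigma=0.002, outlier_rate=3 / 91,
                       outlier_scale=0.25, seed=11),
        )
        from romkit import compute_angle_series

        spike_frames = spiky.provenance["outlier_frames"]
        assert len(spike_frames) >= 1
        s_clean = compute_angle_series(clean, back_flexion)
        s_spiky = compute_angle_series(spiky, back_flexion)
        # spikes whose angle deviation clears the residual threshold must
        # be masked (a spike along the segment axis barely moves the angle)
        sd = s_spiky.residual.std()
        for frame in spike_frames:
            if abs(s_spiky.alpha[frame] - s_clean.alpha[frame]) > 3 * sd:
                assert s_spiky.anomaly_mask[frame]
        r_clean = compute_trial_rom(clean, back_flexion)
        r_spiky = compute_trial_rom(spiky, back_flexion)
        assert abs(r_spiky.rom - r_clean.rom) < 0.5


class TestExtractRom:
    def _series(self, alpha, mask=None):
        alpha = np.asarray(alpha, float)
        return AngleSeries(
            t=np.arange(len(alpha), dtype=float),
            alpha=alpha,
            v0=np.array([0.0, 1, 0]),
            anomaly_mask=mask,
        )

    def test_single_excursion(self):
        alpha = np.r_[np.linspace(0, 90, 30), np.linspace(90, 0, 30)[1:]]
        res = extract_rom(self._series(alpha))
        assert res.rom == pytest.approx(90.0)
        assert not res.multi_peak_flag

    def test_masked_spike_does_not_win(self):
        alpha = np.r_[np.linspace(0, 100, 40), np.linspace(100, 0, 40)[1:]]
        alpha[20] = 150.0
        mask = np.zeros(len(alpha), bool)
        mask[20] = True
        res = extract_rom(self._series(alpha, mask))
        assert res.rom == pytest.approx(100.0)
        assert res.n_anomalies == 1

    def test_bimodal_series_sets_multi_peak_flag(self):
        up = np.linspace(0, 100, 25)
        down = np.linspace(100, 40, 20)[1:]
        up2 = np.linspace(40, 99, 20)[1:]
        down2 = np.linspace(99, 0, 25)[1:]
        res = extract_rom(self._series(np.r_[up, down, up2, down2]))
        assert res.multi_peak_flag
        assert res.rom == pytest.approx(100.0)

    def test_shallow_second_peak_not_flagged(self):
        up = np.linspace(0, 100, 25)
        dip = np.linspace(100, 96, 10)[1:]
        up2 = np.linspace(96, 99, 10)[1:]
        down = np.linspace(99, 0, 25)[1:]
        res = extract_rom(self._series(np.r_[up, dip, up2, down]))
        assert not res.multi_peak_flag

    def test_no_usable_frames_marks_unusable(self):
        alpha = np.linspace(0, 50, 10)
        res = extract_rom(self._series(alpha, np.ones(10, bool)))
        assert not res.usable

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_max_without_anomalies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        alpha = rng.uniform(0, 180, n)
        res = extract_rom(self._series(alpha))
        assert res.rom == max(float(a) for a in alpha)


class TestEndToEnd:
    def test_all_visibilities_low_yields_unusable(self, back_flexion, clean_trial):
        df = clean_trial.df.copy()
        df["visibility"] = 0.4
        traj = TrialTrajectory("S1", clean_trial.movement, "pose33", 1, 15.0, df)
        res = compute_trial_rom(traj, back_flexion)
        assert not res.usable

    def test_spiky_trial_recovers_truth_within_tolerance(self, back_flexion):
        scenario = KinematicScenario(movement=back_flexion, true_rom=60.0)
        noise = NoiseModel(landmark_sigma=0.005, outlier_rate=0.02,
                           outlier_scale=0.2, seed=4)
        res = compute_trial_rom(simulate_trial(scenario, noise), back_flexion)
        assert res.usable
        assert abs(res.rom - 60.0) < 3.0

    def test_mocap_dialect_end_to_end(self):
        from romkit import lookup

        spec = lookup("Neck Rotation")
        traj = make_trial(spec, dialect="mocap39", true_rom=70.0, fps=120.0)
        res = compute_trial_rom(traj, spec)
        assert abs(res.rom - 70.0) < 1e-6
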