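"""Trajectory linking and filopodial lifecycle statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from filoquant import synthetic, tracks
from filoquant.errors import (
    DegenerateTestError,
    InsufficientDataError,
    InvalidParameterError,
)
from filoquant.synthetic import TrajectoryTruth
from filoquant.tracks import (
    Trajectory,
    delta_trace,
    distribution_summary,
    final_delta_ttest,
    instantaneous_speeds,
    link_puncta,
    lognormal_fit,
    speed_molecule_correlation,
    start_molecules,
    trend_curve,
)


def detections(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "molecules"])


def traj_from_molecules(molecules, dt=1.0, speeds_um=0.0):
    molecules = np.asarray(molecules, float)
    n = molecules.size
    x = np.cumsum(np.full(n, speeds_um)) - speeds_um
    frames = np.arange(n)
    return Trajectory(
        id=0,
        frames=frames,
        times=frames * dt,
        xy=np.column_stack([x, np.zeros(n)]),
        molecules=molecules,
    )


class TestLinking:
    def test_single_moving_punctum_is_one_trajectory(self):
        det = detections([(f, 0.3 * f, 0.0, 100.0) for f in range(5)])
        trajs = link_puncta(det)
        assert len(trajs) == 1
        assert trajs[0].n_frames == 5

    def test_steps_beyond_max_link_split(self):
        det = detections([(0, 0.0, 0.0, 100.0), (1, 0.6, 0.0, 100.0)])
        assert len(link_puncta(det)) == 2

    def test_gap_closing_rejoins_across_one_missing_frame(self):
        det = detections(
            [(0, 0.0, 0.0, 100.0), (2, 0.8, 0.0, 110.0), (3, 0.9, 0.0, 115.0)]
        )
        trajs = link_puncta(det)
        assert len(trajs) == 1
        assert trajs[0].gaps == [1]
        np.testing.assert_array_equal(trajs[0].frames, [0, 2, 3])

    def test_gap_beyond_close_distance_stays_split(self):
        det = detections([(0, 0.0, 0.0, 100.0), (2, 1.5, 0.0, 100.0)])
        assert len(link_puncta(det)) == 2

    def test_every_detection_in_exactly_one_trajectory(self):
        truth = TrajectoryTruth.for_phase("initiation")
        det = synthetic.make_trajectory_set(truth, n_traj=20, n_frames=15, rng_seed=4)
        trajs = link_puncta(det)
        assert sum(t.n_frames for t in trajs) == len(det)

    def test_generator_tracks_recovered_exactly(self):
        truth = TrajectoryTruth.for_phase("initiation")
        det = synthetic.make_trajectory_set(truth, n_traj=25, n_frames=20, rng_seed=8)
        trajs = link_puncta(det)
        assert len(trajs) == 25


class TestPerTrajectoryStats:
    def test_start_is_mean_of_first_two_frames(self):
        assert start_molecules(traj_from_molecules([100, 120, 200])) == 110.0
        assert start_molecules(traj_from_molecules([160, 160])) == 160.0

    def test_start_needs_two_frames(self):
        with pytest.raises(InsufficientDataError):
            start_molecules(traj_from_molecules([100]))

    def test_delta_trace_constant_is_zero(self):
        _, deltas = delta_trace(traj_from_molecules([50, 50, 50, 50]))
        np.testing.assert_allclose(deltas, 0.0)

    def test_delta_trace_linear_accretion(self):
        a = 3.0
        molecules = 100 + a * np.arange(6)
        t, deltas = delta_trace(traj_from_molecules(molecules))
        np.testing.assert_allclose(deltas, a * t - a / 2)

    def test_final_delta_ttest_closed_form(self):
        # deltas (1, 2, 3): mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641, df 2
        trajs = [traj_from_molecules([10, 10, 10 + d]) for d in (1.0, 2.0, 3.0)]
        result = final_delta_ttest(trajs)
        assert result.mean == pytest.approx(2.0)
        assert result.t == pytest.approx(math.sqrt(12), rel=1e-6)
        assert result.df == 2
        assert result.p == pytest.approx(0.0742, abs=0.001)
        lo, hi = result.ci95
        assert lo == pytest.approx(2 - 4.302653 / math.sqrt(3), rel=1e-5)
        assert hi == pytest.approx(2 + 4.302653 / math.sqrt(3), rel=1e-5)

    def test_ttest_agrees_with_scipy_on_hand_vectors(self):
        from scipy import stats as sps

        deltas = [4.0, -1.0, 2.5, 0.5, 3.0]
        trajs = [traj_from_molecules([10, 10, 10 + d]) for d in deltas]
        result = final_delta_ttest(trajs)
        ref = sps.ttest_1samp(deltas, 0.0)
        assert result.t == pytest.approx(ref.statistic)
        assert result.p == pytest.approx(ref.pvalue)

    def test_zero_variance_deltas_degenerate(self):
        trajs = [traj_from_molecules([10, 10, 10]) for _ in range(5)]
        with pytest.raises(DegenerateTestError):
            final_delta_ttest(trajs)


class TestSpeeds:
    def test_constant_step_speed(self):
        traj = traj_from_molecules([1, 1, 1], speeds_um=0.160)
        np.testing.assert_allclose(instantaneous_speeds(traj), 160.0)

    def test_stationary_is_zero(self):
        np.testing.assert_allclose(
            instantaneous_speeds(traj_from_molecules([1, 1, 1])), 0.0
        )

    def test_gap_steps_use_elapsed_time(self):
        traj = Trajectory(
            id=0,
            frames=np.array([0, 2]),
            times=np.array([0.0, 2.0]),
            xy=np.array([[0.0, 0.0], [0.320, 0.0]]),
            molecules=np.array([100.0, 100.0]),
            gaps=[1],
        )
        np.testing.assert_allclose(instantaneous_speeds(traj), 160.0)


class TestSpeedMoleculeCorrelation:
    def test_perfect_inverse_relation(self):
        trajs = []
        for start in (50.0, 303.7, 1401.2):  # offsets avoid tied molecule values
            molecules = start + 10 * np.arange(10)
            xy = np.zeros((10, 2))
            xy[:, 0] = np.concatenate([[0], np.cumsum(1000.0 / molecules[:-1])])
            trajs.append(
                Trajectory(
                    id=0,
                    frames=np.arange(10),
                    times=np.arange(10, dtype=float),
                    xy=xy,
                    molecules=molecules,
                )
            )
        rho, _ = speed_molecule_correlation(trajs)
        assert rho == pytest.approx(-1.0)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(0)
        trajs = []
        for i in range(100):
            molecules = rng.lognormal(5, 0.5, 20)
            xy = rng.normal(0, 0.1, (20, 2)).cumsum(axis=0)
            trajs.append(
                Trajectory(
                    id=i,
                    frames=np.arange(20),
                    times=np.arange(20, dtype=float),
                    xy=xy,
                    molecules=molecules,
                )
            )
        rho, _ = speed_molecule_correlation(trajs)
        assert abs(rho) < 0.1

    def test_generator_inverse_law_strongly_negative(self):
        truth = TrajectoryTruth.for_phase("initiation")
        det = synthetic.make_trajectory_set(truth, n_traj=50, n_frames=40, rng_seed=2)
        trajs = link_puncta(det, frame_interval_s=truth.frame_interval_s)
        rho, p = speed_molecule_correlation(trajs)
        assert rho <= -0.4
        assert p < 1e-6

    def test_constant_ranks_undefined(self):
        trajs = [traj_from_molecules([5, 5, 5, 5, 5], speeds_um=0.1)]
        from filoquant.errors import UndefinedStatisticError

        with pytest.raises(UndefinedStatisticError):
            speed_molecule_correlation(trajs)


class TestTrendCurve:
    def test_exact_on_linear_data(self):
        t = np.linspace(0, 90, 120)
        y = 3.0 * t + 2.0
        curve = trend_curve(t, y)
        np.testing.assert_allclose(curve.fit, 3.0 * curve.t + 2.0, rtol=0.01)

    def test_points_beyond_window_excluded(self):
        t = np.concatenate([np.linspace(0, 90, 50), [150.0, 180.0]])
        y = np.concatenate([2.0 * np.linspace(0, 90, 50), [1e6, -1e6]])
        curve = trend_curve(t, y, t_max=100.0)
        assert curve.t.max() <= 100.0
        np.testing.assert_allclose(curve.fit, 2.0 * curve.t, atol=1.0)

    def test_recovers_noisy_sinusoid(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 100, 400))
        signal = np.sin(2 * math.pi * t / 50)
        y = signal + rng.normal(0, 0.3, t.size)
        curve = trend_curve(t, y)
        truth_on_grid = np.sin(2 * math.pi * curve.t / 50)
        assert np.corrcoef(curve.fit, truth_on_grid)[0, 1] > 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            trend_curve(np.arange(5.0), np.arange(5.0))


class TestDistributionSummary:
    def test_zero_slope_error_collapses_cis(self):
        from filoquant.calibration import StandardCurve

        curve = StandardCurve(slope=24.32, slope_se=0.0, r_squared=1.0, df=4)
        summary = distribution_summary([52.0, 160.0, 1200.0], curve)
        assert summary["min"] == (52.0, (52.0, 52.0))
        assert summary["median"][0] == 160.0
        assert summary["max"][0] == 1200.0

    def test_homogeneity_under_scaling(self):
        from filoquant.calibration import StandardCurve

        curve = StandardCurve(slope=24.32, slope_se=1.42, r_squared=0.98, df=4)
        base = distribution_summary([10.0, 20.0, 40.0], curve)
        doubled = distribution_summary([20.0, 40.0, 80.0], curve)
        for key in ("min", "median", "max"):
            assert doubled[key][0] == pytest.approx(2 * base[key][0])
            assert doubled[key][1][0] == pytest.approx(2 * base[key][1][0])

    def test_sampling_median_near_truth(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(math.log(160), 0.6, 237)
        summary = distribution_summary(values)
        assert summary["median"][0] == pytest.approx(160, rel=0.10)


class TestLognormalFit:
    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(0)
        mu, sigma, n = math.log(730), 1.0, 8733
        fit = lognormal_fit(rng.lognormal(mu, sigma, n))
        se_mu = sigma / math.sqrt(n)
        se_sigma = sigma / math.sqrt(2 * n)
        assert abs(fit.mu_log - mu) < 2 * se_mu
        assert abs(fit.sigma_log - sigma) < 2 * se_sigma
        assert fit.ks_p > 0.01

    def test_constant_data_has_zero_sigma(self):
        fit = lognormal_fit(np.full(50, math.e**2))
        assert fit.sigma_log == 0.0
        assert fit.mu_log == pytest.approx(2.0)

    def test_normal_data_fits_better_on_raw_scale(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        values = rng.normal(100, 5, 2000)  # all positive, but not log-normal
        fit = lognormal_fit(values)
        normal_loglik = float(
            np.sum(sps.norm.logpdf(values, values.mean(), values.std()))
        )
        assert normal_loglik > fit.log_likelihood

    def test_nonpositive_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            lognormal_fit([10.0, -1.0])


class TestPhaseBehaviour:
    def test_growth_phases_accumulate_retraction_does_not(self):
        grow = TrajectoryTruth.for_phase("initiation")
        det = synthetic.make_trajectory_set(grow, n_traj=60, n_frames=40, rng_seed=6)
        result = final_delta_ttest(link_puncta(det))
        assert result.mean > 0
        assert result.p < 1e-6

        retract = TrajectoryTruth.for_phase("retraction")
        det = synthetic.make_trajectory_set(retract, n_traj=58, n_frames=40, rng_seed=6)
        result = final_delta_ttest(link_puncta(det))
        assert abs(result.mean) < 10.0  # no systematic accumulation
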