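"""Movement statistics: component estimation, MSD fits, path descriptors."""

import math

import numpy as np
import pandas as pd
import pytest

from platesim.analysis import (
    TrackSet,
    circular_R,
    coherence,
    component_contributions,
    displacement_density,
    estimate_components,
    fit_alpha,
    fit_persistence,
    furth_msd,
    linearity,
    msd_curve,
    rmsd_at,
    summarize,
)
from platesim.fixtures import make_fixture, simulate_tracks


def tracks_from_xy(paths, interval=20.0):
    cells = {}
    for i, xy in enumerate(paths, start=1):
        xy = np.asarray(xy, dtype=float)
        t = np.arange(xy.shape[0]) * interval
        cells[i] = (t, xy, "start", None)
    return TrackSet(cells=cells, interval=interval)


class TestTrackSet:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError):
            TrackSet(cells={1: (np.array([0.0, 0.0]), np.zeros((2, 2)), "start", None)},
                     interval=20.0)

    def test_rejects_unknown_labels(self):
        with pytest.raises(ValueError):
            TrackSet(cells={1: (np.array([0.0]), np.zeros((1, 2)), "teleported", None)},
                     interval=20.0)


class TestLinearity:
    def test_straight_path_is_one(self):
        ts = tracks_from_xy([[(0, 0), (1, 0), (2, 0), (3, 0)]])
        assert linearity(ts) == pytest.approx(1.0)

    def test_out_and_back_is_zero(self):
        ts = tracks_from_xy([[(0, 0), (5, 0), (0, 0)]])
        assert linearity(ts) == pytest.approx(0.0)

    def test_right_angle_legs(self):
        ts = tracks_from_xy([[(0, 0), (1, 0), (1, 1)]])
        assert linearity(ts) == pytest.approx(math.sqrt(2) / 2, abs=1e-4)


class TestCoherence:
    def test_parallel_nets_cohere_fully(self):
        ts = tracks_from_xy([[(0, 0), (3, 0)], [(10, 10), (14, 10)]])
        assert coherence(ts) == pytest.approx(1.0)

    def test_opposite_nets_cancel(self):
        ts = tracks_from_xy([[(0, 0), (3, 0)], [(0, 0), (-3, 0)]])
        assert coherence(ts) == pytest.approx(0.0)

    def test_perpendicular_equal_nets(self):
        ts = tracks_from_xy([[(0, 0), (2, 0)], [(0, 0), (0, 2)]])
        assert coherence(ts) == pytest.approx(math.sqrt(2) / 2)


class TestCircularR:
    def test_identical_angles_give_one(self):
        _, R = circular_R([(2, 0), (5, 0), (0.1, 0)])
        assert R == pytest.approx(1.0)

    def test_opposite_pair_gives_zero(self):
        _, R = circular_R([(1, 0), (-3, 0)])
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_give_near_zero(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * math.pi, 20000)
        _, R = circular_R(np.column_stack([np.cos(ang), np.sin(ang)]))
        assert R < 0.02

    def test_mean_angle_points_at_the_cluster(self):
        ang, R = circular_R([(1, 1), (2, 2), (0.5, 0.6)])
        assert ang == pytest.approx(math.pi / 4, abs=0.05)
        assert R > 0.99


class TestMsdCurve:
    def test_stationary_cells_have_zero_msd(self):
        ts = tracks_from_xy([[(5, 5)] * 10])
        assert (msd_curve(ts)["msd"] == 0).all()

    def test_ballistic_closed_form(self):
        speed = 0.4  # µm/min
        ts = tracks_from_xy([[(speed * 20.0 * i, 0.0) for i in range(20)]])
        msd = msd_curve(ts)
        assert np.allclose(msd["msd"], (speed * msd["lag"]) ** 2)

    def test_two_point_path_has_a_single_lag(self):
        ts = tracks_from_xy([[(0, 0), (3, 4)]])
        msd = msd_curve(ts)
        assert len(msd) == 1
        assert msd["msd"].iloc[0] == pytest.approx(25.0)
        assert msd["n_pairs"].iloc[0] == 1

    def test_overlapping_windows_count_all_pairs(self):
        ts = tracks_from_xy([[(i, 0) for i in range(5)]])
        assert list(msd_curve(ts)["n_pairs"]) == [4, 3, 2, 1]


class TestFitAlpha:
    def test_ballistic_series_gives_two(self):
        ts = tracks_from_xy([[(0.5 * 20 * i, 0) for i in range(30)]])
        fit = fit_alpha(msd_curve(ts))
        assert fit.alpha == pytest.approx(2.0, abs=0.01)

    def test_exact_power_law_self_fit(self):
        t = np.arange(1, 30, dtype=float) * 20.0
        series = pd.DataFrame({"lag": t, "msd": 3.5 * t ** 1.5,
                               "n_pairs": np.arange(29, 0, -1)})
        fit = fit_alpha(series)
        assert fit.k == pytest.approx(3.5, rel=1e-6)
        assert fit.alpha == pytest.approx(1.5, rel=1e-6)

    def test_brownian_fixture_is_diffusive(self):
        ts = make_fixture("brownian_paths", {"n_cells": 80, "n_frames": 60}, seed=4)
        # fit the short-lag portion, where many independent pairs average out
        fit = fit_alpha(msd_curve(ts).iloc[:20])
        assert fit.alpha == pytest.approx(1.0, abs=0.1)

    def test_needs_three_lags(self):
        series = pd.DataFrame({"lag": [20.0, 40.0], "msd": [1.0, 2.0], "n_pairs": [5, 4]})
        with pytest.raises(ValueError):
            fit_alpha(series)


class TestFitPersistence:
    def test_exact_series_self_fit(self):
        t = np.arange(1, 40, dtype=float) * 5.0
        series = pd.DataFrame({"lag": t, "msd": furth_msd(t, 1.0, 30.0),
                               "n_pairs": np.arange(39, 0, -1)})
        fit = fit_persistence(series)
        assert fit.speed == pytest.approx(1.0, rel=1e-4)
        assert fit.persistence_time == pytest.approx(30.0, rel=1e-4)
        assert not fit.at_bound

    def test_model_limits(self):
        # short lags are ballistic, long lags diffusive with slope 2 S^2 P
        S, P = 1.3, 25.0
        t_small = np.array([1e-4])
        assert furth_msd(t_small, S, P)[0] == pytest.approx((S * 1e-4) ** 2, rel=1e-3)
        t_big = np.array([1e6, 2e6])
        slope = np.diff(furth_msd(t_big, S, P))[0] / 1e6
        assert slope == pytest.approx(2 * S * S * P, rel=1e-4)

    def test_integrated_ou_paths_recover_persistence_time(self):
        ts = make_fixture("ou_persistent_paths",
                          {"n_cells": 150, "n_frames": 80, "speed": 1.0,
                           "persistence_time": 30.0, "interval": 5.0}, seed=9)
        fit = fit_persistence(msd_curve(ts).iloc[:26])  # lags to ~4 P
        assert fit.persistence_time == pytest.approx(30.0, rel=0.1)
        assert fit.speed == pytest.approx(1.0, rel=0.05)


class TestEstimateComponents:
    def test_identical_displacements_are_pure_bias(self):
        ts = tracks_from_xy([[(3 * i, 4 * i) for i in range(10)]] * 3)
        est = estimate_components(ts)
        assert est.bias_module == pytest.approx(5.0)
        assert est.pers_module == pytest.approx(0.0)
        assert est.rand_module == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("rand,pers,bias", [
        (8.7, 0.0, 0.0),
        (8.7, 4.0, 0.0),
        (8.7, 0.0, 4.0),
        (8.7, 4.0, 4.0),
        (5.0, 2.0, 1.0),
    ])
    def test_round_trip_recovery(self, rand, pers, bias):
        """Estimates recover the generator settings: <10% relative error on
        nonzero components, <0.5 µm absolute on zero ones."""
        ts = simulate_tracks(50, 72, rand, pers, bias, seed=hash((rand, pers, bias)) % 2**31)
        est = estimate_components(ts)
        for true, got in [(rand, est.rand_module), (pers, est.pers_module),
                          (bias, est.bias_module)]:
            if true == 0.0:
                assert abs(got) < 0.5
            else:
                assert abs(got - true) / true < 0.10

    def test_bias_angle_recovered(self):
        ts = simulate_tracks(50, 72, 6.0, 0.0, 4.0, bias_angle=math.pi / 3, seed=21)
        est = estimate_components(ts)
        assert est.bias_angle == pytest.approx(math.pi / 3, abs=0.15)

    def test_empty_track_set_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_components(TrackSet(cells={}, interval=20.0))


class TestRmsd:
    def test_random_msd_bounds_observed_msd_from_below(self):
        """With persistence or bias present the full MSD exceeds the MSD of
        the random component alone."""
        ts = simulate_tracks(50, 72, 8.7, 4.0, 4.0, seed=2)
        est = estimate_components(ts)
        msd = msd_curve(ts)
        for _, row in msd.iloc[:30].iterrows():
            assert rmsd_at(est.rand_module, row["lag"], ts.interval) <= row["msd"]

    def test_pure_random_rmsd_matches_msd(self):
        ts = simulate_tracks(80, 72, 8.7, 0.0, 0.0, seed=3)
        est = estimate_components(ts)
        msd = msd_curve(ts)
        mid = msd.iloc[5]
        assert rmsd_at(est.rand_module, mid["lag"], ts.interval) == pytest.approx(
            mid["msd"], rel=0.12)


class TestAlphaAcrossRegimes:
    def test_alpha_near_one_for_pure_random(self):
        ts = simulate_tracks(60, 72, 8.7, 0.0, 0.0, seed=5)
        assert fit_alpha(msd_curve(ts)).alpha == pytest.approx(1.0, abs=0.1)

    def test_alpha_increases_with_persistence_and_bias(self):
        a_rand = fit_alpha(msd_curve(simulate_tracks(60, 72, 8.7, 0.0, 0.0, seed=6))).alpha
        a_pers = fit_alpha(msd_curve(simulate_tracks(60, 72, 8.7, 4.0, 0.0, seed=6))).alpha
        a_mixed = fit_alpha(msd_curve(simulate_tracks(60, 72, 8.7, 4.0, 4.0, seed=6))).alpha
        assert a_rand < a_pers < a_mixed <= 2.05


class TestComponentContributions:
    def test_pure_bias_contribution_equals_displacement(self):
        ts = tracks_from_xy([[(6.0 * i, 0.0) for i in range(30)]] * 5)
        cc = component_contributions(ts, window=240.0)
        assert np.allclose(cc["bias"], cc["displacement"], atol=1e-9)
        assert np.allclose(cc["random"], 0.0, atol=1e-9)

    def test_contributions_sum_to_mean_displacement(self):
        ts = simulate_tracks(30, 40, 8.7, 3.0, 2.0, seed=8)
        cc = component_contributions(ts, window=400.0)
        total = cc["random"] + cc["persistence"] + cc["bias"]
        assert np.allclose(total, cc["displacement"], rtol=1e-9)

    def test_random_population_is_random_dominated(self):
        ts = simulate_tracks(40, 60, 8.7, 0.0, 0.0, seed=9)
        cc = component_contributions(ts, window=720.0)
        assert (cc["random"] > 5 * cc["bias"].abs()).all()

    def test_window_must_cover_two_intervals(self):
        ts = simulate_tracks(5, 10, 5.0, 0.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            component_contributions(ts, window=20.0)


class TestDisplacementDensity:
    def test_random_population_modes_at_origin(self):
        ts = simulate_tracks(60, 72, 8.7, 0.0, 0.0, seed=12)
        dm = displacement_density(ts, lag=40.0)
        mx, my = dm.mode()
        assert math.hypot(mx, my) < 4.0

    def test_mixed_population_mode_shifts_along_bias(self):
        ts = simulate_tracks(60, 72, 8.7, 4.0, 4.0, seed=12)
        dm = displacement_density(ts, lag=40.0)
        mx, my = dm.mode()
        assert mx > 5.0
        assert abs(my) < abs(mx)

    def test_density_mass_normalises(self):
        ts = simulate_tracks(40, 40, 8.7, 0.0, 0.0, seed=13)
        dm = displacement_density(ts, lag=20.0, grid=41, pad=0.6)
        assert dm.integral() == pytest.approx(1.0, abs=0.05)


def test_summary_reports_the_standard_column_set():
    ts = simulate_tracks(40, 60, 8.7, 4.0, 4.0, seed=15)
    s = summarize(ts)
    frame = s.to_frame()
    for col in ("rand_module", "pers_module", "bias_module", "mean_displacement",
                "msd_final", "rmsd_final", "alpha", "k_msd", "persistence_time",
                "rms_speed", "linearity", "coherence", "R"):
        assert col in frame.columns
    assert 0 < s.linearity <= 1
    assert 0 <= s.coherence <= 1
    assert 0 <= s.R <= 1
    assert s.rmsd_final <= s.msd_final
    assert 1.0 < s.alpha <= 2.05
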