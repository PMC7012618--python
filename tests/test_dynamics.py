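"""Drift-corrected MSD, distance travelled, and diffusion-model fits."""

import numpy as np
import pandas as pd
import pytest

import focidyn as fd
from focidyn.tracking import TRACK_COLUMNS
from conftest import msd_brute_force


def _tset(rows, dt=30.0):
    return fd.TrajectorySet(df=pd.DataFrame(rows, columns=TRACK_COLUMNS),
                            frame_interval=dt, provenance="ground_truth")


class TestGlobalCenter:
    def test_single_focus_is_its_own_center(self):
        t = _tset([(0, 0, 0.0, 3.2, -1.1, 1.0)])
        assert fd.global_center(t, 0) == (3.2, -1.1)

    def test_two_foci_arithmetic_mean(self):
        t = _tset([(0, 0, 0.0, 0.0, 0.0, 1.0), (1, 0, 0.0, 2.0, 4.0, 1.0)])
        assert fd.global_center(t, 0) == (1.0, 2.0)

    def test_five_focus_frame_matches_hand_mean(self):
        xs = [1.0, 2.5, -0.5, 4.0, 0.25]
        ys = [0.5, -1.5, 2.0, 3.25, -2.0]
        t = _tset([(i, 0, 0.0, x, y, 1.0) for i, (x, y) in enumerate(zip(xs, ys))])
        cx, cy = fd.global_center(t, 0)
        assert abs(cx - sum(xs) / 5) < 1e-12
        assert abs(cy - sum(ys) / 5) < 1e-12

    def test_empty_frame_is_signaled(self, toy_tracks):
        with pytest.raises(ValueError, match="undefined"):
            fd.global_center(toy_tracks, 99)


class TestComputeMSD:
    def test_stationary_foci_have_zero_msd(self):
        rows = [(i, f, 30.0 * f, float(i), float(-i), 1.0)
                for i in range(3) for f in range(6)]
        curve = fd.compute_msd(_tset(rows), max_lag=90.0)
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-15)

    def test_pure_rigid_drift_cancels_exactly(self):
        v = np.array([0.7, -0.3])
        rows = [(i, f, 30.0 * f, i * 2.0 + v[0] * f, -i + v[1] * f, 1.0)
                for i in range(4) for f in range(8)]
        curve = fd.compute_msd(_tset(rows), max_lag=120.0)
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-12)

    def test_matches_brute_force_on_toy_table(self, toy_tracks):
        curve = fd.compute_msd(toy_tracks, max_lag=90.0)
        oracle = msd_brute_force(toy_tracks.df, 30.0, 3)
        for lag, msd, n in zip(curve.lag_s[1:], curve.msd[1:], curve.n_pairs[1:]):
            assert msd == pytest.approx(oracle[lag][0], abs=1e-12)
            assert n == oracle[lag][1]

    def test_matches_brute_force_on_random_fixtures(self, random_fixture_tracks):
        for tset in random_fixture_tracks:
            max_frames = tset.n_frames - 1
            curve = fd.compute_msd(tset, max_lag=max_frames * 30.0)
            oracle = msd_brute_force(tset.df, 30.0, max_frames)
            assert len(curve.lag_s) - 1 == len(oracle)
            for lag, msd, n in zip(curve.lag_s[1:], curve.msd[1:], curve.n_pairs[1:]):
                assert msd == pytest.approx(oracle[lag][0], abs=1e-12)
                assert n == oracle[lag][1]

    def test_lag_zero_reported_as_zero_and_gapped_lag_omitted(self):
        # two foci observed only in frames 0 and 2: lag 30 has no pair
        rows = [(i, f, 30.0 * f, float(i) + f * 0.1, 0.0, 1.0)
                for i in range(2) for f in (0, 2)]
        curve = fd.compute_msd(_tset(rows), max_lag=60.0)
        assert curve.lag_s.tolist() == [0.0, 60.0]
        assert curve.msd[0] == 0.0

    def test_uncorrected_mode_sees_the_drift(self):
        v = np.array([0.1, 0.0])
        rows = [(i, f, 30.0 * f, i * 3.0 + v[0] * 30.0 * f / 30, 0.0, 1.0)
                for i in range(3) for f in range(8)]
        t = _tset(rows)
        corrected = fd.compute_msd(t, max_lag=120.0)
        raw = fd.compute_msd(t, max_lag=120.0, drift_correct=False)
        assert corrected.msd[1:].max() < 1e-12
        assert raw.msd[1] == pytest.approx((0.1) ** 2, abs=1e-12)


class TestDistanceTravelled:
    def test_stationary_focus_travels_zero(self):
        rows = [(0, f, 30.0 * f, 1.0, 1.0, 1.0) for f in range(5)]
        assert fd.distance_travelled(_tset(rows), track_id=0) == 0.0

    def test_straight_path_sums_step_lengths(self):
        # 20 steps of 0.5 µm without drift correction (single focus:
        # correction would cancel its own motion)
        rows = [(0, f, 30.0 * f, 0.5 * f, 0.0, 1.0) for f in range(21)]
        d = fd.distance_travelled(_tset(rows), track_id=0, drift_correct=False)
        assert d == pytest.approx(10.0, abs=1e-12)

    def test_toy_table_matches_hand_enumeration(self, toy_tracks):
        # drift-corrected positions of track 0, enumerated by hand
        df = toy_tracks.df
        gc = df.groupby("frame")[["x_um", "y_um"]].mean()
        sub = df[df.track_id == 0]
        xs = sub["x_um"].to_numpy() - gc["x_um"].to_numpy()
        ys = sub["y_um"].to_numpy() - gc["y_um"].to_numpy()
        expect = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
        got = fd.distance_travelled(toy_tracks, track_id=0)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_path_length_bounds_net_displacement(self, random_fixture_tracks):
        for tset in random_fixture_tracks:
            gc = tset.df.groupby("frame")[["x_um", "y_um"]].mean()
            for tid in tset.track_ids:
                sub = tset.track(tid)
                if len(sub) < 2:
                    continue
                xs = sub["x_um"].to_numpy() - gc.loc[sub["frame"], "x_um"].to_numpy()
                ys = sub["y_um"].to_numpy() - gc.loc[sub["frame"], "y_um"].to_numpy()
                net = float(np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
                assert fd.distance_travelled(tset, track_id=tid) >= net - 1e-12

    def test_track_absent_from_window_is_signaled(self, toy_tracks):
        with pytest.raises(ValueError):
            fd.distance_travelled(toy_tracks, track_id=0, window=(1000.0, 2000.0))


class TestFitMSDModel:
    def test_exact_line_recovers_diffusion_coefficient(self):
        D = 0.004
        lags = np.arange(0, 7) * 30.0
        curve = fd.MSDCurve(lag_s=lags, msd=4 * D * lags,
                            n_pairs=np.full(7, 50), sem=np.zeros(7),
                            frame_interval=30.0)
        fit = fd.fit_msd_model(curve, "free")
        assert fit.params["D"] == pytest.approx(D, abs=1e-10)

    def test_confined_model_self_consistency(self):
        P, tau = 0.25, 90.0
        lags = np.arange(0, 11) * 30.0
        msd = P * (1 - np.exp(-lags / tau))
        curve = fd.MSDCurve(lag_s=lags, msd=msd, n_pairs=np.full(11, 50),
                            sem=np.zeros(11), frame_interval=30.0)
        fit = fd.fit_msd_model(curve, "confined")
        assert fit.params["P"] == pytest.approx(P, rel=0.01)
        assert fit.params["tau"] == pytest.approx(tau, rel=0.01)

    def test_simulated_confinement_plateau_within_20_percent(self):
        cfg = fd.SimulationConfig.mobility_protocol(
            n_foci=100, seed=77, confinement_radius=0.5,
            diffusion_coeff=0.005, nucleus_radius=12.0)
        truth = fd.simulate_trajectories(cfg)
        curve = fd.compute_msd(truth.trajectories, max_lag=300.0)
        fit = fd.fit_msd_model(curve, "confined")
        assert fit.params["P"] == pytest.approx(cfg.msd_plateau, rel=0.2)

    def test_too_few_lags_rejected(self):
        curve = fd.MSDCurve(lag_s=np.array([0.0, 30.0]), msd=np.array([0.0, 0.1]),
                            n_pairs=np.array([5, 5]), sem=np.array([0.0, 0.01]),
                            frame_interval=30.0)
        with pytest.raises(ValueError):
            fd.fit_msd_model(curve, "free")
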