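"""Simulator correctness: determinism, motion statistics, event bookkeeping,
rendering, and the recruitment profile."""

import io

import numpy as np
import pytest
from scipy import stats as sps

import focidyn as fd
from focidyn.synthetic import READ_NOISE_SIGMA


def _cfg(**kw):
    return fd.SimulationConfig.mobility_protocol(**kw)


class TestSimulateTrajectories:
    def test_zero_motion_gives_constant_tracks_and_no_events(self):
        truth = fd.simulate_trajectories(_cfg(n_foci=5, diffusion_coeff=0.0, seed=3))
        for _, sub in truth.trajectories.df.groupby("track_id"):
            assert sub["x_um"].nunique() == 1
            assert sub["y_um"].nunique() == 1
            assert len(sub) == 21
        assert len(truth.events) == 0

    def test_no_foci_gives_empty_outputs(self):
        truth = fd.simulate_trajectories(_cfg(n_foci=0, seed=0))
        assert truth.trajectories.df.empty
        assert len(truth.events) == 0

    def test_same_seed_is_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            truth = fd.simulate_trajectories(
                fd.SimulationConfig.events_protocol(n_foci=15, seed=9))
            p = tmp_path / f"run{run}.csv"
            truth.trajectories.to_csv(p)
            truth.events.to_csv(tmp_path / f"ev{run}.csv")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "ev0.csv").read_bytes() == (tmp_path / "ev1.csv").read_bytes()

    def test_adding_a_focus_does_not_perturb_existing_paths(self):
        a = fd.simulate_trajectories(_cfg(n_foci=5, seed=4))
        b = fd.simulate_trajectories(_cfg(n_foci=6, seed=4))
        for tid in range(5):
            pa = a.trajectories.track(tid)[["x_um", "y_um"]].to_numpy()
            pb = b.trajectories.track(tid)[["x_um", "y_um"]].to_numpy()
            np.testing.assert_array_equal(pa, pb)

    def test_brownian_step_variance_within_chi_square_band(self):
        """Free diffusion: sum of squared steps / (2 D Δt) is chi-square
        with 2·(number of steps) degrees of freedom."""
        D, dt = 0.005, 30.0
        truth = fd.simulate_trajectories(_cfg(
            n_foci=50, seed=11, confinement_radius=None, nucleus_radius=np.inf))
        df = truth.trajectories.df
        X = df.pivot(index="track_id", columns="frame", values="x_um").to_numpy()
        Y = df.pivot(index="track_id", columns="frame", values="y_um").to_numpy()
        sq = np.diff(X) ** 2 + np.diff(Y) ** 2
        m = sq.size
        stat = sq.sum() / (2 * D * dt)
        assert sps.chi2.ppf(0.005, 2 * m) < stat < sps.chi2.ppf(0.995, 2 * m)

    def test_tether_stationary_variance_matches_closed_form(self):
        """Long-run per-axis variance about the anchor converges to the
        tether's stationary variance R²/2 (within 10% at ≥5000 samples)."""
        cfg = fd.SimulationConfig(
            n_foci=60, n_frames=100, frame_interval=30.0, seed=21,
            diffusion_coeff=0.01, confinement_radius=0.5, nucleus_radius=20.0)
        truth = fd.simulate_trajectories(cfg)
        df = truth.trajectories.df
        dev = []
        for tid, sub in df.groupby("track_id"):
            # anchor unknown to the test: use the track's long-run mean
            dev.append(sub["x_um"] - sub["x_um"].mean())
            dev.append(sub["y_um"] - sub["y_um"].mean())
        dev = np.concatenate(dev)
        assert dev.size >= 5000
        assert np.var(dev) == pytest.approx(cfg.stationary_axis_variance, rel=0.10)

    def test_disappearance_times_are_exponential(self):
        lam = 1 / 600
        cfg = fd.SimulationConfig(
            n_foci=400, n_frames=121, frame_interval=30.0, seed=5,
            diffusion_coeff=0.001, confinement_radius=0.3,
            disappearance_rate=lam, nucleus_radius=30.0)
        truth = fd.simulate_trajectories(cfg)
        times = truth.events.disappearances["t_s"].to_numpy()
        assert len(times) > 350
        from conftest import bootstrap_median_ci
        lo, hi = bootstrap_median_ci(times, seed=1)
        # recorded times are ceiling-discretized to the frame grid, so the
        # continuous median ln2/λ must lie within one frame of the CI
        assert lo - cfg.frame_interval <= np.log(2) / lam <= hi

    def test_fusion_conserves_track_counts(self):
        cfg = fd.SimulationConfig.events_protocol(n_foci=40, seed=13,
                                                  fusion_radius=0.8)
        truth = fd.simulate_trajectories(cfg)
        n_fus = len(truth.events.fusions)
        assert n_fus >= 1, "config should produce at least one fusion"
        # child count = parent count - fusions
        assert truth.trajectories.n_tracks == 40 + n_fus          # tracks ever
        live = truth.live_counts()
        assert (np.diff(live) <= 0).all()                         # never increases
        # each fusion: two parents end the frame before, child starts there
        last = truth.trajectories.last_records().set_index("track_id")["frame"]
        first = truth.trajectories.first_records().set_index("track_id")["frame"]
        for _, ev in truth.events.fusions.iterrows():
            p1, p2, child = ev["track_ids"]
            assert last[p1] == last[p2] == ev["frame"] - 1
            assert first[child] == ev["frame"]

    def test_rejects_invalid_configs(self):
        with pytest.raises(ValueError):
            fd.SimulationConfig(n_frames=1)
        with pytest.raises(ValueError):
            fd.SimulationConfig(diffusion_coeff=-1)
        with pytest.raises(ValueError):
            fd.SimulationConfig(pixel_size=0)
        with pytest.raises(ValueError):
            fd.SimulationConfig(diffusion_coeff=np.nan)


class TestRenderMovie:
    def test_empty_truth_renders_background_only(self):
        cfg = _cfg(n_foci=0, seed=0, snr=10)
        truth = fd.simulate_trajectories(cfg)
        stack = fd.render_movie(truth, noise=True)
        noise_sd = np.sqrt(cfg.background_level + READ_NOISE_SIGMA ** 2)
        sem = noise_sd / np.sqrt(stack.frames[0].size)
        assert abs(stack.frames[0].mean() - cfg.background_level) < 5 * sem

    def test_mobility_protocol_has_21_frames(self):
        cfg = fd.SimulationConfig.from_duration(600.0, 30.0, n_foci=3)
        assert cfg.n_frames == 21
        truth = fd.simulate_trajectories(cfg)
        stack = fd.render_movie(truth)
        assert stack.n_frames == 21
        assert stack.frame_interval == 30.0

    def test_single_focus_localized_to_subpixel_accuracy(self):
        """Detection recovers a rendered stationary focus within 0.2 px,
        cross-checked against a least-squares Gaussian-fit oracle."""
        from conftest import gaussian_fit_2d
        from focidyn.tracking import TRACK_COLUMNS
        import pandas as pd
        cfg = _cfg(n_foci=1, diffusion_coeff=0.0, seed=2, snr=10,
                   nucleus_radius=2.0)
        df = pd.DataFrame([(0, f, f * 30.0, 0.337, -0.211, 1.0)
                           for f in range(cfg.n_frames)], columns=TRACK_COLUMNS)
        truth = fd.GroundTruth(
            trajectories=fd.TrajectorySet(df=df, frame_interval=30.0,
                                          provenance="ground_truth"),
            events=fd.EventLog(), drift_um=np.zeros((cfg.n_frames, 2)), config=cfg)
        stack = fd.render_movie(truth, noise=True)
        spots = fd.detect_stack(stack)
        assert (spots.groupby("frame").size() == 1).all()
        err_px = np.hypot(spots["x_um"] - 0.337, spots["y_um"] + 0.211) / cfg.pixel_size
        assert np.sqrt(np.mean(err_px ** 2)) < 0.2
        # least-squares Gaussian-fit oracle over all frames: the centroid
        # detector must track the fit to within its own error scale
        cx_px = (0.337 - stack.origin[0]) / cfg.pixel_size
        cy_px = (-0.211 - stack.origin[1]) / cfg.pixel_size
        oracle_err, agree = [], []
        for k in range(stack.n_frames):
            gx, gy = gaussian_fit_2d(stack.frames[k])
            oracle_err.append(np.hypot(gx - cx_px, gy - cy_px))
            row = spots[spots["frame"] == k].iloc[0]
            agree.append(np.hypot(gx - row["x_px"], gy - row["y_px"]))
        assert np.sqrt(np.mean(np.square(oracle_err))) < 0.2
        assert np.sqrt(np.mean(np.square(agree))) < 0.2

    def test_rejects_bad_psf(self):
        truth = fd.simulate_trajectories(_cfg(n_foci=1, seed=0))
        from dataclasses import replace
        bad = replace(truth.config, psf_sigma=0.0)
        with pytest.raises(ValueError):
            fd.render_movie(truth, config=bad)

    def test_rejects_foci_outside_field(self):
        truth = fd.simulate_trajectories(_cfg(n_foci=5, seed=1))
        with pytest.raises(ValueError, match="outside"):
            fd.render_movie(truth, shape=(8, 8))


class TestRecruitmentProfile:
    def test_baseline_is_one_at_t_zero(self):
        p = fd.RecruitmentParams(A_fast=5, k_fast=0.2, gamma=0.01, A_slow=3, k_slow=0.01)
        assert fd.simulate_recruitment_profile(p, [0.0, 1.0])[0] == 1.0

    def test_long_time_limit_is_one_plus_slow_amplitude(self):
        p = fd.RecruitmentParams(A_fast=2, k_fast=0.05, gamma=0.01, A_slow=1.5, k_slow=0.01)
        r = fd.simulate_recruitment_profile(p, [1e6])
        assert r[0] == pytest.approx(1 + p.A_slow, abs=1e-9)

    def test_default_fast_peak_is_within_two_minutes(self):
        """Numeric argmax of the fast component agrees with the calculus
        closed form ln(1 + k_fast/gamma)/k_fast, and sits ≤ 120 s."""
        p = fd.RecruitmentParams()
        t = np.linspace(0, 600, 60001)
        fast = (1 - np.exp(-p.k_fast * t)) * np.exp(-p.gamma * t)
        t_num = t[np.argmax(fast)]
        assert t_num == pytest.approx(p.fast_peak_time_s, abs=0.02)
        assert p.fast_peak_time_s <= 120.0

    def test_rejects_negative_amplitudes_and_bad_times(self):
        with pytest.raises(ValueError):
            fd.RecruitmentParams(A_fast=-1)
        p = fd.RecruitmentParams()
        with pytest.raises(ValueError):
            fd.simulate_recruitment_profile(p, [-1.0, 0.0])
        with pytest.raises(ValueError):
            fd.simulate_recruitment_profile(p, [0.0, 0.0])


class TestScheduledEvents:
    def test_schedule_matches_event_log(self, scheduled_truth):
        ev = scheduled_truth.events
        assert sorted(ev.fusions["frame"]) == [4, 7, 10, 13, 16]
        assert sorted(ev.disappearances["frame"]) == [5, 8, 11, 14, 17]

    def test_ground_truth_invariants(self, scheduled_truth):
        tset = scheduled_truth.trajectories
        last = tset.last_records().set_index("track_id")["frame"]
        first = tset.first_records().set_index("track_id")["frame"]
        for _, ev in scheduled_truth.events.fusions.iterrows():
            p1, p2, child = ev["track_ids"]
            assert last[p1] == last[p2] == ev["frame"] - 1
            assert first[child] == ev["frame"]
        for _, ev in scheduled_truth.events.disappearances.iterrows():
            (tid,) = ev["track_ids"]
            assert last[tid] == ev["frame"] - 1
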