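"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (double loops, exhaustive enumeration,
iterative model fits) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import focidyn as fd
from focidyn.tracking import TRACK_COLUMNS


# ------------------------------------------------------------------ oracles

def msd_brute_force(df: pd.DataFrame, frame_interval: float,
                    max_lag_frames: int, drift_correct: bool = True) -> dict:
    """O(n·T²) double-loop drift-corrected MSD: lag_s -> (msd, n_pairs)."""
    frames = sorted(df["frame"].unique())
    gc = {}
    for f in frames:
        sf = df[df["frame"] == f]
        gc[f] = (sf["x_um"].mean(), sf["y_um"].mean()) if drift_correct else (0.0, 0.0)
    out = {}
    for L in range(1, max_lag_frames + 1):
        vals = []
        for _, sub in df.groupby("track_id"):
            recs = {int(r.frame): (r.x_um, r.y_um) for r in sub.itertuples()}
            for t in recs:
                if t - L in recs and t in gc and t - L in gc:
                    dx = (recs[t][0] - gc[t][0]) - (recs[t - L][0] - gc[t - L][0])
                    dy = (recs[t][1] - gc[t][1]) - (recs[t - L][1] - gc[t - L][1])
                    vals.append(dx * dx + dy * dy)
        if vals:
            out[L * frame_interval] = (float(np.mean(vals)), len(vals))
    return out


def link_brute_force(spots_by_frame: list[np.ndarray]) -> list[list[int]]:
    """Globally optimal frame-to-frame matching by exhaustive enumeration
    (≤4 spots/frame): returns, per transition, the permutation mapping
    frame-k spot index -> frame-(k+1) spot index minimizing total
    displacement of that transition."""
    out = []
    for a, b in zip(spots_by_frame[:-1], spots_by_frame[1:]):
        assert len(a) == len(b) <= 4
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(len(b))):
            cost = sum(np.hypot(*(a[i] - b[j])) for i, j in enumerate(perm))
            if cost < best_cost:
                best, best_cost = list(perm), cost
        out.append(best)
    return out


def gaussian_fit_2d(patch: np.ndarray):
    """Least-squares isotropic-Gaussian fit; the localization oracle.
    Returns (cx, cy) in patch pixel coordinates."""
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]

    def model(_, amp, cx, cy, sig, bg):
        return (bg + amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                  / (2 * sig ** 2))).ravel()

    r0, c0 = np.unravel_index(np.argmax(patch), patch.shape)
    p0 = [patch.max() - patch.min(), c0, r0, 1.5, float(np.median(patch))]
    popt, _ = optimize.curve_fit(model, None, patch.ravel(), p0=p0, maxfev=20000)
    return popt[1], popt[2]


def bootstrap_median_ci(x: np.ndarray, n_boot: int = 2000, alpha: float = 0.05,
                        seed: int = 0) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(x, size=(n_boot, len(x)), replace=True), axis=1)
    return (float(np.percentile(meds, 100 * alpha / 2)),
            float(np.percentile(meds, 100 * (1 - alpha / 2))))


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def toy_tracks() -> fd.TrajectorySet:
    """3 foci × 4 frames with one missing observation (gap)."""
    rows = [
        # track 0: present all frames
        (0, 0, 0.0, 1.0, 2.0, 1.0), (0, 1, 30.0, 1.2, 2.1, 1.0),
        (0, 2, 60.0, 1.1, 2.4, 1.0), (0, 3, 90.0, 1.5, 2.2, 1.0),
        # track 1: misses frame 2
        (1, 0, 0.0, 4.0, 4.0, 1.0), (1, 1, 30.0, 4.2, 3.9, 1.0),
        (1, 3, 90.0, 4.4, 4.3, 1.0),
        # track 2
        (2, 0, 0.0, 2.5, 5.0, 1.0), (2, 1, 30.0, 2.4, 5.2, 1.0),
        (2, 2, 60.0, 2.8, 5.1, 1.0), (2, 3, 90.0, 2.6, 4.9, 1.0),
    ]
    return fd.TrajectorySet(df=pd.DataFrame(rows, columns=TRACK_COLUMNS),
                            frame_interval=30.0, provenance="ground_truth")


@pytest.fixture(scope="session")
def random_fixture_tracks() -> list[fd.TrajectorySet]:
    """Random small trajectory sets (≤10 foci × ≤20 frames) with gaps."""
    rng = np.random.default_rng(42)
    sets = []
    for n_foci, n_frames in [(2, 5), (5, 12), (10, 20)]:
        rows = []
        for tid in range(n_foci):
            x, y = rng.uniform(-5, 5, 2)
            for f in range(n_frames):
                x += rng.normal(0, 0.3)
                y += rng.normal(0, 0.3)
                if rng.uniform() < 0.1 and 0 < f < n_frames - 1:
                    continue  # gap
                rows.append((tid, f, f * 30.0, x, y, 1.0))
        sets.append(fd.TrajectorySet(
            df=pd.DataFrame(rows, columns=TRACK_COLUMNS),
            frame_interval=30.0, provenance="ground_truth"))
    return sets


@pytest.fixture(scope="session")
def scheduled_truth() -> fd.GroundTruth:
    """Noiseless-renderable movie with 5 scheduled fusions and 5 scheduled
    disappearances among 30 initial foci (events acquisition cadence)."""
    cfg = fd.SimulationConfig.events_protocol(seed=7, n_frames=21)
    return fd.simulate_scheduled_events(
        cfg,
        fusion_frames=(4, 7, 10, 13, 16),
        disappearance_frames=(5, 8, 11, 14, 17),
        n_background=10,
    )


@pytest.fixture(scope="session")
def scheduled_pipeline(scheduled_truth) -> fd.TrajectorySet:
    """detect → track output of the noiseless scheduled movie."""
    stack = fd.render_movie(scheduled_truth, noise=False)
    spots = fd.detect_stack(stack)
    return fd.link_tracks(spots, max_disp=1.0, max_gap=0,
                          frame_interval=scheduled_truth.config.frame_interval)


# fixture groups for the t-test oracle (5 vs 5 values)
GROUP_A = np.array([2.1, 2.5, 1.9, 2.8, 2.3])
GROUP_B = np.array([3.4, 3.1, 3.9, 2.9, 3.6])
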