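"""Drift-corrected mean-square displacement and distance travelled.

Focus mobility is quantified against the per-frame *global centre* (GC) —
the unweighted centroid of all tracked focus positions in a frame — so that
rigid translation of the whole nucleus (stage drift, cell movement) cancels
exactly.  For focus i at lag Δt,

    D_i(Δt)² = [(x_t^i − x_t^GC) − (x_{t−Δt}^i − x_{t−Δt}^GC)]²
             + [(y_t^i − y_t^GC) − (y_{t−Δt}^i − y_{t−Δt}^GC)]²

and MSD(Δt) averages D_i(Δt)² over all foci and all valid time origins
(time-and-ensemble average).  A pair is valid when the focus is observed in
both frames and a global centre is defined in both.  Note the centroid
reference deflates the expected MSD of n independent walkers by the factor
(1 − 1/n); fits against simulated truth must account for it.

Model fits: free diffusion MSD = 4·D·Δt, and confined (tethered) diffusion
MSD = P·(1 − exp(−Δt/τ)) whose plateau P is the squared confinement scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .tracking import TrajectorySet

__all__ = [
    "MSDCurve",
    "MSDFit",
    "global_center",
    "drift_series",
    "compute_msd",
    "distance_travelled",
    "fit_msd_model",
]


@dataclass
class MSDCurve:
    """Lag-indexed mean-square displacement.

    Arrays are aligned: ``lag_s`` (seconds, multiples of the frame
    interval, including lag 0), ``msd`` (µm²), ``n_pairs`` (displacement
    pairs averaged at each lag), ``sem`` (standard error, µm²; NaN where
    fewer than 2 pairs).  Lags with no valid pair are omitted, never
    reported as zero.
    """

    lag_s: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    sem: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, float)
        self.msd = np.asarray(self.msd, float)
        self.n_pairs = np.asarray(self.n_pairs, int)
        self.sem = np.asarray(self.sem, float)
        if (self.msd < 0).any():
            raise ValueError("msd must be nonnegative")
        if (self.n_pairs[self.lag_s > 0] < 1).any():
            raise ValueError("reported lags must have at least one pair")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_s, "msd_um2": self.msd,
                             "n_pairs": self.n_pairs, "sem_um2": self.sem})

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# drift-corrected mean-square displacement\n")
            self.to_frame().to_csv(fh, index=False)


def global_center(trajectories: TrajectorySet, frame: int) -> tuple[float, float]:
    """Unweighted centroid of all tracked focus positions in one frame.

    Raises ``ValueError`` for a frame with no tracked focus — the global
    centre is undefined there and callers must skip, not zero-fill.
    """
    sf = trajectories.at_frame(frame)
    if sf.empty:
        raise ValueError(f"global center undefined: no tracked focus in frame {frame}")
    return float(sf["x_um"].mean()), float(sf["y_um"].mean())


def drift_series(trajectories: TrajectorySet) -> pd.DataFrame:
    """Global-centre position for every frame containing >= 1 focus.

    Returns a DataFrame indexed by frame with columns ``gc_x, gc_y`` (µm).
    """
    g = trajectories.df.groupby("frame")[["x_um", "y_um"]].mean()
    g.columns = ["gc_x", "gc_y"]
    return g


def _corrected_matrices(trajectories: TrajectorySet, drift_correct: bool):
    """Track-by-frame matrices of (drift-corrected) x and y; NaN = absent."""
    df = trajectories.df
    X = df.pivot(index="track_id", columns="frame", values="x_um")
    Y = df.pivot(index="track_id", columns="frame", values="y_um")
    frames = X.columns.to_numpy()
    if drift_correct:
        gc = drift_series(trajectories)
        X = X.sub(gc["gc_x"], axis=1)
        Y = Y.sub(gc["gc_y"], axis=1)
    # reindex onto the full contiguous frame range so lag = column offset
    full = np.arange(frames.min(), frames.max() + 1)
    X = X.reindex(columns=full)
    Y = Y.reindex(columns=full)
    return X.to_numpy(float), Y.to_numpy(float)


def compute_msd(
    trajectories: TrajectorySet,
    max_lag: float | None = None,
    drift_correct: bool = True,
) -> MSDCurve:
    """Time-and-ensemble-averaged (drift-corrected) MSD.

    Parameters
    ----------
    trajectories : TrajectorySet
        Needs >= 2 frames overall.
    max_lag : float, optional
        Largest lag in seconds; defaults to half the movie duration
        (pair counts get unreliable beyond that).
    drift_correct : bool
        Subtract the per-frame global centre (default). Turning it off
        gives raw-position MSD for sensitivity checks.
    """
    if trajectories.df.empty or trajectories.n_frames < 2:
        raise ValueError("need at least 2 frames of tracked positions")
    dt = trajectories.frame_interval
    duration = (trajectories.n_frames - 1) * dt
    if max_lag is None:
        max_lag = duration / 2.0
    if max_lag > duration:
        raise ValueError("max_lag exceeds the movie duration")
    max_lag_frames = int(np.floor(max_lag / dt + 1e-9))

    X, Y = _corrected_matrices(trajectories, drift_correct)
    n_obs = int(np.isfinite(X).sum())

    lags = [0.0]
    msds = [0.0]
    npairs = [n_obs]
    sems = [0.0]
    for L in range(1, max_lag_frames + 1):
        if L >= X.shape[1]:
            break
        dx = X[:, L:] - X[:, :-L]
        dy = Y[:, L:] - Y[:, :-L]
        sq = dx * dx + dy * dy
        valid = np.isfinite(sq)
        n = int(valid.sum())
        if n < 1:
            continue  # lag omitted, never reported as zero
        vals = sq[valid]
        lags.append(L * dt)
        msds.append(float(vals.mean()))
        npairs.append(n)
        sems.append(float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan)

    return MSDCurve(lag_s=np.array(lags), msd=np.array(msds),
                    n_pairs=np.array(npairs), sem=np.array(sems),
                    frame_interval=dt)


def distance_travelled(
    trajectories: TrajectorySet,
    track_id: int | None = None,
    window: tuple[float, float] | float | None = None,
    drift_correct: bool = True,
) -> float | pd.Series:
    """Path length travelled by a focus within a time window.

    Sums Euclidean step lengths between consecutive *observed* frames of
    the (drift-corrected) trajectory inside the window; gap-closed frames
    contribute a single straight step, never an interpolation.

    Parameters
    ----------
    track_id : int, optional
        One track (returns a float) or, when None, all tracks (returns a
        Series indexed by track_id).
    window : (start_s, end_s) or float, optional
        Time window in seconds; a bare float means ``(0, window)``; None
        means the whole movie.  A requested track with fewer than 2
        observations inside the window raises ``ValueError``.
    drift_correct : bool
        Measure in global-centre-corrected coordinates (default), matching
        the MSD convention; raw positions available for sensitivity checks.
    """
    if isinstance(window, (int, float)):
        window = (0.0, float(window))

    df = trajectories.df
    if drift_correct:
        gc = drift_series(trajectories)
        df = df.merge(gc, left_on="frame", right_index=True)
        df = df.assign(x_um=df["x_um"] - df["gc_x"], y_um=df["y_um"] - df["gc_y"])
    if window is not None:
        df = df[(df["t_s"] >= window[0] - 1e-9) & (df["t_s"] <= window[1] + 1e-9)]

    def one(sub: pd.DataFrame) -> float:
        sub = sub.sort_values("frame")
        if len(sub) < 2:
            raise ValueError("trajectory has fewer than 2 observations in window")
        dx = np.diff(sub["x_um"].to_numpy())
        dy = np.diff(sub["y_um"].to_numpy())
        return float(np.hypot(dx, dy).sum())

    if track_id is not None:
        sub = df[df["track_id"] == track_id]
        if sub.empty:
            raise ValueError(f"track {track_id} absent from window")
        return one(sub)
    out = {}
    for tid, sub in df.groupby("track_id"):
        if len(sub) >= 2:
            out[tid] = one(sub)
    return pd.Series(out, name="distance_um").rename_axis("track_id")


@dataclass
class MSDFit:
    """Fitted MSD model parameters with 1-sigma uncertainties."""

    model: str
    params: dict
    stderr: dict
    rmse: float
    success: bool
    message: str

    @property
    def D(self) -> float:
        """Diffusion coefficient, µm²/s (free model; confined: initial-slope
        estimate P/(4τ))."""
        if self.model == "free":
            return self.params["D"]
        return self.params["P"] / (4.0 * self.params["tau"])


def fit_msd_model(curve: MSDCurve, model: str = "free") -> MSDFit:
    """Least-squares fit of a diffusion model to an MSD curve.

    ``model="free"``: MSD = 4·D·Δt (closed-form line through the origin).
    ``model="confined"``: MSD = P·(1 − exp(−Δt/τ)); the plateau P is the
    squared confinement scale.  Needs >= 3 nonzero lags.  Non-convergence
    raises with diagnostics rather than returning silent defaults.
    """
    nz = curve.lag_s > 0
    t = curve.lag_s[nz]
    y = curve.msd[nz]
    if len(t) < 3:
        raise ValueError("need at least 3 nonzero lags to fit")

    if model == "free":
        # exact weighted-by-nothing LS through the origin
        denom = float(np.sum(16.0 * t * t))
        D = float(np.sum(4.0 * t * y) / denom)
        resid = y - 4.0 * D * t
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        dof = max(len(t) - 1, 1)
        se = float(np.sqrt(np.sum(resid ** 2) / dof / np.sum(16.0 * t * t)))
        return MSDFit(model="free", params={"D": D}, stderr={"D": se},
                      rmse=rmse, success=True, message="closed-form fit")
    if model == "confined":
        p0 = [max(float(y.max()), 1e-9), max(float(t[len(t) // 3]), curve.frame_interval)]
        try:
            popt, pcov = optimize.curve_fit(
                lambda tt, P, tau: P * (1.0 - np.exp(-tt / tau)),
                t, y, p0=p0, bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000)
        except (RuntimeError, ValueError) as err:
            raise RuntimeError(
                f"confined MSD fit failed to converge: {err}; p0={p0}, "
                f"lags={t.tolist()}") from err
        resid = y - popt[0] * (1.0 - np.exp(-t / popt[1]))
        d = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        return MSDFit(model="confined",
                      params={"P": float(popt[0]), "tau": float(popt[1])},
                      stderr={"P": float(d[0]), "tau": float(d[1])},
                      rmse=float(np.sqrt(np.mean(resid ** 2))),
                      success=True, message="curve_fit converged")
    raise ValueError("model must be 'free' or 'confined'")
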