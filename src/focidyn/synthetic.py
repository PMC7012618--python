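"""Synthetic ground truth: focus motion, rendered movies, stripe kinetics.

Repair-focus mobility movies are emulated as n foci performing *confined*
Brownian motion inside a circular nuclear region: each focus is tethered to
an anchor point by an Ornstein-Uhlenbeck restoring force, so its
mean-square displacement rises linearly at short lags (slope 4D) and
saturates at long lags — the shape measured for damage foci in live cells.
On top of that intrinsic motion every focus shares a rigid per-frame drift
(stage/nucleus translation), which the analysis must cancel.  Foci may
coalesce when they come within a fusion radius (two tracks end, one child
continues) and may disappear with an exponential lifetime.

The tether is parameterized by ``confinement_radius`` R, defined as the
stationary root-mean-square radial distance from the anchor: the per-axis
stationary variance is R²/2, the relaxation time is τ = R²/(2D), and the
exact OU discretization is used so the short-lag step variance is
2·D·Δt per axis.  The closed-form long-lag MSD plateau (about a fixed
anchor) is 2R²; free diffusion is the R = ∞ special case.

One master seed drives everything; each focus consumes its own counter-based
substream, so adding a focus never perturbs the paths of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .enrichment import RecruitmentParams, StripeROI, biphasic_recruitment
from .events import EVENT_COLUMNS, EventLog
from .imagestack import ImageStack
from .tracking import TRACK_COLUMNS, TrajectorySet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_trajectories",
    "simulate_scheduled_events",
    "render_movie",
    "simulate_recruitment_profile",
    "render_stripe_movie",
]

#: additive Gaussian read noise of the rendering camera model, photons RMS
READ_NOISE_SIGMA = 2.0


@dataclass
class SimulationConfig:
    """Parameters of a focus-motion simulation.

    Defaults reproduce the mobility-movie protocol: a frame every 30 s for
    10 min (21 frames), ~20 etoposide-induced foci in an 8 µm-radius
    nuclear region, D = 0.005 µm²/s with a 0.5 µm tether, imaged at
    0.1 µm/px with a 1.5 px PSF at SNR 10.  Event movies (one frame every
    3 min for an hour) are available via :meth:`events_protocol`.
    """

    n_foci: int = 20
    nucleus_radius: float = 8.0          # µm
    diffusion_coeff: float = 0.005       # µm²/s
    confinement_radius: float | None = 0.5  # µm RMS tether; None = free
    drift_velocity: tuple[float, float] | np.ndarray = (0.0, 0.0)  # µm/s, or (n_frames, 2) µm offsets
    frame_interval: float = 30.0         # s
    n_frames: int = 21
    fusion_radius: float = 0.0           # µm; 0 disables coalescence
    disappearance_rate: float = 0.0      # 1/s; 0 disables
    pixel_size: float = 0.1              # µm/px
    psf_sigma: float = 1.5               # px
    background_level: float = 100.0      # photons
    snr: float = 10.0                    # peak amplitude over background noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diffusion_coeff", "frame_interval",
                     "fusion_radius", "disappearance_rate", "pixel_size",
                     "psf_sigma", "background_level", "snr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        # inf nucleus = unbounded motion (no boundary reflection)
        if not (self.nucleus_radius >= 0):
            raise ValueError("nucleus_radius must be nonnegative")
        if self.confinement_radius is not None:
            if not (self.confinement_radius >= 0):  # inf allowed
                raise ValueError("confinement_radius must be nonnegative")
        if self.n_foci < 0:
            raise ValueError("n_foci must be nonnegative")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")
        drift = np.asarray(self.drift_velocity, float)
        if drift.ndim == 1 and drift.shape != (2,):
            raise ValueError("drift_velocity vector must have 2 components")
        if drift.ndim == 2 and drift.shape != (self.n_frames, 2):
            raise ValueError("per-frame drift series must be (n_frames, 2)")
        if not np.isfinite(drift).all():
            raise ValueError("drift must be finite")

    # --------------------------------------------------- derived quantities
    @property
    def is_confined(self) -> bool:
        r = self.confinement_radius
        return r is not None and np.isfinite(r)

    @property
    def stationary_axis_variance(self) -> float:
        """Stationary per-axis variance of a tethered focus about its
        anchor, R²/2 (µm²)."""
        if not self.is_confined:
            return np.inf
        return self.confinement_radius ** 2 / 2.0

    @property
    def msd_plateau(self) -> float:
        """Closed-form long-lag MSD plateau about the anchor, 2R² (µm²)."""
        return 4.0 * self.stationary_axis_variance

    @property
    def relaxation_time(self) -> float:
        """OU tether relaxation time τ = R²/(2D), seconds."""
        if not self.is_confined:
            return np.inf
        if self.diffusion_coeff == 0:
            return np.inf
        return self.confinement_radius ** 2 / (2.0 * self.diffusion_coeff)

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def drift_offsets(self) -> np.ndarray:
        """Per-frame rigid offsets (n_frames, 2), µm."""
        drift = np.asarray(self.drift_velocity, float)
        if drift.ndim == 2:
            return drift
        t = np.arange(self.n_frames)[:, None] * self.frame_interval
        return drift[None, :] * t

    # ------------------------------------------------------------- protocols
    @classmethod
    def mobility_protocol(cls, **overrides) -> "SimulationConfig":
        """Mobility acquisition: one frame every 30 s for 10 min."""
        base = dict(frame_interval=30.0, n_frames=21)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def events_protocol(cls, **overrides) -> "SimulationConfig":
        """Fusion/disappearance acquisition: one frame every 3 min for an
        hour, with coalescence on and a ~20 min median focus lifetime."""
        base = dict(frame_interval=180.0, n_frames=21,
                    fusion_radius=0.35,
                    disappearance_rate=math.log(2) / 1200.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_duration(cls, duration_s: float, frame_interval: float,
                      **overrides) -> "SimulationConfig":
        """Frame count from a recording duration: both endpoints included,
        e.g. 600 s at 30 s intervals gives 21 frames."""
        n = int(math.floor(duration_s / frame_interval + 1e-9)) + 1
        return cls(frame_interval=frame_interval, n_frames=n, **overrides)

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["drift_velocity"] = np.asarray(self.drift_velocity, float).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if isinstance(d.get("drift_velocity"), list):
            dv = np.asarray(d["drift_velocity"], float)
            d["drift_velocity"] = tuple(dv) if dv.ndim == 1 else dv
        return cls(**d)


@dataclass
class GroundTruth:
    """Simulator output: true trajectories, event schedule, drift."""

    trajectories: TrajectorySet
    events: EventLog
    drift_um: np.ndarray          # (n_frames, 2)
    config: SimulationConfig

    def live_counts(self) -> np.ndarray:
        """True number of live foci in each frame."""
        return self.trajectories.counts_per_frame(self.config.n_frames)

    def write(self, outdir, render: bool = False) -> None:
        """Write trajectory CSV, event CSV, config echo, and optionally the
        rendered 16-bit TIFF movie, into ``outdir``."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trajectories.to_csv(outdir / "truth_tracks.csv")
        self.events.to_csv(outdir / "truth_events.csv")
        self.config.to_yaml(outdir / "config.yaml")
        if render:
            render_movie(self, self.config).to_tiff(outdir / "movie.tif")


def _focus_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based substream: focus ``index`` always gets the same stream
    for a given master seed, independent of how many other foci exist."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


class _Focus:
    __slots__ = ("fid", "rng", "anchor", "pos", "intensity", "birth_frame", "lifetime_s")

    def __init__(self, fid: int, birth_frame: int, config: SimulationConfig,
                 anchor: np.ndarray | None = None, pos: np.ndarray | None = None,
                 intensity: float | None = None):
        self.fid = fid
        self.rng = _focus_rng(config.seed, fid)
        self.birth_frame = birth_frame
        if anchor is None:
            # uniform in a disk leaving room for the tether excursions
            R = config.nucleus_radius if np.isfinite(config.nucleus_radius) else 10.0
            r_max = max(R - (config.confinement_radius
                        if config.is_confined else 0.0), 0.1 * R)
            u = self.rng.uniform(0, 1)
            theta = self.rng.uniform(0, 2 * np.pi)
            anchor = r_max * np.sqrt(u) * np.array([np.cos(theta), np.sin(theta)])
        self.anchor = np.asarray(anchor, float)
        if pos is None:
            if config.is_confined and config.diffusion_coeff > 0:
                # start at tether equilibrium so ensemble stats are stationary
                sd = math.sqrt(config.stationary_axis_variance)
                pos = self.anchor + self.rng.normal(0.0, sd, 2)
            else:
                pos = self.anchor.copy()
        self.pos = np.asarray(pos, float)
        self.intensity = (float(self.rng.uniform(0.8, 1.2))
                          if intensity is None else float(intensity))
        if config.disappearance_rate > 0:
            self.lifetime_s = float(self.rng.exponential(1.0 / config.disappearance_rate))
        else:
            self.lifetime_s = np.inf

    def step(self, config: SimulationConfig) -> None:
        """One exact OU (or free Brownian) transition, then reflection at
        the nuclear boundary."""
        D, dt = config.diffusion_coeff, config.frame_interval
        noise = self.rng.normal(0.0, 1.0, 2)   # always 2 draws: keeps streams aligned
        if config.is_confined:
            if config.confinement_radius == 0:
                self.pos = self.anchor.copy()
            else:
                tau = config.relaxation_time
                rho = math.exp(-dt / tau) if np.isfinite(tau) else 1.0
                sd_eq = math.sqrt(config.stationary_axis_variance)
                sd_step = sd_eq * math.sqrt(max(1.0 - rho * rho, 0.0))
                self.pos = self.anchor + (self.pos - self.anchor) * rho + sd_step * noise
        else:
            self.pos = self.pos + math.sqrt(2.0 * D * dt) * noise
        # radial reflection keeps foci inside the nucleus
        R = config.nucleus_radius
        if not np.isfinite(R):
            return
        r = float(np.hypot(*self.pos))
        while r > R and R > 0:
            self.pos *= (2.0 * R - r) / r
            r = float(np.hypot(*self.pos))


def simulate_trajectories(config: SimulationConfig) -> GroundTruth:
    """Simulate confined, drifting, fusing, disappearing focus trajectories.

    Returns ground-truth trajectories (recorded positions include the rigid
    drift), the event log, and the drift offsets themselves.  Bit-identical
    for identical ``(config, seed)``.

    At a fusion, both parent tracks terminate (last record the frame before
    the merge) and one child track starts at the intensity-weighted mean of
    the parents' positions; total track count never increases.
    """
    drift = config.drift_offsets()
    foci = [_Focus(i, 0, config) for i in range(config.n_foci)]
    next_child = config.n_foci

    records: list[tuple] = []
    event_rows: list[dict] = []

    def record(f: _Focus, frame: int) -> None:
        x, y = f.pos + drift[frame]
        records.append((f.fid, frame, frame * config.frame_interval,
                        float(x), float(y), f.intensity))

    for f in foci:
        record(f, 0)

    for k in range(1, config.n_frames):
        t_k = k * config.frame_interval
        survivors: list[_Focus] = []
        for f in sorted(foci, key=lambda f: f.fid):
            f.step(config)
            if (k - f.birth_frame) * config.frame_interval > f.lifetime_s:
                x, y = f.pos + drift[k]
                event_rows.append({
                    "event_type": "disappearance", "frame": k, "t_s": t_k,
                    "track_ids": (f.fid,), "x_um": float(x), "y_um": float(y),
                })
            else:
                survivors.append(f)
        foci = survivors

        if config.fusion_radius > 0 and len(foci) >= 2:
            pos = np.array([f.pos for f in foci])
            n = len(foci)
            dists = [
                (float(np.hypot(*(pos[i] - pos[j]))), i, j)
                for i in range(n) for j in range(i + 1, n)
            ]
            dists.sort()
            fused_idx: set[int] = set()
            children: list[_Focus] = []
            for d, i, j in dists:
                if d >= config.fusion_radius:
                    break
                if i in fused_idx or j in fused_idx:
                    continue
                fused_idx.update((i, j))
                a, b = foci[i], foci[j]
                w = a.intensity + b.intensity
                child_pos = (a.intensity * a.pos + b.intensity * b.pos) / w
                child = _Focus(next_child, k, config, anchor=child_pos.copy(),
                               pos=child_pos.copy(), intensity=w)
                next_child += 1
                children.append(child)
                x, y = child_pos + drift[k]
                event_rows.append({
                    "event_type": "fusion", "frame": k, "t_s": t_k,
                    "track_ids": (min(a.fid, b.fid), max(a.fid, b.fid), child.fid),
                    "x_um": float(x), "y_um": float(y),
                })
            foci = [f for idx, f in enumerate(foci) if idx not in fused_idx] + children

        for f in foci:
            record(f, k)

    tset = TrajectorySet(
        df=pd.DataFrame(records, columns=TRACK_COLUMNS),
        frame_interval=config.frame_interval,
        provenance="ground_truth",
    )
    events = EventLog(pd.DataFrame(event_rows, columns=EVENT_COLUMNS))
    return GroundTruth(trajectories=tset, events=events, drift_um=drift, config=config)


def simulate_scheduled_events(
    config: SimulationConfig,
    fusion_frames: tuple[int, ...] = (),
    disappearance_frames: tuple[int, ...] = (),
    n_background: int = 10,
    pair_separation: float = 1.6,
    final_separation: float = 0.8,
    site_spacing: float = 3.0,
    wiggle_rms: float = 0.06,
) -> GroundTruth:
    """Ground truth with *scheduled* fusion and disappearance events.

    Places foci on rings with at least ``site_spacing`` µm between
    non-partner foci: ``n_background`` foci wiggle in place for the whole
    movie; each fusion is a pair starting ``pair_separation`` µm apart that
    converges linearly to ``final_separation`` the frame before its
    scheduled merge frame, then coalesces (the pair stays optically
    resolvable right up to the merge, so detection scores the event at the
    scheduled frame, not earlier); each disappearance is a focus removed
    exactly at its scheduled frame.  Small Gaussian positional wiggle
    (``wiggle_rms`` µm RMS, from per-focus substreams) makes the motion
    realistic without ever confusing the linker.

    This is the oracle movie for end-to-end event-scoring checks: the
    returned :class:`EventLog` lists exactly the scheduled events.
    """
    for f in (*fusion_frames, *disappearance_frames):
        if not (1 <= f <= config.n_frames - 3):
            raise ValueError("scheduled frames must leave room to confirm "
                             "the event (1 <= frame <= n_frames - 3)")
    n_sites = n_background + len(fusion_frames) + len(disappearance_frames)
    sites = _ring_sites(n_sites, config.nucleus_radius, site_spacing)
    drift = config.drift_offsets()

    records: list[tuple] = []
    event_rows: list[dict] = []
    dt = config.frame_interval

    def wiggle(rng, n):
        return rng.normal(0.0, wiggle_rms, (n, 2))

    fid = 0
    site_i = 0
    # background foci: present all movie
    for _ in range(n_background):
        rng = _focus_rng(config.seed, fid)
        w = wiggle(rng, config.n_frames)
        inten = float(rng.uniform(0.8, 1.2))
        for k in range(config.n_frames):
            x, y = sites[site_i] + w[k] + drift[k]
            records.append((fid, k, k * dt, float(x), float(y), inten))
        fid += 1
        site_i += 1

    # disappearance foci: vanish at their scheduled frame
    for k_gone in disappearance_frames:
        rng = _focus_rng(config.seed, fid)
        w = wiggle(rng, config.n_frames)
        inten = float(rng.uniform(0.8, 1.2))
        for k in range(k_gone):
            x, y = sites[site_i] + w[k] + drift[k]
            records.append((fid, k, k * dt, float(x), float(y), inten))
        lx, ly = sites[site_i] + w[k_gone] + drift[k_gone]
        event_rows.append({
            "event_type": "disappearance", "frame": int(k_gone),
            "t_s": k_gone * dt, "track_ids": (fid,),
            "x_um": float(lx), "y_um": float(ly),
        })
        fid += 1
        site_i += 1

    # fusion pairs: converge linearly, merge at the scheduled frame
    # (children numbered after all parents)
    child_fid = n_background + len(disappearance_frames) + 2 * len(fusion_frames)
    for k_merge in fusion_frames:
        centre = sites[site_i]
        site_i += 1
        half = np.array([0.5, 0.0])
        rng_a = _focus_rng(config.seed, fid)
        rng_b = _focus_rng(config.seed, fid + 1)
        wa, wb = wiggle(rng_a, config.n_frames), wiggle(rng_b, config.n_frames)
        ia = float(rng_a.uniform(0.8, 1.2))
        ib = float(rng_b.uniform(0.8, 1.2))
        for k in range(k_merge):
            # separation shrinks from pair_separation to final_separation
            # at the frame before the merge, then jumps to zero
            frac = k / max(k_merge - 1, 1)
            s = pair_separation + (final_separation - pair_separation) * frac
            xa = centre - half * s + wa[k] + drift[k]
            xb = centre + half * s + wb[k] + drift[k]
            records.append((fid, k, k * dt, float(xa[0]), float(xa[1]), ia))
            records.append((fid + 1, k, k * dt, float(xb[0]), float(xb[1]), ib))
        rng_c = _focus_rng(config.seed, child_fid)
        wc = wiggle(rng_c, config.n_frames)
        for k in range(k_merge, config.n_frames):
            xc = centre + wc[k] + drift[k]
            records.append((child_fid, k, k * dt, float(xc[0]), float(xc[1]), ia + ib))
        cx, cy = centre + wc[k_merge] + drift[k_merge]
        event_rows.append({
            "event_type": "fusion", "frame": int(k_merge), "t_s": k_merge * dt,
            "track_ids": (fid, fid + 1, child_fid),
            "x_um": float(cx), "y_um": float(cy),
        })
        fid += 2
        child_fid += 1

    tset = TrajectorySet(
        df=pd.DataFrame(records, columns=TRACK_COLUMNS),
        frame_interval=dt, provenance="ground_truth")
    events = EventLog(pd.DataFrame(event_rows, columns=EVENT_COLUMNS))
    return GroundTruth(trajectories=tset, events=events, drift_um=drift, config=config)


def _ring_sites(n: int, nucleus_radius: float, spacing: float) -> np.ndarray:
    """Deterministic focus sites on concentric rings, pairwise separated by
    at least ``spacing`` µm, inside 0.9 × nucleus_radius."""
    sites: list[np.ndarray] = []
    r = 0.9 * nucleus_radius
    while len(sites) < n and r > spacing / 2:
        m = max(int(2 * np.pi * r // spacing), 1)
        for j in range(m):
            if len(sites) >= n:
                break
            theta = 2 * np.pi * j / m + (0.25 if r < 0.9 * nucleus_radius else 0.0)
            sites.append(r * np.array([np.cos(theta), np.sin(theta)]))
        r -= spacing
    if len(sites) < n:
        raise ValueError(f"cannot place {n} sites with spacing {spacing} µm "
                         f"in a {nucleus_radius} µm nucleus")
    return np.array(sites)


# --------------------------------------------------------------- rendering

def render_movie(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    noise: bool = True,
    shape: tuple[int, int] | None = None,
) -> ImageStack:
    """Render ground-truth trajectories as a fluorescence movie.

    Each live focus becomes an isotropic 2D Gaussian of width ``psf_sigma``
    (px) at its subpixel position, with peak amplitude ``snr`` times the
    background noise standard deviation (Poisson shot noise on signal plus
    background, plus Gaussian read noise of ``READ_NOISE_SIGMA`` photons).
    With ``noise=False`` the expected photon image is returned unchanged —
    the noiseless oracle for detection tests.

    The field of view is computed to contain the nucleus plus drift and a
    PSF margin; its physical origin is carried in the returned
    :class:`ImageStack` so detections are directly comparable to truth.
    """
    config = config if config is not None else truth.config
    if config.psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    ps = config.pixel_size
    df = truth.trajectories.df
    margin = 5.0 * config.psf_sigma * ps
    if shape is None:
        lo = -config.nucleus_radius - margin
        hi = config.nucleus_radius + margin
        if not df.empty:
            lo = min(lo, df["x_um"].min() - margin, df["y_um"].min() - margin)
            hi = max(hi, df["x_um"].max() + margin, df["y_um"].max() + margin)
        npx = int(math.ceil((hi - lo) / ps))
        shape = (npx, npx)
        origin = (lo, lo)
    else:
        origin = (-shape[1] * ps / 2.0, -shape[0] * ps / 2.0)
    h, w = shape

    noise_sd = math.sqrt(config.background_level + READ_NOISE_SIGMA ** 2)
    amp = config.snr * noise_sd
    sig = config.psf_sigma

    # full (untruncated) Gaussians: a hard window cutoff would leave kinks
    # that the band-pass detector picks up as rings of spurious maxima
    frames = np.full((config.n_frames, h, w), float(config.background_level))
    xs = np.arange(w)
    ys = np.arange(h)
    for _, rec in df.iterrows():
        k = int(rec["frame"])
        cx = (rec["x_um"] - origin[0]) / ps
        cy = (rec["y_um"] - origin[1]) / ps
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(
                f"focus at ({rec['x_um']:.2f}, {rec['y_um']:.2f}) µm falls "
                "outside the rendered field of view")
        gx = np.exp(-0.5 * ((xs - cx) / sig) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sig) ** 2)
        frames[k] += amp * rec["intensity"] * np.outer(gy, gx)

    if noise:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1 << 20,)))
        frames = rng.poisson(frames).astype(float)
        frames += rng.normal(0.0, READ_NOISE_SIGMA, frames.shape)
        frames = np.clip(frames, 0, None)

    return ImageStack(frames=frames, pixel_size=ps,
                      frame_interval=config.frame_interval, origin=origin)


# ------------------------------------------------- laser-stripe recruitment

def simulate_recruitment_profile(params: RecruitmentParams, times) -> np.ndarray:
    """Relative enrichment R(t) of the two-stage recruitment model.

    ``times`` must be nonnegative and strictly increasing (seconds).
    R(0) = 1 (no enrichment); as t → ∞ with gamma > 0, R → 1 + A_slow.
    """
    t = np.asarray(times, float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a nonempty 1D sequence")
    if (t < 0).any():
        raise ValueError("times must be nonnegative")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    return biphasic_recruitment(t, *params.as_array())


def render_stripe_movie(
    params: RecruitmentParams,
    times,
    shape: tuple[int, int] = (128, 160),
    stripe_width_px: float = 12.0,
    snr: float = 10.0,
    pixel_size: float = 0.1,
    seed: int = 0,
    noise: bool = True,
) -> tuple[ImageStack, StripeROI]:
    """Render a laser-stripe movie with biphasic in-stripe recruitment.

    A vertical stripe through the frame centre carries intensity
    ``base * R(t)`` against a uniform nuclear background ``base``, where
    ``base = snr²`` photons so the per-pixel Poisson SNR of the background
    is ≈ ``snr``.  Returns the movie and the stripe ROI used to render it.
    """
    t = np.asarray(times, float)
    profile = simulate_recruitment_profile(params, t)
    dts = np.diff(t)
    if len(dts) == 0 or not np.allclose(dts, dts[0]):
        raise ValueError("rendered movies need uniformly spaced times")
    h, w = shape
    roi = StripeROI.from_line((h, w), (w / 2.0, 0.0), (w / 2.0, h - 1.0),
                              stripe_width_px)
    base = float(snr) ** 2
    frames = np.empty((len(t), h, w))
    for i, r in enumerate(profile):
        frame = np.full((h, w), base)
        frame[roi.mask] = base * r
        frames[i] = frame
    if noise:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1 << 21,)))
        frames = rng.poisson(frames).astype(float)
        frames += rng.normal(0.0, READ_NOISE_SIGMA, frames.shape)
        frames = np.clip(frames, 0, None)
    stack = ImageStack(frames=frames, pixel_size=pixel_size,
                       frame_interval=float(dts[0]))
    return stack, roi
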