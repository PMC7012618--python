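"""Trajectory container and frame-to-frame spot linking.

Linking is deterministic greedy nearest-neighbour assignment: candidate
(track, spot) pairs are sorted by distance (ties broken by lower track id)
and consumed shortest-first, each track and each spot used at most once.
Unmatched spots seed new tracks; a track silent for more than ``max_gap``
frames is closed.  At the focus densities typical of damage-focus movies
(tens of foci per nucleus, inter-focus spacing well above the per-frame
step length) this recovers the globally optimal matching; the brute-force
optimal matcher lives in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrajectorySet", "link_tracks", "TRACK_COLUMNS"]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "intensity"]

_CSV_HEADER = (
    "# trajectories: 0-based frames, (x, y) = (column, row) in micrometres\n"
)


@dataclass
class TrajectorySet:
    """A set of focus trajectories in physical (µm) coordinates.

    ``df`` is tidy with columns ``track_id, frame, t_s, x_um, y_um,
    intensity``; frames are strictly increasing within a track and each
    (track_id, frame) pair is unique.
    """

    df: pd.DataFrame
    frame_interval: float
    provenance: str = "detected"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df, columns=TRACK_COLUMNS).copy()
        df["track_id"] = df["track_id"].astype(int)
        df["frame"] = df["frame"].astype(int)
        df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
        if df.duplicated(["track_id", "frame"]).any():
            raise ValueError("duplicate (track_id, frame) record")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")
        self.df = df

    # ------------------------------------------------------------ queries
    @property
    def track_ids(self) -> np.ndarray:
        return self.df["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def n_frames(self) -> int:
        return 0 if self.df.empty else int(self.df["frame"].max()) + 1

    def track(self, track_id: int) -> pd.DataFrame:
        out = self.df[self.df["track_id"] == track_id]
        if out.empty:
            raise KeyError(f"no track {track_id}")
        return out

    def at_frame(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    def last_records(self) -> pd.DataFrame:
        """One row per track: its final observation."""
        return self.df.loc[self.df.groupby("track_id")["frame"].idxmax()]

    def first_records(self) -> pd.DataFrame:
        return self.df.loc[self.df.groupby("track_id")["frame"].idxmin()]

    def counts_per_frame(self, n_frames: int | None = None) -> np.ndarray:
        n = n_frames if n_frames is not None else self.n_frames
        counts = np.zeros(n, dtype=int)
        vc = self.df["frame"].value_counts()
        counts[vc.index.to_numpy()] = vc.to_numpy()
        return counts

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_CSV_HEADER)
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float | None = None,
                 provenance: str = "detected") -> "TrajectorySet":
        df = pd.read_csv(path, comment="#")
        if frame_interval is None:
            by_frame = df.drop_duplicates("frame").sort_values("frame")
            dt = np.diff(by_frame["t_s"].to_numpy()) / np.maximum(
                np.diff(by_frame["frame"].to_numpy()), 1)
            if len(dt) == 0:
                raise ValueError("cannot infer frame_interval from a single frame")
            frame_interval = float(np.median(dt))
        return cls(df=df, frame_interval=frame_interval, provenance=provenance)


def link_tracks(
    spots: pd.DataFrame,
    max_disp: float = 1.5,
    max_gap: int = 1,
    frame_interval: float = 30.0,
    n_frames: int | None = None,
) -> TrajectorySet:
    """Link per-frame spots into trajectories.

    Parameters
    ----------
    spots : DataFrame
        Columns ``frame, x_um, y_um, intensity`` (extra columns ignored).
    max_disp : float
        Maximum allowed displacement (µm) between a track's last position
        and a candidate spot, regardless of gap length. Default 1.5 µm —
        a generous bound on per-step focus motion at a 30 s cadence.
    max_gap : int
        Number of consecutive frames a track may be missed and still be
        extended. ``0`` disables gap closing.
    frame_interval : float
        Seconds between frames; copied into the output.
    n_frames : int, optional
        Movie length; defaults to ``max(frame) + 1``.

    Returns
    -------
    TrajectorySet
        Every input spot is assigned to exactly one track. Output is
        invariant to the ordering of spots within a frame.
    """
    if not (max_disp > 0):
        raise ValueError("max_disp must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    spots = pd.DataFrame(spots)
    required = {"frame", "x_um", "y_um"}
    if not spots.empty and not required.issubset(spots.columns):
        raise ValueError(f"spots must have columns {sorted(required)}")
    if spots.empty:
        return TrajectorySet(
            df=pd.DataFrame(columns=TRACK_COLUMNS),
            frame_interval=frame_interval, provenance="detected")
    if "intensity" not in spots.columns:
        spots = spots.assign(intensity=1.0)

    last = int(spots["frame"].max()) if n_frames is None else n_frames - 1

    records: list[tuple] = []          # (track_id, frame, x, y, intensity)
    # active track state: id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    next_id = 0

    for f in range(last + 1):
        sf = spots[spots["frame"] == f]
        # canonical in-frame order => input-order invariance
        sf = sf.sort_values(["x_um", "y_um", "intensity"], kind="stable")
        xs = sf["x_um"].to_numpy(float)
        ys = sf["y_um"].to_numpy(float)
        inten = sf["intensity"].to_numpy(float)

        # drop tracks out of gap range
        active = {tid: st for tid, st in active.items() if st[0] >= f - 1 - max_gap}

        pairs = []
        for tid, (lf, tx, ty) in active.items():
            d = np.hypot(xs - tx, ys - ty)
            for j in np.nonzero(d <= max_disp)[0]:
                pairs.append((float(d[j]), tid, int(j)))
        pairs.sort()

        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        assign: dict[int, int] = {}
        for d, tid, j in pairs:
            if tid in used_tracks or j in used_spots:
                continue
            used_tracks.add(tid)
            used_spots.add(j)
            assign[j] = tid

        for j in range(len(xs)):
            tid = assign.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            active[tid] = (f, xs[j], ys[j])
            records.append((tid, f, f * frame_interval, xs[j], ys[j], inten[j]))

    df = pd.DataFrame(records, columns=TRACK_COLUMNS)
    return TrajectorySet(df=df, frame_interval=frame_interval, provenance="detected")
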