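"""Time-lapse image stack container with physical calibration.

Frames are stored time-major, ``(T, Y, X)`` for 2D movies or ``(T, Z, Y, X)``
for z-stacks.  All downstream quantification runs on 2D frames; z-stacks are
reduced by maximum-intensity projection first, matching how confocal movies
of nuclear foci are normally presented and measured.

Coordinate convention (used everywhere in this package): pixel indices are
0-based, ``(x, y) = (column, row)``, and physical positions in micrometres
are ``origin + index * pixel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A time-ordered fluorescence movie.

    Parameters
    ----------
    frames : ndarray
        ``(T, Y, X)`` or ``(T, Z, Y, X)`` intensity array.
    pixel_size : float
        Lateral calibration, micrometres per pixel. Must be positive.
    frame_interval : float
        Time between consecutive frames, seconds. Must be positive.
    origin : tuple of float
        Physical position (µm) of the centre of pixel ``(row 0, col 0)``,
        as ``(x_um, y_um)``. Lets rendered movies carry the simulation's
        coordinate frame so detections can be compared to ground truth.
    z_step : float or None
        Axial spacing (µm) when frames carry a z-axis; metadata only.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    origin: tuple[float, float] = (0.0, 0.0)
    z_step: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, Y, X) or (T, Z, Y, X)")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def is_zstack(self) -> bool:
        return self.frames.ndim == 4

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from recording start."""
        return np.arange(self.n_frames) * self.frame_interval

    def max_project(self) -> "ImageStack":
        """Maximum-intensity projection along z (no-op for 2D movies)."""
        if not self.is_zstack:
            return self
        return ImageStack(
            frames=self.frames.max(axis=1),
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            origin=self.origin,
            z_step=None,
        )

    # ------------------------------------------------------------------ I/O
    def to_tiff(self, path) -> None:
        """Write a multi-frame 16-bit TIFF; calibration goes in the
        ImageDescription tag as JSON."""
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "origin_um": list(self.origin),
            "z_step_um": self.z_step,
        }
        data = np.clip(np.round(self.frames), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(path, data.astype(np.uint16), description=json.dumps(meta),
                         photometric="minisblack")

    @classmethod
    def from_tiff(
        cls,
        path,
        pixel_size: float | None = None,
        frame_interval: float | None = None,
    ) -> "ImageStack":
        """Read a multi-frame TIFF. Calibration is taken from the JSON
        description written by :meth:`to_tiff` when present; explicit
        arguments override it and are required when it is absent."""
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
        fi = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
        if ps is None or fi is None:
            raise ValueError(
                "pixel_size and frame_interval must be given when the TIFF "
                "carries no calibration metadata"
            )
        if frames.ndim == 2:
            frames = frames[None]
        origin = tuple(meta.get("origin_um", (0.0, 0.0)))
        return cls(
            frames=frames,
            pixel_size=float(ps),
            frame_interval=float(fi),
            origin=origin,
            z_step=meta.get("z_step_um"),
        )
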