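"""Calibrated movie and mask containers shared by the analysis pipeline.

A :class:`Movie` is a set of named, co-registered T×H×W intensity channels
with physical calibration (pixel size in μm, frame interval in s) and an
optional camera dark frame that is subtracted before any quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Movie", "LabeledMaskStack", "CellTrack", "MotilitySummary"]


@dataclass
class Movie:
    """Multi-channel time-lapse with physical calibration.

    Parameters
    ----------
    channels
        Mapping channel name -> float array of shape (T, H, W), nonnegative.
    pixel_size
        Lateral calibration, μm per pixel.
    frame_interval
        Time between frames, seconds.
    dark_frame
        Optional (H, W) camera offset image subtracted from every frame of
        every channel before analysis.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    frame_interval: float
    dark_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if not self.channels:
            raise ValueError("movie needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise ValueError("each channel must be a (T, H, W) array")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.dark_frame is not None:
            self.dark_frame = np.asarray(self.dark_frame, dtype=float)
            if self.dark_frame.shape != shape[1:]:
                raise ValueError("dark_frame shape must match a single frame")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    def corrected(self, channel: str) -> np.ndarray:
        """Dark-subtracted copy of a channel, clipped at zero."""
        data = self.channels[channel]
        if self.dark_frame is None:
            return data.copy()
        return np.clip(data - self.dark_frame[None], 0.0, None)


@dataclass
class LabeledMaskStack:
    """Per-frame integer label images (0 = background).

    Labels are contiguous positive integers within each frame; a label's
    identity is *not* preserved across frames (tracking does that).
    """

    labels: np.ndarray  # (T, H, W) int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be (T, H, W)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.labels[t]


@dataclass
class CellTrack:
    """One cell followed through time.

    ``frames``/``labels``/``centroids`` are aligned lists: the cell carries
    label ``labels[i]`` in frame ``frames[i]`` with centroid
    ``centroids[i]`` in 0-based (row, col) pixel coordinates.
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    flags: dict[str, bool] = field(
        default_factory=lambda: {
            "edge_of_fov": False,
            "low_displacement": False,
            "collision": False,
            "low_expression": False,
        }
    )
    collision_frames: set[int] = field(default_factory=set)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def positions_um(self, pixel_size: float) -> np.ndarray:
        """(N, 2) physical (row, col) coordinates in μm."""
        return np.asarray(self.centroids, dtype=float) * pixel_size


@dataclass
class MotilitySummary:
    """Population motility statistics.

    ``msd`` is a DataFrame with columns ``lag_s``, ``msd_um2``, ``ci_lo``,
    ``ci_hi``, ``n_cells``; per-cell velocity is μm/min and persistence is
    the (dimensionless) net-displacement / path-length ratio in [0, 1].
    """

    msd: "object"  # pandas.DataFrame
    velocity_um_per_min: np.ndarray
    persistence: np.ndarray
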