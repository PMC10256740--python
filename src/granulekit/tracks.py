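"""Core containers for movies and particle trajectories.

All public coordinates are physical (µm), with pixel centers at integer
pixel coordinates, origin at the top-left corner, x rightward and y
downward.  Time is carried as an integer frame index plus a frame
interval in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


@dataclass
class MovieStack:
    """A time-lapse image stack with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative intensities.
    pixel_size : float
        µm per pixel.
    frame_interval : float
        Seconds between frames.
    channel : str
        Free-form channel label.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Elapsed time (s) from first to last frame."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in µm."""
        return (self.frames.shape[2] * self.pixel_size,
                self.frames.shape[1] * self.pixel_size)


@dataclass
class Track:
    """Time-ordered 2-D positions of one particle, in µm."""

    track_id: int
    frame: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    frame_interval: float
    cell_id: int | str | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.frame) == len(self.x_um) == len(self.y_um)):
            raise ValueError("frame, x_um, y_um must have equal length")
        if len(self.frame) < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def t_s(self) -> np.ndarray:
        """Time points in seconds."""
        return self.frame * self.frame_interval

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in µm."""
        return np.column_stack([self.x_um, self.y_um])


@dataclass
class TrackSet:
    """A collection of tracks sharing one time base.

    Backed by a tidy DataFrame with columns
    ``track_id, frame, x_um, y_um`` (plus optional ``cell_id``); the
    frame interval is carried alongside so times are recoverable.
    """

    data: pd.DataFrame
    frame_interval: float
    meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.data = self.data.sort_values(["track_id", "frame"]).reset_index(drop=True)

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def __len__(self) -> int:
        return self.n_tracks

    def get(self, track_id: int) -> Track:
        sub = self.data[self.data["track_id"] == track_id]
        if sub.empty:
            raise KeyError(f"no track with id {track_id}")
        cell = sub["cell_id"].iloc[0] if "cell_id" in sub.columns else None
        return Track(
            track_id=track_id,
            frame=sub["frame"].to_numpy(),
            x_um=sub["x_um"].to_numpy(),
            y_um=sub["y_um"].to_numpy(),
            frame_interval=self.frame_interval,
            cell_id=cell,
        )

    def __iter__(self) -> Iterator[Track]:
        for tid, sub in self.data.groupby("track_id", sort=True):
            cell = sub["cell_id"].iloc[0] if "cell_id" in sub.columns else None
            yield Track(
                track_id=tid,
                frame=sub["frame"].to_numpy(),
                x_um=sub["x_um"].to_numpy(),
                y_um=sub["y_um"].to_numpy(),
                frame_interval=self.frame_interval,
                cell_id=cell,
            )

    def subset(self, track_ids) -> "TrackSet":
        keep = self.data["track_id"].isin(list(track_ids))
        meta = None
        if self.meta is not None:
            meta = self.meta[self.meta["track_id"].isin(list(track_ids))].reset_index(drop=True)
        return TrackSet(self.data[keep].copy(), self.frame_interval, meta)
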