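"""The Track container and its CSV dialect.

A track is the ordered (x, y) positions of one cell over time, in μm, with a
fixed frame interval ``dt`` in minutes.  Tracks are exchanged on disk as CSV
with header ``track_id,frame,x_um,y_um``, one row per observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRACK_CSV_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


@dataclass(frozen=True)
class Track:
    """Ordered positions of one cell.

    Attributes
    ----------
    track_id
        Identifier, unique within a track set.
    frames
        Strictly increasing integer frame indices.
    x, y
        Coordinates in μm; +y points toward the chemoattractant.
    dt
        Frame interval in minutes.
    """

    track_id: int | str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = 0.5

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (frames.shape == x.shape == y.shape) or frames.ndim != 1:
            raise ValueError("frames, x, y must be 1-D arrays of equal length")
        if frames.size == 0:
            raise ValueError("a track needs at least one position")
        if frames.size > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("track coordinates must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        for name, arr in (("frames", frames), ("x", x), ("y", y)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in μm."""
        return np.column_stack([self.x, self.y])

    def translated(self, dx: float, dy: float) -> "Track":
        return Track(self.track_id, self.frames, self.x + dx, self.y + dy, self.dt)


def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks into the long-format table used by the CSV dialect."""
    parts = []
    for t in tracks:
        parts.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "x_um": t.x,
                    "y_um": t.y,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRACK_CSV_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame, dt: float = 0.5) -> list[Track]:
    """Build Track objects from a long-format table.

    Rows are sorted by frame within each track; track order follows first
    appearance in the table.
    """
    missing = [c for c in TRACK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    tracks = []
    for track_id, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id,
                grp["frame"].to_numpy(),
                grp["x_um"].to_numpy(dtype=float),
                grp["y_um"].to_numpy(dtype=float),
                dt,
            )
        )
    return tracks


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path, dt: float = 0.5) -> list[Track]:
    return frame_to_tracks(pd.read_csv(path), dt=dt)
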