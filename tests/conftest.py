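"""Shared fixtures and independent brute-force oracles.

The oracle functions below recompute the track statistics with naive Python
loops, independently of the package's vectorised implementations, so the
tests compare two separately written routes to the same definitions.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from chemoscreen import Track


# ---------------------------------------------------------------- oracles

def oracle_path_length(track: Track) -> float:
    total = 0.0
    for i in range(1, len(track)):
        dx = track.x[i] - track.x[i - 1]
        dy = track.y[i] - track.y[i - 1]
        total += math.sqrt(dx * dx + dy * dy)
    return total


def oracle_speed(track: Track) -> float:
    speeds = []
    for i in range(1, len(track)):
        dx = track.x[i] - track.x[i - 1]
        dy = track.y[i] - track.y[i - 1]
        speeds.append(math.sqrt(dx * dx + dy * dy) / track.dt)
    return sum(speeds) / len(speeds)


def oracle_directionality(track: Track) -> float:
    net = math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])
    return net / oracle_path_length(track)


def oracle_upward_directionality(track: Track) -> float:
    return (track.y[-1] - track.y[0]) / oracle_path_length(track)


def oracle_max_upward(track: Track) -> float:
    return max(track.y[i] - track.y[0] for i in range(len(track)))


# --------------------------------------------------------------- fixtures

def random_tracks(n: int, seed: int, n_points: int = 30, scale: float = 5.0,
                  dt: float = 0.5) -> list[Track]:
    """Unstructured random-walk tracks (not the simulator) for oracle tests."""
    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n):
        steps = rng.normal(0.0, scale, size=(n_points - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos += rng.uniform(-50, 50, size=2)
        tracks.append(Track(i, np.arange(n_points), pos[:, 0], pos[:, 1], dt))
    return tracks


@pytest.fixture
def hundred_random_tracks() -> list[Track]:
    return random_tracks(100, seed=42)


def make_track(points, dt: float = 0.5, track_id=0) -> Track:
    pts = np.asarray(points, dtype=float)
    return Track(track_id, np.arange(len(pts)), pts[:, 0], pts[:, 1], dt)


def well_separated_tracks(n_cells: int = 10, n_frames: int = 40,
                          spacing: float = 24.0, dt: float = 0.5) -> list[Track]:
    """Deterministic upward-migrating tracks guaranteed never to overlap."""
    tracks = []
    frames = np.arange(n_frames)
    for i in range(n_cells):
        x = 12.0 + spacing * i + 3.0 * np.sin(frames / 5.0 + i)
        y = 8.0 + 2.2 * frames + 0.3 * i
        tracks.append(Track(i, frames, x, y, dt))
    return tracks
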