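"""Track-based chemotaxis statistics.

Three per-track metrics summarise chemotactic behaviour in a +y gradient:

``speed``
    Mean over frames of the step length divided by the frame interval
    (μm/minute).
``directionality``
    Net (straight-line, first-to-last) displacement divided by total path
    length; 1 for perfectly straight migration, 0 for a closed loop.
``upward_directionality``
    Signed net displacement along +y divided by total path length, in
    [−1, 1]; positive values mean net migration up the gradient.

A conventional inclusion rule — the *migratory filter* — restricts ensemble
summaries to cells whose maximum displacement from the starting line exceeds
a threshold (default 65 μm), excluding cells that never leave the starting
region.  Tracks with zero path length have undefined directionality; the
metrics return NaN for them rather than 0, so non-motile cells do not bias
group means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Track

logger = logging.getLogger(__name__)

METRIC_NAMES = ["speed", "directionality", "upward_directionality"]


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int | str
    speed: float  # μm/minute
    directionality: float  # [0, 1], NaN if path length is 0
    upward_directionality: float  # [−1, 1], NaN if path length is 0
    is_migratory: bool
    path_length: float  # μm
    net_displacement: float  # μm


def _step_lengths(track: Track) -> np.ndarray:
    return np.hypot(np.diff(track.x), np.diff(track.y))


def path_length(track: Track) -> float:
    """Total migration length: sum of inter-frame step lengths, in μm."""
    return float(_step_lengths(track).sum())


def net_displacement(track: Track) -> float:
    """Straight-line distance from first to last position, in μm."""
    return float(math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))


def speed(track: Track) -> float:
    """Mean frame-to-frame speed in μm/minute; NaN for single-point tracks."""
    if len(track) < 2:
        logger.warning("track %s has <2 positions; speed undefined", track.track_id)
        return float("nan")
    return float(np.mean(_step_lengths(track) / track.dt))


def directionality(track: Track) -> float:
    """Net displacement over path length; NaN when the cell never moved."""
    total = path_length(track)
    if total == 0.0:
        logger.warning(
            "track %s has zero path length; directionality undefined",
            track.track_id,
        )
        return float("nan")
    return net_displacement(track) / total


def upward_directionality(track: Track) -> float:
    """Signed net Δy over path length; NaN when the cell never moved."""
    total = path_length(track)
    if total == 0.0:
        logger.warning(
            "track %s has zero path length; upward directionality undefined",
            track.track_id,
        )
        return float("nan")
    return float(track.y[-1] - track.y[0]) / total


def max_upward_excursion(track: Track) -> float:
    """Maximum displacement above the track's starting line, in μm."""
    return float(np.max(track.y - track.y[0]))


def migratory_filter(
    tracks: Iterable[Track], min_crossing: float = 65.0
) -> list[Track]:
    """Keep tracks that cross strictly more than ``min_crossing`` μm above
    their starting line at any point."""
    if min_crossing < 0:
        raise ValueError("min_crossing must be >= 0")
    return [t for t in tracks if max_upward_excursion(t) > min_crossing]


def compute_metrics(track: Track, min_crossing: float = 65.0) -> TrackMetrics:
    return TrackMetrics(
        track_id=track.track_id,
        speed=speed(track),
        directionality=directionality(track),
        upward_directionality=upward_directionality(track),
        is_migratory=max_upward_excursion(track) > min_crossing,
        path_length=path_length(track),
        net_displacement=net_displacement(track),
    )


def metrics_table(
    tracks: Iterable[Track], min_crossing: float = 65.0
) -> pd.DataFrame:
    """Per-track metrics as a DataFrame (one row per track)."""
    rows = [compute_metrics(t, min_crossing).__dict__ for t in tracks]
    columns = [
        "track_id", "speed", "directionality", "upward_directionality",
        "is_migratory", "path_length", "net_displacement",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def summarize_groups(
    groups: Mapping[str, Sequence[Track] | pd.DataFrame],
    control: str,
    min_crossing: float = 65.0,
    migratory_only: bool = True,
) -> pd.DataFrame:
    """Per-condition mean ± s.d. of each metric with a Welch t-test vs control.

    ``groups`` maps a condition label to either a sequence of tracks or a
    precomputed :func:`metrics_table`.  When ``migratory_only`` is set the
    summary uses only migratory tracks, mirroring the convention of reporting
    chemotaxis statistics for cells that actually enter the channel.

    Returns one row per (condition, metric) with columns
    ``condition, metric, mean, sd, n, t_stat, p_value, flagged``; conditions
    with fewer than two valid values are flagged and carry no test.
    """
    if control not in groups:
        raise ValueError(f"control condition {control!r} not in groups")

    tables: dict[str, pd.DataFrame] = {}
    for label, data in groups.items():
        table = data if isinstance(data, pd.DataFrame) else metrics_table(data, min_crossing)
        if migratory_only and "is_migratory" in table.columns:
            table = table[table["is_migratory"]]
        tables[label] = table

    rows = []
    for label, table in tables.items():
        for metric in METRIC_NAMES:
            values = table[metric].dropna().to_numpy() if metric in table else np.array([])
            ctrl = (
                tables[control][metric].dropna().to_numpy()
                if metric in tables[control]
                else np.array([])
            )
            flagged = values.size < 2
            t_stat = p_value = float("nan")
            if label != control and not flagged and ctrl.size >= 2:
                t_stat, p_value = stats.ttest_ind(values, ctrl, equal_var=False)
            rows.append(
                {
                    "condition": label,
                    "metric": metric,
                    "mean": float(values.mean()) if values.size else float("nan"),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
                    "n": int(values.size),
                    "t_stat": float(t_stat),
                    "p_value": float(p_value),
                    "flagged": bool(flagged),
                }
            )
    return pd.DataFrame(rows)
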