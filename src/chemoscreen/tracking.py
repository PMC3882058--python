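"""Cell detection and frame-to-frame track linking for time-lapse stacks.

Detection thresholds each frame (Otsu by default, or a fixed threshold for
reproducibility), labels connected components, filters them by area and
reports intensity-weighted centroids for sub-pixel accuracy.  Linking is a
deterministic greedy nearest-neighbour assignment between consecutive
frames: candidate pairs are taken in order of increasing distance, links
longer than ``max_disp`` are forbidden, and unmatched detections open new
tracks.  There is no gap closing and no merge/split handling — a cell that
drops out for a frame starts a new track — which suits sparse chemotaxis
channels and keeps the assignment unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import filters, measure

from .tracks import Track

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """One detected cell in one frame (pixel coordinates)."""

    frame_index: int
    x: float  # column, pixels
    y: float  # row, pixels
    area: float  # pixels²
    mean_intensity: float


def detect_cells(
    frame: np.ndarray,
    threshold: float | None = None,
    min_area: float = 1.0,
    max_area: float = float("inf"),
    frame_index: int = 0,
) -> list[Detection]:
    """Detect bright blobs in one frame.

    Pixels above ``threshold`` (Otsu's threshold when None) are labelled;
    connected components with area in [min_area, max_area] are reported by
    their intensity-weighted centroid, weighting each pixel by its intensity
    above the threshold.  A constant frame yields no detections and a logged
    warning.  Results are sorted by (x, y) so downstream linking is
    independent of the labelling order.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_cells expects a single 2-D frame")
    if frame.max() == frame.min():
        logger.warning("frame %d has constant intensity; no detections", frame_index)
        return []
    if threshold is None:
        threshold = float(filters.threshold_otsu(frame))
    mask = frame > threshold
    labels = measure.label(mask, connectivity=2)
    detections = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if not (min_area <= region.area <= max_area):
            continue
        coords = region.coords
        weights = frame[coords[:, 0], coords[:, 1]] - threshold
        total = weights.sum()
        if total <= 0:  # all pixels exactly at threshold; fall back to geometric
            cy, cx = region.centroid
        else:
            cy = float((coords[:, 0] * weights).sum() / total)
            cx = float((coords[:, 1] * weights).sum() / total)
        detections.append(
            Detection(
                frame_index=frame_index,
                x=cx,
                y=cy,
                area=float(region.area),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return sorted(detections, key=lambda d: (d.x, d.y))


def detect_stack(
    stack: np.ndarray,
    threshold: float | None = None,
    min_area: float = 1.0,
    max_area: float = float("inf"),
) -> list[list[Detection]]:
    """Per-frame detections for a (n_frames, h, w) stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("detect_stack expects a 3-D (frames, h, w) stack")
    return [
        detect_cells(stack[i], threshold, min_area, max_area, frame_index=i)
        for i in range(stack.shape[0])
    ]


def estimate_max_disp(detections: Sequence[Sequence[Detection]]) -> float:
    """Default linking gate: 5× the median nearest-neighbour displacement
    between consecutive frames (falls back to 10 px when unresolvable)."""
    nn_dists = []
    for prev, curr in zip(detections, detections[1:]):
        if not prev or not curr:
            continue
        p = np.array([[d.x, d.y] for d in prev])
        c = np.array([[d.x, d.y] for d in curr])
        dists = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
        nn_dists.extend(dists.min(axis=1))
    if not nn_dists:
        return 10.0
    return max(5.0 * float(np.median(nn_dists)), 1.0)


def link_tracks(
    detections: Sequence[Sequence[Detection]],
    max_disp: float | None = None,
    pixel_size: float = 1.0,
    dt: float = 0.5,
) -> tuple[list[Track], dict]:
    """Link per-frame detections into tracks.

    Frames must be in temporal order.  Between consecutive frames, candidate
    (track, detection) pairs are accepted greedily in order of increasing
    distance (ties broken by lowest track id, then detection order), with
    links longer than ``max_disp`` pixels forbidden; this yields the
    mutual-nearest-neighbour matching for well-separated cells.  Unmatched
    detections start new tracks.  Coordinates are converted to μm via
    ``pixel_size``.

    Returns ``(tracks, summary)`` where ``summary`` reports detection and
    fragmentation counts (``n_detections``, ``n_tracks``, ``n_links``,
    ``n_broken`` — track starts after frame 0, i.e. potential fragments).
    """
    if max_disp is None:
        max_disp = estimate_max_disp(detections)
    if not max_disp > 0:
        raise ValueError("max_disp must be > 0")

    # active[track_id] = list of (frame, x, y); position of last detection
    paths: dict[int, list[tuple[int, float, float]]] = {}
    active: dict[int, tuple[float, float]] = {}
    next_id = 0
    n_links = 0
    n_broken = 0

    for frame_i, unordered_dets in enumerate(detections):
        # canonical order makes linking invariant to detection order
        frame_dets = sorted(unordered_dets, key=lambda d: (d.x, d.y, d.area))
        assignments: dict[int, int] = {}  # det index -> track id
        if active and frame_dets:
            track_ids = sorted(active)
            candidates = []
            for ti, tid in enumerate(track_ids):
                tx, ty = active[tid]
                for di, det in enumerate(frame_dets):
                    dist = float(np.hypot(det.x - tx, det.y - ty))
                    if dist <= max_disp:
                        candidates.append((dist, tid, di))
            used_tracks: set[int] = set()
            used_dets: set[int] = set()
            for dist, tid, di in sorted(candidates):
                if tid in used_tracks or di in used_dets:
                    continue
                used_tracks.add(tid)
                used_dets.add(di)
                assignments[di] = tid
        # matched tracks extend; unmatched detections start new tracks
        new_active: dict[int, tuple[float, float]] = {}
        for di, det in enumerate(frame_dets):
            tid = assignments.get(di)
            if tid is None:
                tid = next_id
                next_id += 1
                paths[tid] = []
                if frame_i > 0:
                    n_broken += 1
            else:
                n_links += 1
            paths[tid].append((det.frame_index, det.x, det.y))
            new_active[tid] = (det.x, det.y)
        active = new_active

    tracks = []
    for tid in sorted(paths):
        pts = paths[tid]
        frames = np.array([p[0] for p in pts])
        xs = np.array([p[1] for p in pts]) * pixel_size
        ys = np.array([p[2] for p in pts]) * pixel_size
        tracks.append(Track(tid, frames, xs, ys, dt))
    summary = {
        "n_detections": sum(len(f) for f in detections),
        "n_tracks": len(tracks),
        "n_links": n_links,
        "n_broken": n_broken,
        "max_disp": float(max_disp),
    }
    return tracks, summary


def track_stack(
    stack: np.ndarray,
    threshold: float | None = None,
    min_area: float = 1.0,
    max_area: float = float("inf"),
    max_disp: float | None = None,
    pixel_size: float = 1.0,
    dt: float = 0.5,
) -> tuple[list[Track], dict]:
    """Detect and link in one call."""
    detections = detect_stack(stack, threshold, min_area, max_area)
    return link_tracks(detections, max_disp, pixel_size, dt)


def realign_tracks(tracks: Sequence[Track]) -> list[Track]:
    """Translate every track so it starts at the origin (0, 0).

    Inter-point displacements — and hence every chemotaxis metric — are
    unchanged; this is the conventional preparation for overlaid track
    ("rose") plots.
    """
    return [t.translated(-t.x[0], -t.y[0]) for t in tracks]
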