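"""Synthetic data generators: cell tracks, rendered image stacks, polarized
single-cell images, and screening-plate count tables.

These generators give every downstream stage (tracking, chemotaxis metrics,
polarity quantification, screen hit-calling) a ground-truth-bearing input
without any external data.  All of them are deterministic given their seed.

Motion model
------------
Cells follow a biased persistent random walk.  At each step the new heading
is the normalised sum of three unit vectors weighted by ``persistence``
(previous heading), ``bias * bias_factor`` (+y, the gradient direction) and
``1 - bias * bias_factor`` (an isotropic random direction); the step length
is gamma-distributed with mean ``step_scale * motility_factor``.  With
bias = 1 and persistence = 0 every step is purely +y; with bias = 0 the walk
is unbiased (persistent but symmetric).  The channel walls at x = 0 and
x = channel_width reflect.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CellImageSpec, ConfigurationError, PlateSpec, SimConfig
from .tracks import Track

VEHICLE_LABEL = "vehicle"

__all__ = [
    "simulate_tracks",
    "render_stack",
    "render_polarized_cell",
    "simulate_plate",
    "simulate_screen",
    "simulate_confirmation_plates",
    "VEHICLE_LABEL",
]


def _reflect(x: np.ndarray, width: float) -> np.ndarray:
    """Fold positions back into [0, width] as if the walls were mirrors."""
    period = 2.0 * width
    x = np.mod(x, period)
    return np.where(x > width, period - x, x)


def simulate_tracks(config: SimConfig) -> list[Track]:
    """Simulate ``config.n_cells`` tracks of ``config.n_frames`` positions.

    Cells start on the y = 0 line ("starting line") at uniformly random x in
    [0, channel_width] and execute the biased persistent random walk
    described in the module docstring.  Output is deterministic given
    ``config.seed``.
    """
    if not isinstance(config, SimConfig):
        raise ConfigurationError("simulate_tracks expects a SimConfig")
    rng = np.random.default_rng(config.seed)
    n = int(config.n_cells)
    n_steps = int(config.n_frames) - 1
    b = config.effective_bias
    mean_step = config.effective_step
    shape = config.step_shape

    x = rng.uniform(0.0, config.channel_width, size=n)
    y = np.zeros(n)
    theta0 = rng.uniform(0.0, 2.0 * math.pi, size=n)
    heading = np.column_stack([np.cos(theta0), np.sin(theta0)])

    xs = np.empty((n_steps + 1, n))
    ys = np.empty((n_steps + 1, n))
    xs[0], ys[0] = x, y

    up = np.array([0.0, 1.0])
    for k in range(n_steps):
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        rand_dir = np.column_stack([np.cos(phi), np.sin(phi)])
        v = (
            config.persistence * heading
            + b * up[None, :]
            + (1.0 - b) * rand_dir
        )
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        # vanishing resultant (measure zero): keep the random direction
        degenerate = norm[:, 0] < 1e-12
        if np.any(degenerate):
            v[degenerate] = rand_dir[degenerate]
            norm = np.linalg.norm(v, axis=1, keepdims=True)
        heading = v / norm

        if mean_step > 0:
            steps = rng.gamma(shape, mean_step / shape, size=n)
        else:
            steps = np.zeros(n)
        x = x + steps * heading[:, 0]
        y = y + steps * heading[:, 1]
        reflected = (x < 0.0) | (x > config.channel_width)
        x = _reflect(x, config.channel_width)
        heading[reflected, 0] *= -1.0
        xs[k + 1], ys[k + 1] = x, y

    return [
        Track(i, np.arange(n_steps + 1), xs[:, i], ys[:, i], config.dt)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _gaussian_blob(
    image: np.ndarray, cx: float, cy: float, sigma: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian of the given amplitude to ``image`` in place.

    ``image`` is indexed [row, col] with row = y (origin lower-left when
    displayed with origin='lower').  Only a ±4σ window is evaluated.
    """
    h, w = image.shape
    r0 = max(int(math.floor(cy - 4 * sigma)), 0)
    r1 = min(int(math.ceil(cy + 4 * sigma)) + 1, h)
    c0 = max(int(math.floor(cx - 4 * sigma)), 0)
    c1 = min(int(math.ceil(cx + 4 * sigma)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((cols - cx) ** 2 + (rows - cy) ** 2) / (2.0 * sigma**2)
    )


def render_stack(
    tracks: Sequence[Track],
    appearance: CellImageSpec | None = None,
    pixel_size: float = 1.0,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render tracks as a single-channel image stack with ground truth.

    Each cell becomes an isotropic Gaussian blob (sigma = radius / 2) at its
    μm position converted to pixels; frames share the stack's frame indexing.
    Returns ``(stack, truth)`` where ``stack`` has shape
    (n_frames, height, width) and ``truth`` lists the ground-truth pixel
    centroid of every cell in every frame
    (columns track_id, frame, x_px, y_px) for tracking-recovery tests.

    Raises
    ------
    ValueError
        If any cell falls outside the frame bounds; the message lists the
        offending track ids.
    """
    appearance = appearance or CellImageSpec()
    if not pixel_size > 0:
        raise ConfigurationError("pixel_size must be > 0")
    tracks = list(tracks)

    # span the full contiguous frame range so dropout frames render as
    # pure background rather than being silently skipped
    if tracks:
        all_frames = [int(f) for t in tracks for f in t.frames]
        frames = list(range(min(all_frames), max(all_frames) + 1))
    else:
        frames = [0]
    frame_index = {f: i for i, f in enumerate(frames)}

    margin = 3.0 * appearance.radius
    if shape is None:
        if tracks:
            max_x = max(float(t.x.max()) for t in tracks) / pixel_size
            max_y = max(float(t.y.max()) for t in tracks) / pixel_size
            min_x = min(float(t.x.min()) for t in tracks) / pixel_size
            min_y = min(float(t.y.min()) for t in tracks) / pixel_size
            if min_x < 0 or min_y < 0:
                raise ValueError(
                    "tracks extend below the origin; provide an explicit shape"
                )
            shape = (
                int(math.ceil(max_y + margin)) + 1,
                int(math.ceil(max_x + margin)) + 1,
            )
        else:
            shape = (64, 64)
    h, w = shape

    offenders = []
    for t in tracks:
        x_px = t.x / pixel_size
        y_px = t.y / pixel_size
        if np.any(x_px < 0) or np.any(x_px > w - 1) or np.any(y_px < 0) or np.any(y_px > h - 1):
            offenders.append(t.track_id)
    if offenders:
        raise ValueError(f"tracks outside frame bounds: {offenders}")

    rng = np.random.default_rng(seed)
    stack = np.full((len(frames), h, w), float(appearance.background))
    sigma = appearance.radius / 2.0
    amplitude = appearance.peak_intensity - appearance.background

    truth_rows = []
    for t in tracks:
        for f, xu, yu in zip(t.frames, t.x, t.y):
            cx = xu / pixel_size
            cy = yu / pixel_size
            _gaussian_blob(stack[frame_index[int(f)]], cx, cy, sigma, amplitude)
            truth_rows.append((t.track_id, int(f), cx, cy))

    if appearance.noise_sd > 0:
        stack += rng.normal(0.0, appearance.noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    truth = pd.DataFrame(truth_rows, columns=["track_id", "frame", "x_px", "y_px"])
    return stack, truth


def render_polarized_cell(
    spec: CellImageSpec,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[tuple[float, float], tuple[float, float]]]:
    """Render one cell with a front–back intensity asymmetry.

    The intensity is a Gaussian envelope (sigma = radius / 2) multiplied by a
    smooth logistic ramp along the orientation axis whose leading-to-trailing
    amplitude ratio is ``polarity_ratio`` (the logistic width is 8% of the
    radius, so the ramp saturates well inside the end sections of a
    transection line).  ``polarity_ratio = 1`` gives a symmetric cell.

    Returns ``(image, ground_truth_line)`` where the line runs from the
    trailing point ``center - radius * u`` to the leading point
    ``center + radius * u`` (``u`` the orientation unit vector), in (x, y)
    pixel coordinates — the transection a manual analysis would draw.
    """
    if shape is None:
        side = int(math.ceil(4 * spec.radius)) + 1
        shape = (side, side)
    h, w = shape
    if spec.center is None:
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    else:
        cx, cy = spec.center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("cell centre outside image")

    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)
    ux, uy = math.cos(spec.orientation), math.sin(spec.orientation)
    t = (cols - cx) * ux + (rows - cy) * uy  # along-axis coordinate
    r2 = (cols - cx) ** 2 + (rows - cy) ** 2
    sigma = spec.radius / 2.0
    envelope = np.exp(-r2 / (2.0 * sigma**2))

    p = spec.polarity_ratio
    if p == 1.0:
        asym = np.ones_like(t)
    else:
        tau = 0.08 * spec.radius
        asym = (1.0 + (p - 1.0) / (1.0 + np.exp(-t / tau))) / p

    amplitude = spec.peak_intensity - spec.background
    image = spec.background + amplitude * envelope * asym
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
        np.clip(image, 0.0, None, out=image)

    line = (
        (cx - spec.radius * ux, cy - spec.radius * uy),
        (cx + spec.radius * ux, cy + spec.radius * uy),
    )
    return image, line


# ---------------------------------------------------------------------------
# screening plates
# ---------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator, mean: float, size: int, dispersion: float
) -> np.ndarray:
    """Poisson counts, or negative binomial when dispersion > 1."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 1.0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = mean / (dispersion - 1.0)
    p = 1.0 / dispersion
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _well_name(index: int) -> str:
    return f"W{index + 1:04d}"


def simulate_plate(
    spec: PlateSpec, condition_labels: dict[int, str] | None = None
) -> pd.DataFrame:
    """Simulate per-larva recruitment counts for one plate.

    Returns a table with columns ``well, condition, replicate, count``: one
    row per larva, ``replicate`` numbering the larvae within a well.  Vehicle
    wells are labelled ``"vehicle"``; extract wells default to
    ``"extract_####"`` (override with ``condition_labels`` keyed by well
    index).  Inhibitor wells draw counts with mean
    ``control_mean * inhibitor_effect``; all others with mean
    ``control_mean``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, str, int, int]] = []
    vehicle = set(spec.vehicle_well_indices)
    for well in range(spec.n_wells):
        if well in vehicle:
            condition = VEHICLE_LABEL
        elif condition_labels and well in condition_labels:
            condition = condition_labels[well]
        else:
            condition = f"extract_{well - len(vehicle) + 1:04d}"
        mean = spec.control_mean
        if well in spec.inhibitor_wells:
            mean *= spec.inhibitor_effect
        counts = _draw_counts(rng, mean, spec.larvae_per_well, spec.dispersion)
        for rep, count in enumerate(counts, start=1):
            rows.append((_well_name(well), condition, rep, int(count)))
    return pd.DataFrame(rows, columns=["well", "condition", "replicate", "count"])


def simulate_screen(
    n_extracts: int = 1040,
    n_inhibitors: int = 2,
    inhibitor_effect: float = 0.0,
    control_mean: float = 10.0,
    larvae_per_well: int = 3,
    n_vehicle_wells: int = 8,
    dispersion: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a primary screen of ``n_extracts`` extract wells.

    A random subset of ``n_inhibitors`` extracts are true inhibitors with
    recruitment reduced to ``inhibitor_effect`` of control.  Returns the
    plate table and the ground-truth map ``condition -> effect multiplier``
    (1.0 for inert extracts).
    """
    rng = np.random.default_rng(seed)
    n_wells = n_extracts + n_vehicle_wells
    inhibitor_extracts = (
        rng.choice(n_extracts, size=n_inhibitors, replace=False)
        if n_inhibitors
        else np.array([], dtype=int)
    )
    inhibitor_wells = frozenset(int(i) + n_vehicle_wells for i in inhibitor_extracts)
    spec = PlateSpec(
        n_wells=n_wells,
        seed=int(rng.integers(0, 2**31 - 1)),
        control_mean=control_mean,
        larvae_per_well=larvae_per_well,
        inhibitor_wells=inhibitor_wells,
        inhibitor_effect=inhibitor_effect,
        n_vehicle_wells=n_vehicle_wells,
        dispersion=dispersion,
    )
    table = simulate_plate(spec)
    truth = {f"extract_{i + 1:04d}": 1.0 for i in range(n_extracts)}
    for well in inhibitor_wells:
        truth[f"extract_{well - n_vehicle_wells + 1:04d}"] = inhibitor_effect
    return table, truth


def simulate_confirmation_plates(
    conditions: Iterable[str],
    truth: dict[str, float],
    n_replicates: int = 3,
    control_mean: float = 10.0,
    larvae_per_well: int = 3,
    n_vehicle_wells: int = 4,
    dispersion: float = 1.0,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Simulate replicate plates re-testing candidate conditions.

    Each replicate plate carries every candidate in one well plus
    ``n_vehicle_wells`` vehicle wells; a candidate's counts follow its true
    effect from ``truth`` (inert if absent).
    """
    conditions = list(conditions)
    rng = np.random.default_rng(seed)
    plates = []
    for _ in range(n_replicates):
        n_wells = len(conditions) + n_vehicle_wells
        labels = {
            n_vehicle_wells + i: cond for i, cond in enumerate(conditions)
        }
        spec_seed = int(rng.integers(0, 2**31 - 1))
        plate_rng = np.random.default_rng(spec_seed)
        rows: list[tuple[str, str, int, int]] = []
        for well in range(n_wells):
            if well < n_vehicle_wells:
                condition = VEHICLE_LABEL
                mean = control_mean
            else:
                condition = labels[well]
                mean = control_mean * truth.get(condition, 1.0)
            counts = _draw_counts(plate_rng, mean, larvae_per_well, dispersion)
            for rep, count in enumerate(counts, start=1):
                rows.append((_well_name(well), condition, rep, int(count)))
        plates.append(
            pd.DataFrame(rows, columns=["well", "condition", "replicate", "count"])
        )
    return plates
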