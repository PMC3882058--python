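"""Fluorescence polarity quantification along a cell transection line.

A line is drawn through a cell from its trailing edge to its leading edge;
the per-pixel intensity profile along that line is split into a trailing
section (mean ``b``), a leading section (mean ``a``) and a reference section
(mean ``c``, by default the whole line), and the polarity index is

    index = |log10(a / b)| * (a + b) / c .

The index is 0 for a front–back-symmetric cell, grows with the leading-to-
trailing intensity ratio, is symmetric in (a, b) and invariant under a
global intensity rescaling (gain change).  Section boundaries are
configurable; because index *magnitudes* (not their ordering) depend on
them, every report carries the fractions used.

For Z-stacks the quantification operates on a maximum-intensity projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

DEFAULT_SECTION_FRACTIONS = (0.25, 0.25)

Point = tuple[float, float]
Line = tuple[Point, Point]


@dataclass(frozen=True)
class IntensityProfile:
    """Per-pixel intensities along a trailing→leading transection line."""

    values: np.ndarray
    pixel_size: float = 1.0
    section_fractions: tuple[float, float] = DEFAULT_SECTION_FRACTIONS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 4:
            raise ValueError("profile needs at least 4 pixels")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("profile values must be finite and >= 0")
        trailing, leading = self.section_fractions
        if not (0 < trailing <= 0.5 and 0 < leading <= 0.5):
            raise ValueError("section fractions must be in (0, 0.5]")
        if trailing + leading > 1.0:
            raise ValueError("section fractions must sum to <= 1")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PolarityResult:
    a: float  # leading-section mean
    b: float  # trailing-section mean
    c: float  # reference-section mean
    index: float  # |log10(a/b)| * (a+b)/c; NaN when undefined


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (n_slices, h, w) stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D stack")
    return stack.max(axis=0)


def extract_profile(
    image: np.ndarray,
    line: Line,
    pixel_size: float = 1.0,
    section_fractions: tuple[float, float] = DEFAULT_SECTION_FRACTIONS,
) -> IntensityProfile:
    """Sample the image along a trailing→leading segment.

    Intensities are bilinearly interpolated at ``round(length) + 1`` evenly
    spaced points (≈ unit pixel spacing, symmetric in the endpoints so that
    reversing the line exactly reverses the profile).  Both endpoints must
    lie inside the image and the line must span at least 4 sample points.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("extract_profile expects a 2-D image (project stacks first)")
    (x0, y0), (x1, y1) = line
    h, w = image.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"line endpoint ({x}, {y}) outside image")
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("zero-length line")
    n = int(round(length)) + 1
    if n < 4:
        raise ValueError("line too short: need >= 4 sample points")
    ts = np.linspace(0.0, 1.0, n)
    cols = x0 + ts * (x1 - x0)
    rows = y0 + ts * (y1 - y0)
    values = ndimage.map_coordinates(image, [rows, cols], order=1)
    return IntensityProfile(values, pixel_size, section_fractions)


def section_means(profile: IntensityProfile) -> tuple[float, float, float]:
    """Means (a, b, c) of the leading, trailing and reference sections.

    ``b`` averages the first ``trailing_frac`` of the profile, ``a`` the last
    ``leading_frac``, ``c`` the whole line.
    """
    values = profile.values
    n = len(values)
    trailing_frac, leading_frac = profile.section_fractions
    n_b = int(round(trailing_frac * n))
    n_a = int(round(leading_frac * n))
    if n_b < 1 or n_a < 1:
        raise ValueError(
            "section fractions round to empty sections; draw a longer line"
        )
    b = float(values[:n_b].mean())
    a = float(values[-n_a:].mean())
    c = float(values.mean())
    return a, b, c


def polarity_index(a: float, b: float, c: float, floor: float | None = None) -> float:
    """``|log10(a/b)| * (a + b) / c``.

    Undefined (NaN, with a logged warning) when any input is non-positive —
    e.g. a background-subtracted section averaging 0 — unless ``floor`` is
    given, in which case a and b are clamped up to ``floor`` first.  Clamping
    inflates indices near the floor, so it is off by default.
    """
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be > 0")
        a, b = max(a, floor), max(b, floor)
    if a <= 0 or b <= 0 or c <= 0:
        logger.warning(
            "polarity index undefined for a=%g, b=%g, c=%g", a, b, c
        )
        return float("nan")
    return abs(math.log10(a / b)) * (a + b) / c


def measure_cell(
    image: np.ndarray,
    line: Line,
    section_fractions: tuple[float, float] = DEFAULT_SECTION_FRACTIONS,
    floor: float | None = None,
) -> PolarityResult:
    """Extract the profile, take section means and compute the index."""
    profile = extract_profile(image, line, section_fractions=section_fractions)
    a, b, c = section_means(profile)
    return PolarityResult(a, b, c, polarity_index(a, b, c, floor=floor))


def polarity_pipeline(
    cells: Iterable[tuple[str, np.ndarray, Line, str]],
    control: str,
    section_fractions: tuple[float, float] = DEFAULT_SECTION_FRACTIONS,
    alpha: float = 0.05,
    floor: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell polarity indices plus a group comparison against a control.

    ``cells`` yields ``(cell_id, image, line, condition)``; 3-D images are
    max-projected first.  Returns ``(per_cell, summary)``:

    * ``per_cell``: columns ``cell_id, a, b, c, index, condition,
      trailing_frac, leading_frac``.
    * ``summary``: per-condition mean/sd/n with the one-way ANOVA p-value
      across all conditions and, for non-control conditions, the
      Dunnett-adjusted p-value of the many-to-one comparison against the
      control, plus a ``reduced`` flag (mean below control and adjusted
      p ≤ alpha).

    Conditions in which every index is missing are excluded from the
    comparison with a warning.
    """
    trailing_frac, leading_frac = section_fractions
    rows = []
    for cell_id, image, line, condition in cells:
        result = measure_cell(
            max_project(image), line, section_fractions, floor=floor
        )
        rows.append(
            {
                "cell_id": cell_id,
                "a": result.a,
                "b": result.b,
                "c": result.c,
                "index": result.index,
                "condition": condition,
                "trailing_frac": trailing_frac,
                "leading_frac": leading_frac,
            }
        )
    per_cell = pd.DataFrame(rows)
    if per_cell.empty:
        raise ValueError("no cells supplied")
    if control not in set(per_cell["condition"]):
        raise ValueError(f"control condition {control!r} not present")

    groups: dict[str, np.ndarray] = {}
    for condition, grp in per_cell.groupby("condition", sort=False):
        values = grp["index"].dropna().to_numpy()
        if values.size == 0:
            logger.warning("condition %r has no defined indices; excluded", condition)
            continue
        groups[condition] = values
    if control not in groups:
        raise ValueError("control condition has no defined indices")

    others = [cond for cond in groups if cond != control]
    anova_p = float("nan")
    dunnett_p: dict[str, float] = {}
    if others and all(groups[c].size >= 2 for c in groups):
        anova_p = float(stats.f_oneway(*(groups[c] for c in groups)).pvalue)
        # fixed rng: Dunnett's randomised quadrature must be reproducible
        res = stats.dunnett(
            *(groups[c] for c in others), control=groups[control], rng=0
        )
        dunnett_p = dict(zip(others, (float(p) for p in res.pvalue)))

    control_mean = float(groups[control].mean())
    summary_rows = []
    for condition, values in groups.items():
        p_adj = dunnett_p.get(condition, float("nan"))
        summary_rows.append(
            {
                "condition": condition,
                "mean_index": float(values.mean()),
                "sd_index": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
                "n": int(values.size),
                "anova_p": anova_p,
                "p_adj": p_adj,
                "reduced": bool(
                    condition != control
                    and values.mean() < control_mean
                    and p_adj <= alpha
                ),
                "trailing_frac": trailing_frac,
                "leading_frac": leading_frac,
            }
        )
    return per_cell, pd.DataFrame(summary_rows)
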