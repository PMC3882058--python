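"""Configuration types for the synthetic-data generators.

All simulated quantities carry explicit units: track coordinates in
micrometres with a frame interval ``dt`` in minutes, images in pixels with an
explicit ``pixel_size`` (μm/pixel).  The coordinate convention throughout the
package is origin at the lower-left with +y pointing toward the
chemoattractant source ("upward").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigurationError(message)


def _finite(*values: float) -> bool:
    return all(math.isfinite(float(v)) for v in values)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the biased persistent random-walk track generator.

    The defaults mirror a chemotaxis-chamber assay in which migration down a
    260-μm-wide channel is imaged every 30 seconds for 20 minutes (40 frames,
    ``dt`` = 0.5 min).  ``bias`` weights each step toward +y (the gradient
    direction), ``persistence`` weights it toward the previous heading, and
    the remainder is an isotropic random component.  Drug treatment is
    emulated multiplicatively: ``motility_factor`` scales the step length and
    ``bias_factor`` scales the gradient bias.

    Parameters
    ----------
    seed
        Seed for the generator; identical configs (including seed) reproduce
        identical tracks bit-for-bit.
    n_cells
        Number of tracks to simulate.
    n_frames
        Positions per track (≥ 2).
    dt
        Frame interval in minutes (> 0).
    step_scale
        Mean step length in μm per frame for untreated cells.  The default,
        5 μm per 0.5-min frame (10 μm/min), is an illustrative value typical
        of neutrophil chemotaxis, not a fitted one.
    bias
        Weight of the +y gradient pull, in [0, 1].  1 with persistence 0
        gives purely upward steps; 0 gives an unbiased walk.
    persistence
        Weight of the previous heading, in [0, 1).
    channel_width
        Lateral extent of the channel in μm; walls at x = 0 and
        x = channel_width reflect.
    motility_factor, bias_factor
        Drug-effect multipliers in [0, 1] applied to ``step_scale`` and
        ``bias`` respectively.
    step_shape
        Shape parameter of the gamma-distributed step length (mean fixed at
        ``step_scale * motility_factor``); larger values give more uniform
        steps.
    """

    seed: int
    n_cells: int
    n_frames: int = 40
    dt: float = 0.5
    step_scale: float = 5.0
    bias: float = 0.8
    persistence: float = 0.5
    channel_width: float = 260.0
    motility_factor: float = 1.0
    bias_factor: float = 1.0
    step_shape: float = 4.0

    def __post_init__(self) -> None:
        _require(
            _finite(
                self.dt, self.step_scale, self.bias, self.persistence,
                self.channel_width, self.motility_factor, self.bias_factor,
                self.step_shape,
            ),
            "SimConfig parameters must be finite",
        )
        _require(int(self.n_cells) >= 0, "n_cells must be >= 0")
        _require(int(self.n_frames) >= 2, "n_frames must be >= 2")
        _require(self.dt > 0, "dt must be > 0")
        _require(self.step_scale >= 0, "step_scale must be >= 0")
        _require(0.0 <= self.bias <= 1.0, "bias must be in [0, 1]")
        _require(0.0 <= self.persistence < 1.0, "persistence must be in [0, 1)")
        _require(self.channel_width > 0, "channel_width must be > 0")
        _require(
            0.0 <= self.motility_factor <= 1.0,
            "motility_factor must be in [0, 1]",
        )
        _require(0.0 <= self.bias_factor <= 1.0, "bias_factor must be in [0, 1]")
        _require(self.step_shape > 0, "step_shape must be > 0")

    @property
    def effective_bias(self) -> float:
        return self.bias * self.bias_factor

    @property
    def effective_step(self) -> float:
        return self.step_scale * self.motility_factor


@dataclass(frozen=True)
class CellImageSpec:
    """Appearance of one rendered cell: an isotropic Gaussian blob, optionally
    with a smooth front–back intensity asymmetry.

    ``polarity_ratio`` is the leading-to-trailing amplitude ratio along the
    orientation axis; 1 encodes a round, unpolarized cell.  Reversed polarity
    is expressed by rotating ``orientation`` by π, never by a ratio < 1.
    """

    center: tuple[float, float] | None = None  # (x, y) pixels; None = image centre
    radius: float = 8.0  # pixels; Gaussian sigma is radius / 2
    peak_intensity: float = 100.0
    polarity_ratio: float = 1.0
    orientation: float = math.pi / 2  # radians; leading edge direction
    background: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        _require(
            _finite(self.radius, self.peak_intensity, self.polarity_ratio,
                    self.orientation, self.background, self.noise_sd),
            "CellImageSpec parameters must be finite",
        )
        _require(self.radius > 0, "radius must be > 0")
        _require(self.background >= 0, "background must be >= 0")
        _require(
            self.peak_intensity > self.background,
            "peak_intensity must exceed background",
        )
        _require(
            self.polarity_ratio >= 1.0,
            "polarity_ratio must be >= 1; encode reversed polarity by "
            "rotating orientation by pi",
        )
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")


@dataclass(frozen=True)
class PlateSpec:
    """Layout and count statistics of one synthetic screening plate.

    Wells are indexed 0..n_wells-1; the first ``n_vehicle_wells`` are
    vehicle controls, the rest carry extracts.  Each well holds
    ``larvae_per_well`` larvae and each larva contributes one recruitment
    count drawn from a Poisson distribution with mean ``control_mean`` (inert
    wells) or ``control_mean * inhibitor_effect`` (inhibitor wells).
    ``dispersion`` > 1 switches to a negative binomial with variance
    ``dispersion * mean``.
    """

    n_wells: int
    seed: int = 0
    control_mean: float = 10.0
    larvae_per_well: int = 3
    inhibitor_wells: frozenset[int] = field(default_factory=frozenset)
    inhibitor_effect: float = 0.0
    n_vehicle_wells: int = 8
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        _require(int(self.n_wells) >= 0, "n_wells must be >= 0")
        _require(self.control_mean > 0, "control_mean must be > 0")
        _require(int(self.larvae_per_well) >= 1, "larvae_per_well must be >= 1")
        _require(
            0.0 <= self.inhibitor_effect <= 1.0,
            "inhibitor_effect must be in [0, 1]",
        )
        _require(int(self.n_vehicle_wells) >= 0, "n_vehicle_wells must be >= 0")
        _require(self.dispersion >= 1.0, "dispersion must be >= 1")
        wells = frozenset(int(w) for w in self.inhibitor_wells)
        n_vehicle = min(int(self.n_vehicle_wells), int(self.n_wells))
        extract_wells = range(n_vehicle, int(self.n_wells))
        _require(
            wells <= set(extract_wells),
            "inhibitor_wells must be extract wells "
            f"(indices {n_vehicle}..{self.n_wells - 1})",
        )
        object.__setattr__(self, "inhibitor_wells", wells)

    @property
    def vehicle_well_indices(self) -> range:
        return range(min(self.n_vehicle_wells, self.n_wells))

    @property
    def extract_well_indices(self) -> range:
        return range(min(self.n_vehicle_wells, self.n_wells), self.n_wells)
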