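# Methods

This note records the models, parameter choices and numerical conventions
behind `chemoscreen`, and what the synthetic-data validation does and does
not demonstrate about real imaging data.

## Coordinate and unit conventions

Tracks are stored in μm with the frame interval `dt` in minutes; images are
pixel arrays with an explicit `pixel_size` (μm/pixel) and are indexed
`[row, col]` with row = y, so that displaying with `origin='lower'` puts
the origin at the lower left. Throughout the package +y is the direction of
the chemoattractant gradient ("upward"). Conversions between μm and pixels
are always explicit arguments, never implicit.

## Track simulator: biased persistent random walk

The generator emulates cells migrating up a gradient in a laterally
confined channel, imaged every 30 s for 20 min (40 frames, `dt` = 0.5 min)
in a 260-μm-wide chamber. No published motility parameters exist for this
preparation, so the walk model is phenomenological and its defaults are
illustrative, not fitted:

* **Heading.** The new heading is the normalised sum of three unit
  vectors: the previous heading weighted by `persistence` (default 0.5),
  +y weighted by `b = bias · bias_factor` (default bias 0.8), and an
  isotropic random direction weighted by `1 − b`. This makes the two
  boundary cases exact: `bias = 1, persistence = 0` gives purely upward
  steps, and `bias = 0` gives a (persistent but) symmetric walk with zero
  mean upward directionality. Mean upward drift is monotone in `bias`.
* **Step length.** Gamma-distributed with shape 4 (coefficient of
  variation 0.5) and mean `step_scale · motility_factor`; the default
  `step_scale` of 5 μm/frame corresponds to 10 μm/min, a typical
  neutrophil chemotaxis speed. `motility_factor = 0` freezes cells in
  place.
* **Drug effects** are multiplicative: `motility_factor` scales step
  length and `bias_factor` scales the gradient pull, reproducing the
  qualitative treated-cell phenotype (slow, undirected, rarely passing the
  migratory filter).
* **Boundaries.** The walls at x = 0 and x = `channel_width` reflect both
  the position and the lateral component of the heading. Cells start on
  the y = 0 line at uniformly random x.

All draws come from one `numpy` Generator seeded by `SimConfig.seed`, so
identical configs are bit-reproducible.

## Image rendering

Cells are rendered as isotropic Gaussian blobs with σ = radius/2 on a
constant background, with optional additive Gaussian noise (clipped at 0).
`render_stack` spans the full contiguous frame range of its input tracks,
so a simulated detection dropout leaves an empty frame rather than a
silently skipped one, and returns the ground-truth pixel centroids as a
sidecar table.

A polarized cell multiplies the same Gaussian envelope by a logistic ramp
along the orientation axis whose leading/trailing amplitude ratio is
`polarity_ratio`; the logistic width is 8% of the radius, so the ramp
saturates well inside the outer quarters of the cell and the ratio of
leading- to trailing-section means along the transection line reproduces
`polarity_ratio` to within a few percent. The generator's ground-truth line
runs from `center − radius·u` to `center + radius·u` (u the orientation
unit vector), i.e. trailing → leading, matching the manual convention.
Reversed polarity is encoded by rotating the orientation by π; ratios < 1
are rejected to keep the parameterisation unambiguous.

## Tracking

Detection thresholds each frame (per-frame Otsu by default; a fixed
threshold is available and preferable for reproducibility on synthetic
data), labels 8-connected components, filters by area, and reports
centroids weighted by intensity above threshold — the weighting is what
delivers sub-pixel (< 1 px) accuracy on rendered blobs. Constant frames
yield no detections and a logged warning.

Linking is greedy: candidate (track, detection) pairs between consecutive
frames are accepted in order of increasing distance, with ties broken by
track id and detection order, and links longer than `max_disp` (default
5× the median per-frame nearest-neighbour displacement) forbidden. For
well-separated cells this equals the mutual-nearest-neighbour matching.
Detections are sorted canonically (by x, then y) before assignment, so the
result is invariant to detection order. There is **no gap closing and no
merge/split handling**: a cell that disappears for one frame starts a new
track. This is documented, deliberate behaviour suited to sparse channels;
fragmentation counts are reported in the link summary.

`realign_tracks` translates each track to start at the origin. Every
chemotaxis metric is translation-invariant, so realignment is purely for
overlay ("rose") plots.

## Chemotaxis metrics

Definitions are as in the README. Numerical conventions:

* A track with zero path length has *undefined* directionality and upward
  directionality, reported as NaN (never 0): a non-motile cell has no
  direction, and coding it as 0 would bias group means toward zero.
  Single-point tracks likewise have undefined speed.
* "Straight-line distance migrated in the upward direction" is the signed
  net Δy, not an unsigned projection — upward directionality must reach −1
  for a cell migrating straight down the gradient.
* The migratory filter keeps tracks whose *maximum* excursion above their
  starting line strictly exceeds the threshold (default 65 μm), so a cell
  that advances and retreats still counts as migratory.
* Group summaries compare each condition to a designated control with
  Welch's unequal-variance t-test. The equal-variance Student test is the
  textbook default for such comparisons, but Welch is the more robust
  choice when treatment changes the variance (it usually does), and the
  two coincide as variances equalise. Summaries use migratory tracks only
  by default — matching how chamber assays are conventionally reported —
  but the API computes metrics for any track, and filtering is explicit.

## Polarity index

Profiles are sampled by bilinear interpolation at `round(length) + 1`
evenly spaced points along the user-supplied line (≈ 1 px spacing; the
symmetric sampling makes reversing the line exactly reverse the profile).
The trailing section mean b averages the first `trailing_frac` of samples,
the leading mean a the last `leading_frac`, and the reference mean c the
whole line.

The section geometry is a genuine free choice: published figures that use
an index of this form do not fix the boundaries precisely, and the index
*magnitude* (though not the ordering of conditions) depends on them. The
defaults are trailing_frac = leading_frac = 0.25 with c = the whole-line
mean; every per-cell table and group summary therefore carries the
fractions used.

If a or b is non-positive (possible after background subtraction) the
index is undefined and reported as NaN; an optional positive `floor`
clamps a and b instead, but is off by default because clamping inflates
indices near the floor. Z-stacks are reduced by maximum-intensity
projection before measurement — a simplification that discards axial
polarity. Line placement is the user's responsibility (on synthetic cells
the generator's ground-truth line is used); there is no automatic
leading-edge detection, mirroring the manual line-drawing procedure the
assay uses in practice.

Group comparison across conditions uses one-way ANOVA followed by
Dunnett's many-to-one test against the control. Dunnett's p-values are
computed by randomised quadrature of a multivariate t distribution, so the
implementation pins that quadrature's internal seed to keep results
bit-reproducible.

## Screen pipeline

The plate generator draws one count per larva (default 3 larvae/well) from
a Poisson distribution with mean 10 for inert wells — the typical number of
neutrophils recruited to a tailfin wound in a control larva — scaled by
`inhibitor_effect` for planted inhibitors; a negative-binomial option
(`dispersion` > 1) models over-dispersed plates. Default screens carry
1040 extracts plus 8 vehicle wells; confirmation plates re-test candidates
alongside 4 vehicle wells each.

The primary rule calls a candidate when its mean count is ≤ 30% of the
vehicle mean with at least 3 scored larvae. The 0.3 threshold encodes a
"near-complete block" phenotype — a full inhibitor passes with wide margin
while Poisson flukes at a control mean of 10 are rare (a well of 3 larvae
must total ≤ 9 against a Poisson(30) sum, probability ≈ 7×10⁻⁶) — and it
is configurable and echoed in every report. Confirmation requires the
fraction-of-control to be ≤ threshold on *every* replicate plate, plus a
significant one-way ANOVA and a Dunnett-adjusted p ≤ α (default 0.05)
against pooled vehicle counts. Candidates appearing on fewer than two
replicates stay "unresolved". α ≤ 0 confirms nothing by definition (a
p-value can underflow to exactly 0, so `p ≤ 0` is not left to float
comparison).

With these defaults the funnel is sharply powered: simulated screens with
two planted full inhibitors confirm exactly the planted pair in ≈100% of
runs, while screens with no planted inhibitors confirm essentially nothing
(the primary stage alone admits ~0.007 false candidates per 1040-well
screen in expectation). Both properties are recomputed by
`scripts/acceptance.py` at run time.

## What the synthetic validation does and does not show

Passing tests demonstrate that the *computations* are correct — metrics
match independent brute-force oracles to 1e-9, the tracker recovers
rendered ground truth to sub-pixel accuracy, simulated gradient bias is
recoverable from track ensembles, the polarity index behaves as its
algebra requires, and the screen funnel has the designed power and error
control *under the generative models above*. The generators deliberately
omit features of real data: uneven illumination and photobleaching,
touching and dividing cells, non-Gaussian cell shapes, motion blur,
drift, larva-to-larva variability beyond Poisson noise, and toxicity
(modelled only as missing counts). Performance on real images and plates
therefore depends on how far those assumptions hold, and thresholds
(detection, `max_disp`, the 0.3 screen threshold) should be reviewed per
dataset.

## Problem sizes used in the validation suite

Oracle and bound checks use 100–1000 random tracks; tracking recovery uses
10 non-overlapping cells over 40 frames; bias recovery uses 4 bias levels
× 200 tracks; polarity monotonicity uses 4 ratio levels × 20 cells; screen
power uses 100 simulated 1040-extract screens and the null calibration 200
— sizes chosen so each property is measured with comfortable statistical
margin while the whole suite runs in seconds.
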