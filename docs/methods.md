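# Methods

## Substrate model

A substrate is a height map *h(x, y)* in μm on an isotropic grid
(default 1 μm/px — a trail of width 9–11 μm then spans ≥ 9 px; finer
grids are configurable).  Height 0 is the pristine reference plane;
resorption only removes material, so the final map never exceeds the
pristine map anywhere.  The substrate is treated as semi-infinite: the
deepest simulated excavation (≤ 68 μm) is far less than the ~300 μm
thickness of a real cut slice, so the slice bottom is never modelled.

Roughness is synthesized as a Gaussian random field smoothed with an
isotropic Gaussian kernel (correlation length default 20 μm — published
profilometry reports amplitudes, not spatial correlation, so this is a
free parameter) and scaled so the row-wise mean *R*<sub>a</sub> matches
the preset target exactly; rows play the role of profilometer line scans
(several hundred μm long).  *R*<sub>q</sub> is emergent, because a single
amplitude cannot pin both moments of the same field, and always satisfies
*R*<sub>q</sub> ≥ *R*<sub>a</sub>.  The measured-condition targets are:

| condition     | R<sub>a</sub> (μm) | R<sub>q</sub> (μm) | events/cm² | adhesion (cells/cm²) |
|---------------|------|-------|-------|--------|
| bone rough    | 6.27 | 7.71  | 449   | 11,400 |
| bone smooth   | 1.05 | 2.27  | 359*  | 11,400 |
| dentin rough  | 15.14| 18.51 | 3,134 | 17,200 |
| dentin smooth | 3.75 | 5.21  | 2,507*| 17,200 |

\* smooth-surface event densities were not published separately (the
rough/smooth difference was reported as a non-significant trend toward
rough); smooth presets use 0.8 × the rough intensity as a stated
assumption.

## Event model

Events arrive as a homogeneous Poisson process with the published
observed intensity, positions uniform, each event independently a trail
with probability 0.5 (the trail:pit ratio is unpublished; analyses that
constrain the presets pooled pits and trails).

**Geometry.** Each event draws an overall (length, width) pair from a
bivariate log-normal law: log-dimensions Gaussian with correlation ρ,
draws swapped so length ≥ width.  Marginal coefficients of variation are
fixed at 0.6 (only means ± SEM were published; 0.6 reproduces the long
length tail beyond 300 μm seen in measured histograms).  Pit footprints
are ellipses with axes (L, W), area (π/4)·L·W; trail footprints are
stadium-like bands of width W and overall length L, area
(L−W)·W + (π/4)·W².  `calibrate_geometry` fits the log-scale locations
and ρ so that the Monte-Carlo pooled mixture matches the three published
moments (mean area, mean length, mean width) within 2 %; because the
published mean area exceeds shape-factor × L̄ × W̄, a positive
length–width correlation is required (ρ ≈ 0.9 for bone targets
580/53/9.5, ρ ≈ 0.7 for dentin 700/59/11).  Infeasible target triples
raise a calibration error.

**Depth.** Each donor has a depth plateau *D*<sub>max</sub> (defaults
from the published per-donor plateaus: 35/55/68 μm and 32/59/62 μm in two
experiments; cohort emulation draws donors uniformly over 32–68 μm).  A
per-event depth request follows a saturating depth–area law

> d = D<sub>max</sub> · (1 − exp(−A/A₀)) · η,  clamped to [1 μm, D<sub>max</sub>]

with A₀ = 150 μm² and log-normal noise η (cv 0.08).  Small events are
shallow; large events resorb to the plateau and then grow only in area,
which is the observed depth/area relationship and what the
`plateau_depth` estimator exploits (mean maximum depth of the
top-quartile-area events).  An area-independent depth law cannot
produce that saturation, which is why this form was chosen.

**Pits** are excavated as vertical-walled elliptical cavities lowered to
the (clamped) depth below the *local pristine* surface, so substrate
roughness does not leak into excavation depth.

**Trails** are sequences of cycles.  Cycle *i* excavates a band of width
W and horizontal extent *s*<sub>i</sub> ∈ [3, 21] μm (the mechanistic
bound from crescent sealing-ring geometry) down to the target depth,
with a rounded cap behind the first front and a linear ramp of extent
*s*<sub>i</sub> descending ahead of the new front; the front then
advances by *s*<sub>i</sub>.  The next cycle's band replaces the previous
ramp, leaving a continuous full-depth floor — an isolated cycle on flat
ground removes 1.5 · s · w · d of material (declared ramp shape factor
1.5).  Steps are drawn uniformly on [3, 21] μm with the last step solved
so the footprint spans the drawn event length.  Headings follow a
persistent random walk with wrapped-normal increments, default sd 2°:
micrographs show trails as nearly straight longitudinal traces, and
because the quantifier reads width from a bounding rectangle it cannot
distinguish centreline wander from sealing-ring width — a larger default
would silently inflate every measured trail width, so the default keeps
wander well below one ring width over a typical trail.  Overlapping
excavations combine by pointwise minimum height (deepest wins).

All randomness flows through one numpy generator per replicate; runs are
bit-reproducible from their seed.

## Quantification

Detection operates on excavation = pristine − final (never on absolute
height, so roughness cannot create false events): pixels deeper than a
threshold (default 0.5 μm — above any numerical texture, far below the
≥ 1 μm event depths) are resorbed; 8-connected components (4-connected
switchable) above a minimum area (default 20 μm²) are "resorption
events", matching the operational definition of an area of resorption
surrounded by unresorbed margin.  Fused excavations are therefore single
events, as in manual analysis.

Per event: area = pixel count × px²; length/width = longer/shorter side
of the minimum-area rotated bounding rectangle of the pixel centres
(rotating calipers on the convex hull); maximum depth; quantized depth =
z-step × ⌈depth / z-step⌉ (the confocal slice-counting rule, default
z-step 1 μm); volume = summed excavation × px²; centroid; an edge flag
for events touching the map border (included in summaries by default, as
in whole-slice imaging).  Pixel-centre calipers are nearly unbiased for
elongated footprints, read compact axis-aligned shapes up to one pixel
short, and can tilt a few pixels off the true axes of near-circular
components where the area objective is flat; no constant pixel padding
can remove all three effects at once, so none is applied.

Summaries report resorbed-area %, events/cm², and mean ± SEM of the
per-event morphometrics; cohort aggregation averages per-donor summaries
(mean of per-donor means, SEM across donors), treating the donor as the
experimental unit.  Comparative statistics use Welch's unequal-variance
t-test (donor variances differ visibly between conditions; Student's
form is available through scipy directly).  Dimension histograms use the
fixed published binning — fourteen length bins (0–20 … 270–300, 300–330,
open tail; the published overlapping "300–330, >300" pair is resolved as
[300, 330) and [330, ∞)) and eleven width bins (0–5 … 60–70, with an
open final bin standing in for the published 70–80 μm terminal bin);
bins are half-open with edge values assigned upward.

## What the synthetic data does and does not emulate

Emulated: Poisson event placement at published intensities, pooled
pit/trail geometry matching published moments, substrate roughness at
published R<sub>a</sub>, donor depth plateaus with inter-donor spread,
event fusion at realistic coverage, and the 16-donor cohort structure.

Not emulated: spatial interaction between cells (trails neither attract
nor avoid existing excavations), within-donor temporal dynamics, real
optical artefacts of reflected-light or confocal imaging, and any
biological driver of donor variability.  Consequently, passing round
trips validate the *measurement pipeline* against a known generative
model — they do not validate the generative model against biology.

One structural consequence is worth stating explicitly: at the published
dentin event density (3,134 events/cm², ≈ 2 % coverage) about 7 % of
simulated events fuse into connected complexes.  Fusion lowers the
recovered event density by the same amount and, more visibly, inflates
the pooled mean *width*, because the bounding-rectangle width of two
crossing trails (tens of μm) is far larger than any single ring width.
The pooled dentin width read-out therefore sits ~15 % above the
published 11 μm even though single-event widths are recovered to within
a few per cent.  The published width was itself measured after fusion on
real dentin at even higher coverage, so a latent per-event law
calibrated to the published moment and then pushed through fusion again
necessarily over-reads this one statistic; we report it as computed
rather than re-calibrating the generator around it.

## Problem sizes and numerical choices

The acceptance computation pools 56 rough-bone replicates of 0.1 cm² and
64 rough-dentin replicates of 0.025 cm² at 1 μm/px (≈ 2,500 and ≈ 4,700
events), sizes chosen so Monte-Carlo error on the heavy-tailed mean-area
read-out is ≈ 2–3 %; the depth plateau uses three 0.04 cm² replicates of
the donor-1 profile (≈ 350 events).  Per-replicate seeds derive from
numpy `SeedSequence` spawning of the master seed.  Degenerate inputs are
validated eagerly (non-positive dimensions, empty profiles, events fully
outside the map → warning no-op, empty labels, too few events for
plateau or t-test estimation).  Geometry calibration iterates on common
random numbers (10⁵ draws) and verifies on an independent draw; ties in
the minimum-area rectangle resolve to the first optimal hull-edge angle.

## Known limitations

* The pooled dentin width over-read described above (t-statistic level,
  not per event).
* Minimum-area rectangles on rasterized near-circular components carry a
  few-pixel axis ambiguity; length/width are meaningful for elongated
  traces.
* Published resorbed-area percentages (0.6 % / 6.7 %) are mutually
  inconsistent with the published event densities and mean sizes
  (449 × 580 μm² ⇒ 0.26 %), so presets reproduce counts and per-event
  geometry; resorbed-% enters comparisons only through the published
  fold ratio.
* Trail turning statistics, trail:pit ratio, per-event dimension
  variances and the roughness correlation length are free parameters
  with stated defaults; none is constrained by published values.
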