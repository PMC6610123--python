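# Methods

## Measurement geometry

The unit of measurement is a ten-landmark annotation of one egg image: poles
`L1`/`L2`, the endpoints of the `q2` chord (`M1`/`M2`), the endpoints of the
`q1` and `q3` chords, and an optional scale-bar pair with its printed length
in mm. Raw quantities are the straight length `|L1 L2|`, the three chord
lengths, and the curvature fit; derived traits follow the definitions in the
README.

**Angle of curvature.** Two readings of "the angle formed by the length-axis
endpoints and the q2 midpoint" are possible: the vertex angle at the
midpoint, or the central angle of the circumscribed arc. We use the central
angle, because it assigns 0° to a straight egg (the vertex reading would
assign 180°) and grows monotonically with visible bending. The arc is the
circumcircle of the three points, solved in closed form from the
perpendicular bisectors; the central angle is the angle subtended by the arc
that passes through the q2 midpoint, which may exceed 180° for extreme
configurations. Curved length is `radius × angle`. Angles are stored in
degrees and converted exactly (π/180) to radians for final output.

**Collinearity.** Three points are treated as collinear when twice the
triangle area is below 1e−9 of the squared point span. This avoids fitting
astronomically large circles to straight eggs; a collinear fit reports
radius ∞, angle 0, and curved length equal to the chord.

**Curvature gating.** Curvature is reported only for aspect ratio > 1. For
rounder eggs the three fit points are nearly coincident relative to egg
size and the fitted angle is dominated by landmark noise, so it carries no
usable signal. Curvature is unsigned.

**Derived traits and units.** All text inputs are millimetres; strings in
other units are rejected rather than converted. Width from images is the
widest of the three quartile diameters; breadth is only ever available from
text (a flattened egg's second transverse diameter cannot be read from one
silhouette).

## Silhouette simulator

The simulator produces outlines with *known* parameters so the measurement
pipeline can be validated closed-loop.

**Diameter profile.** A straight egg of unit axis length has diameter
profile `d(s)` interpolated through anchors `(0,0)`, `(0.25,q1)`,
`(0.5,q2)`, `(0.75,q3)`, `(1,0)` with a monotone-per-segment cubic (PCHIP
interior derivatives). With `q1 = q2 = D = 1/AR` and `q3 = D/(1+asym)`, the
definitional formulas return the requested parameters exactly: the profile
maximum is `D`, attained at the anchors, and the wider quartile sits at the
`L1` end (the asymmetry parameter is unsigned, so this orientation is
observationally irrelevant).

**Pole tips.** The end derivatives of the profile are clamped to zero,
giving spindle-shaped (cusped) poles. This is deliberate: pole detection
locates the boundary points where the margin turns steepest, and for oblate
or spherical parameter combinations a smooth wide outline would have its
curvature maxima on the *sides*, not at the symmetry-axis ends. The cusp
makes the poles the global curvature maxima for every grid combination
while leaving all measured quantities (chords, axis length, arc) unchanged.

**Bending.** A curved egg maps the midline onto a circular arc of central
angle θ whose **chord equals the original axis length** (radius
`R = L / (2·sin(θ/2))`), with boundary points offset radially by their
original half-diameters. Consequences, all exact by construction: θ = 0 is
the identity; the arc through the deformed poles and the q2 midpoint has
central angle θ; diameters along arc length are preserved; the straight
length of the bent egg equals L, so the straight-length aspect ratio remains
the generating one; the chord/arc ratio is `sin(θ/2)/(θ/2)` (≈ 0.8270 at
120°); enclosed area scales by exactly the arc-lengthening factor
`(θ/2)/sin(θ/2)`. The alternative arc-length-preserving bend was rejected
because it shrinks the chord by ~17% at 120°, making the generated aspect
ratio unrecoverable by a protocol that measures straight length.

**Validation grid.** 24 parameter combinations: aspect ratios
{0.5, 1, 2, 6} × asymmetries {0, 0.2, 0.8} × curvatures {0°, 30°, 120°},
with nonzero curvature omitted at aspect ratio ≤ 1 (bent oblate eggs are
outside the validated space). Rasterisation is deterministic
scan-conversion; masks must span ≥ 100 px on the long axis.

## Automated landmark placement

`find_poles` resamples the outline to 2048 equidistant vertices, estimates
curvature as the boxcar-smoothed *signed* turning angle per arc length
(window 1.5% of perimeter; signing makes pixel-staircase noise on
rasterised outlines cancel), takes local maxima exceeding 1.1× the median
margin curvature, suppresses non-maximal peaks within 5% of perimeter of a
stronger one, and picks the pair separated by at least a quarter of the
perimeter each way that maximises the product of curvature scores (ties:
larger separation, then lowest boundary index). Each chosen peak is refined
to the sharpest original vertex within the smoothing window, since the
boxcar displaces a cusp peak by up to half its width. If fewer than two
salient maxima exist (a near-perfect circle), two points at maximal
boundary separation are used and the result is flagged.

`place_guides` intersects the perpendicular bisector of `L1 L2` with the
outline — taking the two distinct crossings nearest the chord midpoint,
which for strongly bent eggs both lie on the same side of it — fits the arc
through `L1`, mid(`M1 M2`), `L2`, and drops the quartile chords along the
perpendiculars (radials) to that arc at the two points bisecting each
half-arc, keeping the crossings nearest the arc. For collinear fits the
quartile stations sit at quarter points of the straight axis. Scale-bar
landmarks are synthesised from the silhouette's `px_per_mm` metadata.

**Click-noise model.** Repeat-measurement studies displace every landmark
by isotropic Gaussian noise of scale `jitter_px` and then project the
margin landmarks (poles, chord endpoints) back onto the outline — a human
drops those points *on the egg margin*, so click error slides along the
outline rather than leaving it; scale-bar clicks stay unconstrained. This
constraint matters: near a pole tip, margin-constrained error can only
slide the landmark inward along the egg, which shortens the measured chord
and sagitta and produces the systematic *underestimation* of strong
curvature that repeat measurements show (≈ +0.9° at θ = 120° with 2 px
noise on a 200-px egg), along with a slight overestimation near θ = 0.
Free-space isotropic noise, by contrast, is almost unbiased for curvature
(measured bias below 0.02° under the same conditions) because the angle is
locally linear in symmetric perturbations. With zero jitter the pipeline is
fully deterministic and the seed is ignored; with jitter, results are
reproducible given the seed. Accuracy reports place guides once per
silhouette and redraw only the jitter between repeats; discrepancies are
reported as actual − measured, so positive curvature discrepancy means
underestimation.

## Record curation

**Grammar.** A text measurement is one of `a ± b` (average and deviation),
`a–b` / `a-b` / `a to b` (range), or a bare number, each with an optional
`mm` suffix. When several forms appear in one string the precedence is
average±deviation > range > single value. The descriptor records the
decimal places of the least precise numeral as printed (trailing zeros
significant). Representative values: the mean, the range midpoint (the
median of two values), or the value itself.

**Derivation and merging.** Width is the wider and breadth the narrower of
the two reported transverse diameters; volume is computed from linear
dimensions whenever length and width exist, otherwise a reported volume is
accepted as-is (flagged `reported`). When an entry has both a text
description and an image with a scale bar, the text value wins for every
shared trait; asymmetry and curvature exist only from images. Every final
field carries a provenance flag.

**Exclusion filters.** Records whose image-derived aspect ratio (or
asymmetry) lies strictly above the 99.9th percentile of the nonmissing
values — the top 0.1 percentile, where measurement variance blows up — are
removed. Percentiles use linear interpolation, under which 10,000 distinct
values lose exactly 10 records; when all values tie, nothing exceeds the
percentile and nothing is removed. Thresholds can be frozen and re-applied,
making the filter idempotent under fixed thresholds. Curvature is nulled
wherever the final aspect ratio is ≤ 1.

**Missing values** are empty TSV fields (locale-neutral), and the pipeline
output is byte-stable across runs.

## QC metrics

Intraspecific variation, four ways, all as percent difference
`100·(max−min)/median` unless stated: (1) within one description — ranges
directly, average±deviation as `100·2·dev/mean` (algebraically the range
form applied to mean±dev); (2) across publications — same-species entries
are first grouped into independent observations by single-linkage chaining
on calculated volume with a 1.0×10⁻⁵ mm³ threshold ("repeats" differ by no
more than the threshold; chaining makes the grouping order-independent),
then the group-median lengths are compared; (3) reported text length vs
re-measured image length; (4) triaxial vs rotationally symmetric volume,
`(1/6)πlwb` vs `(1/6)πlw²` — a breadth of half the width gives 66.7%
regardless of scale.

Precision, two ways: decimal places of the printed length (base mm,
trailing zeros count), and relative precision `100 × 10^(−decimals) /
length` — the smallest printed unit as a percent of egg length, so
"1.00 mm" → 1%. The stated definition and its worked example disagree on
the direction of the ratio; the worked example (1.00 mm within 1%) wins.
For range descriptors the representative (midpoint) length is used.

Phylogenetic coverage compares entries per rank with a user-supplied
species-count table as entries per 100 estimated species, flagging ranks
below 1 per 100. No online taxonomy service is queried.

## Synthetic data

`synthetic_raw_records` emulates the *format* and broad distributions of
compiled egg data: lognormal lengths centred at 1 mm (σ = 0.3 dex),
lognormal aspect ratios centred at 1.8, the three text styles at roughly
57.5 / 28.5 / 14 % (single / range / avg±dev), 13% volume-only entries, 30%
of records with image measurements (80% of those with a scale bar), ±5%
intraspecific scatter, and 1–3 printed decimals. It carries no real
taxonomic signal, no transcription errors, and no unit heterogeneity, so
pipeline tests demonstrate correctness of the rules, not robustness to
dirty archival text.

## Problem sizes and numerical choices

Tests and validation scripts run the closed-loop grid at 300 px per unit
axis length with ~384-vertex outlines and 2048-point resampling, jitter
studies at 200 px with up to 500 repeats, and pipeline tests on 400–500
synthetic records — sizes at which every check completes in seconds while
the discretisation error (pole localisation ≈ half a resample step) stays
far below the recovery tolerances. Transform round-trips are exact to
1e−12 relative; the arc fit matches an independent grid-search oracle to
1e−6 relative on random triples.

## Known limitations

- Real micrographs (background, texture, chorion ornament, broken scale
  bars) are out of scope; raster input must already be a clean binary mask.
- The pole definition is genuinely ambiguous for smooth oblate outlines;
  the simulator sidesteps this with cusped tips, and flat real eggs would
  need operator judgement.
- The click-noise model reproduces the *signs* of human repeat-measurement
  error, not its magnitudes, which embed operator-specific behaviour.
- Taxon strings pass through verbatim; no name reconciliation is attempted.
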