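# eggshape

Landmark-based morphometrics for insect eggs: a toolkit for measuring egg
size and shape from images, validating the measurement geometry against
simulated silhouettes with known parameters, and curating literature-derived
egg-description records into an analysis-ready trait table.

## Who this is for

Comparative and evolutionary biologists compiling offspring-size data from
the primary literature face two measurement problems: published egg
*descriptions* are heterogeneous free text ("0.6 ± 0.05 mm", "0.5–0.7 mm",
"1 mm"), and published egg *images* must be re-measured consistently across
thousands of figures of varying quality. This package implements a guided
landmark protocol for the second problem, a text-measurement grammar and
merge/filter pipeline for the first, and the QC metrics needed to interpret
the combined dataset.

## The measurement model

An egg outline is summarised by ten landmarks: poles `L1`, `L2` at the ends
of the axis of rotational symmetry, the endpoints of three transverse chords
at the first quartile, midpoint, and third quartile of the curved length
axis (`q1`, `q2`, `q3`), and an optional scale-bar pair. From these:

- **length** `l` — straight distance `|L1 L2|` (mm when a scale bar is present)
- **width** `w = max(q1, q2, q3)`
- **volume** `V = (1/6)·π·l·w²` for a rotationally symmetric ellipsoid, or
  `(1/6)·π·l·w·b` when a distinct breadth `b` is reported
- **aspect ratio** `l / w` — 1 spherical, >1 prolate, <1 oblate
- **asymmetry** `max(q1, q3) / min(q1, q3) − 1` — 0 for a front/back
  symmetric egg
- **angle of curvature** — the central angle of the circular arc through
  `L1`, `L2` and the midpoint of the `q2` chord; 0° for a straight egg, and
  reported only when aspect ratio exceeds 1

For analysis, strictly positive size traits (length, width, breadth, volume,
aspect ratio) are log10 transformed and the zero-inflated shape traits
(asymmetry, curvature in radians) are square-root transformed.

The silhouette simulator inverts this model: it generates outlines whose
quartile diameters, axis length and midline curvature hit requested
parameter values exactly, so the automated measurement pipeline can be
validated closed-loop on a 24-point grid of aspect ratios {0.5, 1, 2, 6} ×
asymmetries {0, 0.2, 0.8} × curvatures {0°, 30°, 120°}.

## Worked example

`examples/simulate_and_recover.py` simulates eggs with known parameters,
re-measures them with the automated landmark protocol, and prints the
actual-minus-measured discrepancies:

```
zero-jitter recovery (discrepancy = actual - measured):
  AR  asym   curv |     d(AR)   d(asym)   d(curv)
 0.5   0.2    0.0 |   0.00000   0.00000       n/a
 2.0   0.2    0.0 |   0.00000   0.00000    0.0000
 2.0   0.0  120.0 |   0.00000  -0.00000    0.0000
 6.0   0.8   30.0 |   0.00000   0.00000    0.0000

with 2 px margin-click jitter, 200 repeats (curved egg):
curvature discrepancy: +0.86 deg (positive: the protocol underestimates strong curvature)
```

With noise-free landmarks the protocol inverts the generator exactly (the
oblate egg reports no curvature, by definition). With 2 px of click noise
constrained to the egg margin, strongly curved eggs are measured with a
systematically smaller angle — the discrepancy is positive under the
actual-minus-measured convention.

The other examples cover the remaining capabilities, each printing a short
annotated report:

- `examples/measure_landmarks.py` — derive traits from one hand-placed
  landmark set with a scale bar
- `examples/curate_records.py` — parse, merge and filter a synthetic raw
  record table into the final trait TSV
- `examples/qc_report.py` — intraspecific-variation, precision and
  phylogenetic-coverage QC

A thin CLI wraps the same library calls:

```sh
eggshape simulate --grid table9 --out sims/
eggshape measure --mask sims/egg_06_ar2_asym0_curv0.png
eggshape validate --grid table9 --reps 5
eggshape derive --raw raw.tsv --out final.tsv
eggshape qc --final final.tsv --species-counts counts.tsv
```

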