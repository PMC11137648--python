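# Methods

This note documents the models and procedures `spinedss` implements, the
parameters that matter, what the phantom generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Pipeline

A study is read in the clinical order: vertebra localization on the
mid-sagittal slice; herniation diagnosis per disc from the posterior disc
ROI; for herniated discs, MSU size/zone classification on the correlated
axial slice; Pfirrmann grading, which the pathway gates to MSU-2/3 discs
(grading is exposed for any disc, and the gate can be forced open);
finally rule-based advice. All stages are pure functions of their inputs
and seeds.

## Coordinate and unit conventions

Coordinates are 0-based pixel `(x, y)` with `x` the column and `y` the
row; in sagittal phantoms `y` grows caudally and the dorsal direction is
`+x`. Conversions to millimetres use the pixel spacing, default
0.2646 mm/px (typical of resampled 512×512 lumbar series); DICOM headers
override it when present. Masks are rasters with foreground 1 in memory
and 255 in PNG files.

## Vertebra chain model

Localization detects vertebral bodies rather than discs (stronger image
evidence) behind a `callable(image) -> DetectorResult` interface. The
reference detector is classical: Gaussian smoothing (σ = 1.5 px),
intensity threshold (245), connected components, area filter
(1000–30000 px²) and aspect filter (≤ 3:1), centroids sorted
cranial→caudal. Any learned detector can replace it.

The chain constraints use λ1 = 0.6, λ2 = 1.25, θ1 = 140°, θ2 = 180°.
Two readings were fixed here:

- **Inclusive 180°.** The angle constraint is evaluated as
  θ1 < angle ≤ θ2. A perfectly collinear chain measures exactly 180°,
  which is the anatomical ideal, not a violation.
- **Deviance attribution.** A violated distance ratio Vi/Vi−1 implicates
  the shared vertex Pi, and a violated angle implicates its vertex.
  Endpoints, which have no interior constraint, are flagged when their
  single segment departs from the median segment length by more than the
  λ band (the median is robust to a single bad segment).

**Repair.** Because a displaced point contaminates the ratios of its
neighbors, deviant indices arrive in contiguous runs around the true
outlier. A run bracketed by clean points is re-spaced evenly along the
segment between the bracketing points (a one-point run is exactly the
midpoint of its neighbors); a run touching an end of the chain is
extrapolated point by point from the nearest clean pair. An endpoint
flagged while its neighbor is also flagged is deferred for one iteration,
since its only evidence passes through that neighbor. The loop runs to a
fixed point or `max_repair_iters` (default 5; non-convergence is
reported, not raised). Repair is idempotent, never moves clean points,
and raises when every point is deviant (no reference left).

**Detectability limit.** With θ1 = 140° and inter-vertebral spacing L,
an interior point displaced laterally by d is flagged once
2·atan(d/L) > 40°, i.e. d ≳ 0.36·L (about 7 mm at the default phantom
geometry) — which is why the closed-loop experiments inject outliers of
at least 9 mm at interior points. Endpoints see only one segment, so a
lateral endpoint displacement below ~0.5·L (~15 mm here) is invisible to
the constraints by construction; this is a genuine limitation of
distance/angle post-processing, not of the implementation.

## Posterior disc ROI and diagnosis

The diagnosis ROI is the oriented rectangle whose long side is the full
segment between adjacent vertebra centers and whose short side extends a
fixed 44 px from that line toward the dorsal side ("the posterior half of
the disc, and anything extruded beyond it"). Resampling is bilinear with
zero padding, output 64×44. The reference classifier shares the grading
feature stack (below) with a logistic head; it sits behind a
`(roi, model) -> (label, score)` interface a CNN could implement.
Degenerate rule: a constant patch (no structure at all) is labelled
normal with score 0 instead of extrapolating the model out of
distribution.

Score invariance guarantee: LBP and PHOG are exactly invariant to
patch-wide additive shifts; HPI changes only when a pixel crosses one of
the 64 four-unit-wide histogram bins. Any shift that preserves
`floor(v/4)` for every pixel therefore leaves the score bit-identical.

## MSU grid

The six marker points are the disc center D, the dorsal canal point Q and
the four ventral apices of the superior/inferior articular processes; the
posterior disc margin M on the AP axis is carried as a seventh required
annotation because the size-1 band needs a posterior-margin origin (the
disc center alone cannot anchor it). Construction: AP axis = line D→Q
with coordinate s (0 at D, positive dorsally) and lateral coordinate t;
per side the facet reference is the midpoint of the superior and inferior
apices; the intra-facet line joins the two references and crosses the AP
axis at s_if; s0 = s(M). Size bands: 1 for s ≤ s0 + (s_if−s0)/2, 2 up to
s_if (both inclusive), 3 strictly beyond. Zone boundaries at half the
facet offsets (A/B) and the facet offsets (B/C); a point exactly on a
lateral boundary takes the more lateral zone, and compound zones are not
emitted — the label comes from the single apex point, defined as the mask
pixel with maximal s (ties: minimal |t|, then raster order). All of this
is invariant under rigid transforms applied jointly to markers and mask.

Segmentation is an interface; the reference implementation thresholds
(default 180 on the 8-bit scale) the band dorsal of the posterior disc
margin, keeps the largest connected component and fills holes. An empty
mask under an upstream herniation assertion warns rather than raises,
because the upstream diagnosis may simply be wrong.

`rasterize_regions` paints all nine regions pixel-by-pixel from the same
grid; it exists as an independent cross-check of the analytic assignment
(the two must agree at the apex pixel) and for visualization.

## Pfirrmann features and MLP

The descriptor is HPI (64) + LBP (256) + PHOG (252) = 572 dimensions,
each block normalized to sum 1 at extraction, then z-scored per dimension
with training statistics at model input. Only the total length is
externally fixed; the 64+256+252 split and the LBP/PHOG hyperparameters
are package conventions recorded in model metadata:

- LBP: 8 neighbors at radius 1, bit k for neighbor k ordered E, NE, N,
  NW, W, SW, S, SE; a bit is set when neighbor ≥ center; border pixels
  excluded. A 180° patch rotation permutes codes by a 4-bit rotation,
  which the tests use as an oracle.
- PHOG: unsigned orientations in [0°, 180°) over 12 bins, magnitude
  weighted (central-difference gradients), pyramid levels 0–2
  (1 + 4 + 16 cells, row-major per level). A gradient-free patch maps to
  the uniform vector 1/252.

The grading crop is the oriented rectangle centered between adjacent
vertebra centers, width equal to their distance along the inter-center
line and 1.5× that across the disc, resampled to 48×96.

The classifier is a 572-300-150-5 MLP (ReLU, softmax cross-entropy)
trained with seeded mini-batch SGD: learning rate 0.01, momentum 0.9,
batch 32, 200 epochs by default. The architecture is locked; the
optimizer settings are configurable. Grade predictions break probability
ties toward the lower grade and render as Roman numerals I–V in reports.
Training is a pure function of (data, config, seed); all five grades must
be present or training refuses with the missing grades listed.

## Metrics

All ratio metrics raise a typed error on a zero denominator — silent
zeros corrupt averages. Multi-class precision/sensitivity are one-vs-rest
per class; overall accuracy is micro (trace/total). DSC and IoU satisfy
DSC = 2·IoU/(1+IoU) exactly, which doubles as a consistency check between
independently reported overlap numbers. Fleiss' kappa is computed via
statsmodels with validation (constant row sums, ≥ 2 raters) added here;
unanimous tables give exactly 1. Reader-study changes are **relative**:
(assisted − unassisted)/unassisted for accuracy and
(unassisted − assisted)/unassisted for time, as percentages rounded to
two decimals, with cross-task means of both.

## Decision rules

Management: no herniation or MSU size 1 → conservative (size dominates
zone); size 2/3 → surgical consideration with the approach from the zone
(A → posterior/MED; B, C → lateral PTED-or-OLIF); Pfirrmann IV–V
("> 3") sets the interbody-fusion flag. A herniated disc whose axial
pathway was not completed maps to conservative under an explicit
`incomplete-msu` rule rather than failing, so the engine is total over
the whole discrete assessment lattice. Sizes 2 and 3 are deliberately not
distinguished in management. Every advice lists the rule ids that fired,
and reports carry a fixed disclaimer: this is decision support, not an
autonomous diagnosis.

## Phantom generator

The generator produces the study conditions the tests run under: 512×512
8-bit slices at 0.2646 mm/px, six vertebral bodies (sagittal) and one
disc level (axial), additive Gaussian noise σ = 8 clipped to [0, 255].
Geometry is procedural — superellipses along a 10° lordotic arc with
±2 px center jitter — because exact analytic ground truth is worth more
here than photorealism.

Grade appearance encodes the degeneration criteria as separable classes:
disc mean intensity 230 − 35·(g−1), nucleus/annulus contrast
1 − (g−1)/4, disc height factor 0.6 at grade 5 (1.0 otherwise). The
brightest nucleus is capped at 238 and vertebral bodies render at 255 so
a brightness-based detector can always separate bone from disc.
Herniated discs get a posterior bulge beyond the disc margin; the
44 px ROI strip covers margin plus bulge at the phantom's 56 px disc
width. Axial slices render disc, canal and facet structures at
intensities below the segmentation threshold, and the herniation blob at
230 above it.

Axial herniations are planted by inverting the MSU grid transform: the
apex (s, t) is sampled at least 3 px inside every boundary of the target
region, the blob is a half-ellipse on the posterior margin with a
one-pixel spike to the exact apex (so rasterization cannot move the apex
more than one pixel, and the planted label is recovered without boundary
ties). Unsatisfiable targets raise after 20 bounded retries, naming the
target. One axial slice is emitted per herniated disc; slice selection on
real data is left to the caller.

**What the phantoms do not emulate** — and hence what passing tests do
not show about real MRI: anatomical shape variability and pathology
beyond the modelled bulge, intensity inhomogeneity and scanner
differences, partial-volume and through-plane effects, neighboring
organs, and realistic inter-grade ambiguity (phantom grades are separable
by construction, so the ~1.0 held-out accuracies measure pipeline
correctness, not clinical performance). Claims about real data need real
annotated data through the same interfaces.

## Problem sizes and numerical choices

The bundled experiments use 200 sagittal phantoms for the repair closed
loop, 1000 axial phantoms for MSU oracle agreement (segmentation scored
on a 100-case subsample), and a 500-disc cohort (100 phantoms × 5 discs;
375 train / 125 held out, grade-balanced) for grading and diagnosis —
sizes chosen so the full suite runs on a laptop-class CPU in minutes
while keeping binomial noise on the reported rates around or below a
percentage point. Tolerances: metric identities to 1e-12; angle
computations clip cosines to [−1, 1]; rectangle corners agree to 1e-6;
permutation nulls are asserted as 0.2 ± 0.06 (5-class) and 0.5 ± 0.1
(binary, averaged over 5 permutation draws). Degenerate inputs have
defined behavior throughout (typed errors or documented fallbacks) rather
than NaNs.
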