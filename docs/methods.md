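# Methods

## Problem and pipeline

`blistercount` estimates how many pills remain in a medication blister
pack from a single photograph, by comparing the pack against a
reference extracted once from a photograph of the same pack while still
full. The pipeline has four stages — blister localisation,
normalisation, circle detection, and per-pocket classification — each
built from classical image-processing primitives so that every decision
is inspectable.

### Blister localisation

A blister differs from a plain background by texture, not by a single
colour, so localisation thresholds a *heterogeneity* image: grayscale →
5×5 median (noise suppression) → 9×9 local sample standard deviation →
Otsu's 256-bin global threshold. The binary foreground is consolidated
by two dilations with 50 px horizontal/vertical line elements followed
by a closing with a 50×50 square, implemented as separable running
maximum/minimum filters. The largest 8-connected component's bounding
box is the proposed crop; ties go to the larger box, then the
topmost-leftmost. Because the structuring elements have fixed pixel
sizes, detection runs at a bounded working resolution (long edge
≤ 1500 px, config `detect_long_edge`) and the box is rescaled to native
coordinates. A structureless image raises a blister-not-found error and
callers fall back to a manual crop; cluttered scenes (hands, desks)
remain a documented failure mode of this strategy, which the synthetic
`background="cluttered"` setting reproduces for stress tests.

### Normalisation

Crops are scaled to a 1000 px long edge (bicubic), rotated 90° CCW to
vertical when wider than tall (recorded in `rotated_90`, making pill
coordinates invertible to within 1 px), converted to HSV, and each
channel is enhanced with CLAHE. On the value channel — the input to all
edge analysis — pixels above 0.95 are treated as specular reflections
and replaced by inward (biharmonic) interpolation from their region
boundary, then an unsharp mask (σ = 6 px, amount 0.6, i.e. "strength
60" read as a percentage) emphasises rims and creases. Hue is equalised
as a plain [0, 1] channel; its circular topology is ignored because no
downstream stage consumes hue.

CLAHE uses an 8×8 tile grid with clip limit **0.005**. The clip limit
matters more than it may appear: at 0.01 the maximum contrast slope
(≈ clip × 256) amplifies flat-area sensor noise so strongly that the
local-std baseline inside *intact* pockets approaches the 0.05
classification margin, and crease edges drown in noise edges. 0.005
halves the amplification while still stretching genuine low-contrast
structure; both values are one config field apart (`clahe_clip`).

### Edge and circle detection

Canny edge detection runs on the sharpened value channel with σ = 2 and
per-image thresholds: the high hysteresis threshold is Otsu's threshold
of the Sobel gradient magnitude of the smoothed channel (computed on the
same unnormalised gradient scale the hysteresis stage uses), bounded
below by a noise floor (`canny_high_floor = 0.1` on that scale), and the
low threshold is 0.4× the high one. The Otsu rule adapts to the contrast
of each image; the floor covers the degenerate case of a structureless
image, whose unimodal noise-gradient histogram Otsu would otherwise
split in half.

Circles are detected with a full-ring-voting Circle Hough Transform
over integer radii 30–130 px (`hough_radius_step = 1`; a coarser grid
is configurable but attenuates ideal thin rings whose radius falls
between grid points). The accumulator is evaluated as a ring
convolution via FFT — identical vote counts to the classical per-pixel
drawing formulation, at a per-image cost independent of edge density,
with the ring-kernel spectra reused across same-shaped images — and
each plane is normalised by the ideal perimeter pixel count 2πr, so a
fully supported circle scores a *metric* of 1. Peaks above
`1 − sensitivity` are accepted, strongest first, with non-maximum
suppression of any weaker peak whose center lies within `rmin` per axis
of an accepted one.

**Sensitivity calibration.** The published sensitivity 0.93 belongs to
a proprietary two-stage detector whose metric has a different scale; it
is kept available in config but is not the default. With the metric
defined above, measured on 18 synthetic fixtures (both styles, three
grid layouts), true pills score ≥ 0.56 while the strongest off-pill
accumulator peak per image stays ≤ 0.23. The default sensitivity 0.6
(metric threshold 0.40) sits midway, leaving ≈ 0.16 margin on both
sides. The threshold also stays above the cross-radius sidelobes that
large rings cast at small radii (≈ 0.1–0.3), which the permissive 0.93
setting would report as spurious circles under this metric.

### Registration artifact rules

Registration assumes a full blister, so population statistics over the
detected circles are dominated by genuine pills. The cascade, in order:

1. **Radius**: discard circles deviating > 50 % from the mean radius.
2. **Circle-edge ratio (CER)**: if the CER standard deviation across
   the radius-rule survivors is ≥ 0.04, discard circles outside
   mean ± 2σ; below 0.04 the image is considered already clean and the
   rule is skipped. σ uses the sample (n−1) estimator.
3. **Metric rescue**: if the mean metric is > 0.15 (informative),
   re-accept CER-discarded circles whose metric exceeds 75 % of the
   metric median — pills carrying a reflection or a dent should not be
   lost to rule 2.
4. **Column alignment**: after vertical alignment pills sit in columns.
   In the outermost column of each image half (members within one mean
   radius of the extreme center column), a circle whose center deviates
   from the *outer column's own median column* by more than 5 % of the
   image width is kept only under stricter limits (CER within
   mean ± 1σ **and** metric ≥ the median metric). The anchor is the
   outer column's median rather than the half-blister median: for
   two-column packs the two coincide, but for three or more columns the
   half median falls between columns and would condemn an entire honest
   column.

All rules are per-circle predicates of batch statistics, so the
accepted set is invariant to input order. The reference record keeps
the accepted centers and the means of radius, CER and local std.

### Counting rules

Detected circles are matched to reference positions one-to-one:
candidates lie within `mean_radius + 10 px`; positions are served
greedily in order of their nearest free candidate; among a position's
candidates the smallest radius deviation from the reference mean wins.
One-to-one assignment prevents a single circle from satisfying two
adjacent pockets on dense grids.

A matched pocket is labelled **taken** iff `Δσₗ > 0.05`, or
`0.02 < Δσₗ ≤ 0.05` and `ΔCER ≥ 0.025` (deltas = measured − reference
mean; the σ bounds are strict, the CER bound inclusive, matching the
"at least 0.025" vs "increase of 0.05" phrasing of the rule set).
Unmatched pockets are taken by definition and carry no deltas. Features
are measured on the circle as detected in the current image.

For odd pill counts (asymmetric layouts) the image might be presented
180° rotated relative to registration. Both orientations are evaluated
by summing, over *all* reference pills, the distance to the nearest
detected circle; the smaller total wins, ties going to the original.
Summing over all reference pills rather than only matched pairs is
deliberate: a sum over matched pairs can favour the wrong orientation
simply because it matches fewer pockets. A 180° rotation maps the
accumulator onto itself, so the rotated candidate set is obtained by
transforming circle coordinates, not by re-detection.

A counting image whose long edge differs from the reference's by more
than 5 % is rejected as incompatible (the coordinate comparison assumes
similar crops).

## Synthetic study conditions

The generator renders the image properties the pipeline measures,
deliberately not photo-realism:

* **Geometry**: rectangular pocket grids (defaults 5×2; odd layouts drop
  the last pocket), pocket pitch 2.6 r, blister margin 2 r, rounded
  corners of 0.3 r. With these proportions the pocket radius after
  1000 px normalisation depends only on the row count and stays inside
  the [30, 130] Hough band for 3–7 rows.
* **Gray style**: opaque cover; intact pockets are smooth domes
  (+0.16 peak) with a strong dark rim ring (depth 0.28, width ≈ 1.2 px).
* **Transparent style**: lighter body, a coloured pill disk (0.78 r)
  under a faint sheen, weaker rim (depth 0.14).
* **Taken pockets**: the rim is broken by 2–4 angular gaps of 12–26°
  half-width with radial wobble (raising CER), and the interior carries
  a crumple texture — four oriented sinusoids (λ = 8–18 px) plus
  blurred speckle, amplitude 0.05 (gray) / 0.022 (transparent) — chosen
  so that after the full preprocessing chain the gray-style local-std
  increase clears 0.05 and the transparent one clears 0.02 with rim
  disruption. The gray margin intentionally exceeds the transparent
  one, reproducing the fact that deformations are far more visible on
  opaque foil; transparent taken pockets are the pipeline's known weak
  point and are classified mostly through the CER path.
* **Nuisances**: per-pocket specular reflections (probability 0.10,
  painted ≥ 0.985 after blur so the in-fill stage sees them), Gaussian
  blur σ = 0.8, additive sensor noise σ = 0.008, a mild illumination
  gradient, and a flat dark background (or random rectangles/segments
  for the `cluttered` stress setting).
* **Determinism**: one `numpy` Generator seeded from the spec renders
  bit-identical output; sequences re-randomise only photometric
  nuisances per frame through `SeedSequence(seed, spawn_key=(frame,))`.

What the fixtures do *not* model: perspective and lens distortion,
hands and real clutter, non-round pockets, embossed foil text, complex
illumination. Passing rates on these fixtures therefore demonstrate the
internal consistency and the intended operating point of the method,
not its accuracy on real photographs.

## Evaluation design and problem sizes

The standard batches (module `blistercount.suites`) mirror the method's
validation plan at desk scale: 20 full blisters (10 gray /
10 transparent, five grid layouts, ≥ 200 pills) for registration
scoring; 10 gray-style sequences of 1 registration frame + 10 scored
frames (100 scored frames, pockets emptied along a seeded random order
until the blister is empty) for counting; 50 flat-background
photographs with varying framing and scale for localisation. A pill
counts as detected when an accepted circle center lies within half the
mean radius of its true center (one-to-one); localisation succeeds when
the predicted box contains ≥ 95 % of the true blister with at most 8 %
of the blister long edge of margin on any side — the geometric proxy
for a human "centered, bounded border" judgment. Registration and
counting are scored from ground-truth crops (the manual-crop analogue),
isolating those stages from localisation errors; localisation is scored
on its own suite.

`scripts/acceptance.py --seed S --out f.json` recomputes all five
headline rates from scratch; every random choice descends from the
single seed.

## Numerical choices and degenerate inputs

* Neighbourhood filters use edge-repeating reflect padding.
* Otsu on a constant image returns the constant and an all-background
  binary; CLAHE passes constant channels through unchanged.
* `fill_reflections` on an all-saturated channel warns and returns the
  input (no boundary to interpolate from).
* The local-std filter uses the sample (n−1) estimator.
* Morphological closing pads with foreground on the erosion step so
  border blobs are not eaten.
* FFT accumulation is float32; values are clipped to [0, ∞) against
  round-off and the metric to [0, 1].
* Matching and NMS tie-breaks are fully deterministic (value, then
  row, column, radius).

## Known limitations

* Transparent-cover taken pockets sit near the intermediate
  classification band; real transparent blisters would fare worse than
  the synthetic rates suggest.
* The localisation stage requires a flat, plain background by design.
* The artifact cascade presumes a full blister at registration; a
  partially used registration image degrades the reference silently.
* Counting accuracy depends on crop similarity between registration and
  counting images; beyond the `mean_radius + 10 px` matching slack,
  pockets fall back to "taken".
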