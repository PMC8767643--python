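# Methods

This note documents the models and numerical choices behind each pipeline
stage, the parameters that matter, what the synthetic generator does and
does not emulate, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and connectivity

x = column index (rightward), y = row index (downward), 0-based. Bounding
boxes are half-open `[min, max)`. Connected components and boundary
adjacency use 8-connectivity throughout — diagonal leaf tips are common in
rosette silhouettes, and using one convention everywhere keeps pixel counts
consistent between stages. Extent measures are inclusive pixel counts
(`max − min + 1`), so a single pixel has height = width = 1.

## Segmentation

The plant/background split is classical color thresholding: inclusive bands
on HSV and CIELAB channels (HSV with H in degrees [0, 360), S, V in [0, 1];
CIELAB under D65/2°), combined by a per-config boolean rule and cleaned by
removing foreground components smaller than `min_object_px` and filling
holes smaller than `fill_hole_px`. Threshold values are inherently
experiment-specific — in the original campaigns they were tuned by visually
iterating over plant/segmentation overlays across the whole panel — so the
package treats them as config, and ships defaults tuned once against the
synthetic generator:

| mask   | channel  | band        | rationale                             |
|--------|----------|-------------|---------------------------------------|
| sat    | HSV S    | [0.40, 1]   | leaves/flowers are saturated; chamber background is not |
| lab_b  | LAB b    | [20, 127]   | green and yellow tissue is strongly yellow–blue positive |
| bright | HSV V    | [0.12, 1]   | guard against dark sensor noise       |

combined as `(sat | lab_b) & bright`, `min_object_px = 12`,
`fill_hole_px = 16`. Combine rules are parsed with an AST whitelist (names,
`~ & | ^`, parentheses) and evaluated pixelwise, so configs cannot execute
arbitrary code. No learned segmentation is included: without ground-truth
masks for real campaigns there is nothing to train on, which is exactly the
regime the threshold workflow is designed for.

## Holistic traits

Convex-hull area is the shoelace area (via the hull of foreground pixel
centers); degenerate sets (< 3 points or collinear) get area 0. An empty
mask produces an all-zero record with an `empty` flag rather than an
exception, because occluded or dead plant-days are data, not errors.

ExG defaults to the variant `2G − R + B` used by the workflow this package
reimplements; the canonical Woebbecke form `2G − R − B` is selectable
(`variant="canonical"`) and the variant is recorded with the value, since
the two differ by 2B and are not comparable across studies.

Biovolume is `sqrt(side_area² × top_area)` (px^1.5 scale), monotone in both
arguments. Δ-series bridge missing imaging days: `Δ(d)` is taken against the
previous *available* day, which on an every-other-day schedule is the only
sensible choice. Outlier removal uses median ± 3 sample (n−1) standard
deviations per trait per day; with fewer than two finite values it passes
data through unchanged.

## NIR mask transfer

Registration is scale + offset only (both cameras point straight down; no
rotation is physically expected): NIR position = RGB position × scale +
offset, inverted with nearest-neighbor sampling, with out-of-frame source
positions treated as background. A transferred mask that comes out empty is
flagged and its summaries become missing rather than zero. The 75th
percentile uses linear interpolation between order statistics (the common
numerics default). `calibrate_registration` grid-searches scale and offset
to maximize Jaccard overlap on a bright fixture imaged by both cameras; it
is a coarse helper, not a general-purpose registration solver.

## Boundary curvature (HOCS)

Curvature at a boundary pixel is the normalized area integral invariant
(AII): the fraction of the discrete disc (squared distance ≤ r²) centered
there that is foreground, with pixels outside the frame counting as
background. The per-pixel disc counts are computed as an FFT convolution of
the 0/1 mask with the 0/1 disc kernel and rounded back to exact integers
(counts are integral; FFT error at these sizes is ~1e−9), which the test
suite verifies against a naive double-loop oracle bit-for-bit.

Boundary = foreground pixels with ≥1 background 8-neighbor, image border
included; interior hole boundaries are included because leaf holes carry
curvature signal. Boundary points are weighted equally (no arc-length
weighting). The descriptor evaluates the AII at every boundary point for
radii 5, 10, …, 125 px and histograms each radius into 5 uniform bins on
[0, 1] (right edge of the last bin closed), normalizing each row to sum 1
so scales are comparable. The construction is exactly invariant to
translation and to 90°-multiple rotations, and stable (not exact) under
arbitrary rotation; both properties are tested.

## Flower phenology

The flower mask is `(CIELAB b ≥ threshold) AND plant_mask`; restricting to
the plant mask keeps yellow clutter (fallen petals of neighbors, labels)
out. The threshold comes from a first-match-wins rule table keyed by DAS
range and treatment, because flower and background chromaticity drift with
plant age; the shipped default is a single rule at b ≥ 60, calibrated once
on the generator palette (leaves b ≈ 30–40, flowers b ≈ 75–85).

Components < 100 px are dropped (exactly 100 survives). Anthesis is the
first imaging day with a surviving component — deliberately with no bud
filter, so yellow petals protruding from buds are a known false-positive
mode. Flower-count estimation splits clumps: a component ≤ 1.5 ×
`flower_ref_px` counts as one flower, larger ones as
`round_half_up(pixels / flower_ref_px)` (at least 1). `flower_ref_px` — the
pixel area of one fully open flower in top view — is a per-rig calibration
constant (113 px for the generator's radius-6 discs); the 1.5 split factor
and half-up rounding are package conventions.

Canopy width is the x-span of all component bounding boxes; canopy angle is
the apex angle `2·atan(width / (2·height))` of the isoceles triangle with
that width standing on the side-view plant height — a package definition
for a trait that is usually only named, not formalized. Raceme-branch
assignment cuts a complete-linkage hierarchical tree (Euclidean distance on
min x, max x, min y, max y, centroid x, centroid y) into *k* flat clusters;
*k* comes from a manual count or a model prediction, and only the partition
(not the label numbering) is meaningful.

## Models

Branch-count prediction is regression, not classification: counts are
many-valued and long-tailed. "Accuracy" for integer counts is not standard;
here it is the fraction of predictions matching the true count after
half-up rounding, with `1 − MAPE` reported alongside as a threshold-free
alternative. Features: DAS, flower pixels, estimated flower count, with
drop-one subsets supported (flower pixels and component count are nearly
collinear).

Stress classification uses a 20-feature panel in a fixed canonical order
(NIR mean and p75; top/side pixel and hull areas with their Δs; pot weight
before/after watering; area below rim; height and width with Δs; ExG;
ordinal flowering group early/intermediate/late = 0/1/2 from anthesis
terciles; branch count). Plant height is measured in the side view, width
in the top view. The majority class is down-sampled without replacement to
the minority size before CV.

Folds are shuffled, unstratified partitions (sizes within 1); the seed is
recorded in every report. ROC AUC is computed from the Mann–Whitney rank
statistic with ties counting ½ — an implementation cross-checked in tests
against scikit-learn's reference, which is never used as the pipeline's own
scorer. Classifier hyperparameters are library defaults except KNN with
K = 1. Folds whose training or test labels collapse to a single class are
skipped and the report flagged. Regression on an all-constant feature
matrix is flagged rather than refused.

## Synthetic generator

The generator states a world and keeps it fixed: rosettes of 6–10 ruffled
elliptical leaves (length 50–68 px, aspect 0.38–0.52, hue 108–122°) around
the pot center, saturating growth `1 − exp(−rate·(DAS − 10))` with rate
0.06–0.10/day, flowering onset uniform on 41–51 DAS, 1–6 raceme branches.
Flowers are radius-6 yellow discs (113 px) in per-branch clusters; each
branch reaches its steady-state load of 4 open flowers by the first
flowering observation, so flower output is linear in branch count — the
regime the branch regression assumes. By default neighboring flowers
overlap into clumps (exercising the split rule); `flower_overlap=False`
renders disjoint flowers for exactness tests.

Drought symptoms from the onset day (default 4 days into treatment):
projected area shrinks 3%/day, leaf boundaries ruffle sinusoidally
(amplitude 0.18, frequency 9 lobes), hue shifts 9° toward yellow
(depressing greenness), NIR plant intensity drops 22 levels, and pots are
watered to a lower target weight. The NIR camera renders at half the RGB
resolution with a fixed (3, 2) px offset — a known registration the
transfer stage must reproduce. One integer seed drives everything through
`SeedSequence` children per plant-day; a control/stress pair at equal seed
consumes the random stream identically, giving true morphological twins.

Not emulated: petal geometry, leaf occlusion and tearing, soil texture,
specular lighting, camera motion, watering-system failures, or
genotype-by-treatment interaction beyond the stress transforms. A green
test on this world therefore establishes that the pipeline measures what
the generator renders — it does not certify performance on facility imagery,
where threshold tables and the flower reference area must be recalibrated
and segmentation quality dominates.

## Numerical conventions and degenerate inputs

- Percentiles: linear interpolation. Rounding of count predictions and
  clump splits: half-up (not banker's).
- Thresholds are inclusive bands; `low > high` is a config error.
- Empty plant mask → flagged zero traits; empty flower set → zero flowers,
  missing canopy metrics; empty transferred NIR mask → missing summaries.
- Small-object removal and hole filling are strict (`< size`), monotone in
  their size parameter.
- AUC requires both classes; single-class folds are skipped, not imputed.

## Limitations

Real threshold tables for segmentation and flower detection must be tuned
per campaign; the defaults only bracket the synthetic palette. The
registration helper assumes no rotation. Anthesis calling inherits the
bud-protrusion false-positive mode by design. Branch-count regression
presumes flower output roughly proportional to branch count; genotypes with
strongly unequal per-branch flowering would need richer features. No
physical-unit calibration (px→mm) is attempted.
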