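# Methods

This note documents the models, numerical choices, and limitations behind
each pipeline, and what the synthetic generators do and do not emulate.

## Geospatial plumbing

Orthomosaics and elevation rasters are read and written as GeoTIFFs through
`tifffile`, handling the ModelPixelScale/ModelTiepoint tag pair (north-up
affine transforms), the GeoKey EPSG code, and the GDAL nodata convention.
Plot boundaries are GeoJSON polygons (attribute `plot_id`); an inward buffer
in meters guards against neighboring-plot bleed. Rasterization uses the
center rule: a pixel belongs to a plot iff its center lies inside the
polygon, matching common zonal-statistics behavior and making clips of
pixel-aligned rectangles exact. Plot images are resized with
nearest-neighbor interpolation by default (destination index *i* maps to
source index ⌊i·src/dst⌋), which preserves raw digital numbers for index
math; bilinear is selectable. Nodata pixels are excluded from all
statistics, never zero-filled.

## Vegetation indices

GLI and ExG − ExR are computed in floating point on raw digital numbers
(0–255), not reflectance — consistent with an uncalibrated RGB sensor.
GLI is undefined where r = g = b = 0; those pixels are treated like nodata
and excluded from plot means rather than mapped to 0. The ExG − ExR
binarization threshold defaults to 0 (the sign rule): the index is an
explicit green-vs-red contrast, so its zero crossing is the natural
soil/vegetation boundary. Both the index choice and threshold are
configurable; other RGB indices are extension points.

## Classical maturity (LOESS / SEG)

Per-plot mean GLI over 6–9 flights is fitted with either:

* **LOESS** — tricube-weighted local polynomials. Defaults: span 0.75,
  degree 2, evaluated on a 0.1-day grid. With only 6–9 observations a
  smaller span leaves too few points per neighborhood for a quadratic;
  span is floored so each local fit stays solvable.
* **Segmented regression** — a continuous piecewise-linear fit in the hinge
  basis {1, t, (t − b)₊}. Breakpoints (default 2) are chosen by exhaustive
  SSE search on a coarse 1-day grid followed by local refinement at the
  0.1-day grid step; with ≤ 9 observations the least-squares solves are tiny
  and the two-stage search gives the same optimum as a full fine-grid pair
  search at a fraction of the cost.

Maturity is the first grid day at which the fitted curve falls to ≤ 0.06,
linearly interpolated between the bracketing grid points. Greenness can dip
spuriously early in the window, so the search starts at the curve maximum;
a curve that never reaches the threshold is flagged `never_crossed` rather
than forced to a number, and a curve already below threshold crosses at the
first grid day. Raising the threshold can only move the crossing earlier on
a monotone-declining curve, which the tests assert.

Known bias: both fitters carry model bias on a logistic-shaped decline
(a piecewise-linear or locally-quadratic approximation of a sigmoid),
about ±1 day at 6 flights even with zero noise and larger near the edges of
the flight window. The recovery tests therefore bound the *mean absolute
error* (≤ 1.5 days over 200 plots), not per-plot agreement with the grid
resolution.

## CNN-LSTM maturity regressor

Architecture: four time-distributed convolution blocks (3×3 'same' kernels,
ReLU, 2×2 max pool stride 2), flatten, dropout (default 20 %), single-layer
LSTM (default 256 units), linear 1-unit head. Weights are Xavier-uniform,
seeded; images are scaled to [0, 1]. The default filter ladder is
(16, 32, 64, 128); filters, kernel, LSTM width and the rest are config. The
loss is the standard Huber with δ = σ (default 0.1 days): quadratic within
σ, linear beyond, so badly-scored plots do not dominate. The optimizer is
Adam with per-epoch learning-rate decay lr/(1 + decay·epoch); the default
decay 10⁻³ follows the convention that "decay" modifies the learning rate,
not the weights.

The network and its backpropagation are written directly in NumPy (im2col
convolutions, BPTT through the LSTM), in float32, single-threaded and
deterministic given the seed; seeds for initialization, dropout,
shuffling, splitting, and augmentation are derived independently.

Two numerical choices matter in practice:

* **Label standardization.** The head regresses z-scores of the training
  labels (mean/std stored with the checkpoint, predictions returned in
  days). Without it, day-scale targets (≈ 70–90) are unreachable within a
  few hundred Adam steps.
* **Optimization on tiny sets.** With σ = 0.1 days the Huber loss is
  effectively an L1 loss, and on a 16-plot set the optimizer can fall into
  a symmetric trap: predictions collapse to the label median, per-sample
  gradients cancel through the shared weights, and training stalls with a
  vanishing gradient. Whether an initialization escapes depends
  unpredictably on the data/init pair, so `train_with_restarts` applies the
  standard remedy for small nonconvex fits: deterministic restarts cycling
  through three symmetry-breaking init variants (baseline, LSTM input
  weights ×8, head weights ×8) and then fresh seeds, with a collapsed
  attempt recognized early (prediction spread < 0.5 days at epoch 20) and
  abandoned. With batch 4, lr 3·10⁻³, no decay and no dropout, the restart
  loop drove a 16-plot, 6-flight, 64×256 stack below 1 day of training MAE
  on every data seed probed, in 1–3 attempts.

GDD fusion: daily GDD = max(0, (tmax + tmin)/2 − tbase), accumulated from
planting and sampled at each flight's days-after-planting; base temperature
defaults to 10 °C (standard for beans) and the computation is config since
thermal-time conventions vary. The cumulative value at each flight (scaled
by 10⁻³) passes through a small dense+ReLU embedding and is concatenated
with that flight's CNN feature vector before the LSTM.

Augmentation perturbs a chosen fraction of training plots with one of:
constant brightness shift, contrast scaling about the image mean, or
Gaussian blur — photometric changes that emulate cloudiness and sun-angle
variation across flights; labels are untouched. Splitting is stratified by
environment (equal test share from each), with 10 % of the remaining
training pool held out for validation.

## Stand counting

Both classical counters take any {0, 1} vegetation mask; the in-repo mask
source is ExG − ExR binarization, and a learned segmenter can be plugged in.

* **Contour chain**: mask rendered as 0/255 grayscale → 5×5 Gaussian blur
  (σ = 1.1, the blur a 5×5 kernel implies) → Canny (L2 gradient) → dilation
  with a 5×5 kernel for 100 iterations → 3×3 closing → external-contour
  count. The iterated square dilation is computed exactly as a single
  Chebyshev-radius-200 dilation via a chessboard distance transform, and
  the external-contour count equals the 8-connected component count of the
  closed image. Note the geometry this implies: each edge ring grows by
  200 px, so blobs merge when centers come within roughly 2·(r + 202) px
  (more diagonally, where the square structuring element reaches √2
  farther). Counting is only exact for very widely separated plants —
  consistent with this chain being the weakest counter in practice.
* **Watershed chain**: blur → Euclidean distance transform → local maxima
  with min_distance 40 px as markers (3×3-connected labeling) → watershed
  constrained to the mask; the count is the number of segments. Peaks
  ≥ 40 px apart split merged plant pairs; peaks closer than that are
  deliberately suppressed, so two plants closer than 40 px (≈ 8 cm at
  0.2 cm/px) count as one.

Detection evaluation uses greedy one-to-one matching (predictions in
descending score order claim the unmatched GT box of highest IoU ≥ 0.5);
Hungarian assignment is available and agrees on unambiguous layouts. Boxes
are half-open pixel rectangles, so IoU equals a pixel-rasterization count
exactly for integer boxes. Metrics: P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), Ac = TP/(TP+FP+FN); undefined ratios are NaN, never 0.
Pseudo-labeling keeps detections with score ≥ 0.5 as training annotations
(an optional GT-agreement mode filters by IoU against reference boxes
instead); inference keeps boxes at score ≥ 0.1. The detector itself is a
pluggable interface; the repository ships a deterministic mock detector
(seeded jitter of known layouts plus optional low-score spurious boxes)
that exercises matching, thresholding, and pseudo-labeling.

## Plant distribution

Plant centroids (box centers) are sorted along the row axis — by default
the axis of larger coordinate spread, since row plots are much longer than
wide — and consecutive center-to-center Euclidean distances are converted
to cm by the GSD (an along-row projected distance is optional). Distances
< 4 cm flag *jointed* plants, > 15 cm flag gaps; the boundary values are
normal (strict inequalities). A plot with fewer than 10 flagged instances
is labeled `acceptable`, otherwise `poor`. Multi-row plots should be
assessed row by row; cross-row neighbor pairing would inflate distances.

## Plant height

All quantiles use linear interpolation between order statistics (the
"type 7" rule); on small samples the convention shifts bounds, so it is
fixed package-wide. The quantile method takes soil as the *median of values
at or below* the q_soil quantile (≤, inclusive) and vegetation as the q_veg
quantile; defaults q_soil 0.25, q_veg 0.99. When a DTM exists the
CSM-difference path is preferred and plot height is the q_veg quantile of
in-plot CSM values. Negative heights (noise pushing soil above vegetation)
are reported as-is with a flag rather than clamped, so downstream outlier
filtering sees them. Point-cloud z-values are denoised with the 1.5×IQR
filter before quantile extraction; the same filter serves as the generic
outlier step (quartiles by the same type-7 rule). Per-plot estimates from
2–3 flights are averaged arithmetically.

## Synthetic generators

All generators are pure functions of parameters + seed.

* **Senescence**: plot-mean GLI follows a logistic decline from 0.20 to
  0.02 with rate 0.35 d⁻¹ (a roughly two-week dry-down), parameterized so
  the noiseless curve crosses 0.06 exactly at the plot's true maturity day;
  flights default to 6 dates spanning days 60–100, true maturities uniform
  on 70–92, Gaussian noise σ = 0.005 on the plot means.
* **Maturity image stacks**: each pixel is green (GLI ≈ 0.45) or brown
  (GLI ≈ 0.019) with a date-dependent mixing probability chosen so the
  plot-mean per-pixel GLI reproduces the scalar series (binomial error
  < 0.01 at 64×256). This encodes maturity purely in color composition —
  the feature the CNN is meant to read — but contains no canopy texture,
  shadows, weeds, or registration error; recovery on these stacks shows
  the estimator machinery works, not that real-field accuracy is attained.
* **Plot images**: green ellipse blobs (radius ~12 px, jittered) in 1–2
  rows on noisy soil, 66–166 plants per plot, with ground-truth boxes;
  jointed pairs (3 cm) and gaps (20 cm) can be planted at known indices.
  Soil noise is kept small enough that the ExG − ExR sign rule recovers
  the blob mask to < 1 % pixel error; real soil/residue variation is far
  messier.
* **Elevation fields**: a gently tilted soil plane (gradients ~4 mm/m)
  with one parabolic canopy dome per plot over an inscribed ellipse
  (~64 % cover). The dome's elevation-above-soil distribution is uniform
  on (0, h), a rounded-canopy stand-in for photogrammetric surface models;
  apex heights are uniform on 20–70 cm, pixel and point noise σ = 1 cm,
  DTM = noiseless soil plane, point cloud ~2000 pts/m² from the same
  surface. Under these conditions the quantile method is nearly unbiased
  (soil-statistic bias ≈ −0.4 cm against vegetation-quantile bias
  ≈ −0.016·h), which is what makes ≤ 2 cm MAE achievable; real fields add
  SfM artifacts, wind-blown leaves, and georeferencing error that this
  surface does not model.

## Problem sizes

The recovery checks run at: 200 plots × 6 flights for classical maturity;
100 plots for plant height; 0–20 blobs per mask for counter exactness
(contour-chain masks are large because of the 200 px merge radius); 16
plots at 64×256 for the CNN-LSTM capacity check, with reduced filter
counts (8, 16, 32, 64) and a 64-unit LSTM; smaller configurations of the
same shapes appear in the unit tests for fast feedback. These sizes were
chosen to exercise each method's full path at desk scale.

## Known limitations

* The classical counters assume a clean binary mask; mask quality (weeds,
  shadow, residue) dominates their real-world error and is out of scope.
* The CNN-LSTM is a CPU-scale NumPy implementation; it is intended for
  method validation and small trials, not for training at the scale of
  multi-environment imagery archives.
* Shapefile input is not supported; plot boundaries are GeoJSON. LAS point
  clouds are not parsed; xyz text/CSV is.
* Calendar re-basing of maturity (days after a fixed reference date) is
  left to the user; the package reports days after planting.
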