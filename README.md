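# beanpheno

Drone-based plot-level phenotyping for dry bean (*Phaseolus vulgaris* L.)
breeding trials: **relative maturity** (RM), **stand count** (SC), and
**plant height** (PH) from RGB orthomosaics, elevation models, and point
clouds.

Breeding programs score hundreds of plots for maturity date, emerged-plant
counts, and canopy height by walking the field. This package implements the
corresponding image-based pipelines for data a standard RGB drone + SfM
photogrammetry workflow already produces (orthomosaic, DSM/DTM, point
cloud), plus synthetic-field generators so every pipeline can be tested
end-to-end against known ground truth without any imagery downloads.

## What it computes

**Relative maturity.** Plot-mean greenness leaf index
GLI = (2G − R − B)/(2G + R + B) declines as pods brown down. Per plot, a
curve is fitted through the per-flight means — LOESS (tricube local
polynomials) or segmented regression (continuous piecewise-linear with
SSE-searched breakpoints) — and maturity is the first day the fitted curve
falls to the 0.06 threshold after its seasonal maximum. Alternatively, a
CNN-LSTM consumes the plot-image sequence directly: four time-distributed
convolutional layers embed each flight image, an LSTM reads the sequence,
and a linear head regresses maturity in days after planting, trained with a
Huber loss (σ = 0.1) under Adam; cumulative growing degree days (GDD) can be
fused into the per-flight features through a small dense subnetwork. The
network is implemented in pure NumPy with hand-written backpropagation.

**Stand count.** An ExG − ExR mask ((2g − r − b) − (1.4r − g) > 0) separates
seedlings from soil. Two classical counters operate on the mask: a contour
chain (Gaussian blur → Canny → 5×5 dilation ×100 → 3×3 closing → external
contours) and a watershed chain (blur → Euclidean distance transform → local
maxima ≥ 40 px apart → marker-based watershed). A detection harness converts
VIA annotations to COCO boxes, matches predictions to ground truth
one-to-one at IoU ≥ 0.5, reports P = TP/(TP+FP), R = TP/(TP+FN),
F1, Ac = TP/(TP+FP+FN), and supports pseudo-labeling behind a pluggable
detector interface.

**Plant distribution.** Box centroids sorted along the row give neighbor
distances in cm via the ground sample distance; pairs < 4 cm are flagged
*jointed*, gaps > 15 cm are flagged, and plots with fewer than 10 flagged
instances are labeled acceptable.

**Plant height.** With a bare-soil DTM, CSM = DSM − DTM and plot height is a
high quantile of in-plot CSM values. Without one, the in-plot elevation
distribution is split: soil = median of values at or below the q_soil
quantile (0.25/0.5), vegetation = the q_veg quantile (0.9/0.99), height =
vegetation − soil. Point clouds take the same path after 1.5×IQR denoising;
multi-flight estimates are averaged.

## Worked example

```sh
beanpheno simulate --what maturity --out fixtures --seed 1 --n-plots 12
beanpheno maturity classical --vi-csv fixtures/vi_series.csv \
    --method loess --out maturity.csv
beanpheno evaluate --pred-csv maturity.csv --gt-csv fixtures/truth.csv \
    --pred-col maturity_dap --gt-col true_maturity_dap --out metrics.json
```

`maturity.csv` holds one row per plot, e.g.

```
plot_id,method,maturity_dap,status,threshold
P0000,LOESS,82.5635,crossed,0.06
P0001,LOESS,93.7398,crossed,0.06
```

— the estimated maturity in days after planting, how the threshold was
reached (`crossed` vs `never_crossed`), and the threshold used.
`metrics.json` then reports the recovery accuracy against the generator's
true crossing days:

```json
{"n": 12, "mae": 1.3181, "mse": 2.3387, "rmse": 1.5293, "r": 0.9973, "r2": 0.9946}
```

i.e. the LOESS + 0.06-threshold pipeline recovers the true maturity of these
synthetic plots to within about 1.3 days on average, with r ≈ 0.997 against
truth. The same pattern works for the other pipelines: `simulate --what
elevation` + `beanpheno height`, and `simulate --what field` + `beanpheno
standcount classical` / `plantdist`.

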