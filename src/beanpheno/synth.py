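"""Synthetic field-trial data with known ground truth.

Every pipeline in the package is exercised against these generators:

* senescence: per-plot logistic green-down curves of mean GLI over 6-9
  flights, parameterized so the noiseless curve crosses the maturity
  threshold exactly at the declared true maturity day;
* maturity image stacks: plot images whose green/brown pixel mixture is tied
  to the senescence curve, so plot-mean GLI follows the scalar series;
* plot images for stand counting: green plant blobs at known centers on a
  textured soil background, with ground-truth boxes and optionally planted
  jointed pairs (< 4 cm) and gaps (> 15 cm) at known indices;
* elevation fields: a tilted soil plane with per-plot parabolic canopy domes
  of known apex height, rendered as DSM/DTM rasters and sampled as a point
  cloud.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box as shapely_box

from .geotiff import Affine
from .geoplots import FlightRecord, PlotImageSeries, PlotShape, Raster
from .vegindex import VITimeSeries, gli

# Colors chosen so GLI and ExG-ExR separate vegetation from soil the way a
# real canopy does: green pixels GLI ~ 0.45, senesced/brown pixels ~ 0.019.
GREEN_RGB = (60, 160, 60)
BROWN_RGB = (132, 110, 80)
SOIL_RGB = (120, 100, 80)


@dataclass
class SenescenceParams:
    """Green-down trajectories: GLI decays logistically through maturity."""

    n_plots: int = 200
    flight_days: tuple = (60, 68, 76, 84, 92, 100)
    maturity_range: tuple[float, float] = (70.0, 92.0)
    initial: float = 0.20           # pre-senescence plot-mean GLI
    final: float = 0.02             # fully brown plot-mean GLI
    steepness: float = 0.35         # logistic rate (1/day); ~2-week dry-down
    noise_sigma: float = 0.005
    threshold: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.final < self.threshold < self.initial:
            raise ValueError("threshold must lie strictly between final and initial GLI")
        days = np.asarray(self.flight_days, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("flight days must be strictly increasing")
        lo, hi = self.maturity_range
        if not days[0] <= lo <= hi <= days[-1]:
            raise ValueError("flight days must span the maturity range")


def senescence_curve(t, true_day: float, p: SenescenceParams) -> np.ndarray:
    """Noiseless logistic GLI(t) crossing ``p.threshold`` exactly at true_day."""
    amplitude = (p.initial - p.final) / (p.threshold - p.final)
    t0 = true_day - np.log(amplitude - 1.0) / p.steepness
    return p.final + (p.initial - p.final) / (
        1.0 + np.exp(p.steepness * (np.asarray(t, dtype=float) - t0)))


def gen_senescence_series(p: SenescenceParams) -> tuple[list[VITimeSeries], np.ndarray]:
    """Per-plot noisy GLI series plus the true maturity days."""
    rng = np.random.default_rng(p.seed)
    days = np.asarray(p.flight_days, dtype=float)
    true_days = rng.uniform(*p.maturity_range, size=p.n_plots)
    series = []
    for i, td in enumerate(true_days):
        values = senescence_curve(days, td, p)
        if p.noise_sigma:
            values = values + rng.normal(0.0, p.noise_sigma, size=days.size)
        series.append(VITimeSeries(plot_id=f"P{i:04d}", days=days,
                                   values=np.clip(values, -1.0, 1.0)))
    return series, true_days


def gen_maturity_image_stack(p: SenescenceParams,
                             image_size: tuple[int, int] = (64, 256)
                             ) -> tuple[PlotImageSeries, np.ndarray]:
    """Image stack whose plot-mean GLI follows the senescence series.

    Each pixel is green or brown with a date-dependent mixing probability;
    since the plot mean of per-pixel GLI is linear in the green fraction, the
    stack reproduces the scalar series up to binomial sampling error.
    Returns (stack, true maturity days) - the labels for the CNN-LSTM.
    """
    series, true_days = gen_senescence_series(p)
    rng = np.random.default_rng(p.seed + 1)
    h, w = image_size
    gli_green = gli(*GREEN_RGB)
    gli_brown = gli(*BROWN_RGB)
    flights = [FlightRecord(f"day{d:03d}", int(d), 0.5) for d in p.flight_days]
    n_f, n_p = len(p.flight_days), p.n_plots
    data = np.empty((n_f, n_p, h, w, 3), dtype=np.uint8)
    green = np.array(GREEN_RGB, dtype=np.uint8)
    brown = np.array(BROWN_RGB, dtype=np.uint8)
    for j, s in enumerate(series):
        frac = np.clip((s.values - gli_brown) / (gli_green - gli_brown), 0.0, 1.0)
        for i in range(n_f):
            is_green = rng.random((h, w)) < frac[i]
            data[i, j] = np.where(is_green[..., None], green, brown)
    stack = PlotImageSeries(data=data, flights=flights,
                            plot_ids=[s.plot_id for s in series])
    return stack, true_days


@dataclass
class FieldSimParams:
    """Geometry shared by the stand-count and plant-height simulations."""

    # stand-count plot images
    image_size: tuple[int, int] = (640, 3872)        # (height, width) pixels
    image_gsd_cm: float = 0.2
    plants_range: tuple[int, int] = (66, 166)
    blob_radius_px: float = 12.0
    rows_per_plot: int = 2
    jointed_at: tuple = ()          # pair indices forced closer than 4 cm
    gap_at: tuple = ()              # pair indices forced wider than 15 cm
    # elevation field
    n_plots: int = 100
    plot_size_m: tuple[float, float] = (2.0, 1.0)    # (along-row, across-row)
    alley_m: float = 0.4
    elevation_gsd_m: float = 0.02
    soil_z0_m: float = 100.0
    soil_tilt: tuple[float, float] = (0.004, -0.003)
    height_range_cm: tuple[float, float] = (20.0, 70.0)
    noise_sigma_m: float = 0.01                      # 1 cm pixel noise
    canopy_fraction: float = 0.45                    # dome semi-axes / plot half-size
    cloud_density_per_m2: float = 2000.0
    seed: int = 0


def gen_plot_image(p: FieldSimParams, n_plants: int | None = None,
                   seed: int | None = None):
    """One stand-count plot: image, ground-truth boxes, count, centers.

    Plants are green ellipse blobs in ``rows_per_plot`` rows on noisy soil.
    Nominal within-row spacing is jittered but kept inside the (4, 15) cm
    normal band; ``jointed_at``/``gap_at`` override the distance after those
    pair indices (row 0) to plant known spacing defects.
    Returns (image uint8, AnnotationSet, true_count, centers (n, 2)).
    """
    from .standcount import AnnotationSet, Box

    rng = np.random.default_rng(p.seed if seed is None else seed)
    h, w = p.image_size
    if n_plants is None:
        n_plants = int(rng.integers(p.plants_range[0], p.plants_range[1] + 1))
    # soil noise kept small enough that ExG-ExR stays negative over soil
    image = (SOIL_RGB + rng.normal(0, 5, size=(h, w, 3))).clip(0, 255).astype(np.uint8)

    rows = p.rows_per_plot
    per_row = [n_plants // rows + (1 if r < n_plants % rows else 0) for r in range(rows)]
    ys = [h * (r + 1) / (rows + 1) for r in range(rows)]
    margin = 4 * p.blob_radius_px
    centers, boxes = [], []
    for r, (n_row, y0) in enumerate(zip(per_row, ys)):
        if n_row == 0:
            continue
        spacing = (w - 2 * margin) / max(n_row - 1, 1)
        gaps = np.full(max(n_row - 1, 0), spacing)
        gaps *= rng.uniform(0.85, 1.15, size=gaps.size)
        if r == 0:
            for i in p.jointed_at:
                if i < gaps.size:
                    gaps[i] = 3.0 / p.image_gsd_cm      # 3 cm < 4 cm: jointed
            for i in p.gap_at:
                if i < gaps.size:
                    gaps[i] = 20.0 / p.image_gsd_cm     # 20 cm > 15 cm: gap
        xs = margin + np.concatenate([[0.0], np.cumsum(gaps)])
        xs = np.clip(xs, margin / 2, w - margin / 2)
        for x0 in xs:
            rx = p.blob_radius_px * rng.uniform(0.8, 1.2)
            ry = p.blob_radius_px * rng.uniform(0.8, 1.2)
            y_j = y0 + rng.uniform(-0.1, 0.1) * p.blob_radius_px
            _draw_ellipse(image, x0, y_j, rx, ry, rng)
            centers.append((x0, y_j))
            boxes.append(Box(x=x0 - rx, y=y_j - ry, w=2 * rx, h=2 * ry))
    ann = AnnotationSet(plot_id="sim_plot", boxes=boxes, image_size=(h, w),
                        provenance="manual")
    return image, ann, len(boxes), np.array(centers)


def _draw_ellipse(image, cx, cy, rx, ry, rng):
    h, w = image.shape[:2]
    x0, x1 = max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, w)
    y0, y1 = max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    xx, yy = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    patch = image[y0:y1, x0:x1]
    color = GREEN_RGB + rng.normal(0, 6, size=(inside.sum(), 3))
    patch[inside] = color.clip(0, 255).astype(np.uint8)


def gen_disk_mask(k: int, radius: int = 15, spacing: int = 700,
                  seed: int = 0, jitter: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask of ``k`` well-separated disks on a grid with jitter.

    The default spacing keeps neighbors beyond the merge distance of the
    heavily-dilating contour chain (whose Chebyshev ball reaches ~2*(r+202)
    px diagonally); watershed-only fixtures can use much tighter spacing.
    Returns (mask, centers (k, 2) as (x, y)).
    """
    rng = np.random.default_rng(seed)
    if k == 0:
        return np.zeros((4 * radius, 4 * radius), dtype=np.uint8), np.empty((0, 2))
    ncols = int(np.ceil(np.sqrt(k)))
    nrows = int(np.ceil(k / ncols))
    pad = spacing // 2
    h = (nrows - 1) * spacing + 2 * pad
    w = (ncols - 1) * spacing + 2 * pad
    mask = np.zeros((h, w), dtype=np.uint8)
    centers = []
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(k):
        r, c = divmod(i, ncols)
        cx = pad + c * spacing + rng.uniform(-jitter, jitter) * spacing
        cy = pad + r * spacing + rng.uniform(-jitter, jitter) * spacing
        mask |= ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2).astype(np.uint8)
        centers.append((cx, cy))
    return mask, np.array(centers)


def gen_elevation_field(p: FieldSimParams):
    """Tilted soil plane with per-plot canopy domes of known apex height.

    Each plot's canopy is a parabolic dome over an inscribed ellipse: its
    elevation-above-soil distribution is uniform on (0, h), so a rounded
    canopy top is represented the way photogrammetric surface models see
    real plots.  The DSM adds Gaussian pixel noise; the DTM is the noiseless
    soil plane; the point cloud samples the same surface at random positions
    with its own noise.

    Returns (dsm, dtm, cloud (n, 3), shapes, true_heights_cm).
    """
    rng = np.random.default_rng(p.seed)
    ncols = int(np.ceil(np.sqrt(p.n_plots)))
    nrows = int(np.ceil(p.n_plots / ncols))
    plot_l, plot_w = p.plot_size_m
    pitch_x = plot_l + p.alley_m
    pitch_y = plot_w + p.alley_m
    field_w = ncols * pitch_x + p.alley_m
    field_h = nrows * pitch_y + p.alley_m
    gx, gy = p.soil_tilt

    true_heights = rng.uniform(*p.height_range_cm, size=p.n_plots)

    origin_x, origin_y = 500000.0, 4300000.0
    gsd = p.elevation_gsd_m
    npx = int(np.ceil(field_w / gsd))
    npy = int(np.ceil(field_h / gsd))
    transform = Affine(gsd, 0.0, origin_x, 0.0, -gsd, origin_y)

    # pixel-center world coordinates; y decreases downward
    xs = origin_x + (np.arange(npx) + 0.5) * gsd
    ys = origin_y - (np.arange(npy) + 0.5) * gsd
    xg, yg = np.meshgrid(xs - origin_x, origin_y - ys)   # local coords >= 0
    soil = p.soil_z0_m + gx * xg + gy * yg

    canopy = np.zeros_like(soil)
    shapes = []
    plot_geoms = []
    for i in range(p.n_plots):
        r, c = divmod(i, ncols)
        x0 = p.alley_m + c * pitch_x
        y0 = p.alley_m + r * pitch_y
        plot_geoms.append((x0, y0))
        shapes.append(PlotShape(
            plot_id=f"P{i:04d}",
            polygon=shapely_box(origin_x + x0, origin_y - (y0 + plot_w),
                                origin_x + x0 + plot_l, origin_y - y0)))
        cx, cy = x0 + plot_l / 2, y0 + plot_w / 2
        ax, ay = p.canopy_fraction * plot_l, p.canopy_fraction * plot_w
        rho2 = ((xg - cx) / ax) ** 2 + ((yg - cy) / ay) ** 2
        inside = rho2 < 1.0
        canopy[inside] = np.maximum(
            canopy[inside], true_heights[i] / 100.0 * (1.0 - rho2[inside]))

    dsm_values = soil + canopy + rng.normal(0.0, p.noise_sigma_m, size=soil.shape)
    dsm = Raster(values=dsm_values, transform=transform, crs_epsg=32616)
    dtm = Raster(values=soil.copy(), transform=transform, crs_epsg=32616)

    n_points = int(p.cloud_density_per_m2 * field_w * field_h)
    px = rng.uniform(0, field_w, size=n_points)
    py = rng.uniform(0, field_h, size=n_points)
    pz = p.soil_z0_m + gx * px + gy * py
    for i, (x0, y0) in enumerate(plot_geoms):
        cx, cy = x0 + plot_l / 2, y0 + plot_w / 2
        ax, ay = p.canopy_fraction * plot_l, p.canopy_fraction * plot_w
        rho2 = ((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2
        inside = rho2 < 1.0
        pz[inside] += true_heights[i] / 100.0 * (1.0 - rho2[inside])
    pz += rng.normal(0.0, p.noise_sigma_m, size=n_points)
    cloud = np.column_stack([origin_x + px, origin_y - py, pz])

    return dsm, dtm, cloud, shapes, true_heights
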