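"""Per-plot plant height from elevation rasters or point clouds.

When a bare-soil digital terrain model (DTM) exists, the crop surface model
CSM = DSM - DTM gives above-ground height directly and a single high
quantile of the in-plot CSM values is the plot height.  Without a DTM, the
in-plot elevation distribution itself is split: soil is the median of values
at or below the q_soil quantile (0.25 or 0.5), vegetation is the q_veg
quantile (0.9 or 0.99), and their difference is the plot height.  Point
clouds take the same quantile path after an IQR denoising pass on the
z-values; multi-flight estimates are averaged.  All quantiles use linear
interpolation between order statistics (the "type 7" rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geoplots import PlotShape, Raster, polygon_pixel_mask


@dataclass
class ElevationSample:
    plot_id: str
    values: np.ndarray            # elevations (m)
    source: str                   # DSM | CSM | PC

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.source not in ("DSM", "CSM", "PC"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class HeightParams:
    q_soil: float = 0.25
    q_veg: float = 0.99
    kout: float = 1.5
    source_preference: str = "csm"    # csm when a DTM exists, else quantile

    def __post_init__(self) -> None:
        if not 0 < self.q_soil < self.q_veg <= 1:
            raise ValueError("require 0 < q_soil < q_veg <= 1")
        if self.kout <= 0:
            raise ValueError("kout must be > 0")


@dataclass
class PlotHeight:
    plot_id: str
    height_cm: float
    method: str                        # quantile-subtraction | csm-difference
    source: str
    per_flight_cm: list[float] = field(default_factory=list)
    n_flights: int = 1
    flags: list[str] = field(default_factory=list)


def csm_difference(dsm: Raster, dtm: Raster) -> Raster:
    """Per-pixel DSM - DTM; grids must be co-registered; nodata propagates."""
    if dsm.values.shape != dtm.values.shape:
        raise ValueError(
            f"grid mismatch: DSM {dsm.values.shape} vs DTM {dtm.values.shape}")
    if dsm.transform != dtm.transform or dsm.crs_epsg != dtm.crs_epsg:
        raise ValueError("DSM and DTM are not co-registered (transform/CRS differ)")
    bad = dsm.nodata_mask() | dtm.nodata_mask()
    csm = dsm.values - dtm.values
    csm[bad] = np.nan
    return Raster(values=csm, transform=dsm.transform, crs_epsg=dsm.crs_epsg,
                  nodata=None)


def extract_elevation(source, shape: PlotShape, source_tag: str | None = None
                      ) -> ElevationSample:
    """All in-plot elevation values from a raster or an (n, 3) point cloud.

    Raster pixels use the center rule; point clouds use point-in-polygon on
    (x, y).  Nodata/NaN values are excluded; an empty intersection raises.
    """
    polygon = shape.buffered()
    if isinstance(source, Raster):
        inside, (row0, col0) = polygon_pixel_mask(
            source.transform, source.values.shape, polygon)
        win = np.s_[row0:row0 + inside.shape[0], col0:col0 + inside.shape[1]]
        keep = inside & ~source.nodata_mask()[win]
        values = source.values[win][keep]
        tag = source_tag or "DSM"
    else:
        points = np.asarray(source, dtype=float)
        if points.ndim != 2 or points.shape[1] < 3:
            raise ValueError("point cloud must be an (n, >=3) xyz array")
        inside = shapely.contains_xy(polygon, points[:, 0], points[:, 1])
        values = points[inside, 2]
        values = values[np.isfinite(values)]
        tag = source_tag or "PC"
    if values.size == 0:
        raise ValueError(f"plot {shape.plot_id}: no elevation data inside the polygon")
    return ElevationSample(plot_id=shape.plot_id, values=values, source=tag)


def iqr_filter(values: np.ndarray, kout: float = 1.5) -> np.ndarray:
    """Keep values within [Q1 - kout*IQR, Q3 + kout*IQR] (type-7 quartiles).

    Fewer than 4 values pass through unchanged with a warning - quartiles are
    not meaningful there.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("iqr_filter: fewer than 4 values, passing through", stacklevel=2)
        return values
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - kout * iqr, q3 + kout * iqr
    return values[(values >= lo) & (values <= hi)]


def quantile_height(sample: ElevationSample, params: HeightParams | None = None
                    ) -> float:
    """Soil/vegetation quantile split: (q_veg quantile - median of values at
    or below the q_soil quantile) x 100, in cm.

    Negative heights (noise pushing soil above vegetation) are returned as-is
    so downstream outlier filtering can see them.
    """
    params = params or HeightParams()
    v = sample.values
    if v.size == 0:
        raise ValueError(f"plot {sample.plot_id}: empty elevation sample")
    soil_cut = np.quantile(v, params.q_soil)
    soil = np.median(v[v <= soil_cut])
    veg = np.quantile(v, params.q_veg)
    return float((veg - soil) * 100.0)


def csm_plot_height(sample: ElevationSample, q: float = 0.9) -> float:
    """Plot height from CSM values: the q-quantile x 100 (already above ground)."""
    if sample.values.size == 0:
        raise ValueError(f"plot {sample.plot_id}: empty elevation sample")
    return float(np.quantile(sample.values, q) * 100.0)


def average_flights(per_flight_cm: list[float], plot_id: str = "",
                    method: str = "quantile-subtraction",
                    source: str = "DSM") -> PlotHeight:
    """Arithmetic mean of the 1-3 per-flight height estimates."""
    if not per_flight_cm:
        raise ValueError("no per-flight heights to average")
    heights = [float(h) for h in per_flight_cm]
    mean = float(np.mean(heights))
    flags = ["negative_height"] if mean < 0 else []
    return PlotHeight(plot_id=plot_id, height_cm=mean, method=method, source=source,
                      per_flight_cm=heights, n_flights=len(heights), flags=flags)


def heights_from_raster(raster: Raster, shapes: list[PlotShape],
                        params: HeightParams | None = None,
                        is_csm: bool = False) -> pd.DataFrame:
    """Per-plot heights from one DSM (quantile path) or CSM (quantile of CSM)."""
    params = params or HeightParams()
    rows = []
    for shape in shapes:
        sample = extract_elevation(raster, shape,
                                   source_tag="CSM" if is_csm else "DSM")
        if is_csm:
            h = csm_plot_height(sample, q=params.q_veg)
            method = "csm-difference"
        else:
            h = quantile_height(sample, params)
            method = "quantile-subtraction"
        rows.append({"plot_id": shape.plot_id, "method": method,
                     "source": sample.source, "height_cm": h,
                     "flags": "negative_height" if h < 0 else ""})
    return pd.DataFrame(rows)


def heights_from_cloud(points: np.ndarray, shapes: list[PlotShape],
                       params: HeightParams | None = None) -> pd.DataFrame:
    """Per-plot heights from an xyz point cloud, with IQR denoising of z."""
    params = params or HeightParams()
    rows = []
    for shape in shapes:
        sample = extract_elevation(points, shape)
        clean = iqr_filter(sample.values, kout=params.kout)
        h = quantile_height(ElevationSample(shape.plot_id, clean, "PC"), params)
        rows.append({"plot_id": shape.plot_id, "method": "quantile-subtraction",
                     "source": "PC", "height_cm": h,
                     "flags": "negative_height" if h < 0 else ""})
    return pd.DataFrame(rows)


def read_xyz(path) -> np.ndarray:
    """Read a whitespace- or comma-delimited xyz point-cloud text file."""
    try:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        return np.loadtxt(path, ndmin=2)
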