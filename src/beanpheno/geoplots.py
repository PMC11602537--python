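"""Plot extraction from orthomosaics and assembly of multi-flight image stacks.

A breeding trial is flown repeatedly through the season; each flight yields a
georeferenced orthomosaic.  Per-plot images are clipped out of each
orthomosaic with the plot-boundary polygons (optionally shrunk by an inward
buffer so neighboring plots cannot bleed in), resized to a common shape, and
stacked into a 5-axis array ordered (flight, plot, row, column, band) that
feeds the maturity models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape as shapely_shape

from .geotiff import Affine, read_geotiff


@dataclass
class Orthomosaic:
    """Georeferenced RGB raster (digital numbers 0-255)."""

    image: np.ndarray            # (H, W, >=3)
    transform: Affine
    crs_epsg: int | None = None
    nodata: float | None = None

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] < 3:
            raise ValueError(
                f"expected >=3 bands, got array of shape {self.image.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    @property
    def gsd_cm(self) -> float:
        """Ground sample distance in cm/pixel (CRS units assumed meters)."""
        sx, sy = self.transform.pixel_size
        return float((sx + sy) / 2.0 * 100.0)

    def nodata_mask(self) -> np.ndarray:
        """Boolean (H, W) mask of nodata pixels (all bands equal to nodata)."""
        if self.nodata is None:
            return np.zeros(self.shape, dtype=bool)
        return np.all(self.image[..., :3] == self.nodata, axis=-1)


@dataclass
class Raster:
    """Single-band georeferenced raster (elevation models etc.)."""

    values: np.ndarray           # (H, W) float
    transform: Affine
    crs_epsg: int | None = None
    nodata: float | None = None

    def nodata_mask(self) -> np.ndarray:
        mask = ~np.isfinite(self.values)
        if self.nodata is not None:
            mask |= self.values == self.nodata
        return mask


@dataclass(frozen=True)
class PlotShape:
    """A plot boundary polygon with an optional inward buffer (m)."""

    plot_id: str
    polygon: Polygon
    buffer_m: float = 0.0

    def __post_init__(self) -> None:
        if self.buffer_m < 0:
            raise ValueError("buffer must be >= 0")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"plot {self.plot_id}: polygon is not a valid simple ring")

    def buffered(self) -> Polygon:
        if self.buffer_m == 0:
            return self.polygon
        poly = self.polygon.buffer(-self.buffer_m)
        if poly.is_empty:
            raise ValueError(
                f"plot {self.plot_id}: inward buffer {self.buffer_m} m erases the polygon")
        return poly


@dataclass(frozen=True)
class FlightRecord:
    flight_date: str
    days_after_planting: int
    gsd_cm: float
    altitude_m: float | None = None

    def __post_init__(self) -> None:
        if self.days_after_planting < 0:
            raise ValueError("days_after_planting must be >= 0")
        if self.gsd_cm <= 0:
            raise ValueError("gsd_cm must be > 0")


@dataclass
class PlotImageSeries:
    """The 5-axis (flight, plot, row, column, band) stack and its labels."""

    data: np.ndarray
    flights: list[FlightRecord]
    plot_ids: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 5 or self.data.shape[4] != 3:
            raise ValueError("stack must have axes (flight, plot, row, col, 3)")
        if self.data.shape[0] != len(self.flights):
            raise ValueError("flight axis does not match flight records")
        if self.data.shape[1] != len(self.plot_ids):
            raise ValueError("plot axis does not match plot_ids")
        daps = [f.days_after_planting for f in self.flights]
        if any(b <= a for a, b in zip(daps, daps[1:])):
            raise ValueError("days after planting must be strictly increasing")

    @property
    def image_size(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("stack", data=self.data)
            ds.attrs["axes"] = "flight,plot,row,col,band"
            h5.create_dataset("plot_ids", data=np.array(self.plot_ids, dtype="S"))
            h5.create_dataset(
                "days_after_planting",
                data=np.array([f.days_after_planting for f in self.flights]))
            h5.create_dataset(
                "flight_dates", data=np.array([f.flight_date for f in self.flights], dtype="S"))
            h5.create_dataset("gsd_cm", data=np.array([f.gsd_cm for f in self.flights]))

    @classmethod
    def load(cls, path) -> "PlotImageSeries":
        with h5py.File(path, "r") as h5:
            data = h5["stack"][...]
            plot_ids = [s.decode() for s in h5["plot_ids"][...]]
            daps = h5["days_after_planting"][...]
            dates = [s.decode() for s in h5["flight_dates"][...]]
            gsds = h5["gsd_cm"][...]
        flights = [FlightRecord(d, int(dap), float(g))
                   for d, dap, g in zip(dates, daps, gsds)]
        return cls(data, flights, plot_ids)


def load_orthomosaic(path) -> Orthomosaic:
    """Read a >=3-band GeoTIFF into an :class:`Orthomosaic`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"orthomosaic not found: {path}")
    data, transform, epsg, nodata = read_geotiff(path)
    if data.ndim == 2 or (data.ndim == 3 and data.shape[2] < 3):
        raise ValueError(f"expected >=3 bands in {path}, got shape {data.shape}")
    if transform is None:
        raise ValueError(f"{path} carries no georeferencing (missing CRS/geotransform tags)")
    return Orthomosaic(image=data, transform=transform, crs_epsg=epsg, nodata=nodata)


def load_raster(path) -> Raster:
    """Read a single-band GeoTIFF (DSM/DTM/CSM) into a :class:`Raster`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    data, transform, epsg, nodata = read_geotiff(path)
    if data.ndim != 2:
        raise ValueError(f"expected a single-band raster in {path}, got shape {data.shape}")
    if transform is None:
        raise ValueError(f"{path} carries no georeferencing (missing CRS/geotransform tags)")
    return Raster(values=np.asarray(data, dtype=float), transform=transform,
                  crs_epsg=epsg, nodata=nodata)


def polygon_pixel_mask(transform: Affine, raster_shape: tuple[int, int],
                       polygon: Polygon) -> tuple[np.ndarray, tuple[int, int]]:
    """Center-rule rasterization of ``polygon`` restricted to its bounding window.

    Returns (mask, (row0, col0)): a boolean array over the window of rows/cols
    whose pixel centers may fall inside the polygon, and the window origin.
    A pixel belongs to the plot iff its center lies inside the polygon.
    """
    h, w = raster_shape
    xs, ys = polygon.exterior.coords.xy
    cols, rows = transform.colrow(np.asarray(xs), np.asarray(ys))
    col0 = max(int(np.floor(cols.min())), 0)
    col1 = min(int(np.ceil(cols.max())), w)
    row0 = max(int(np.floor(rows.min())), 0)
    row1 = min(int(np.ceil(rows.max())), h)
    if col0 >= col1 or row0 >= row1:
        raise ValueError("polygon does not intersect the raster extent")
    cc, rr = np.meshgrid(np.arange(col0, col1) + 0.5, np.arange(row0, row1) + 0.5)
    cx, cy = transform.xy(cc.ravel(), rr.ravel())
    inside = shapely.contains_xy(polygon, cx, cy).reshape(rr.shape)
    return inside, (row0, col0)


def _resize_nearest(image: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize by index mapping dest i -> floor(i*src/dst)."""
    oh, ow = out_size
    sh, sw = image.shape[:2]
    ri = (np.arange(oh) * sh // oh).astype(int)
    ci = (np.arange(ow) * sw // ow).astype(int)
    return image[np.ix_(ri, ci)]


def _resize_bilinear(image: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize
    out = resize(image.astype(float), out_size + image.shape[2:],
                 order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else out


def clip_plot(ortho: Orthomosaic, plot: PlotShape, out_size: tuple[int, int],
              interpolation: str = "nearest") -> np.ndarray:
    """Clip one plot out of an orthomosaic and resize it to ``out_size``.

    Pixels whose centers fall outside the (buffered) polygon are zeroed before
    resizing; they are excluded, not data.  ``interpolation`` is ``nearest``
    (default, preserves digital numbers) or ``bilinear``.
    """
    oh, ow = out_size
    if oh <= 0 or ow <= 0:
        raise ValueError("out_size must be positive")
    polygon = plot.buffered()
    if polygon.area == 0:
        raise ValueError(f"plot {plot.plot_id}: polygon has zero area")
    inside, (row0, col0) = polygon_pixel_mask(ortho.transform, ortho.shape, polygon)
    if not inside.any():
        raise ValueError(f"plot {plot.plot_id}: no pixel centers inside the polygon")
    window = ortho.image[row0:row0 + inside.shape[0], col0:col0 + inside.shape[1], :3].copy()
    window[~inside] = 0
    # trim to the tight bounding box of in-polygon pixels
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    window = window[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if interpolation == "nearest":
        return _resize_nearest(window, out_size)
    if interpolation == "bilinear":
        return _resize_bilinear(window, out_size)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def build_time_series(images: Mapping[str, Mapping[str, np.ndarray]],
                      flights: Sequence[FlightRecord]) -> PlotImageSeries:
    """Stack per-flight, per-plot images into a :class:`PlotImageSeries`.

    ``images`` maps flight_date -> plot_id -> (H, W, 3) image.  Flights are
    ordered by ascending days after planting regardless of input order; plots
    are ordered by sorted plot_id.
    """
    flights = sorted(flights, key=lambda f: f.days_after_planting)
    missing = [f.flight_date for f in flights if f.flight_date not in images]
    if missing:
        raise ValueError(f"no images supplied for flights: {missing}")
    plot_sets = {f.flight_date: set(images[f.flight_date]) for f in flights}
    reference = plot_sets[flights[0].flight_date]
    for f in flights[1:]:
        diff = reference.symmetric_difference(plot_sets[f.flight_date])
        if diff:
            raise ValueError(
                f"flight {f.flight_date}: plot sets differ, offending ids {sorted(diff)}")
    plot_ids = sorted(reference)
    first = images[flights[0].flight_date][plot_ids[0]]
    size = first.shape[:2]
    for f in flights:
        for pid in plot_ids:
            if images[f.flight_date][pid].shape[:2] != size:
                raise ValueError(
                    f"flight {f.flight_date} plot {pid}: image size "
                    f"{images[f.flight_date][pid].shape[:2]} != {size}")
    data = np.stack([
        np.stack([images[f.flight_date][pid][..., :3] for pid in plot_ids])
        for f in flights])
    return PlotImageSeries(data=data, flights=list(flights), plot_ids=plot_ids)


def read_plot_shapes(path, id_field: str = "plot_id") -> list[PlotShape]:
    """Read plot polygons from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        raise ValueError(f"no features in {path}")
    shapes = []
    seen = set()
    for feat in features:
        props = feat.get("properties", {})
        if id_field not in props:
            raise ValueError(f"feature missing attribute {id_field!r} in {path}")
        pid = str(props[id_field])
        if pid in seen:
            raise ValueError(f"duplicate plot_id {pid!r} in {path}")
        seen.add(pid)
        geom = shapely_shape(feat["geometry"])
        buffer_m = float(props.get("buffer_m", 0.0))
        shapes.append(PlotShape(plot_id=pid, polygon=geom, buffer_m=buffer_m))
    return shapes


def write_plot_shapes(path, shapes: Sequence[PlotShape], crs_epsg: int | None = None) -> None:
    features = []
    for s in shapes:
        features.append({
            "type": "Feature",
            "properties": {"plot_id": s.plot_id, "buffer_m": s.buffer_m},
            "geometry": json.loads(shapely.to_geojson(s.polygon)),
        })
    gj = {"type": "FeatureCollection", "features": features}
    if crs_epsg is not None:
        gj["crs"] = {"type": "name",
                     "properties": {"name": f"urn:ogc:def:crs:EPSG::{crs_epsg}"}}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_flights_csv(path) -> list[FlightRecord]:
    """Read flight metadata CSV (flight_date, days_after_planting, gsd_cm)."""
    df = pd.read_csv(path)
    required = {"flight_date", "days_after_planting", "gsd_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flights CSV missing columns {sorted(missing)}")
    records = [FlightRecord(str(r.flight_date), int(r.days_after_planting),
                            float(r.gsd_cm),
                            float(r.altitude_m) if "altitude_m" in df.columns else None)
               for r in df.itertuples()]
    return records
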