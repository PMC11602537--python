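"""RGB vegetation indices and per-plot index extraction.

Two indices are used across the pipelines, both computed directly on raw
digital numbers (0-255), not reflectance:

* GLI (greenness leaf index) = (2G - R - B) / (2G + R + B), bounded in
  [-1, 1]; it declines toward 0 as a bean canopy browns down, which is what
  the maturity models exploit.
* ExG - ExR (excess green minus excess red) = (2g - r - b) - (1.4r - g), an
  unnormalized contrast that is positive over vegetation and negative over
  soil, used as the binarization mask source for stand counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geoplots import FlightRecord, Orthomosaic, PlotShape, polygon_pixel_mask


@dataclass
class VITimeSeries:
    """Per-plot mean vegetation-index values over flights."""

    plot_id: str
    days: np.ndarray       # days after planting, strictly increasing
    values: np.ndarray     # mean index value per flight
    index_name: str = "gli"
    masked: bool = False

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must align")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("index values must be finite")
        if self.index_name == "gli" and (np.any(self.values > 1) or np.any(self.values < -1)):
            raise ValueError("GLI values must lie in [-1, 1]")


def _as_float_bands(r, g, b):
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("digital numbers must be >= 0")
    return r, g, b


def gli(r, g, b):
    """Greenness leaf index (2G - R - B)/(2G + R + B) on digital numbers.

    Pixels with a zero denominator (r = g = b = 0) are undefined and returned
    as NaN so downstream means can exclude them.
    """
    r, g, b = _as_float_bands(r, g, b)
    num = 2.0 * g - r - b
    den = 2.0 * g + r + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def exgr(r, g, b):
    """Excess green minus excess red, (2g - r - b) - (1.4r - g), unnormalized."""
    r, g, b = _as_float_bands(r, g, b)
    out = (2.0 * g - r - b) - (1.4 * r - g)
    return out if out.ndim else float(out)


INDEX_FUNCTIONS = {"gli": gli, "exgr": exgr}


def compute_index(image: np.ndarray, index: str) -> np.ndarray:
    """Evaluate a named index over an (H, W, >=3) RGB image."""
    if index not in INDEX_FUNCTIONS:
        raise ValueError(f"unknown index {index!r}; known: {sorted(INDEX_FUNCTIONS)}")
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected an (H, W, >=3) image, got shape {image.shape}")
    return INDEX_FUNCTIONS[index](image[..., 0], image[..., 1], image[..., 2])


def binarize_vegetation(image: np.ndarray, index: str = "exgr",
                        threshold: float = 0.0) -> np.ndarray:
    """Binary vegetation mask: 1 where index > threshold (soil = 0)."""
    values = compute_index(image, index)
    return (np.nan_to_num(values, nan=-np.inf) > threshold).astype(np.uint8)


def extract_plot_vi(ortho: Orthomosaic, shapes: list[PlotShape], flight: FlightRecord,
                    index: str = "gli",
                    soil_mask: tuple[str, float] | None = None) -> pd.DataFrame:
    """Mean index value per plot for one flight.

    ``soil_mask=(index_name, threshold)`` restricts the mean to vegetation
    pixels (index > threshold).  Nodata pixels and undefined-index pixels are
    always excluded.  Plots with no surviving pixels get a NaN mean, never 0.
    """
    if not shapes:
        raise ValueError("empty shape list")
    idx_img = compute_index(ortho.image, index)
    nodata = ortho.nodata_mask()
    veg = None
    if soil_mask is not None:
        mask_index, mask_threshold = soil_mask
        veg = compute_index(ortho.image, mask_index) > mask_threshold
    rows = []
    for plot in shapes:
        inside, (row0, col0) = polygon_pixel_mask(
            ortho.transform, ortho.shape, plot.buffered())
        win = np.s_[row0:row0 + inside.shape[0], col0:col0 + inside.shape[1]]
        keep = inside & ~nodata[win] & np.isfinite(idx_img[win])
        if veg is not None:
            keep &= veg[win]
        values = idx_img[win][keep]
        rows.append({
            "plot_id": plot.plot_id,
            "flight_date": flight.flight_date,
            "days_after_planting": flight.days_after_planting,
            "index": index,
            "mean_value": float(values.mean()) if values.size else np.nan,
            "n_pixels": int(values.size),
        })
    return pd.DataFrame(rows)


def series_from_table(df: pd.DataFrame, masked: bool = False) -> list[VITimeSeries]:
    """Group a vegindex output table into per-plot :class:`VITimeSeries`."""
    out = []
    for pid, grp in df.groupby("plot_id", sort=True):
        grp = grp.sort_values("days_after_planting")
        grp = grp[np.isfinite(grp["mean_value"])]
        out.append(VITimeSeries(plot_id=str(pid),
                                days=grp["days_after_planting"].to_numpy(dtype=float),
                                values=grp["mean_value"].to_numpy(dtype=float),
                                index_name=str(grp["index"].iloc[0]),
                                masked=masked))
    return out
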