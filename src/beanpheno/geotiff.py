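"""Minimal georeferenced-TIFF reading and writing built on :mod:`tifffile`.

Only the subset of the GeoTIFF tag vocabulary needed for plot-level
phenotyping is handled: a north-up affine geotransform expressed through the
``ModelPixelScale`` + ``ModelTiepoint`` tag pair (or a full
``ModelTransformation`` matrix on read), an EPSG code from the GeoKey
directory, and the GDAL nodata convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_MODEL_TRANSFORMATION = 34264
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GDAL_NODATA = 42113

# GeoKey ids for the coordinate reference system
_KEY_GT_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


@dataclass(frozen=True)
class Affine:
    """World transform ``x = a*col + b*row + c``, ``y = d*col + e*row + f``.

    Follows the GDAL ordering with the origin at the outer corner of pixel
    (0, 0); pixel centers therefore live at half-integer pixel coordinates.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.determinant) < 1e-18:
            raise ValueError("geotransform is not invertible")

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def xy(self, col, row):
        """Map pixel coordinates (col, row) to world (x, y)."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def colrow(self, x, y):
        """Map world (x, y) to fractional pixel coordinates (col, row)."""
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        det = self.determinant
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return col, row

    @property
    def pixel_size(self) -> tuple[float, float]:
        """(width, height) of one pixel in world units (both positive)."""
        return (float(np.hypot(self.a, self.d)), float(np.hypot(self.b, self.e)))


def write_geotiff(path, data: np.ndarray, transform: Affine,
                  crs_epsg: int | None = None, nodata: float | None = None) -> None:
    """Write ``data`` (2-D single band or 3-D band-interleaved) as GeoTIFF.

    Only north-up transforms (b = d = 0) can be expressed through the
    pixel-scale/tiepoint pair used here.
    """
    if transform.b != 0 or transform.d != 0:
        raise ValueError("only north-up (non-rotated) transforms are supported on write")
    sx, sy = transform.a, -transform.e  # GeoTIFF pixel scale has positive sy for y-down
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, 12, 3, (sx, sy, 0.0)),
        (TAG_MODEL_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
    ]
    if crs_epsg is not None:
        geographic = 4000 <= crs_epsg < 5000  # EPSG geographic 2-D range used in practice
        model_type = 2 if geographic else 1
        cs_key = _KEY_GEOGRAPHIC_TYPE if geographic else _KEY_PROJECTED_CS_TYPE
        keys = (1, 1, 0, 2,
                _KEY_GT_MODEL_TYPE, 0, 1, model_type,
                cs_key, 0, 1, crs_epsg)
        extratags.append((TAG_GEO_KEY_DIRECTORY, 3, len(keys), keys))
    if nodata is not None:
        text = repr(float(nodata)) if not float(nodata).is_integer() else str(int(nodata))
        extratags.append((TAG_GDAL_NODATA, 2, len(text) + 1, text + "\x00"))
    photometric = "rgb" if data.ndim == 3 and data.shape[2] == 3 else "minisblack"
    tifffile.imwrite(path, data, photometric=photometric, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, Affine | None, int | None, float | None]:
    """Read a GeoTIFF; returns (array, transform, epsg, nodata).

    ``transform`` is ``None`` when the file carries no georeferencing tags.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}

    transform = None
    if TAG_MODEL_TRANSFORMATION in tags:
        m = np.asarray(tags[TAG_MODEL_TRANSFORMATION], dtype=float).reshape(4, 4)
        transform = Affine(m[0, 0], m[0, 1], m[0, 3], m[1, 0], m[1, 1], m[1, 3])
    elif TAG_MODEL_PIXEL_SCALE in tags and TAG_MODEL_TIEPOINT in tags:
        sx, sy = tags[TAG_MODEL_PIXEL_SCALE][:2]
        tp = tags[TAG_MODEL_TIEPOINT]
        # tiepoint: raster (i, j, k) -> model (x, y, z)
        i, j, _, x, y, _ = tp[:6]
        transform = Affine(float(sx), 0.0, float(x) - float(i) * float(sx),
                           0.0, -float(sy), float(y) + float(j) * float(sy))

    epsg = None
    if TAG_GEO_KEY_DIRECTORY in tags:
        keys = tags[TAG_GEO_KEY_DIRECTORY]
        for k in range(4, len(keys) - 3, 4):
            key_id, location, _count, value = keys[k:k + 4]
            if key_id in (_KEY_PROJECTED_CS_TYPE, _KEY_GEOGRAPHIC_TYPE) and location == 0:
                epsg = int(value)

    nodata = None
    if TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            nodata = None
    return data, transform, epsg, nodata
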