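import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from beanpheno.geotiff import Affine, write_geotiff
from beanpheno.geoplots import Orthomosaic, PlotShape


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_ortho(rng):
    """100x100 RGB orthomosaic at 5 cm GSD, UTM-like coordinates."""
    image = rng.integers(1, 255, size=(100, 100, 3), dtype=np.uint8)
    transform = Affine(0.05, 0.0, 500000.0, 0.0, -0.05, 4300000.0)
    return Orthomosaic(image=image, transform=transform, crs_epsg=32616)


@pytest.fixture()
def ortho_file(tmp_path, small_ortho):
    path = tmp_path / "ortho.tif"
    write_geotiff(path, small_ortho.image, small_ortho.transform,
                  crs_epsg=small_ortho.crs_epsg)
    return path


def rect_plot(ortho: Orthomosaic, row0, row1, col0, col1, plot_id="P1") -> PlotShape:
    """Plot polygon exactly covering pixel rows [row0, row1) x cols [col0, col1)."""
    t = ortho.transform
    x0, y0 = t.xy(col0, row0)
    x1, y1 = t.xy(col1, row1)
    return PlotShape(plot_id=plot_id,
                     polygon=shapely_box(min(x0, x1), min(y0, y1),
                                         max(x0, x1), max(y0, y1)))
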