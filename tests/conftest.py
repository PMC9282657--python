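import numpy as np
import pytest
import shapely
from shapely.geometry import box

from dasygrid import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mc_area():
    """Monte Carlo area oracle: rejection sampling over the bounding box.

    Independent of shapely's area computation: only the point-in-polygon
    predicate is shared, applied to random points.
    """

    def _mc_area(geom, n=1_000_000, seed=0, bounds=None):
        minx, miny, maxx, maxy = bounds or geom.bounds
        gen = np.random.default_rng(seed)
        xs = gen.uniform(minx, maxx, n)
        ys = gen.uniform(miny, maxy, n)
        inside = shapely.contains_xy(geom, xs, ys)
        return (maxx - minx) * (maxy - miny) * inside.mean()

    return _mc_area


@pytest.fixture(scope="session")
def mc_pixel_masses():
    """Monte Carlo rasterization oracle: per-pixel polygon mass estimates.

    Samples points uniformly over the polygon's bounding box and bins the
    in-polygon hits by grid cell; each hit carries an equal share of the
    box area times density.
    """

    def _mc(geom, density, spec, n=1_000_000, seed=0):
        minx, miny, maxx, maxy = geom.bounds
        gen = np.random.default_rng(seed)
        xs = gen.uniform(minx, maxx, n)
        ys = gen.uniform(miny, maxy, n)
        inside = shapely.contains_xy(geom, xs, ys)
        xs, ys = xs[inside], ys[inside]
        cols = np.floor((xs - spec.origin_x) / spec.resolution).astype(int)
        rows = np.floor((spec.origin_y - ys) / spec.resolution).astype(int)
        ok = (rows >= 0) & (rows < spec.n_rows) & (cols >= 0) & (cols < spec.n_cols)
        masses = np.zeros((spec.n_rows, spec.n_cols))
        weight = density * (maxx - minx) * (maxy - miny) / n
        np.add.at(masses, (rows[ok], cols[ok]), weight)
        return masses

    return _mc


@pytest.fixture(scope="session")
def small_scene():
    """One modest clustered scene shared by read-only tests."""
    return generate_scene(SceneParams(seed=7, n_coarse=6, fine_per_coarse=12.0))


def square(x0, y0, side):
    return box(x0, y0, x0 + side, y0 + side)
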