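import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from heatscape.synthetic import (Building, SiteSpec, SynthConfig, Tree,
                                 gen_reference_series, gen_site_rasters)


@pytest.fixture(scope="session")
def one_year_config() -> SynthConfig:
    return SynthConfig(start_year=1995, end_year=1995, seed=11)


@pytest.fixture(scope="session")
def reference_year(one_year_config):
    return gen_reference_series(one_year_config)


@pytest.fixture(scope="session")
def box_site_rasters():
    """40 m scene with a single 10 m box building."""
    spec = SiteSpec(extent=(40.0, 40.0), buildings=[
        Building(Polygon([(15, 15), (25, 15), (25, 25), (15, 25)]), 10.0)])
    return gen_site_rasters(spec)


@pytest.fixture(scope="session")
def mixed_site_rasters():
    """40 m scene with a building and a tree."""
    spec = SiteSpec(extent=(40.0, 40.0),
                    buildings=[Building(Polygon([(5, 5), (15, 5), (15, 15), (5, 15)]), 12.0)],
                    trees=[Tree((28.0, 28.0), 5.0, 10.0, 2.5)])
    return gen_site_rasters(spec)


def random_scene(rng: np.random.Generator, max_size: int = 50):
    """Random toy scene for shadow-oracle comparisons."""
    n = int(rng.integers(20, max_size + 1))
    spec = SiteSpec(extent=(float(n), float(n)))
    placed = []
    for _ in range(rng.integers(1, 4)):
        w, h = rng.uniform(3, 9, 2)
        x0 = rng.uniform(1, n - w - 1)
        y0 = rng.uniform(1, n - h - 1)
        poly = Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)])
        if any(poly.intersection(p).area > 0 for p in placed):
            continue
        placed.append(poly)
        spec.buildings.append(Building(poly, float(rng.uniform(4, 20))))
    for _ in range(rng.integers(0, 3)):
        r = rng.uniform(2, 5)
        cx = rng.uniform(r + 1, n - r - 1)
        cy = rng.uniform(r + 1, n - r - 1)
        top = rng.uniform(5, 14)
        spec.trees.append(Tree((cx, cy), float(r), float(top), float(rng.uniform(1, 3))))
    return gen_site_rasters(spec)
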