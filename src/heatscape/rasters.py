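"""Site raster stack (DEM / DSM / CHM) and single-band GeoTIFF I/O.

Rasters follow the map convention used throughout the package: row 0 is
the northern edge, columns increase eastward, cells are squares indexed
at their centres.  GeoTIFF files are written through tifffile with the
ModelPixelScale / ModelTiepoint tags so GIS tools can georeference them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass
class SiteRasters:
    """Ground (dem), ground+building (dsm) and vegetation-height (chm) grids.

    ``chm`` is vegetation height above ground (m); ``trunk`` is the crown
    base height above ground (m), zero where there is no vegetation —
    shadow casting treats the crown as opaque between the two.
    """

    dem: np.ndarray
    dsm: np.ndarray
    chm: np.ndarray
    cell_size: float = 1.0
    trunk: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)  # map x, y of the NW corner

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.dem, self.dsm, self.chm)}
        if len(shapes) != 1:
            raise ValueError("dem/dsm/chm must share one shape")
        if self.trunk is None:
            self.trunk = np.zeros_like(self.chm)
        if self.trunk.shape != self.chm.shape:
            raise ValueError("trunk raster shape mismatch")
        if np.any(self.dsm < self.dem - 1e-9):
            raise ValueError("dsm must be >= dem everywhere")
        if np.any(self.chm < 0):
            raise ValueError("chm must be non-negative")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dem.shape

    @property
    def building_height(self) -> np.ndarray:
        return self.dsm - self.dem

    def window(self, r0: int, r1: int, c0: int, c1: int) -> "SiteRasters":
        """Sub-raster by row/col slice (half-open), origin adjusted."""
        ox, oy = self.origin
        return SiteRasters(
            self.dem[r0:r1, c0:c1].copy(),
            self.dsm[r0:r1, c0:c1].copy(),
            self.chm[r0:r1, c0:c1].copy(),
            self.cell_size,
            self.trunk[r0:r1, c0:c1].copy(),
            (ox + c0 * self.cell_size, oy - r0 * self.cell_size),
        )


def write_geotiff(path, grid: np.ndarray, cell_size: float,
                  origin: tuple[float, float] = (0.0, 0.0)) -> None:
    """Write a single-band float32 GeoTIFF with pixel-scale/tiepoint tags."""
    scale = (float(cell_size), float(cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)
    tifffile.imwrite(
        path,
        np.asarray(grid, dtype=np.float32),
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, scale),
            (_MODEL_TIEPOINT, "d", 6, tiepoint),
        ],
    )


def read_geotiff(path):
    """Read a single-band GeoTIFF; returns (grid, cell_size, origin)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray().astype(float)
        tags = page.tags
        cell = float(tags[_MODEL_PIXEL_SCALE].value[0]) if _MODEL_PIXEL_SCALE in tags else 1.0
        if _MODEL_TIEPOINT in tags:
            tp = tags[_MODEL_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        else:
            origin = (0.0, 0.0)
    return grid, cell, origin


def write_site_rasters(rasters: SiteRasters, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("dem", "dsm", "chm", "trunk"):
        write_geotiff(d / f"{name}.tif", getattr(rasters, name),
                      rasters.cell_size, rasters.origin)


def read_site_rasters(directory) -> SiteRasters:
    from pathlib import Path

    d = Path(directory)
    layers = {}
    cell = 1.0
    origin = (0.0, 0.0)
    for name in ("dem", "dsm", "chm", "trunk"):
        p = d / f"{name}.tif"
        if p.exists():
            layers[name], cell, origin = read_geotiff(p)
    return SiteRasters(layers["dem"], layers["dsm"], layers["chm"],
                       cell, layers.get("trunk"), origin)
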