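"""Habitat rasters: cover/cropland class grids and distance-to-cover surfaces.

The study landscape is agricultural cropland (the densest elk forage)
interspersed with forest/shrubland patches ("cover").  The habitat covariate
used throughout the package is the Euclidean distance from a point to the
nearest cover cell centre, expressed in units of 100 m so that selection
coefficients stay O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

#: habitat class codes
CROPLAND = 0
COVER = 1

#: metres per distance-covariate unit
DIST_UNIT_M = 100.0


@dataclass
class LandscapeGrid:
    """A habitat-class raster with a derived distance-to-cover surface.

    Parameters
    ----------
    habitat : ndarray of int, shape (nrows, ncols)
        Class codes (``COVER`` = forest/shrubland, ``CROPLAND``).  Row 0 is
        the *top* of the grid (raster convention).
    cell_size : float
        Cell edge length in metres.
    origin : (float, float)
        ``(x, y)`` of the lower-left corner in metres.
    """

    habitat: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    dist_cover: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.habitat = np.asarray(self.habitat)
        if self.habitat.ndim != 2:
            raise ValueError("habitat grid must be 2-D")
        if not (self.habitat == COVER).any():
            raise ValueError("landscape has no cover cells; distance to cover undefined")
        # exact Euclidean distance (between cell centres) to the nearest cover cell
        self.dist_cover = (
            ndimage.distance_transform_edt(self.habitat != COVER) * self.cell_size
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.habitat.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid in metres."""
        nr, nc = self.habitat.shape
        x0, y0 = self.origin
        return (x0, x0 + nc * self.cell_size, y0, y0 + nr * self.cell_size)

    def _to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) of points, in cell-centre coordinates."""
        x0, y0 = self.origin
        nr = self.habitat.shape[0]
        col = (np.asarray(x, float) - x0) / self.cell_size - 0.5
        # row 0 is the top row; y increases upward
        row = nr - 1 - ((np.asarray(y, float) - y0) / self.cell_size - 0.5)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def dist_to_cover(self, x, y, units: str = "m") -> np.ndarray:
        """Bilinear lookup of the distance-to-cover surface at points.

        ``units='m'`` returns metres, ``'100m'`` the covariate scale used in
        the selection models.
        """
        row, col = self._to_rowcol(x, y)
        out = ndimage.map_coordinates(
            self.dist_cover, np.vstack([np.atleast_1d(row), np.atleast_1d(col)]),
            order=1, mode="nearest",
        )
        if units == "100m":
            out = out / DIST_UNIT_M
        elif units != "m":
            raise ValueError(f"unknown units {units!r}")
        return out if np.ndim(x) else float(out[0])

    def habitat_at(self, x, y) -> np.ndarray:
        """Nearest-cell habitat class at points."""
        row, col = self._to_rowcol(x, y)
        r = np.clip(np.round(np.atleast_1d(row)).astype(int), 0, self.shape[0] - 1)
        c = np.clip(np.round(np.atleast_1d(col)).astype(int), 0, self.shape[1] - 1)
        out = self.habitat[r, c]
        return out if np.ndim(x) else int(out[0])


def make_landscape(
    nrows: int = 120,
    ncols: int = 120,
    cell_size: float = 50.0,
    n_patches: int = 8,
    patch_radius: tuple[float, float] = (3.0, 10.0),
    origin: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> LandscapeGrid:
    """Generate a cropland matrix with circular forest/shrubland patches.

    Patch centres are uniform on the grid; radii (in cells) uniform on
    ``patch_radius``.  At least one patch is always placed.
    """
    if n_patches < 1:
        raise ValueError("need at least one cover patch (distance undefined otherwise)")
    rng = np.random.default_rng(seed)
    habitat = np.full((nrows, ncols), CROPLAND, dtype=np.int8)
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    for _ in range(n_patches):
        cy, cx = rng.uniform(0, nrows), rng.uniform(0, ncols)
        rad = rng.uniform(*patch_radius)
        habitat[(rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2] = COVER
    if not (habitat == COVER).any():  # all patches fell off-grid edges (tiny radius)
        habitat[int(nrows // 2), int(ncols // 2)] = COVER
    return LandscapeGrid(habitat=habitat, cell_size=cell_size, origin=origin)


def write_ascii_grid(grid: LandscapeGrid, path: str | Path) -> None:
    """Write the habitat classes as an ESRI ASCII grid."""
    nr, nc = grid.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\ncellsize {grid.cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.habitat:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> LandscapeGrid:
    """Read a habitat-class ESRI ASCII grid."""
    meta: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    habitat = np.array(rows, dtype=np.int8)
    if habitat.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError("grid shape does not match header")
    return LandscapeGrid(
        habitat=habitat,
        cell_size=meta["cellsize"],
        origin=(meta["xllcorner"], meta["yllcorner"]),
    )
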