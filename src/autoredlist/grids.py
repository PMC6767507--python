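"""Equal-area raster grids and plain-text raster I/O.

All spatial computation in this package happens on a single shared
equal-area grid in metres (the global analyses this tool emulates use a
Mollweide projection; here the projection is carried only as a tag that
inputs must agree on — nothing is ever reprojected silently).

Rasters are exchanged as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows of whitespace-separated values, top row first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GridMismatchError

DEFAULT_CRS_TAG = "local-equal-area-m"


@dataclass(frozen=True)
class GridSpec:
    """Definition of an equal-area raster grid.

    The origin is the lower-left corner in projected metres; row 0 of any
    raster array is the *top* row (standard raster order).
    """

    rows: int
    cols: int
    cell_size: float  # metres
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs_tag: str = DEFAULT_CRS_TAG

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def width(self) -> float:
        return self.cols * self.cell_size

    @property
    def height(self) -> float:
        return self.rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys): x centers per column, y centers per row (row 0 = top)."""
        xs = self.x_origin + (np.arange(self.cols) + 0.5) * self.cell_size
        ys = self.y_origin + (self.rows - np.arange(self.rows) - 0.5) * self.cell_size
        return xs, ys

    def matches(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.rows == other.rows
            and self.cols == other.cols
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and self.crs_tag == other.crs_tag
        )

    def require_match(self, other: "GridSpec", what: str = "raster") -> None:
        if not self.matches(other):
            raise GridMismatchError(f"{what} grid does not match: {other} vs {self}")


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = -9999

    def __post_init__(self):
        if self.values.shape != (self.grid.rows, self.grid.cols):
            raise ValueError(
                f"array shape {self.values.shape} does not match grid "
                f"({self.grid.rows}, {self.grid.cols})"
            )


def write_ascii_grid(path: str | Path, raster: Raster) -> None:
    path = Path(path)
    g = raster.grid
    is_int = np.issubdtype(raster.values.dtype, np.integer)
    fmt = "%d" if is_int else "%.6f"
    nodata = int(raster.nodata) if is_int else raster.nodata
    header = (
        f"ncols {g.cols}\n"
        f"nrows {g.rows}\n"
        f"xllcorner {g.x_origin:.6f}\n"
        f"yllcorner {g.y_origin:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)


def read_ascii_grid(path: str | Path, crs_tag: str = DEFAULT_CRS_TAG, dtype=None) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=dtype if dtype is not None else float)
    grid = GridSpec(
        rows=int(header["nrows"]),
        cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        crs_tag=crs_tag,
    )
    values = np.atleast_2d(values)
    if dtype is None and np.all(values == np.round(values)):
        values = values.astype(np.int64)
    return Raster(grid=grid, values=values, nodata=header["nodata_value"])
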