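"""Raster grids on a common cell-centre-registered lattice.

Rasters are stored row-major with row 0 = northernmost row.  The on-disk
format is the ESRI ASCII grid dialect (plain text), which round-trips
float32 values exactly when written with full precision.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "Raster", "PredictorStack", "read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geotransform of a north-up raster: origin is the lower-left corner."""

    xll: float
    yll: float
    cellsize: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (nrows, ncols)."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def point_to_rowcol(self, x, y):
        """Map point coordinates to (row, col); out-of-extent points get -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cellsize).astype(int)
        row = (self.nrows - 1) - np.floor((y - self.yll) / self.cellsize).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)


@dataclass
class Raster:
    """A single layer: float array plus grid and nodata sentinel."""

    values: np.ndarray
    grid: Grid
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def sample(self, x, y) -> np.ndarray:
        """Look up values at point locations; NaN outside extent or on nodata."""
        row, col = self.grid.point_to_rowcol(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        ok = (row >= 0) & (col >= 0)
        if np.any(ok):
            v = self.values[row[ok], col[ok]]
            v = np.where(self.mask[row[ok], col[ok]], v, np.nan)
            out[ok] = v
        return out

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.grid, self.nodata)


def read_raster(path: str | os.PathLike) -> Raster:
    """Read an ESRI ASCII grid (cell-centre or corner registered header)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        body = fh.read()
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"missing required ASCII grid header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise ValueError("missing xllcorner/xllcenter header field")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(io.StringIO(body)).reshape(nrows, ncols)
    return Raster(values, Grid(xll, yll, cellsize, nrows, ncols), nodata)


def write_raster(raster: Raster, path: str | os.PathLike) -> None:
    g = raster.grid
    vals = np.where(raster.mask, raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xll!r}\n")
        fh.write(f"yllcorner {g.yll!r}\n")
        fh.write(f"cellsize {g.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


@dataclass
class PredictorStack:
    """Named co-registered layers with continuous/categorical flags.

    All layers must share the grid exactly; the stack-level nodata mask is
    the intersection of per-layer masks.
    """

    layers: dict[str, Raster] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, raster: Raster, kind: str = "continuous") -> None:
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {kind!r}")
        if self.layers:
            ref = next(iter(self.layers.values())).grid
            if raster.grid != ref:
                raise ValueError(
                    f"grid mismatch for layer {name!r}: {raster.grid} vs stack grid {ref}"
                )
        if kind == "categorical":
            vals = raster.valid_values()
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"categorical layer {name!r} holds non-integer codes")
        self.layers[name] = raster
        self.kinds[name] = kind

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> Grid:
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self.layers.values())).grid

    @property
    def mask(self) -> np.ndarray:
        m = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            m &= r.mask
        return m

    def continuous_names(self) -> list[str]:
        return [n for n in self.names if self.kinds[n] == "continuous"]

    def categorical_names(self) -> list[str]:
        return [n for n in self.names if self.kinds[n] == "categorical"]

    def table(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        """Extract per-layer values at (row, col) index arrays."""
        return {n: r.values[rows, cols] for n, r in self.layers.items()}

    def table_at_points(self, x, y) -> dict[str, np.ndarray]:
        return {n: r.sample(x, y) for n, r in self.layers.items()}

    def subset(self, names: list[str]) -> "PredictorStack":
        out = PredictorStack()
        for n in names:
            out.add(n, self.layers[n], self.kinds[n])
        return out
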