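"""Georeferenced regular-grid rasters and neighborhood (buffer) statistics.

A :class:`GridRaster` is a rectangular field of one covariate or of PM2.5 on
a planar grid with square cells. Conventions used throughout the package:

* coordinates are planar meters; ``x`` increases east, ``y`` increases north;
* row 0 is the **north** edge of the grid (image convention), column 0 the
  west edge; cell values are registered at cell centers;
* the georeference origin ``(x_origin, y_origin)`` is the **lower-left
  corner** of the grid, matching the ESRI ASCII grid header.

Serialization uses the ESRI ASCII grid format (``.asc``), a plain-text
raster format understood by every GIS stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

NODATA_DEFAULT = -9999.0


@dataclass
class GridRaster:
    """A single-band raster with square cells on a planar grid.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; cells equal to ``nodata`` are excluded from every
        statistic. Stored as float64.
    x_origin, y_origin : float
        Coordinates (m) of the lower-left *corner* of the grid.
    cell_size_m : float
        Cell edge length in meters; must be positive.
    nodata : float
        Marker for missing cells.
    units : str
        Unit tag carried through operations (e.g. ``"km"``, ``"%"``,
        ``"ug/m3"``, ``"unitless"``).
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size_m: float = 90.0
    nodata: float = NODATA_DEFAULT
    units: str = "unitless"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.ncols * self.cell_size_m,
            self.y_origin + self.nrows * self.cell_size_m,
        )

    def same_geometry(self, other: "GridRaster", rtol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x_origin, other.x_origin, rtol=rtol)
            and np.isclose(self.y_origin, other.y_origin, rtol=rtol)
            and np.isclose(self.cell_size_m, other.cell_size_m, rtol=rtol)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) center coordinate arrays of shape (nrows, ncols)."""
        cs = self.cell_size_m
        x = self.x_origin + (np.arange(self.ncols) + 0.5) * cs
        y = self.y_origin + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return np.meshgrid(x, y)

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.mask()] = np.nan
        return out

    def with_values(self, values: np.ndarray, units: str | None = None,
                    name: str | None = None) -> "GridRaster":
        """A copy sharing this raster's geometry but holding new values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
            name=self.name if name is None else name,
        )

    def mean(self) -> float:
        """Mean over non-nodata cells."""
        m = self.mask()
        if not m.any():
            raise ValueError("raster has no valid cells")
        return float(self.values[m].mean())

    # -- point lookup -------------------------------------------------------
    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing point (x, y).

        Cells are half-open intervals ``[edge, edge + cell)`` in both axes,
        so a point lying exactly on a shared edge belongs to the cell whose
        index is obtained by flooring (east / north neighbor).
        """
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x < xmax and ymin <= y < ymax):
            raise ValueError(
                f"point ({x}, {y}) outside raster extent "
                f"x[{xmin}, {xmax}) y[{ymin}, {ymax})"
            )
        col = int(np.floor((x - self.x_origin) / self.cell_size_m))
        row_from_south = int(np.floor((y - self.y_origin) / self.cell_size_m))
        return self.nrows - 1 - row_from_south, col


def extract_at_points(raster: GridRaster, xs, ys) -> np.ndarray:
    """Raster values at points, by nearest-cell (containing-cell) lookup.

    No interpolation: each point takes the value of the cell that contains
    it. Points outside the raster extent raise ``ValueError`` naming the
    point. Nodata cells yield NaN.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have the same length")
    out = np.empty(xs.shape[0])
    vals = raster.masked()
    for i, (x, y) in enumerate(zip(xs, ys)):
        r, c = raster.index_of(x, y)
        out[i] = vals[r, c]
    return out


def circular_kernel(radius_m: float, cell_size_m: float) -> np.ndarray:
    """0/1 kernel of cells whose center lies within ``radius_m`` of the
    target cell center. Requires ``radius_m >= cell_size_m / 2``; at that
    minimum the kernel is the single center cell."""
    if radius_m < cell_size_m / 2:
        raise ValueError(
            f"buffer radius {radius_m} m is smaller than half a cell "
            f"({cell_size_m / 2} m)"
        )
    n = int(np.floor(radius_m / cell_size_m))
    offs = np.arange(-n, n + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    dist = np.hypot(di, dj) * cell_size_m
    return (dist <= radius_m + 1e-9).astype(float)


def focal_mean(raster: GridRaster, radius_m: float) -> GridRaster:
    """Circular focal (buffer) mean of a raster.

    Each output cell is the mean of input values at cells whose center lies
    within ``radius_m`` of that cell's center. Boundary cells use the
    truncated kernel (no padding), nodata cells are omitted from the mean,
    and neighborhoods containing no valid cell yield nodata. Units are
    preserved.
    """
    kernel = circular_kernel(radius_m, raster.cell_size_m)
    valid = raster.mask().astype(float)
    filled = np.where(raster.mask(), raster.values, 0.0)
    if kernel.size == 1:
        out = raster.masked()
    else:
        num = signal.fftconvolve(filled, kernel, mode="same")
        den = signal.fftconvolve(valid, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0.5, num / np.maximum(den, 1e-300), np.nan)
    result = np.where(np.isfinite(out), out, raster.nodata)
    return raster.with_values(result, name=f"{raster.name}@{radius_m:g}m")


def focal_mean_brute(raster: GridRaster, radius_m: float) -> GridRaster:
    """Direct per-cell kernel enumeration of the focal mean.

    Independent O(n^2 k^2) reference used to validate :func:`focal_mean`;
    intended for small rasters only.
    """
    kernel = circular_kernel(radius_m, raster.cell_size_m)
    n = kernel.shape[0] // 2
    vals = raster.masked()
    out = np.full_like(vals, np.nan)
    nrows, ncols = vals.shape
    for r in range(nrows):
        for c in range(ncols):
            acc, cnt = 0.0, 0
            for di in range(-n, n + 1):
                for dj in range(-n, n + 1):
                    if kernel[di + n, dj + n] == 0:
                        continue
                    rr, cc = r + di, c + dj
                    if 0 <= rr < nrows and 0 <= cc < ncols and np.isfinite(vals[rr, cc]):
                        acc += vals[rr, cc]
                        cnt += 1
            if cnt:
                out[r, c] = acc / cnt
    result = np.where(np.isfinite(out), out, raster.nodata)
    return raster.with_values(result)


def resample_nearest(raster: GridRaster, target: GridRaster) -> GridRaster:
    """Resample ``raster`` onto ``target``'s geometry by nearest neighbor.

    Each target cell takes the value of the source cell containing the
    target cell's center — the standard approach for bringing a coarse
    raster (e.g. a 1 km population grid) onto a fine analysis grid.
    The target extent must lie within the source extent.
    """
    if target.cell_size_m > raster.cell_size_m + 1e-9:
        raise ValueError("target cell size must not exceed source cell size")
    X, Y = target.cell_centers()
    sxmin, symin, sxmax, symax = raster.extent
    if X.min() < sxmin or X.max() >= sxmax or Y.min() < symin or Y.max() >= symax:
        raise ValueError("target extent falls outside the source raster")
    cols = np.floor((X - raster.x_origin) / raster.cell_size_m).astype(int)
    rows_s = np.floor((Y - raster.y_origin) / raster.cell_size_m).astype(int)
    rows = raster.nrows - 1 - rows_s
    vals = raster.values[rows, cols]
    vals = np.where(vals == raster.nodata, target.nodata, vals)
    return target.with_values(vals, units=raster.units, name=raster.name)


# -- ESRI ASCII grid I/O ----------------------------------------------------

def write_ascii_grid(raster: GridRaster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (plain text, ``.asc``)."""
    path = Path(path)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.x_origin:.6f}\n"
        f"yllcorner {raster.y_origin:.6f}\n"
        f"cellsize {raster.cell_size_m:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.8g")
    return path


def read_ascii_grid(path: str | Path, units: str = "unitless") -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    return GridRaster(
        values=values,
        x_origin=meta["xllcorner"],
        y_origin=meta["yllcorner"],
        cell_size_m=meta["cellsize"],
        nodata=meta.get("nodata_value", NODATA_DEFAULT),
        units=units,
        name=path.stem,
    )
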