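"""Gridded raster container and plain-text (ESRI ASCII grid) I/O.

A :class:`GridRaster` is the common currency of the pipeline: a rectangular
grid of square cells in planar km coordinates.  Row 0 is the *top* row, as in
the ASCII-grid convention, so the y coordinate of a cell center decreases
with row index.  The same container carries continuous suitability surfaces
(float in [0, 1]), categorical land-cover codes (int), or binary habitat
masks (0/1 int); ``kind`` records which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999

__all__ = ["GridRaster", "read_ascii_grid", "write_ascii_grid", "pixels_to_area_km2"]


@dataclass
class GridRaster:
    """Single-band raster on a square-cell grid.

    Parameters
    ----------
    values
        2-D array, shape (n_rows, n_cols).  Row 0 is the northernmost row.
    cell_size_km
        Side length of a square cell in km (e.g. 4.5 km for 2.5 arc-minute
        climate grids near the equator).
    origin_km
        (x, y) of the grid's lower-left corner in km.
    mask
        Optional boolean array, True where the cell is nodata.
    kind
        "binary", "categorical" or "continuous".
    """

    values: np.ndarray
    cell_size_km: float = 1.0
    origin_km: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km ** 2

    def same_geometry(self, other: "GridRaster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size_km - other.cell_size_km) <= tol
            and abs(self.origin_km[0] - other.origin_km[0]) <= tol
            and abs(self.origin_km[1] - other.origin_km[1]) <= tol
        )

    def require_same_geometry(self, other: "GridRaster") -> None:
        if not self.same_geometry(other):
            raise ValueError("raster geometries do not match")

    def valid(self) -> np.ndarray:
        """Boolean array of data (non-masked) cells."""
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.mask

    def cell_centers_km(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped like ``values``."""
        rows, cols = np.indices(self.shape)
        x = self.origin_km[0] + (cols + 0.5) * self.cell_size_km
        y = self.origin_km[1] + (self.n_rows - rows - 0.5) * self.cell_size_km
        return x, y

    def copy(self) -> "GridRaster":
        return GridRaster(
            self.values.copy(),
            self.cell_size_km,
            self.origin_km,
            None if self.mask is None else self.mask.copy(),
            self.kind,
        )


def pixels_to_area_km2(n_pixels: int, cell_size_km: float) -> float:
    """Area in km² covered by ``n_pixels`` square cells of the given side."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return n_pixels * cell_size_km ** 2


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize
    header, NODATA sentinel, one text row per grid row, north first)."""
    path = Path(path)
    vals = np.array(raster.values, dtype=float, copy=True)
    if raster.mask is not None:
        vals[raster.mask] = NODATA
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_km[0]!r}\n"
        f"yllcorner {raster.origin_km[1]!r}\n"
        f"cellsize {raster.cell_size_km!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, kind: str = "continuous") -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any
    conforming file; header keys are case-insensitive)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    ncols = int(header.get("ncols", data.shape[1]))
    nrows = int(header.get("nrows", data.shape[0]))
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"grid body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", NODATA)
    mask = data == nodata
    if kind in ("binary", "categorical"):
        values = np.where(mask, 0, data).astype(int)
    else:
        values = np.where(mask, np.nan, data)
    return GridRaster(
        values=values,
        cell_size_km=header.get("cellsize", 1.0),
        origin_km=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        mask=mask if mask.any() else None,
        kind=kind,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
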