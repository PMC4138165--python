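"""Co-registered climate raster stacks on a regular lon/lat grid.

A :class:`ClimateStack` holds named single-band layers sharing one grid
geometry and one nodata mask. The grid convention is the usual geospatial
one: row 0 is the northernmost row, cell addressing is 0-based, and a point
belongs to the half-open cell ``[x, x + cell) x (y - cell, y]``. The CRS is
fixed to geographic WGS84 (EPSG:4326).

Layers are read and written as ESRI ASCII grids (``.asc``), a plain-text
single-band raster format understood by GDAL/QGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GridGeometry",
    "ClimateStack",
    "SuitabilityMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "load_stack",
]

#: nodata sentinel used when writing ASCII grids
_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid: top-left corner, square cells in degrees."""

    origin_lon: float  # west edge of column 0
    origin_lat: float  # north edge of row 0
    cell_size: float   # degrees per cell, square cells
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer edges."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def cell_of(self, lon, lat):
        """Row/col indices of the cells containing the given points.

        Points outside the grid get index -1 in the offending dimension.
        Uses the half-open convention [x, x+cell) x (y-cell, y].
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        # row r spans lat in (origin - (r+1)*cell, origin - r*cell]; floor of
        # (origin - lat)/cell lands boundary latitudes in the row below, as
        # the half-open convention requires
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        bad_col = (col < 0) | (col >= self.n_cols)
        bad_row = (row < 0) | (row >= self.n_rows)
        col = np.where(bad_col, -1, col)
        row = np.where(bad_row, -1, row)
        return row, col

    def cell_center(self, row, col):
        """Lon/lat of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class ClimateStack:
    """Named co-registered raster layers with a shared nodata mask."""

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    nodata_mask: np.ndarray | None = None  # True where nodata
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.geometry.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid {self.geometry.shape}"
                )
            self.layers[name] = arr
        if self.nodata_mask is None:
            mask = np.zeros(self.geometry.shape, dtype=bool)
            for arr in self.layers.values():
                mask |= ~np.isfinite(arr)
            self.nodata_mask = mask
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.geometry.shape:
                raise ValueError("nodata_mask shape mismatch")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown layers: {missing}")
        return ClimateStack(
            geometry=self.geometry,
            layers={n: self.layers[n] for n in names},
            nodata_mask=self.nodata_mask.copy(),
        )

    def with_mask(self, extra_nodata: np.ndarray) -> "ClimateStack":
        """Return a copy whose nodata mask additionally covers `extra_nodata`."""
        return ClimateStack(
            geometry=self.geometry,
            layers={n: a.copy() for n, a in self.layers.items()},
            nodata_mask=self.nodata_mask | np.asarray(extra_nodata, dtype=bool),
        )

    def env_at_cells(self, rows, cols) -> np.ndarray:
        """Environment matrix (n_points x n_layers) at the given cells."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        out = np.column_stack([self.layers[n][rows, cols] for n in self.layers])
        return out

    def env_at_points(self, lon, lat) -> np.ndarray:
        """Environment matrix at the cells containing the given points.

        Raises if any point is off-grid or on a nodata cell.
        """
        row, col = self.geometry.cell_of(lon, lat)
        off = (row < 0) | (col < 0)
        if np.any(off):
            raise ValueError(f"points off grid at indices {np.nonzero(off)[0].tolist()}")
        bad = self.nodata_mask[row, col]
        if np.any(bad):
            raise ValueError(
                f"points on nodata cells at indices {np.nonzero(bad)[0].tolist()}"
            )
        return self.env_at_cells(row, col)

    def env_table(self) -> np.ndarray:
        """(n_valid_cells x n_layers) matrix over all valid cells, row-major order."""
        valid = self.valid_mask
        return np.column_stack([self.layers[n][valid] for n in self.layers])

    def write_dir(self, directory: str | Path) -> list[Path]:
        """Write one ``<layer>.asc`` ASCII grid per layer; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, arr in self.layers.items():
            p = directory / f"{name}.asc"
            write_ascii_grid(p, arr, self.geometry, mask=self.nodata_mask)
            paths.append(p)
        return paths


@dataclass
class SuitabilityMap:
    """Per-cell suitability in [0, 1] on a stack's grid; nodata propagated.

    ``extrapolation_mask``, when present, flags cells whose environment falls
    outside the range the producing model was trained on (scored anyway, but
    to be read with caution)."""

    geometry: GridGeometry
    values: np.ndarray
    nodata_mask: np.ndarray
    provenance: str = ""
    extrapolation_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError("suitability shape does not match geometry")
        valid = ~self.nodata_mask
        vals = self.values[valid]
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ValueError("suitability values must lie in [0, 1]")

    def write(self, path: str | Path) -> None:
        write_ascii_grid(path, self.values, self.geometry, mask=self.nodata_mask)


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    geometry: GridGeometry,
    mask: np.ndarray | None = None,
) -> None:
    """Write a single-band ESRI ASCII grid (.asc)."""
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.shape:
        raise ValueError("values shape does not match geometry")
    out = values.copy()
    if mask is not None:
        out[np.asarray(mask, dtype=bool)] = _NODATA
    out[~np.isfinite(out)] = _NODATA
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.origin_lon!r}\n"
        f"yllcorner {geometry.origin_lat - geometry.n_rows * geometry.cell_size!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry, np.ndarray]:
    """Read an ESRI ASCII grid; returns (values, geometry, nodata_mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})")
    geom = GridGeometry(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value")
    mask = ~np.isfinite(data)
    if nodata is not None:
        mask |= data == nodata
    values = data.astype(float)
    values[mask] = np.nan
    return values, geom, mask


def load_stack(paths: Iterable[str | Path], names: Sequence[str] | None = None) -> ClimateStack:
    """Load single-band ASCII grids into a stack; layer order = input order.

    All files must share the grid geometry exactly; the stack's nodata mask is
    the union of the per-layer masks.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster paths given")
    if names is None:
        names = [p.stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("names and paths length mismatch")
    layers: dict[str, np.ndarray] = {}
    geom: GridGeometry | None = None
    mask: np.ndarray | None = None
    for name, p in zip(names, paths):
        values, g, m = read_ascii_grid(p)
        if geom is None:
            geom, mask = g, m
        else:
            if not geom.approx_equal(g):
                raise ValueError(f"grid mismatch in layer {name!r} ({p})")
            mask = mask | m
        layers[name] = values
    return ClimateStack(geometry=geom, layers=layers, nodata_mask=mask)
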