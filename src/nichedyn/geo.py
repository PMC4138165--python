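"""Occurrence records, background sampling, and correlated-variable pruning.

Occurrences are point records (lon, lat, optional year/source) in WGS84
decimal degrees. Background points characterise the climate available in a
rectangular study region; they are drawn uniformly over the valid cells of a
raster stack and stand in for pseudo-absences throughout the niche and SDM
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import ClimateStack

__all__ = [
    "OccurrenceSet",
    "BackgroundRegion",
    "FilterReport",
    "PruneReport",
    "filter_occurrences",
    "sample_background",
    "prune_correlated",
]


@dataclass
class OccurrenceSet:
    """Point occurrence records for one region."""

    records: pd.DataFrame  # columns lon, lat, optional year, source
    region_id: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in ("lon", "lat"):
            if col not in df.columns:
                raise ValueError(f"occurrence table missing column {col!r}")
        if "year" not in df.columns:
            df["year"] = np.nan
        if "source" not in df.columns:
            df["source"] = ""
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, region_id: str = "") -> "OccurrenceSet":
        return cls(records=pd.read_csv(path), region_id=region_id)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, columns=["lon", "lat", "year", "source"])


@dataclass
class BackgroundRegion:
    """Uniform random points over the valid cells of a bounding box."""

    west: float
    east: float
    south: float
    north: float
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (n, 2) lon/lat
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.west < self.east and self.south < self.north):
            raise ValueError("background box must satisfy west < east and south < north")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def lon(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class FilterReport:
    n_input: int
    n_missing_coords: int
    n_off_grid_or_nodata: int
    n_too_old: int
    n_duplicate_cell: int
    n_kept: int


def filter_occurrences(
    occ: OccurrenceSet,
    stack: ClimateStack,
    min_year: int | None = None,
) -> tuple[OccurrenceSet, FilterReport]:
    """Clean an occurrence set against a raster stack.

    Drops, in order: records with missing coordinates; records off-grid or on
    nodata cells; records older than ``min_year`` (records with no year are
    kept); and all but the first record per raster cell, so at most one record
    remains per cell at the stack's resolution. Idempotent.
    """
    df = occ.records.copy()
    n_input = len(df)

    has_coords = np.isfinite(df["lon"].to_numpy(dtype=float)) & np.isfinite(
        df["lat"].to_numpy(dtype=float)
    )
    n_missing = int((~has_coords).sum())
    df = df[has_coords]

    row, col = stack.geometry.cell_of(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    on_grid = (row >= 0) & (col >= 0)
    valid = on_grid.copy()
    valid[on_grid] = ~stack.nodata_mask[row[on_grid], col[on_grid]]
    n_bad_cell = int((~valid).sum())
    df = df[valid]
    row, col = row[valid], col[valid]

    if min_year is not None:
        years = pd.to_numeric(df["year"], errors="coerce")
        keep = years.isna().to_numpy() | (years.to_numpy() >= min_year)
        n_old = int((~keep).sum())
        df = df[keep]
        row, col = row[keep], col[keep]
    else:
        n_old = 0

    # cell-level dedup: first record in input order wins
    cell_id = row * stack.geometry.n_cols + col
    _, first_idx = np.unique(cell_id, return_index=True)
    keep_mask = np.zeros(len(df), dtype=bool)
    keep_mask[np.sort(first_idx)] = True
    n_dup = int((~keep_mask).sum())
    df = df[keep_mask]

    if len(df) == 0:
        raise ValueError("all occurrence records were filtered out")
    report = FilterReport(
        n_input=n_input,
        n_missing_coords=n_missing,
        n_off_grid_or_nodata=n_bad_cell,
        n_too_old=n_old,
        n_duplicate_cell=n_dup,
        n_kept=len(df),
    )
    return OccurrenceSet(records=df.reset_index(drop=True), region_id=occ.region_id), report


def sample_background(
    bounds: tuple[float, float, float, float],
    stack: ClimateStack,
    n: int,
    seed: int,
    replace: bool = True,
) -> BackgroundRegion:
    """Draw ``n`` uniform random points over valid cells inside a box.

    ``bounds`` is (west, east, south, north). Cells are chosen uniformly among
    valid cells intersecting the box (with replacement by default, as in the
    usual 10,000-point background protocol) and each point is placed uniformly
    within its cell.
    """
    west, east, south, north = bounds
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = stack.geometry
    lon_centers = geom.origin_lon + (np.arange(geom.n_cols) + 0.5) * geom.cell_size
    lat_centers = geom.origin_lat - (np.arange(geom.n_rows) + 0.5) * geom.cell_size
    in_box = np.outer(
        (lat_centers > south) & (lat_centers <= north),
        (lon_centers >= west) & (lon_centers < east),
    )
    candidates = np.flatnonzero(in_box & stack.valid_mask)
    if candidates.size == 0:
        raise ValueError("background box contains no valid cells")
    if not replace and candidates.size < n:
        raise ValueError(
            f"only {candidates.size} valid cells in box; cannot draw {n} without replacement"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=replace)
    row, col = np.unravel_index(chosen, geom.shape)
    jitter_lon = rng.uniform(0.0, geom.cell_size, size=n)
    jitter_lat = rng.uniform(0.0, geom.cell_size, size=n)
    lon = geom.origin_lon + col * geom.cell_size + jitter_lon
    lat = geom.origin_lat - row * geom.cell_size - jitter_lat
    return BackgroundRegion(
        west=west, east=east, south=south, north=north,
        points=np.column_stack([lon, lat]), seed=seed,
    )


@dataclass
class PruneReport:
    dropped: list[tuple[str, str, float]]  # (kept_layer, dropped_layer, r)
    degenerate: list[str]                  # zero-variance layers removed
    max_abs_r_after: float


def prune_correlated(
    stack: ClimateStack,
    background: BackgroundRegion | None,
    r_max: float = 0.90,
) -> tuple[ClimateStack, PruneReport]:
    """Greedily drop layers until no pair exceeds |Pearson r| > r_max.

    Correlations are computed over the background sample when one is given
    (the default protocol) or over all valid cells otherwise. While any pair
    exceeds the threshold, the later-ordered member of the worst pair is
    dropped; the earlier layer in input order is kept. Zero-variance layers
    are removed up front with a warning.
    """
    if stack.n_layers < 2:
        raise ValueError("need at least 2 layers to prune")
    if background is not None:
        env = stack.env_at_points(background.lon, background.lat)
    else:
        env = stack.env_table()
    names = stack.layer_names

    sd = env.std(axis=0)
    degenerate = [n for n, s in zip(names, sd) if s == 0]
    for n in degenerate:
        warnings.warn(f"layer {n!r} has zero variance over the sample; dropping")
    keep = [i for i, n in enumerate(names) if n not in degenerate]
    env = env[:, keep]
    names = [names[i] for i in keep]

    dropped: list[tuple[str, str, float]] = []
    while len(names) >= 2:
        r = np.corrcoef(env, rowvar=False)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        if abs(r[i, j]) <= r_max:
            break
        lo, hi = min(i, j), max(i, j)  # keep earlier in input order
        dropped.append((names[lo], names[hi], float(r[i, j])))
        env = np.delete(env, hi, axis=1)
        del names[hi]

    max_r = 0.0
    if len(names) >= 2:
        r = np.corrcoef(env, rowvar=False)
        np.fill_diagonal(r, 0.0)
        max_r = float(np.max(np.abs(r)))
    report = PruneReport(dropped=dropped, degenerate=degenerate, max_abs_r_after=max_r)
    return stack.subset(names), report
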