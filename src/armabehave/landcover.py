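"""Categorical land-cover rasters, seasons, and buffered class proportions.

The study landscape is a mosaic of four land-use/land-cover (LU/LC) classes
— forest, closed savanna, open savanna and floodable grassland — mapped
separately for the dry (April–September) and wet (October–March) seasons.
Rasters are stored as plain-text ESRI ASCII grids in a projected metric CRS
matching the track data; no reprojection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: integer class codes used in rasters, in canonical order
CLASS_CODES = {
    "forest": 1,
    "closed_savanna": 2,
    "open_savanna": 3,
    "floodable_grassland": 4,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

DRY_MONTHS = frozenset({4, 5, 6, 7, 8, 9})


def season_of(timestamp) -> str:
    """Classify a timestamp into the ``"dry"`` (Apr–Sep) or ``"wet"``
    (Oct–Mar) season of the Pantanal.

    Accepts anything pandas can coerce to a timestamp; only the calendar
    month matters.
    """
    month = pd.Timestamp(timestamp).month
    return "dry" if month in DRY_MONTHS else "wet"


def season_of_series(timestamps: pd.Series) -> pd.Series:
    """Vectorized :func:`season_of` over a datetime series."""
    months = pd.DatetimeIndex(timestamps).month
    return pd.Series(
        np.where(np.isin(months, list(DRY_MONTHS)), "dry", "wet"),
        index=timestamps.index,
    )


@dataclass
class CategoricalRaster:
    """A single-band categorical grid in a projected metric CRS.

    ``data`` is stored row-major with row 0 at the *top* (northernmost),
    the ESRI ASCII grid convention.  ``xll``/``yll`` locate the lower-left
    corner of the grid; ``cell`` is the square cell size in meters.
    """

    data: np.ndarray
    xll: float
    yll: float
    cell: float
    nodata: int = -9999
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int32)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        nrows, ncols = self.data.shape
        return (
            self.xll,
            self.yll,
            self.xll + ncols * self.cell,
            self.yll + nrows * self.cell,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates: (xs per column, ys per row, top-down)."""
        nrows, ncols = self.data.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cell
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cell
        return xs, ys

    def value_at(self, x: float, y: float) -> int:
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        nrows, _ = self.data.shape
        col = min(int((x - self.xll) / self.cell), self.data.shape[1] - 1)
        row_from_bottom = min(int((y - self.yll) / self.cell), nrows - 1)
        return int(self.data[nrows - 1 - row_from_bottom, col])

    # -- text I/O (ESRI ASCII grid) --------------------------------------

    def write_ascii(self, path) -> None:
        nrows, ncols = self.data.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cell!r}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            np.savetxt(fh, self.data, fmt="%d")

    @classmethod
    def read_ascii(cls, path) -> "CategoricalRaster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh, dtype=np.int32)
        data = np.atleast_2d(data)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"grid shape {data.shape} does not match header in {path}")
        return cls(
            data=data,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cell=header["cellsize"],
            nodata=int(header.get("nodata_value", -9999)),
        )


@dataclass
class SeasonalLandCover:
    """Dry- and wet-season rasters for the same landscape."""

    dry: CategoricalRaster
    wet: CategoricalRaster

    def for_season(self, season: str) -> CategoricalRaster:
        if season not in ("dry", "wet"):
            raise ValueError(f"unknown season {season!r}")
        return self.dry if season == "dry" else self.wet


def buffer_proportions(
    x: float,
    y: float,
    raster: CategoricalRaster,
    radius: float = 30.0,
) -> dict[str, float]:
    """Proportion of each LU/LC class within ``radius`` meters of a point.

    Membership uses the cell-center-in-circle rule: a cell contributes if
    its center lies within Euclidean distance ``radius`` (inclusive) of
    (x, y).  Deterministic and exact; adequate when the buffer is of the
    order of the cell size (default 30 m buffer on 30 m cells).

    Returns a mapping class name -> proportion, summing to 1 over cells
    with valid class codes.

    Raises ``ValueError`` if the point is outside the raster extent or no
    valid cell center falls within the buffer (the caller is expected to
    flag and exclude such observations).
    """
    if not raster.contains(x, y):
        raise ValueError(f"point ({x}, {y}) outside raster extent")
    nrows, ncols = raster.data.shape
    # bounding box of the circle, in array indices
    col_lo = max(int(np.floor((x - radius - raster.xll) / raster.cell)), 0)
    col_hi = min(int(np.ceil((x + radius - raster.xll) / raster.cell)), ncols - 1)
    rb_lo = max(int(np.floor((y - radius - raster.yll) / raster.cell)), 0)
    rb_hi = min(int(np.ceil((y + radius - raster.yll) / raster.cell)), nrows - 1)
    if col_hi < col_lo or rb_hi < rb_lo:
        raise ValueError("buffer does not overlap the raster")

    cols = np.arange(col_lo, col_hi + 1)
    rows_bottom = np.arange(rb_lo, rb_hi + 1)
    cx = raster.xll + (cols + 0.5) * raster.cell
    cy = raster.yll + (rows_bottom + 0.5) * raster.cell
    dx2 = (cx - x) ** 2
    dy2 = (cy - y) ** 2
    inside = dy2[:, None] + dx2[None, :] <= radius * radius

    rows_top = nrows - 1 - rows_bottom
    block = raster.data[np.ix_(rows_top, cols)]
    values = block[inside]
    values = values[values != raster.nodata]
    if values.size == 0:
        raise ValueError("buffer contains no valid land-cover cell")

    out = {}
    n = values.size
    for name, code in raster.class_codes.items():
        out[f"p_{name}"] = float(np.count_nonzero(values == code)) / n
    return out


def extract_covariates(
    obs: pd.DataFrame,
    landcover: SeasonalLandCover,
    radius: float = 30.0,
) -> pd.DataFrame:
    """Season-matched buffered land-cover proportions per observation.

    ``obs`` needs columns ``x``, ``y``, ``timestamp``.  Observations whose
    buffer falls outside the raster (or on pure no-data) are flagged with
    ``valid = False`` and carry NaN proportions; callers exclude them from
    downstream regression and log the count.
    """
    seasons = season_of_series(pd.to_datetime(obs["timestamp"], utc=False))
    records = []
    for (xi, yi), season in zip(obs[["x", "y"]].to_numpy(), seasons):
        raster = landcover.for_season(season)
        try:
            props = buffer_proportions(float(xi), float(yi), raster, radius=radius)
            props["valid"] = True
        except ValueError:
            props = {f"p_{name}": np.nan for name in raster.class_codes}
            props["valid"] = False
        props["season"] = season
        records.append(props)
    cov = pd.DataFrame.from_records(records, index=obs.index)
    return cov


def write_landcover(landcover: SeasonalLandCover, out_dir) -> dict[str, str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for season in ("dry", "wet"):
        p = out_dir / f"landcover_{season}.asc"
        landcover.for_season(season).write_ascii(p)
        paths[season] = str(p)
    return paths


def read_landcover(dry_path, wet_path) -> SeasonalLandCover:
    return SeasonalLandCover(
        dry=CategoricalRaster.read_ascii(dry_path),
        wet=CategoricalRaster.read_ascii(wet_path),
    )
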