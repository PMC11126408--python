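"""Raster data model, GeoTIFF / ESRI ASCII I/O, and terrain derivatives.

All rasters in a scene share one grid: ``n_rows x n_cols`` square cells of
``cell_size`` metres, map origin at the lower-left corner, row 0 at the top
(north).  Cells are addressed ``(row, col)`` everywhere in this package.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


class LandUse(IntEnum):
    """Land-use codes; the shipped legend (``data/landuse_legend.csv``) mirrors this."""

    CONSTRUCTION = 1
    RIVER = 2
    LAKE = 3
    OTHER_WATER = 4
    FOREST = 5
    BARELAND = 6
    FARMLAND = 7
    ROAD = 8


#: land-use codes counted as green infrastructure (raster foreground)
GI_CLASSES = (LandUse.FOREST, LandUse.FARMLAND)
#: water sub-types (each carries its own resistance value)
WATER_CLASSES = (LandUse.RIVER, LandUse.LAKE, LandUse.OTHER_WATER)


def landuse_legend() -> dict[int, str]:
    """Return the shipped ``code -> name`` land-use legend."""
    with resources.files("ginet.data").joinpath("landuse_legend.csv").open() as fh:
        return {int(row["code"]): row["name"] for row in csv.DictReader(fh)}


@dataclass
class Grid:
    """A single-band raster on a uniform square-cell grid.

    Parameters
    ----------
    values
        ``(n_rows, n_cols)`` array; row 0 is the northern edge.
    cell_size
        Cell edge length in metres (> 0).
    origin
        Map coordinates ``(x, y)`` of the lower-left corner.
    nodata
        Sentinel value marking missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares (30 m cell -> 0.09 ha)."""
        return self.cell_size**2 / 10_000.0

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def congruent(self, other: "Grid") -> bool:
        """True if *other* lives on the same grid (shape, cell size, origin)."""
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A congruent grid carrying *values* (metadata copied from self)."""
        g = replace(self, values=np.asarray(values))
        if nodata is not None:
            g.nodata = nodata
        return g

    def cell_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of cell centers."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def __eq__(self, other: object) -> bool:  # value-identity, used by round-trip tests
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.congruent(other)
            and np.isclose(self.nodata, other.nodata)
            and np.array_equal(self.nodata_mask, other.nodata_mask)
            and np.allclose(
                np.where(self.nodata_mask, 0, self.values.astype(float)),
                np.where(other.nodata_mask, 0, other.values.astype(float)),
            )
        )


def check_congruent(*grids: Grid) -> None:
    """Raise if the given grids do not share one scene grid."""
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent(g):
            raise ValueError(
                f"grids are not congruent: {first.shape}/{first.cell_size} vs "
                f"{g.shape}/{g.cell_size}"
            )


# ---------------------------------------------------------------------------
# I/O: single-band GeoTIFF and ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_raster(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write *grid* as a single-band GeoTIFF (``.tif``) or ESRI ASCII grid (``.asc``).

    The format is taken from *format* (``"geotiff"`` or ``"ascii"``) or, if omitted,
    from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "ascii" if path.suffix.lower() in {".asc", ".txt"} else "geotiff"
    if format == "ascii":
        _write_ascii(grid, path)
    elif format == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format: {format!r}")


def read_raster(path: str | Path, kind: str = "continuous") -> Grid:
    """Read a single-band GeoTIFF or ESRI ASCII grid.

    ``kind="categorical"`` casts values to integers (land-use / class rasters);
    ``kind="continuous"`` keeps floats (DEM, slope, resistance, current).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".asc", ".txt"}:
        grid = _read_ascii(path)
    else:
        grid = _read_geotiff(path)
    if kind == "categorical":
        grid.values = np.rint(grid.values).astype(np.int64)
        grid.nodata = int(round(grid.nodata))
    elif kind != "continuous":
        raise ValueError(f"unknown raster kind: {kind!r}")
    return grid


def _write_ascii(grid: Grid, path: Path) -> None:
    vals = np.asarray(grid.values)
    is_int = np.issubdtype(vals.dtype, np.integer)
    nodata = int(grid.nodata) if is_int else grid.nodata
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    fmt = "%d" if is_int else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required ASCII-grid header field {key!r}")
    values = np.loadtxt(path, skiprows=n_header, ndmin=2)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if "nodata_value" not in header and np.any(values == DEFAULT_NODATA):
        raise ValueError(f"{path}: values contain the nodata sentinel but no NODATA_value header")
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data block does not match declared nrows/ncols")
    return Grid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=nodata,
    )


def _write_geotiff(grid: Grid, path: Path) -> None:
    cs = float(grid.cell_size)
    # tie raster pixel (0, 0) (top-left) to its map coordinate
    top_y = grid.origin[1] + grid.n_rows * cs
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], top_y, 0.0)),
        (_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    vals = np.asarray(grid.values)
    if np.issubdtype(vals.dtype, np.integer):
        vals = vals.astype(np.int32)
    else:
        vals = vals.astype(np.float64)
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_geotiff(path: Path) -> Grid:
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band (single-page) GeoTIFF")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        values = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
    if not np.isclose(sx, sy):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
    tie = tags[_MODEL_TIEPOINT]
    top_x, top_y = tie[3], tie[4]
    n_rows = values.shape[0]
    nodata = DEFAULT_NODATA
    if _GDAL_NODATA in tags:
        nodata = float(tags[_GDAL_NODATA])
    elif np.any(values == DEFAULT_NODATA):
        raise ValueError(f"{path}: values contain the nodata sentinel but no GDAL_NODATA tag")
    return Grid(
        values=values,
        cell_size=float(sx),
        origin=(float(top_x), float(top_y - n_rows * sx)),
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Terrain derivative: Horn slope
# ---------------------------------------------------------------------------

def slope_percent(dem: Grid) -> Grid:
    """Slope as a dimensionless fraction (rise/run; 0.5 means a 50 % slope).

    Uses Horn's 3x3 finite-difference stencil (the common GIS default); border
    cells use edge-replicated neighbours.  Nodata cells propagate to the output.
    """
    z = np.asarray(dem.values, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope_percent needs a DEM of at least 3x3 cells")
    mask = dem.nodata_mask
    zf = np.where(mask, np.nan, z)
    p = np.pad(zf, 1, mode="edge")
    cs = dem.cell_size
    # Horn 1981 weights: +-(1, 2, 1) across the 3x3 neighbourhood
    gx = (
        (p[:-2, 2:] + 2 * p[1:-1, 2:] + p[2:, 2:])
        - (p[:-2, :-2] + 2 * p[1:-1, :-2] + p[2:, :-2])
    ) / (8.0 * cs)
    gy = (
        (p[2:, :-2] + 2 * p[2:, 1:-1] + p[2:, 2:])
        - (p[:-2, :-2] + 2 * p[:-2, 1:-1] + p[:-2, 2:])
    ) / (8.0 * cs)
    slope = np.hypot(gx, gy)
    slope = np.where(mask | ~np.isfinite(slope), dem.nodata, slope)
    return dem.with_values(slope)
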