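"""Core domain types and I/O for vector city models.

A city is a flat table of polygonal urban elements (gardens, rooftops,
streets, parks ...) in a projected, metre-unit CRS, each carrying a
land-use category and surface attributes.  Every indicator consumes this
representation together with a per-land-use attribute table of parameter
ranges (green fraction, NO2 sequestration capacity, food yield, SCS curve
numbers and role flags).

Vector layers are read and written as GeoJSON; sky-view-factor rasters as
single-band GeoTIFF (or Esri ASCII grid).
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

__all__ = [
    "SchemaError",
    "CRSError",
    "CityModel",
    "AttributeTable",
    "SvfGrid",
    "NeighbourhoodLayer",
    "SummaryStats",
    "IntervalEstimate",
    "read_city",
    "write_city",
    "read_svf",
    "write_svf",
    "read_neighbourhoods",
    "write_neighbourhoods",
    "default_attribute_table",
    "urban_attribute_table",
    "read_attribute_table",
    "write_attribute_table",
    "summarize",
    "make_rng",
    "substream",
]


class SchemaError(ValueError):
    """A required column or attribute is missing or malformed."""


class CRSError(ValueError):
    """The layer is not in a projected, metre-unit CRS."""


#: Mandatory columns of the urban representation.
MANDATORY_COLUMNS = ("land_use", "floors", "area")

#: All attribute columns of the urban representation, in canonical order.
CITY_COLUMNS = (
    "land_use",
    "land_use_verbose",
    "floors",
    "area",
    "flat_area",
    "edible_area",
)

#: CRS names that denote geographic (degree-unit) systems and are rejected.
_GEOGRAPHIC_CRS = {
    "EPSG:4326",
    "OGC:CRS84",
    "URN:OGC:DEF:CRS:OGC:1.3:CRS84",
    "CRS84",
    "WGS84",
    "EPSG:4258",
}


def _check_projected(crs: str | None) -> str:
    if crs is None or str(crs).strip() == "":
        raise CRSError(
            "layer has no CRS; a projected CRS with metre units is required "
            "(e.g. 'EPSG:25831')"
        )
    if str(crs).upper() in _GEOGRAPHIC_CRS:
        raise CRSError(
            f"CRS {crs!r} is geographic (degree units); reproject the layer "
            "to a projected CRS in metres"
        )
    return str(crs)


# ---------------------------------------------------------------------------
# City model
# ---------------------------------------------------------------------------

@dataclass
class CityModel:
    """Polygon city representation: one row per urban element.

    ``df`` columns: ``land_use``, ``land_use_verbose``, ``floors``, ``area``,
    ``flat_area``, ``edible_area`` and a ``geometry`` column of shapely
    (multi)polygons.  The index holds unique element ids.  ``crs`` is the
    name of a projected, metre-unit CRS.
    """

    df: pd.DataFrame
    crs: str

    def __post_init__(self) -> None:
        self.crs = _check_projected(self.crs)
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def geometry(self) -> np.ndarray:
        return self.df["geometry"].to_numpy()

    @property
    def total_area(self) -> float:
        return float(self.df["area"].sum())

    def copy(self) -> "CityModel":
        return CityModel(self.df.copy(), self.crs)

    def validate(self) -> None:
        df = self.df
        for col in CITY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"city is missing mandatory column {col!r}")
        if "geometry" not in df.columns:
            raise SchemaError("city is missing the geometry column")
        if df.index.has_duplicates:
            raise SchemaError("element ids are not unique")
        if len(df) == 0:
            return
        if (df["floors"] < 0).any():
            raise SchemaError("floors must be >= 0")
        if (df["area"] <= 0).any():
            raise SchemaError("area must be > 0")
        bad_flat = (df["flat_area"] < 0) | (df["flat_area"] > df["area"] * (1 + 1e-9))
        if bad_flat.any():
            raise SchemaError("flat_area must lie in [0, area]")
        bad_ed = (df["edible_area"] < 0) | (df["edible_area"] > df["area"] * (1 + 1e-9))
        if bad_ed.any():
            raise SchemaError("edible_area must lie in [0, area]")
        geoms = df["geometry"].to_numpy()
        if shapely.is_empty(geoms).any() or (~shapely.is_valid(geoms)).any():
            raise SchemaError("geometries must be valid and non-empty")
        # The declared area should track the polygon area; tolerate small
        # digitisation error, warn beyond 5%.
        geom_area = shapely.area(geoms)
        rel = np.abs(geom_area - df["area"].to_numpy()) / df["area"].to_numpy()
        if (rel > 0.05).any():
            n = int((rel > 0.05).sum())
            warnings.warn(
                f"{n} element(s) have a declared area deviating >5% from the "
                "polygon area",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Attribute table (per-land-use parameters)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "pGreen", "no2_seq1", "no2_seq2", "food1", "food2", "CN1", "CN2",
    "edible", "public", "private", "harvest",
)

# Per-land-use defaults: green fraction, NO2 sequestration capacity range
# (ug s^-1 m^-2), food yield range (kg m^-2 yr^-1), SCS curve-number range,
# and role flags (urban-agriculture solution, public green, private green,
# rainwater harvesting capable).
_DEFAULT_ROWS: list[tuple] = [
    # land_use              pGreen no2_1 no2_2 food1 food2 CN1 CN2  edib  publ  priv  harv
    ("Edible private garden", 0.6, 0.07, 0.09, 0.2,  6.6,  85, 88, True,  False, True,  True),
    ("Community garden",      1.0, 0.07, 0.09, 0.2,  2.2,  85, 88, True,  True,  False, True),
    ("Commercial garden",     1.0, 0.07, 0.09, 4.0,  6.6,  85, 85, True,  False, False, True),
    ("Rooftop garden",        1.0, 0.07, 0.07, 0.2,  2.2,  67, 88, True,  False, False, True),
    ("Hydroponic rooftop",    1.0, 0.07, 0.07, 9.0, 19.0,  98, 98, True,  False, False, True),
    ("Arable land",           0.6, 0.00, 0.07, 4.0,  6.6,  85, 88, False, True,  False, False),
    ("Normal garden",         0.6, 0.07, 0.07, 1.0,  1.0,  74, 86, False, False, True,  False),
    ("Permanent crops",       0.6, 0.09, 0.09, 4.0,  6.6,  65, 77, False, True,  False, False),
    ("Vacant",                1.0, 0.07, 0.09, 1.0,  1.0,  74, 87, False, False, False, False),
    ("Grass",                 1.0, 0.07, 0.07, 1.0,  1.0,  74, 86, False, True,  False, False),
    ("Mulcher",               1.0, 0.00, 0.00, 1.0,  1.0,  88, 88, False, False, False, False),
    ("Raised bed",            1.0, 0.07, 0.07, 1.0,  1.0,  67, 88, False, False, False, True),
    ("Trees",                 1.0, 0.11, 0.11, 1.0,  1.0,  70, 77, False, True,  False, False),
    ("Vegetated pergola",     1.0, 0.07, 0.07, 1.0,  1.0,  98, 98, False, False, False, False),
]


@dataclass
class AttributeTable:
    """Per-land-use parameter rows, keyed by land-use category."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "land_use":
            if "land_use" in df.columns:
                df = df.set_index("land_use")
            else:
                raise SchemaError("attribute table needs a 'land_use' key")
        missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"attribute table is missing columns {missing}")
        if df.index.has_duplicates:
            raise SchemaError("land_use keys are not unique")
        num = df[list(_TABLE_COLUMNS[:7])].astype(float)
        if (num["no2_seq1"] > num["no2_seq2"]).any():
            raise SchemaError("no2_seq1 must be <= no2_seq2")
        if (num["food1"] > num["food2"]).any():
            raise SchemaError("food1 must be <= food2")
        if (num["CN1"] > num["CN2"]).any():
            raise SchemaError("CN1 must be <= CN2")
        if ((num["CN1"] <= 0) | (num["CN2"] > 100)).any():
            raise SchemaError("curve numbers must lie in (0, 100]")
        if ((num["pGreen"] < 0) | (num["pGreen"] > 1)).any():
            raise SchemaError("pGreen must lie in [0, 1]")
        self.df = df

    def __contains__(self, land_use: str) -> bool:
        return land_use in self.df.index

    def check_covers(self, land_uses: Iterable[str]) -> None:
        """Raise if any of ``land_uses`` has no row (silent zeros hide data
        mistakes)."""
        unknown = sorted(set(land_uses) - set(self.df.index))
        if unknown:
            raise SchemaError(
                f"land uses missing from the attribute table: {unknown}"
            )

    def flagged(self, flag: str) -> list[str]:
        """Land uses whose boolean ``flag`` column is set."""
        col = self.df[flag].astype(bool)
        return list(self.df.index[col])

    def col(self, name: str, land_uses: Sequence[str]) -> np.ndarray:
        """Column ``name`` aligned to ``land_uses`` (raises on unknowns)."""
        self.check_covers(land_uses)
        return self.df[name].loc[list(land_uses)].to_numpy()


def default_attribute_table() -> AttributeTable:
    """The built-in attribute table of the 14 urban-green land uses."""
    df = pd.DataFrame(_DEFAULT_ROWS, columns=("land_use",) + _TABLE_COLUMNS)
    return AttributeTable(df.set_index("land_use"))


#: Impervious, non-green urban rows used alongside the green defaults when a
#: whole city (buildings, streets) is analysed rather than green elements
#: alone.  Curve number 98 is the standard impervious-surface value.
_IMPERVIOUS_ROWS: list[tuple] = [
    ("Rooftop",  0.0, 0.0, 0.0, 0.0, 0.0, 98, 98, False, False, False, False),
    ("Streets",  0.0, 0.0, 0.0, 0.0, 0.0, 98, 98, False, False, False, False),
]


def urban_attribute_table() -> AttributeTable:
    """The green defaults extended with impervious urban land uses
    (Rooftop, Streets: pGreen 0, CN 98) so city-wide indicator runs cover
    every element."""
    df = pd.DataFrame(
        _DEFAULT_ROWS + _IMPERVIOUS_ROWS,
        columns=("land_use",) + _TABLE_COLUMNS,
    )
    return AttributeTable(df.set_index("land_use"))


def read_attribute_table(path: str | Path) -> AttributeTable:
    df = pd.read_csv(path)
    for flag in ("edible", "public", "private", "harvest"):
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return AttributeTable(df)


def write_attribute_table(table: AttributeTable, path: str | Path) -> None:
    table.df.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster grid (sky view factor and friends)
# ---------------------------------------------------------------------------

@dataclass
class SvfGrid:
    """North-up raster grid in the city CRS.

    ``values`` is a 2-D float array with NaN marking nodata; ``x_origin`` /
    ``y_origin`` are the coordinates of the grid's top-left corner and
    ``cell_size`` the square pixel pitch in metres.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "EPSG:25831"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D (single band)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of x and y coordinates of every cell centre
        (row-major order)."""
        nrow, ncol = self.values.shape
        xs = self.x_origin + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(nrow) + 0.5) * self.cell_size
        X, Y = np.meshgrid(xs, ys)
        return X.ravel(), Y.ravel()

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


_TIFF_PIXEL_SCALE = 33550
_TIFF_TIEPOINT = 33922


def read_svf(path: str | Path) -> SvfGrid:
    """Read a sky-view-factor raster from GeoTIFF (.tif/.tiff) or Esri
    ASCII grid (.asc).

    The raster must be single band; finite values are expected in [0, 1]
    (more than 1% outside that range is treated as a format error).
    """
    path = Path(path)
    if path.suffix.lower() == ".asc":
        grid = _read_asc(path)
    else:
        grid = _read_tif(path)
    finite = grid.values[np.isfinite(grid.values)]
    if finite.size:
        frac_out = np.mean((finite < 0) | (finite > 1))
        if frac_out > 0.01:
            raise ValueError(
                f"{frac_out:.1%} of finite cells lie outside [0, 1]; this "
                "does not look like a sky-view-factor raster"
            )
    return grid


def _read_tif(path: Path) -> SvfGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise ValueError("SVF raster must be single band")
        tags = page.tags
        if _TIFF_PIXEL_SCALE not in tags or _TIFF_TIEPOINT not in tags:
            raise ValueError("GeoTIFF lacks georeferencing tags")
        sx, sy = tags[_TIFF_PIXEL_SCALE].value[:2]
        tie = tags[_TIFF_TIEPOINT].value
        # tiepoint maps raster (i, j) -> model (x, y); anchored at (0, 0)
        x0 = tie[3] - tie[0] * sx
        y0 = tie[4] + tie[1] * sy
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise ValueError("only square pixels are supported")
        crs = "EPSG:25831"
        nodata = None
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                crs = meta.get("crs", crs)
                nodata = meta.get("nodata")
            except (json.JSONDecodeError, TypeError):
                pass
        values = np.asarray(arr, dtype=float)
        if nodata is not None:
            values[values == nodata] = np.nan
    return SvfGrid(values, x0, y0, float(sx), crs)


def write_svf(grid: SvfGrid, path: str | Path) -> None:
    """Write a grid to GeoTIFF (.tif/.tiff) or Esri ASCII grid (.asc)."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(grid, path)
        return
    import tifffile

    meta = json.dumps({"crs": grid.crs, "nodata": None})
    scale = (grid.cell_size, grid.cell_size, 0.0)
    tie = (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)
    tifffile.imwrite(
        path,
        grid.values.astype(np.float32),
        description=meta,
        extratags=[
            (_TIFF_PIXEL_SCALE, "d", 3, scale),
            (_TIFF_TIEPOINT, "d", 6, tie),
        ],
    )


def _read_asc(path: Path) -> SvfGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header lacks {key}")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match header dimensions")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    cell = header["cellsize"]
    y0 = header["yllcorner"] + int(header["nrows"]) * cell
    return SvfGrid(values, header["xllcorner"], y0, cell)


def _write_asc(grid: SvfGrid, path: Path) -> None:
    nrow, ncol = grid.shape
    nodata = -9999.0
    values = np.where(np.isfinite(grid.values), grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {grid.x_origin}\n")
        fh.write(f"yllcorner {grid.y_origin - nrow * grid.cell_size}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, values, fmt="%.6g")


# ---------------------------------------------------------------------------
# Neighbourhoods
# ---------------------------------------------------------------------------

@dataclass
class NeighbourhoodLayer:
    """Named neighbourhood polygons with inhabitant counts."""

    df: pd.DataFrame
    crs: str

    def __post_init__(self) -> None:
        self.crs = _check_projected(self.crs)
        for col in ("name", "inhabitants", "geometry"):
            if col not in self.df.columns:
                raise SchemaError(f"neighbourhood layer is missing {col!r}")
        if self.df["name"].duplicated().any():
            raise SchemaError("neighbourhood names are not unique")
        if (self.df["inhabitants"] < 0).any():
            raise SchemaError("inhabitants must be >= 0")


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def _geojson_crs_name(doc: dict) -> str | None:
    crs = doc.get("crs")
    if isinstance(crs, dict):
        return crs.get("properties", {}).get("name")
    return None


def _read_features(path: str | Path) -> tuple[pd.DataFrame, str]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    crs = _check_projected(_geojson_crs_name(doc))
    rows = []
    ids = []
    for k, feat in enumerate(doc.get("features", [])):
        props = dict(feat.get("properties") or {})
        props["geometry"] = shape(feat["geometry"])
        rows.append(props)
        ids.append(feat.get("id", k))
    cols = None
    if not rows:
        cols = ["geometry"]
    df = pd.DataFrame(rows, columns=cols, index=pd.Index(ids, name="id"))
    return df, crs


def _write_features(df: pd.DataFrame, crs: str, path: str | Path) -> None:
    features = []
    prop_cols = [c for c in df.columns if c != "geometry"]
    for idx, row in df.iterrows():
        props = {}
        for c in prop_cols:
            v = row[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[c] = v
        features.append(
            {
                "type": "Feature",
                "id": int(idx) if isinstance(idx, (int, np.integer)) else idx,
                "properties": props,
                "geometry": mapping(row["geometry"]),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_city(path: str | Path) -> CityModel:
    """Read an urban representation from a GeoJSON file.

    Missing ``edible_area`` is filled with 0, missing ``flat_area`` with
    ``area`` and missing ``land_use_verbose`` with the land use itself.
    Missing mandatory columns (``land_use``, ``floors``, ``area``) raise a
    :class:`SchemaError`; a geographic CRS raises :class:`CRSError`.
    """
    df, crs = _read_features(path)
    if len(df):
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        if "edible_area" not in df.columns:
            df["edible_area"] = 0.0
        if "flat_area" not in df.columns:
            df["flat_area"] = df["area"]
        if "land_use_verbose" not in df.columns:
            df["land_use_verbose"] = df["land_use"]
        df["floors"] = df["floors"].astype(int)
        for col in ("area", "flat_area", "edible_area"):
            df[col] = df[col].astype(float)
        df["edible_area"] = df["edible_area"].fillna(0.0)
        df["flat_area"] = df["flat_area"].fillna(df["area"])
        df = df[list(CITY_COLUMNS) + ["geometry"]]
    else:
        df = pd.DataFrame(columns=list(CITY_COLUMNS) + ["geometry"])
    return CityModel(df, crs)


def write_city(city: CityModel, path: str | Path) -> None:
    """Write the urban representation to GeoJSON (round-trip stable)."""
    _write_features(city.df, city.crs, path)


def read_neighbourhoods(path: str | Path) -> NeighbourhoodLayer:
    df, crs = _read_features(path)
    if len(df):
        df["inhabitants"] = df["inhabitants"].astype(int)
    else:
        df = pd.DataFrame(columns=["name", "inhabitants", "geometry"])
    return NeighbourhoodLayer(df, crs)


def write_neighbourhoods(layer: NeighbourhoodLayer, path: str | Path) -> None:
    _write_features(layer.df, layer.crs, path)


# ---------------------------------------------------------------------------
# Statistics containers
# ---------------------------------------------------------------------------

class SummaryStats(NamedTuple):
    """Six-number summary (same unit as the input)."""

    min: float
    q25: float
    median: float
    mean: float
    q75: float
    max: float


class IntervalEstimate(NamedTuple):
    """Monte-Carlo interval: (lower, median, upper) at confidence ``level``."""

    lower: float
    median: float
    upper: float
    level: float


def summarize(values: Iterable[float]) -> SummaryStats:
    """Six-number summary with linear-interpolation (type-7) quantiles."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    return SummaryStats(
        float(arr.min()), float(q25), float(med), float(arr.mean()),
        float(q75), float(arr.max()),
    )


# ---------------------------------------------------------------------------
# Randomness
# ---------------------------------------------------------------------------

def make_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Normalise a seed (or pass an existing generator through)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible substream of a master seed.

    Streams for distinct names are independent, so adding one consumer
    never perturbs another's draws.
    """
    tag = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
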