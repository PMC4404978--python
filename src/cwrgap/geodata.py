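"""Georeferenced grids, occurrence tables, spherical geometry, and file I/O.

Everything downstream (distribution models, gap scores, niche overlap) moves
through two containers defined here: :class:`Raster`, a rectangular
geographic WGS84 grid of cell-center-registered values with a nodata
sentinel, and :class:`OccurrenceSet`, a taxon's germplasm (G) and
herbarium/reference (H) point records.  Grids are north-up (row 0 is the
northmost row) with square cells in decimal degrees.  Distances are
great-circle on a 6371-km sphere, which is accurate to well under a percent
at the 50-100 km buffer scales used in the gap analysis.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

OCCURRENCE_COLUMNS = [
    "taxon",
    "record_type",
    "longitude",
    "latitude",
    "country",
    "source",
    "record_id",
]


class GeodataError(ValueError):
    """Raised on contract violations in grid/occurrence handling."""


# ---------------------------------------------------------------------------
# grid and raster containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a geographic (WGS84) north-up grid with square cells.

    ``x_min`` / ``y_max`` locate the outer north-west corner; cell values are
    registered at cell centers.  ``resolution`` is in decimal degrees per
    cell (2.5 arc-minutes = 2.5/60 degrees reproduces the working resolution
    of the source study; any positive value is accepted).
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeodataError("grid must have at least one row and column")
        if self.resolution <= 0:
            raise GeodataError("resolution must be positive")
        if self.y_max - self.n_rows * self.resolution < -90 - 1e-9:
            raise GeodataError("grid extends south of -90 latitude")
        if self.y_max > 90 + 1e-9:
            raise GeodataError("grid extends north of +90 latitude")
        if self.x_min < -180 - 1e-9 or self.x_max > 180 + 1e-9:
            raise GeodataError("grid longitude span outside [-180, 180]")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.resolution

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the cell containing (lon, lat); None when outside."""
        col = int(math.floor((lon - self.x_min) / self.resolution))
        row = int(math.floor((self.y_max - lat) / self.resolution))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_min + (col + 0.5) * self.resolution,
            self.y_max - (row + 0.5) * self.resolution,
        )


@dataclass
class Raster:
    """A 2-D array of values (real or integer class codes) on a GridSpec."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise GeodataError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a valid datum is present."""
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(self.values)
        out = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            out &= ~np.isnan(self.values)
        return out

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        return Raster(self.spec, values, self.nodata if nodata is None else nodata)

    def sample(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Values at point locations; NaN outside the grid or on nodata."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        out = np.full(lons.shape, np.nan)
        cols = np.floor((lons - self.spec.x_min) / self.spec.resolution).astype(int)
        rows = np.floor((self.spec.y_max - lats) / self.spec.resolution).astype(int)
        ok = (
            (rows >= 0)
            & (rows < self.spec.n_rows)
            & (cols >= 0)
            & (cols < self.spec.n_cols)
        )
        vals = self.values[rows[ok], cols[ok]].astype(float)
        valid = self.mask[rows[ok], cols[ok]]
        vals[~valid] = np.nan
        out[ok] = vals
        return out


@dataclass
class VariableStack:
    """Named environmental layers sharing one grid.

    ``roles`` tags each variable as bioclim, altitude, or edaphic; the
    19 + 1 + 7 = 27-layer configuration mirrors the WorldClim bioclim set
    plus altitude plus seven soil drivers used for distribution modeling.
    """

    names: list[str]
    layers: dict[str, Raster]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise GeodataError("variable names must be unique")
        specs = {id(self.layers[n].spec) for n in self.names}
        ref = self.layers[self.names[0]].spec
        for n in self.names:
            if self.layers[n].spec != ref:
                raise GeodataError("all layers must share one GridSpec")
        for n in self.names:
            if self.roles.get(n) not in {"bioclim", "altitude", "edaphic"}:
                raise GeodataError(f"unknown role for variable {n!r}")

    @property
    def spec(self) -> GridSpec:
        return self.layers[self.names[0]].spec

    def names_for(self, roles: Iterable[str]) -> list[str]:
        wanted = set(roles)
        return [n for n in self.names if self.roles[n] in wanted]

    def land_mask(self) -> np.ndarray:
        """Cells valid in every layer (sea/nodata is consistent by contract)."""
        m = np.ones(self.spec.shape, dtype=bool)
        for n in self.names:
            m &= self.layers[n].mask
        return m

    def matrix_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_cells, n_variables) matrix of layer values at given cells."""
        out = np.empty((len(rows), len(self.names)))
        for j, n in enumerate(self.names):
            out[:, j] = self.layers[n].values[rows, cols]
        return out

    def subset(self, names: Sequence[str]) -> "VariableStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise GeodataError(f"variables not in stack: {missing}")
        return VariableStack(
            list(names),
            {n: self.layers[n] for n in names},
            {n: self.roles[n] for n in names},
        )


# ---------------------------------------------------------------------------
# occurrence records
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceRecord:
    """One germplasm (G) or herbarium/reference (H) record for a taxon."""

    taxon: str
    record_type: str
    longitude: float | None
    latitude: float | None
    country: str | None
    source: str
    record_id: str

    def __post_init__(self) -> None:
        if self.record_type not in {"G", "H"}:
            raise GeodataError(
                f"record_type must be 'G' or 'H', got {self.record_type!r}"
            )
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise GeodataError(f"longitude {self.longitude} out of range")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise GeodataError(f"latitude {self.latitude} out of range")

    @property
    def has_coords(self) -> bool:
        return self.longitude is not None and self.latitude is not None


@dataclass
class OccurrenceSet:
    taxon: str
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.taxon != self.taxon:
                raise GeodataError(
                    f"record taxon {r.taxon!r} does not match set taxon {self.taxon!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def of_type(self, record_type: str) -> list[OccurrenceRecord]:
        return [r for r in self.records if r.record_type == record_type]

    def coords(self, record_type: str | None = None) -> np.ndarray:
        """(n, 2) lon/lat array of georeferenced records, optionally by type."""
        recs = self.records if record_type is None else self.of_type(record_type)
        pts = [(r.longitude, r.latitude) for r in recs if r.has_coords]
        return np.array(pts, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# spherical geometry
# ---------------------------------------------------------------------------


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def cell_area_km2(spec: GridSpec, row: int) -> float:
    """Area in km^2 of one cell in the given row.

    Uses the small-cell spherical approximation
    ``(pi R / 180 * res)^2 * cos(lat_center)`` with R = 6371 km, which is
    symmetric about the equator and adequate at arc-minute resolutions.
    """
    if not 0 <= row < spec.n_rows:
        raise GeodataError(f"row {row} out of range [0, {spec.n_rows})")
    lat_center = spec.y_max - (row + 0.5) * spec.resolution
    side = math.pi * EARTH_RADIUS_KM / 180.0 * spec.resolution
    return side * side * math.cos(math.radians(lat_center))


def cell_area_raster(spec: GridSpec) -> np.ndarray:
    """(n_rows, n_cols) array of per-cell areas in km^2."""
    per_row = np.array([cell_area_km2(spec, r) for r in range(spec.n_rows)])
    return np.repeat(per_row[:, None], spec.n_cols, axis=1)


def buffer_mask(
    points: Sequence[tuple[float, float]], spec: GridSpec, radius_km: float
) -> Raster:
    """Binary raster of cells whose center lies within radius_km of any point.

    With ``radius_km=50`` around germplasm collection coordinates this is the
    CA50 geometry of the gap analysis.
    """
    if radius_km <= 0:
        raise GeodataError("radius_km must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        raise GeodataError("no germplasm coordinates: empty point list")
    lons = spec.lon_centers()
    lats = spec.lat_centers()
    lon_grid, lat_grid = np.meshgrid(lons, lats)
    out = np.zeros(spec.shape, dtype=bool)
    # per-point latitude-band prefilter keeps this linear in grid size
    deg_pad = math.degrees(radius_km / EARTH_RADIUS_KM) + spec.resolution
    for lon0, lat0 in pts:
        rows = np.where(np.abs(lats - lat0) <= deg_pad)[0]
        if rows.size == 0:
            continue
        sub = haversine_km(lon_grid[rows, :], lat_grid[rows, :], lon0, lat0)
        out[rows, :] |= sub <= radius_km
    return Raster(spec, out.astype(np.uint8), nodata=255)


# ---------------------------------------------------------------------------
# raster file I/O (ESRI ASCII grid and single-band GeoTIFF)
# ---------------------------------------------------------------------------

_GEOTIFF_MODEL_PIXEL_SCALE = 33550
_GEOTIFF_MODEL_TIEPOINT = 33922
_GEOTIFF_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_EPSG_WGS84 = 4326


def write_raster(raster: Raster, path: str | os.PathLike) -> None:
    """Write a raster; dialect chosen by extension (.asc/.txt vs .tif/.tiff)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".asc", ".txt"}:
        _write_ascii_grid(raster, path)
    elif ext in {".tif", ".tiff"}:
        _write_geotiff(raster, path)
    else:
        raise GeodataError(f"unknown raster extension {ext!r}")


def read_raster(path: str | os.PathLike) -> Raster:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".asc", ".txt"}:
        return _read_ascii_grid(path)
    if ext in {".tif", ".tiff"}:
        return _read_geotiff(path)
    raise GeodataError(f"unknown raster extension {ext!r}")


def _write_ascii_grid(raster: Raster, path: str | os.PathLike) -> None:
    spec = raster.spec
    vals = raster.values
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_min!r}\n")
        fh.write(f"yllcorner {spec.y_min!r}\n")
        fh.write(f"cellsize {spec.resolution!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        if np.issubdtype(vals.dtype, np.integer):
            fmt = "%d"
        else:
            fmt = "%.17g"  # round-trips float64 bit-exactly
        np.savetxt(fh, vals, fmt=fmt)


def _read_ascii_grid(path: str | os.PathLike) -> Raster:
    header: dict[str, float] = {}
    with open(path, "r", encoding="ascii") as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0].lower() not in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                if len(header) >= 5:  # NODATA_value is optional in the dialect
                    fh.seek(pos)
                    break
                raise GeodataError(f"malformed ASCII grid header line: {line!r}")
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        vals = np.loadtxt(fh, ndmin=2)
    try:
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        res = header["cellsize"]
        spec = GridSpec(
            n_rows=n_rows,
            n_cols=n_cols,
            x_min=header["xllcorner"],
            y_max=header["yllcorner"] + n_rows * res,
            resolution=res,
        )
    except KeyError as exc:
        raise GeodataError(f"ASCII grid header missing {exc}") from exc
    if vals.shape != (n_rows, n_cols):
        raise GeodataError(
            f"ASCII grid body shape {vals.shape} != header ({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    if np.all(vals == np.floor(vals)) and abs(nodata) < 2**31 and nodata == int(nodata):
        # integer-valued grids (class codes) come back as integers
        vals_int = vals.astype(np.int64)
        if np.array_equal(vals_int.astype(float), vals):
            return Raster(spec, vals_int, nodata=int(nodata))
    return Raster(spec, vals, nodata=nodata)


def _write_geotiff(raster: Raster, path: str | os.PathLike) -> None:
    import tifffile

    spec = raster.spec
    vals = raster.values
    if np.issubdtype(vals.dtype, np.integer):
        data = vals.astype(np.int32)
    else:
        data = vals.astype(np.float32)
    geokeys = (
        1, 1, 0, 3,
        _KEY_MODEL_TYPE, 0, 1, 2,       # ModelTypeGeographic
        _KEY_RASTER_TYPE, 0, 1, 1,      # RasterPixelIsArea
        _KEY_GEOGRAPHIC_TYPE, 0, 1, _EPSG_WGS84,
    )
    nodata_str = (
        str(int(raster.nodata))
        if float(raster.nodata) == int(raster.nodata)
        else repr(float(raster.nodata))
    )
    extratags = [
        (_GEOTIFF_MODEL_PIXEL_SCALE, "d", 3, (spec.resolution, spec.resolution, 0.0)),
        (_GEOTIFF_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_min, spec.y_max, 0.0)),
        (_GEOTIFF_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path: str | os.PathLike) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        vals = page.asarray()
        try:
            scale = tags[_GEOTIFF_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_GEOTIFF_MODEL_TIEPOINT].value
            geokeys = tags[_GEOTIFF_GEO_KEY_DIRECTORY].value
        except KeyError as exc:
            raise GeodataError("GeoTIFF lacks georeferencing tags") from exc
        nodata = -9999.0
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    keys = np.asarray(geokeys).reshape(-1, 4)
    kv = {int(k): int(v) for k, _, cnt, v in keys[1:] if cnt == 1}
    if kv.get(_KEY_MODEL_TYPE) != 2 or kv.get(_KEY_GEOGRAPHIC_TYPE) != _EPSG_WGS84:
        raise GeodataError("GeoTIFF CRS is not geographic WGS84 (EPSG:4326)")
    if abs(scale[0] - scale[1]) > 1e-12 * max(abs(scale[0]), 1.0):
        raise GeodataError("GeoTIFF cells are not square")
    if vals.ndim != 2:
        raise GeodataError("only single-band GeoTIFF supported")
    spec = GridSpec(
        n_rows=vals.shape[0],
        n_cols=vals.shape[1],
        x_min=float(tiepoint[3]),
        y_max=float(tiepoint[4]),
        resolution=float(scale[0]),
    )
    if np.issubdtype(vals.dtype, np.integer):
        nodata = int(nodata)
    return Raster(spec, vals, nodata=nodata)


# ---------------------------------------------------------------------------
# occurrence table I/O
# ---------------------------------------------------------------------------


def occurrences_to_frame(sets: Iterable[OccurrenceSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for r in s.records:
            rows.append(
                {
                    "taxon": r.taxon,
                    "record_type": r.record_type,
                    "longitude": r.longitude,
                    "latitude": r.latitude,
                    "country": r.country,
                    "source": r.source,
                    "record_id": r.record_id,
                }
            )
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def write_occurrences(sets: Iterable[OccurrenceSet], path: str | os.PathLike) -> None:
    occurrences_to_frame(sets).to_csv(path, index=False)


def _parse_row(row: pd.Series) -> OccurrenceRecord:
    def _opt_float(v) -> float | None:
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    def _opt_str(v) -> str | None:
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return str(v)

    return OccurrenceRecord(
        taxon=str(row["taxon"]),
        record_type=str(row["record_type"]),
        longitude=_opt_float(row["longitude"]),
        latitude=_opt_float(row["latitude"]),
        country=_opt_str(row["country"]),
        source="" if _opt_str(row["source"]) is None else str(row["source"]),
        record_id=str(row["record_id"]),
    )


def frame_to_occurrences(
    df: pd.DataFrame,
) -> tuple[list[OccurrenceSet], pd.DataFrame]:
    """Parse a standardized occurrence table into per-taxon sets.

    Rows that violate the record contract (unknown record_type, coordinates
    out of range) are quarantined with a reason, never silently dropped.
    """
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise GeodataError(f"occurrence table missing columns: {missing}")
    sets: dict[str, OccurrenceSet] = {}
    bad_rows: list[dict] = []
    for idx, row in df.iterrows():
        try:
            rec = _parse_row(row)
        except (GeodataError, ValueError) as exc:
            bad = dict(row)
            bad["row"] = idx
            bad["reason"] = str(exc)
            bad_rows.append(bad)
            continue
        sets.setdefault(rec.taxon, OccurrenceSet(rec.taxon)).records.append(rec)
    quarantine = pd.DataFrame(bad_rows, columns=OCCURRENCE_COLUMNS + ["row", "reason"])
    return list(sets.values()), quarantine


def read_occurrences(
    path: str | os.PathLike,
) -> tuple[list[OccurrenceSet], pd.DataFrame]:
    """Read a UTF-8 CSV occurrence table; returns (sets, quarantine report)."""
    df = pd.read_csv(path, dtype={"taxon": str, "record_type": str,
                                  "country": str, "source": str,
                                  "record_id": str})
    return frame_to_occurrences(df)
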