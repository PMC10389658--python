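"""Environmental summarization within sampling regions.

Two kinds of environmental sources are summarised per language region:

* **point stations** — annual weather-station summaries (temperature in
  degrees C, precipitation in mm).  All station-year values whose station
  lies inside the region are pooled and the grand mean and the number of
  contributing annual values are reported;
* **rasters** — gridded numeric fields (elevation m, specific humidity,
  biomass Mg/ha) summarised by zonal statistics over cells whose centers
  fall inside the region, and categorical land-cover grids summarised by
  per-class cell counts.

Output variables follow the naming grammar
``v_<short_name>_<units>__<stat>`` (e.g., ``v_tavg_dC__avg``,
``v_elev_m__median``, ``v_lc_tall_ct__sum``), and all variables join the
language table in a single master CSV, one row per language.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import ValidationError
from .language_table import LanguageRecord, records_to_frame
from .sampling_regions import SamplingRegion

logger = logging.getLogger(__name__)

STATION_PARAMS = ("tmin", "tmax", "tavg", "prcp")

#: Numeric zonal statistics, in output order.
NUMERIC_STATS = (
    "n", "null_cells", "minimum", "maximum", "range", "average", "median",
    "first_quartile", "third_quartile", "std_dev", "variance", "coeff_var",
)

_NAME_PART = re.compile(r"^[A-Za-z0-9]+(_[A-Za-z0-9]+)*$")


@dataclass(frozen=True)
class StationRecord:
    """One station-year of annual climate summaries; parameters may be None."""

    station_id: str
    lon: float
    lat: float
    year: int
    tmin: float | None = None
    tmax: float | None = None
    tavg: float | None = None
    prcp: float | None = None

    def __post_init__(self) -> None:
        if self.year <= 0:
            raise ValidationError(f"{self.station_id}: year must be positive")
        if not (-180 <= self.lon <= 180 and -90 <= self.lat <= 90):
            raise ValidationError(f"{self.station_id}: coordinates out of range")
        if all(getattr(self, p) is None for p in STATION_PARAMS):
            raise ValidationError(
                f"{self.station_id} {self.year}: no parameter present"
            )


@dataclass
class RasterGrid:
    """A north-up regular lon/lat grid (numeric or categorical).

    ``values`` has shape (n_rows, n_cols) with row 0 the northernmost;
    the grid origin (``xll``, ``yll``) is the lower-left corner in
    degrees, matching the ESRI ASCII grid convention.
    """

    xll: float
    yll: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    kind: str = "numeric"  # or "categorical"
    crs: str = "WGS84"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ValidationError("cell size must be positive")
        if self.values.ndim != 2:
            raise ValidationError("raster values must be 2-D")
        if self.kind not in ("numeric", "categorical"):
            raise ValidationError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical" and not np.issubdtype(
            self.values.dtype, np.integer
        ):
            raise ValidationError("categorical grids hold integer class codes")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) of cell centers."""
        cols = self.xll + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.yll + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        lon, lat = np.meshgrid(cols, rows)
        return lon, lat

    def sample(self, lon: float, lat: float) -> float:
        """Value of the cell containing (lon, lat); nodata -> nan."""
        col = int((lon - self.xll) / self.cell_size)
        row = self.n_rows - 1 - int((lat - self.yll) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            return float("nan")
        v = self.values[row, col]
        return float("nan") if v == self.nodata else float(v)

    def is_nodata(self) -> np.ndarray:
        return self.values == self.nodata


def read_ascii_grid(path, kind: str = "numeric") -> RasterGrid:
    """Read an ESRI ASCII grid (text raster interchange format)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValidationError(f"{path}: missing header field {req}")
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(f"{path}: data shape does not match header")
    if kind == "categorical":
        values = values.astype(int)
    return RasterGrid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
        kind=kind,
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        fmt = "%d" if grid.kind == "categorical" else "%.10g"
        np.savetxt(fh, grid.values, fmt=fmt)


@dataclass
class ExtractionConfig:
    """Temporal windows and numeric conventions for extraction.

    The station window defaults to the 1951-1980 climate-normal period;
    the humidity window to 1960-1980 (the gridded humidity source starts
    in 1960).  Both windows are inclusive at both ends.
    """

    station_window: tuple[int, int] = (1951, 1980)
    humidity_window: tuple[int, int] = (1960, 1980)
    #: numpy interpolation method for quartiles ("linear" = type 7).
    quartile_method: str = "linear"
    #: a raster cell contributes iff its center lies inside the region.
    cell_rule: str = "center"

    def __post_init__(self) -> None:
        for label, (start, end) in (
            ("station_window", self.station_window),
            ("humidity_window", self.humidity_window),
        ):
            if start > end:
                raise ValidationError(f"{label}: start {start} > end {end}")


def filter_station_years(
    records: Iterable[StationRecord], window: tuple[int, int]
) -> list[StationRecord]:
    """Keep records with window start <= year <= window end (inclusive)."""
    start, end = window
    if start > end:
        raise ValidationError(f"invalid window {window}")
    return [r for r in records if start <= r.year <= end]


def summarize_stations(
    region: SamplingRegion, records: Sequence[StationRecord]
) -> dict[str, tuple[float, int]]:
    """Pooled mean and sample size per parameter over in-region stations.

    All station-year values whose station point lies within the region
    polygon are pooled into a single grand mean per parameter; ``n`` is
    the number of contributing annual values (not stations).  Parameters
    with no contributing values are reported as (nan, 0).
    """
    if not records:
        inside = np.zeros(0, dtype=bool)
    else:
        lons = np.array([r.lon for r in records])
        lats = np.array([r.lat for r in records])
        inside = shapely.contains_xy(region.polygon, lons, lats)
    out: dict[str, tuple[float, int]] = {}
    for param in STATION_PARAMS:
        values = [
            getattr(r, param)
            for r, ok in zip(records, inside)
            if ok and getattr(r, param) is not None
        ]
        out[param] = (float(np.mean(values)) if values else float("nan"), len(values))
    return out


def _region_cells(region: SamplingRegion, raster: RasterGrid) -> np.ndarray:
    """Boolean mask of raster cells whose centers lie strictly inside."""
    lon, lat = raster.cell_centers()
    return shapely.contains_xy(region.polygon, lon.ravel(), lat.ravel()).reshape(
        raster.values.shape
    )


def zonal_numeric(
    region: SamplingRegion,
    raster: RasterGrid,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Zonal statistics of a numeric raster over a region.

    Returns the full statistics set (counts, extremes, central tendency,
    dispersion); with zero contributing cells every statistic except the
    counts is nan.  Variance and standard deviation use the n-1
    denominator; the coefficient of variation is std_dev/average and is
    nan when the average is zero.
    """
    if raster.kind != "numeric":
        raise ValidationError("zonal_numeric requires a numeric raster")
    config = config or ExtractionConfig()
    mask = _region_cells(region, raster)
    nodata = raster.is_nodata()
    n_null = int(np.sum(mask & nodata))
    x = raster.values[mask & ~nodata].astype(float)
    stats: dict[str, float] = {s: float("nan") for s in NUMERIC_STATS}
    stats["n"] = float(len(x))
    stats["null_cells"] = float(n_null)
    if len(x) == 0:
        return stats
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=config.quartile_method)
    avg = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    stats.update(
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        range=float(np.max(x) - np.min(x)),
        average=avg,
        median=float(med),
        first_quartile=float(q1),
        third_quartile=float(q3),
        std_dev=sd,
        variance=sd**2,
        coeff_var=sd / avg if avg != 0 else float("nan"),
    )
    return stats


def zonal_categorical(
    region: SamplingRegion,
    raster: RasterGrid,
    class_map: Mapping[int, str],
) -> dict[str, int]:
    """Per-class cell counts of a categorical raster over a region.

    Classes named in ``class_map`` but absent from the region are reported
    as 0; codes found in the region but missing from ``class_map`` are
    flagged with a warning and excluded.
    """
    if raster.kind != "categorical":
        raise ValidationError("zonal_categorical requires a categorical raster")
    mask = _region_cells(region, raster)
    if not mask.any():
        warnings.warn(
            f"{region.language_id}: region covers no raster cells", stacklevel=2
        )
    codes = raster.values[mask & ~raster.is_nodata()]
    counts = {name: 0 for name in class_map.values()}
    unknown: dict[int, int] = {}
    for code, n in zip(*np.unique(codes, return_counts=True)):
        name = class_map.get(int(code))
        if name is None:
            unknown[int(code)] = int(n)
        else:
            counts[name] += int(n)
    if unknown:
        warnings.warn(
            f"{region.language_id}: codes missing from class_map: {unknown}",
            stacklevel=2,
        )
    return counts


def name_variable(short_name: str, units: str, stat: str) -> str:
    """Compose a ``v_<short_name>_<units>__<stat>`` variable name."""
    for label, part in (("short_name", short_name), ("units", units), ("stat", stat)):
        if not part:
            raise ValidationError(f"{label} must be non-empty")
        if "__" in part:
            raise ValidationError(f"{label} {part!r} must not contain '__'")
        if label == "units" and "_" in part:
            raise ValidationError(f"units {part!r} must not contain separators")
        if not _NAME_PART.match(part):
            raise ValidationError(f"{label} {part!r} contains invalid characters")
    return f"v_{short_name}_{units}__{stat}"


def parse_variable(name: str) -> tuple[str, str, str]:
    """Split a ``v_*`` variable name back into (short_name, units, stat)."""
    m = re.match(
        r"^v_([A-Za-z0-9_]+)_([A-Za-z0-9]+)__([A-Za-z0-9]+(?:_[A-Za-z0-9]+)*)$", name
    )
    if not m:
        raise ValidationError(f"{name!r} does not follow the naming grammar")
    return m.group(1), m.group(2), m.group(3)


@dataclass
class EnvSummary:
    """Named per-language environmental variables."""

    language_id: str
    variables: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.variables:
            parse_variable(name)


def summarize_environment(
    region: SamplingRegion,
    stations: Sequence[StationRecord] | None = None,
    numeric_rasters: Mapping[str, tuple[RasterGrid, str]] | None = None,
    landcover: tuple[RasterGrid, Mapping[int, str]] | None = None,
    config: ExtractionConfig | None = None,
) -> EnvSummary:
    """All environmental variables for one region.

    ``numeric_rasters`` maps short names to ``(grid, units)`` — e.g.
    ``{"elev": (dem, "m"), "qa": (humidity, "unitless")}``.  Station
    records should already be filtered to the analysis window.
    """
    config = config or ExtractionConfig()
    out: dict[str, float] = {}
    if stations is not None:
        units = {"tmin": "dC", "tmax": "dC", "tavg": "dC", "prcp": "mm"}
        for param, (mean, n) in summarize_stations(region, stations).items():
            out[name_variable(param, units[param], "avg")] = mean
            out[name_variable(param, units[param], "n")] = float(n)
    for short, (grid, unit) in (numeric_rasters or {}).items():
        stats = zonal_numeric(region, grid, config)
        for stat, value in stats.items():
            out[name_variable(short, unit, stat)] = value
    if landcover is not None:
        grid, class_map = landcover
        for name, count in zonal_categorical(region, grid, class_map).items():
            out[name_variable(f"lc_{name}", "ct", "sum")] = float(count)
    return EnvSummary(region.language_id, out)


def assemble_master_table(
    records: Sequence[LanguageRecord],
    regions: Sequence[SamplingRegion],
    summaries: Sequence[EnvSummary],
) -> pd.DataFrame:
    """One row per language: linguistic variables, area diagnostics, v_*.

    Languages without a region keep their row with empty environmental
    cells (a warning is logged).  Column order is stable: language table
    columns, then area diagnostics, then sorted v_* variables.
    """
    lang = records_to_frame(records).set_index("id", drop=False)
    region_by_id = {r.language_id: r for r in regions}
    summary_by_id = {s.language_id: s for s in summaries}
    env_columns = sorted({name for s in summaries for name in s.variables})
    area_cols = [
        "base_buffer_area_km2", "clipped_buffer_area_km2",
        "region_area_km2", "inflation_ratio",
    ]
    rows = []
    for rec in records:
        row = dict(lang.loc[rec.id])
        region = region_by_id.get(rec.id)
        if region is None:
            logger.warning("%s: no sampling region; env cells left empty", rec.id)
            row.update({c: np.nan for c in area_cols + env_columns})
        else:
            row.update(
                base_buffer_area_km2=region.base_buffer_area,
                clipped_buffer_area_km2=region.clipped_buffer_area,
                region_area_km2=region.region_area,
                inflation_ratio=region.inflation_ratio,
            )
            summary = summary_by_id.get(rec.id)
            for col in env_columns:
                row[col] = summary.variables.get(col, np.nan) if summary else np.nan
        rows.append(row)
    columns = list(lang.columns) + area_cols + env_columns
    return pd.DataFrame(rows, columns=columns)


def read_station_csv(path) -> list[StationRecord]:
    """Read ``station_id,lon,lat,year,tmin,tmax,tavg,prcp`` CSV."""
    df = pd.read_csv(path, dtype={"station_id": str})
    records = []
    for _, row in df.iterrows():
        kwargs = {p: None if pd.isna(row.get(p)) else float(row[p])
                  for p in STATION_PARAMS}
        records.append(
            StationRecord(
                station_id=str(row["station_id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                year=int(row["year"]),
                **kwargs,
            )
        )
    return records


def write_station_csv(records: Sequence[StationRecord], path) -> None:
    rows = [
        {
            "station_id": r.station_id, "lon": r.lon, "lat": r.lat,
            "year": r.year, "tmin": r.tmin, "tmax": r.tmax,
            "tavg": r.tavg, "prcp": r.prcp,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["station_id", "lon", "lat", "year"] + list(STATION_PARAMS)
    ).to_csv(path, index=False)
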