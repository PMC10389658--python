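"""Seeded miniature-world generator for end-to-end pipeline testing.

Generates, from a single root seed, every input the analysis pipeline
consumes: a land/sea coastline, language point locations denser near the
equator, spatially autocorrelated environmental rasters in which
temperature, humidity, precipitation and biomass are positively
inter-correlated and negatively correlated with elevation, a weather
station network with a configurable northern-hemisphere coverage bias,
phoneme inventories in which consonant heaviness has a planted linear
dependence on local temperature, and a genealogy yielding the 1-10
relatedness scale.

The planted effect model is ``h_i = a + b * T_i + eps_i`` with
``eps ~ Normal(0, effect_noise_sd)``; the latent heaviness ``h_i`` is then
decomposed into the integer inventory fields (OnsCoda, CTotal) whose
recomputed index approximates ``h_i`` to within the 0.25 granularity of
CTotal/4, so the planted slope is recoverable by regressing the recomputed
index on extracted temperature.

Random fields are white noise smoothed with a Gaussian kernel — a simple,
dependency-light construction with adequate spatial autocorrelation for
testing zonal summaries.  Geography is schematic by design: no attempt is
made to mimic real continents, real families, or realistic phoneme
co-occurrence beyond marginals and the planted links.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box, mapping, shape

from .errors import ValidationError
from .language_table import (
    GLOTC_CATEGORIES,
    LanguageRecord,
    TONE_CATEGORIES,
    write_language_csv,
)
from .env_extract import RasterGrid, StationRecord, write_ascii_grid, write_station_csv
from .relatedness import RelatednessTable, write_relatedness_csv
from .sampling_regions import GeoPoint

#: Land-cover class codes emitted by the generator.
LANDCOVER_CLASSES = {0: "water", 1: "short", 2: "med", 3: "tall", 4: "snow"}

_KM_PER_DEG = 111.195  # mean spherical kilometres per degree


@dataclass
class SynthConfig:
    """All knobs of the synthetic world; defaults define the test world.

    Defaults give a 60 x 90 degree tropical-to-temperate box with ~35%
    land, 80 languages concentrated at low latitude, a 0.5 degree raster,
    a station network matching the 1951-1980 analysis window, and a
    planted heaviness-temperature slope of -0.15 index units per degree C
    (consonant heaviness decreasing with temperature).
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (-30.0, 30.0, -45.0, 45.0)
    land_fraction_target: float = 0.35
    n_languages: int = 80
    tropics_bias: float = 2.0
    raster_cell_deg: float = 0.5
    field_smoothness: float = 6.0  # correlation length, degrees
    base_temp: float = 27.0  # equatorial sea-level mean, degrees C
    lapse_per_km: float = 6.5  # degrees C per km of elevation
    lat_gradient: float = 0.45  # degrees C per degree of |latitude|
    noise_sd: float = 1.0  # smooth temperature noise, degrees C
    effect_intercept: float = 12.0  # a, heaviness index units
    effect_slope: float = -0.15  # b, index units per degree C
    effect_noise_sd: float = 1.0  # eps, index units
    station_density: float = 40.0  # stations per 1e6 km^2 of land
    north_bias: float = 1.0  # 0 = hemispherically even coverage
    obs_noise_sd: float = 0.5  # station observation noise, degrees C
    years: tuple[int, int] = (1951, 1980)
    tree_depth: int = 3
    plant_ejective_altitude: bool = True
    plant_tone_humidity: bool = True
    min_separation_deg: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.land_fraction_target < 1.0):
            raise ValidationError("land_fraction_target must be in (0, 1)")
        for name in ("raster_cell_deg", "field_smoothness", "effect_noise_sd",
                     "obs_noise_sd"):
            if getattr(self, name) < 0 or (
                name in ("raster_cell_deg", "field_smoothness")
                and getattr(self, name) <= 0
            ):
                raise ValidationError(f"{name} must be positive")
        if self.tropics_bias < 0:
            raise ValidationError("tropics_bias must be >= 0")
        if self.tree_depth < 1:
            raise ValidationError("tree_depth must be >= 1")
        if self.years[0] > self.years[1]:
            raise ValidationError("years range is inverted")


@dataclass
class SynthWorld:
    """The generated world plus its truth record."""

    config: SynthConfig
    coastline: shapely.Geometry
    land_mask: RasterGrid  # categorical 1 = land, 0 = sea
    languages: list[GeoPoint]
    rasters: dict[str, RasterGrid]
    landcover_classes: dict[int, str]
    stations: list[StationRecord]
    language_records: list[LanguageRecord]
    relatedness: RelatednessTable
    truth: pd.DataFrame


def _smooth_field(shape_: tuple[int, int], sigma_cells: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field (smoothed white noise)."""
    noise = rng.standard_normal(shape_)
    smooth = ndimage.gaussian_filter(noise, sigma_cells, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _grid_axes(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    lon_min, lon_max, lat_min, lat_max = config.extent
    cs = config.raster_cell_deg
    n_cols = int(round((lon_max - lon_min) / cs))
    n_rows = int(round((lat_max - lat_min) / cs))
    lon_c = lon_min + (np.arange(n_cols) + 0.5) * cs
    lat_c = lat_max - (np.arange(n_rows) + 0.5) * cs  # row 0 = north
    return lon_c, lat_c


def _grid(config: SynthConfig, values: np.ndarray, kind="numeric") -> RasterGrid:
    lon_min, _, lat_min, _ = config.extent
    return RasterGrid(
        xll=lon_min, yll=lat_min, cell_size=config.raster_cell_deg,
        values=values, kind=kind,
    )


def make_world(config: SynthConfig, rng: np.random.Generator | None = None):
    """Generate the coastline and land mask.

    Land is the upper quantile of a smooth random field, so the cell-wise
    land fraction equals the target up to grid discreteness.  The
    coastline polygon is the exact union of the land cells.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lon_c, lat_c = _grid_axes(config)
    sigma = config.field_smoothness / config.raster_cell_deg
    z = _smooth_field((len(lat_c), len(lon_c)), sigma, rng)
    threshold = np.quantile(z, 1.0 - config.land_fraction_target)
    land = (z > threshold).astype(int)
    achieved = land.mean()
    if abs(achieved - config.land_fraction_target) > 0.05:
        raise ValidationError(
            f"land fraction {achieved:.3f} unreachable for target "
            f"{config.land_fraction_target}"
        )
    coastline = _mask_to_polygons(land, config)
    return coastline, _grid(config, land, kind="categorical")


def _mask_to_polygons(land: np.ndarray, config: SynthConfig):
    """Union of land cells as a (multi)polygon, via per-row run rectangles."""
    lon_min, _, lat_min, lat_max = config.extent
    cs = config.raster_cell_deg
    rects = []
    n_rows, n_cols = land.shape
    for row in range(n_rows):
        top = lat_max - row * cs
        bottom = top - cs
        cols = np.flatnonzero(land[row])
        if len(cols) == 0:
            continue
        # contiguous runs of land cells in this row
        breaks = np.flatnonzero(np.diff(cols) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(cols) - 1]])
        for s, e in zip(starts, ends):
            west = lon_min + cols[s] * cs
            east = lon_min + (cols[e] + 1) * cs
            rects.append(box(west, bottom, east, top))
    if not rects:
        raise ValidationError("no land generated")
    return shapely.union_all(rects)


def make_languages(
    config: SynthConfig, land, rng: np.random.Generator | None = None
) -> list[GeoPoint]:
    """Language points on land, denser toward the equator.

    Latitude density is proportional to ``exp(-tropics_bias * |lat| / 90)``;
    points closer than ``min_separation_deg`` are rejected.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    if land.is_empty:
        raise ValidationError("land geometry is empty")
    lon_min, lon_max, lat_min, lat_max = config.extent
    points: list[GeoPoint] = []
    coords: list[tuple[float, float]] = []
    max_attempts = 2000 * config.n_languages
    attempts = 0
    while len(points) < config.n_languages:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                f"placed only {len(points)}/{config.n_languages} languages "
                "under the separation constraint"
            )
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        if rng.uniform() > math.exp(-config.tropics_bias * abs(lat) / 90.0):
            continue
        if not shapely.contains_xy(land, lon, lat):
            continue
        if any(
            abs(lon - x) < config.min_separation_deg
            and abs(lat - y) < config.min_separation_deg
            for x, y in coords
        ):
            continue
        lang_id = f"L{len(points):04d}"
        points.append(GeoPoint(lang_id, float(lon), float(lat)))
        coords.append((lon, lat))
    return points


def make_rasters(
    config: SynthConfig,
    land_mask: RasterGrid,
    rng: np.random.Generator | None = None,
) -> dict[str, RasterGrid]:
    """Inter-correlated environmental rasters over the world extent.

    Temperature falls with |latitude| and with elevation (lapse rate);
    humidity, precipitation and biomass are increasing monotone transforms
    of temperature plus smooth noise, hence positively inter-correlated
    with it and negatively with elevation.  Land cover is water over sea,
    snow where very cold, and biomass terciles (short/med/tall) elsewhere.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    land = land_mask.values.astype(bool)
    shape_ = land.shape
    sigma = config.field_smoothness / config.raster_cell_deg
    _, lat_c = _grid_axes(config)
    lat_grid = np.repeat(lat_c[:, None], shape_[1], axis=1)

    elev = np.clip(600.0 + 500.0 * _smooth_field(shape_, sigma, rng), 0.0, None)
    elev[~land] = 0.0

    tnoise = config.noise_sd * _smooth_field(shape_, sigma, rng)
    tavg = (
        config.base_temp
        - config.lat_gradient * np.abs(lat_grid)
        - config.lapse_per_km * elev / 1000.0
        + tnoise
    )
    tmax = tavg + 6.0
    tmin = tavg - 6.0

    qa = np.clip(
        0.004 + 0.0006 * tavg + 0.0012 * _smooth_field(shape_, sigma, rng),
        1e-4, 0.04,
    )
    prcp = np.clip(
        300.0 + 60.0 * tavg + 250.0 * _smooth_field(shape_, sigma, rng), 0.0, None
    )
    biomass = np.clip(
        8.0 * (tavg - 5.0) + 25.0 * _smooth_field(shape_, sigma, rng), 0.0, None
    )
    biomass[~land] = 0.0

    lc = np.zeros(shape_, dtype=int)  # water
    snow = land & (tavg < -5.0)
    lc[snow] = 4
    veg = land & ~snow
    if veg.any():
        lo, hi = np.quantile(biomass[veg], [1 / 3, 2 / 3])
        lc[veg & (biomass <= lo)] = 1
        lc[veg & (biomass > lo) & (biomass <= hi)] = 2
        lc[veg & (biomass > hi)] = 3

    return {
        "elev": _grid(config, elev),
        "tavg": _grid(config, tavg),
        "tmax": _grid(config, tmax),
        "tmin": _grid(config, tmin),
        "qa": _grid(config, qa),
        "prcp": _grid(config, prcp),
        "biomass": _grid(config, biomass),
        "landcover": _grid(config, lc, kind="categorical"),
    }


def make_stations(
    config: SynthConfig,
    land_mask: RasterGrid,
    rasters: dict[str, RasterGrid],
    rng: np.random.Generator | None = None,
) -> list[StationRecord]:
    """Station network with optional northern-hemisphere coverage bias.

    Station count follows the configured density over total land area;
    per-cell placement intensity is proportional to land area times
    ``max(0, 1 + north_bias * lat / 90)``.  Each station contributes one
    record per year in the configured range, sampling the local raster
    value plus Gaussian observation noise.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    land = land_mask.values.astype(bool)
    _, lat_c = _grid_axes(config)
    lat_grid = np.repeat(lat_c[:, None], land.shape[1], axis=1)
    cell_area = (config.raster_cell_deg * _KM_PER_DEG) ** 2 * np.cos(
        np.radians(lat_grid)
    )
    land_area = float(cell_area[land].sum())
    n_stations = rng.poisson(config.station_density * land_area / 1e6)
    records: list[StationRecord] = []
    if n_stations == 0:
        return records

    weights = cell_area * np.clip(1.0 + config.north_bias * lat_grid / 90.0, 0.0, None)
    weights[~land] = 0.0
    flat = weights.ravel()
    flat = flat / flat.sum()
    cells = rng.choice(len(flat), size=n_stations, replace=True, p=flat)
    n_rows, n_cols = land.shape
    lon_min, _, lat_min, lat_max = config.extent
    cs = config.raster_cell_deg
    y0, y1 = config.years
    for i, cell in enumerate(cells):
        row, col = divmod(int(cell), n_cols)
        lon = lon_min + (col + rng.uniform()) * cs
        lat = lat_max - (row + rng.uniform()) * cs
        base = {p: rasters[p].sample(lon, lat) for p in ("tavg", "tmax", "tmin")}
        base["prcp"] = rasters["prcp"].sample(lon, lat)
        for year in range(y0, y1 + 1):
            records.append(
                StationRecord(
                    station_id=f"S{i:05d}",
                    lon=float(lon),
                    lat=float(lat),
                    year=year,
                    tmin=base["tmin"] + rng.normal(0, config.obs_noise_sd),
                    tmax=base["tmax"] + rng.normal(0, config.obs_noise_sd),
                    tavg=base["tavg"] + rng.normal(0, config.obs_noise_sd),
                    prcp=max(0.0, base["prcp"] + rng.normal(0, 60.0)),
                )
            )
    return records


def decompose_heaviness(
    h: float, rng: np.random.Generator
) -> tuple[int, int, int, float]:
    """Split a latent heaviness value into (onset, coda, ctotal, error).

    OnsCoda is drawn from a broad marginal first, then CTotal (the finer
    0.25-granularity term) absorbs the remainder; if the rounded CTotal
    falls outside 6..128 the onset/coda total is shifted until the
    recomposed index is within 0.25 of the latent value or no shift helps.
    """
    preferred = int(np.clip(round(rng.normal(2.5, 1.3)), 0, 6))
    best = None
    # try onset+coda totals outward from the preferred draw; CTotal absorbs
    # the remainder at 0.25 granularity
    for candidate in sorted(range(7), key=lambda c: (abs(c - preferred), c)):
        ct_cand = int(np.clip(round(4.0 * (h - candidate)), 6, 128))
        err_cand = abs(candidate + ct_cand / 4.0 - h)
        if best is None or err_cand < best[2] - 1e-12:
            best = (candidate, ct_cand, err_cand)
        if err_cand <= 0.25:
            best = (candidate, ct_cand, err_cand)
            break
    oc, ct, err = best
    onset = min(3, (oc + 1) // 2)
    coda = oc - onset
    return onset, coda, ct, err


def planted_consheavy(
    temperatures: np.ndarray,
    intercept: float,
    slope: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recomputed ConsHeavy after planting ``h = a + b*T + eps`` and
    decomposing into integer inventory fields.

    This is the quantity a slope-recovery simulation regresses on T: the
    integer decomposition adds bounded (±0.25) rounding error but no
    temperature-dependent bias.
    """
    out = np.empty(len(temperatures))
    for i, t in enumerate(np.asarray(temperatures, dtype=float)):
        h = intercept + slope * t + rng.normal(0, noise_sd)
        h = float(np.clip(h, 1.5, 33.0))
        onset, coda, ct, _ = decompose_heaviness(h, rng)
        out[i] = (onset + coda) + ct / 4.0
    return out


def make_phonologies(
    config: SynthConfig,
    languages: Sequence[GeoPoint],
    rasters: dict[str, RasterGrid],
    rng: np.random.Generator | None = None,
) -> tuple[list[LanguageRecord], pd.DataFrame]:
    """Language records with the planted heaviness-temperature effect.

    Returns the records and a truth table holding each language's true
    local temperature, elevation, humidity, the latent heaviness before
    integer decomposition, and the planted (a, b) parameters.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    records: list[LanguageRecord] = []
    truth_rows = []
    qa_land = rasters["qa"].values[rasters["elev"].values > -1]  # full grid
    qa_lo, qa_hi = np.quantile(qa_land, [0.1, 0.9])
    for p in languages:
        t_true = rasters["tavg"].sample(p.lon, p.lat)
        elev_true = rasters["elev"].sample(p.lon, p.lat)
        qa_true = rasters["qa"].sample(p.lon, p.lat)
        h = config.effect_intercept + config.effect_slope * t_true + rng.normal(
            0, config.effect_noise_sd
        )
        h = float(np.clip(h, 1.5, 33.0))
        onset, coda, ctotal, _ = decompose_heaviness(h, rng)

        obstr = int(np.clip(round(ctotal * rng.uniform(0.4, 0.9)), 1, ctotal))
        vq = int(rng.integers(3, 11))
        vtotal = vq + int(rng.integers(0, 15))

        if config.plant_tone_humidity:
            # higher humidity -> more complex tone systems
            u = (qa_true - qa_lo) / max(qa_hi - qa_lo, 1e-9)
            score = float(np.clip(u + rng.normal(0, 0.35), 0, 1))
            tone_cat = TONE_CATEGORIES[
                int(np.clip(np.digitize(score, [0.45, 0.6, 0.75, 0.88]), 0, 4))
            ]
        else:
            tone_cat = str(
                rng.choice(TONE_CATEGORIES, p=[0.5, 0.1, 0.2, 0.12, 0.08])
            )

        if config.plant_ejective_altitude:
            p_ej = 1.0 / (1.0 + math.exp(-(-2.2 + 1.8 * elev_true / 1000.0)))
        else:
            p_ej = 0.15
        has_ej = rng.uniform() < p_ej
        n_ej = int(1 + rng.poisson(2.0)) if has_ej else 0
        n_imp = int(1 + rng.poisson(0.8)) if rng.uniform() < 0.12 else 0
        n_res = int(1 + rng.poisson(0.6)) if rng.uniform() < 0.08 else 0
        glot_c = _glot_c_label(n_ej, n_imp, n_res)

        vow_index = None
        if rng.uniform() < 0.6:
            vow_index = float(
                np.clip(0.62 - 0.011 * h + rng.normal(0, 0.04), 0.26, 0.64)
            )

        records.append(
            LanguageRecord(
                id=p.id,
                name=f"Lang {p.id[1:]}",
                lon=p.lon,
                lat=p.lat,
                stable=bool(rng.uniform() < 0.8),
                onset=onset,
                coda=coda,
                vq=vq,
                vtotal=vtotal,
                ctotal=ctotal,
                obstr=obstr,
                tone_cat=tone_cat,
                obs_lat=bool(rng.uniform() < 0.15),
                f_rnd_v=bool(rng.uniform() < 0.1),
                glot_c=glot_c,
                n_ejectives=n_ej,
                n_implosives=n_imp,
                n_glot_res=n_res,
                velar_nas=bool(rng.uniform() < 0.5),
                nv_pattern=str(rng.choice(["None", "Some", "All"], p=[0.7, 0.2, 0.1])),
                pnc=bool(rng.uniform() < 0.2),
                vlength=str(
                    rng.choice(["None", "Some", "All", "Other"], p=[0.5, 0.2, 0.25, 0.05])
                ),
                aspirates=bool(rng.uniform() < 0.3),
                vow_index=vow_index,
            )
        )
        truth_rows.append(
            {
                "id": p.id,
                "lon": p.lon,
                "lat": p.lat,
                "t_true": t_true,
                "elev_true": elev_true,
                "qa_true": qa_true,
                "h_latent": h,
                "effect_intercept": config.effect_intercept,
                "effect_slope": config.effect_slope,
            }
        )
    return records, pd.DataFrame(truth_rows)


def _glot_c_label(n_ej: int, n_imp: int, n_res: int) -> str:
    key = (n_ej > 0, n_imp > 0, n_res > 0)
    labels = {
        (False, False, False): "No",
        (True, False, False): "Ej",
        (False, True, False): "Imp",
        (False, False, True): "Res",
        (True, True, False): "Ej & Imp",
        (True, False, True): "Ej & Res",
        (True, True, True): "Ej Imp & Res",
        (False, True, True): "Imp & Res",
    }
    label = labels[key]
    assert label in GLOTC_CATEGORIES
    return label


def make_relatedness(
    config: SynthConfig,
    languages: Sequence[GeoPoint],
    rng: np.random.Generator | None = None,
) -> RelatednessTable:
    """Random family forest on the 1-10 relatedness scale.

    Languages are partitioned into families; within a family each language
    gets a random path in a binary tree of depth ``tree_depth`` and the
    pair distance is ``1 + levels-to-join`` capped at 8.  Cross-family
    pairs are 10, except a small disputed fraction scored 9.  Singleton
    families are isolates (value 10 against everything).
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    ids = [p.id for p in languages]
    n = len(ids)
    n_families = max(1, n // 6)
    family = {lang: int(rng.integers(n_families)) for lang in ids}
    path = {
        lang: tuple(int(b) for b in rng.integers(0, 2, size=config.tree_depth))
        for lang in ids
    }
    from collections import Counter

    fam_sizes = Counter(family.values())
    isolates = {lang for lang in ids if fam_sizes[family[lang]] == 1}

    distances: dict[tuple[str, str], int] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            key = (a, b) if a <= b else (b, a)
            if family[a] == family[b]:
                lcp = 0
                for x, y in zip(path[a], path[b]):
                    if x != y:
                        break
                    lcp += 1
                distances[key] = min(8, 1 + (config.tree_depth - lcp))
            elif (
                a not in isolates
                and b not in isolates
                and rng.uniform() < 0.01
            ):
                distances[key] = 9  # disputed higher-level grouping
            else:
                distances[key] = 10
    return RelatednessTable(list(ids), distances, isolates)


def generate_world(config: SynthConfig) -> SynthWorld:
    """Generate the complete world from the root seed.

    A single :class:`numpy.random.SeedSequence` derives one child seed per
    stage, so stages are independently reproducible.
    """
    children = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(c) for c in children]
    coastline, land_mask = make_world(config, rngs[0])
    languages = make_languages(config, coastline, rngs[1])
    rasters = make_rasters(config, land_mask, rngs[2])
    stations = make_stations(config, land_mask, rasters, rngs[3])
    records, truth = make_phonologies(config, languages, rasters, rngs[4])
    relatedness = make_relatedness(config, languages, rngs[5])
    return SynthWorld(
        config=config,
        coastline=coastline,
        land_mask=land_mask,
        languages=languages,
        rasters=rasters,
        landcover_classes=dict(LANDCOVER_CLASSES),
        stations=stations,
        language_records=records,
        relatedness=relatedness,
        truth=truth,
    )


def save_world(world: SynthWorld, out_dir) -> dict[str, str]:
    """Write the world in the formats the pipeline consumes.

    Returns a mapping of artefact name to file path: language CSV, station
    CSV, coastline GeoJSON, ASCII-grid rasters, relatedness CSV, land-cover
    class map JSON, and the truth-record CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = out / "languages.csv"
    write_language_csv(world.language_records, p)
    paths["languages"] = str(p)

    p = out / "stations.csv"
    write_station_csv(world.stations, p)
    paths["stations"] = str(p)

    p = out / "coastline.geojson"
    with open(p, "w") as fh:
        json.dump(
            {
                "type": "FeatureCollection",
                "features": [
                    {"type": "Feature", "geometry": mapping(world.coastline),
                     "properties": {}}
                ],
            },
            fh,
        )
    paths["coastline"] = str(p)

    for name, grid in world.rasters.items():
        p = out / f"{name}.asc"
        write_ascii_grid(grid, p)
        paths[f"raster_{name}"] = str(p)
    p = out / "land_mask.asc"
    write_ascii_grid(world.land_mask, p)
    paths["land_mask"] = str(p)

    p = out / "relatedness.csv"
    write_relatedness_csv(world.relatedness, p)
    paths["relatedness"] = str(p)

    p = out / "landcover_classes.json"
    with open(p, "w") as fh:
        json.dump(world.landcover_classes, fh)
    paths["landcover_classes"] = str(p)

    p = out / "truth.csv"
    world.truth.to_csv(p, index=False)
    paths["truth"] = str(p)

    p = out / "config.json"
    with open(p, "w") as fh:
        json.dump(asdict(world.config), fh, indent=2)
    paths["config"] = str(p)
    return paths


def load_coastline(path):
    """Read a coastline GeoJSON written by :func:`save_world`."""
    with open(path) as fh:
        obj = json.load(fh)
    geoms = [shape(f["geometry"]) for f in obj["features"]]
    return shapely.union_all(geoms)
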