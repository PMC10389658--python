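"""Pipeline orchestration: configuration, staged runs, manifests.

A run executes the stages in dependency order::

    synth -> regions -> extract -> pairwise -> analyze

``synth`` generates a seeded synthetic world (alternatively, real-data
input paths may be supplied); ``regions`` builds the constrained Voronoi
sampling regions; ``extract`` summarises stations and rasters into the
master CSV; ``pairwise`` produces relatedness-class difference tables;
``analyze`` runs the replication statistics.  Every produced file is
checksummed into a JSON run manifest.  With ``resume=True`` a stage whose
outputs already exist with checksums matching the previous manifest is
skipped; skipping is never silent — it is recorded in the new manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    chi_square_presence,
    correlogram,
    dichotomize,
    group_summary,
    linear_assoc,
    two_group_means,
)
from .env_extract import (
    ExtractionConfig,
    assemble_master_table,
    filter_station_years,
    read_ascii_grid,
    read_station_csv,
    summarize_environment,
)
from .errors import LingscapeError, ValidationError
from .language_table import read_language_csv
from .relatedness import pairwise_differences, read_relatedness_csv, summarize_by_class
from .sampling_regions import (
    GeoPoint,
    build_regions,
    inflation_report,
    regions_from_geojson,
    regions_to_geojson,
)
from .synthetic_world import SynthConfig, generate_world, load_coastline, save_world

logger = logging.getLogger(__name__)

STAGES = ("synth", "regions", "extract", "pairwise", "analyze")


class StageError(LingscapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One reproducible run: either a synth config or real-data paths."""

    out_dir: str
    seed: int = 0
    synth: SynthConfig | None = None
    #: real-data mode: paths for languages, stations, coastline, rasters,
    #: relatedness, landcover_classes (same layout save_world emits).
    inputs: dict | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    radius_km: float = 100.0
    stages: tuple[str, ...] = STAGES
    resume: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.inputs is None):
            raise ValidationError(
                "exactly one of synth config or input paths must be given"
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {unknown}")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a YAML (or JSON) run configuration."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        if "synth" in raw and raw["synth"] is not None:
            synth = dict(raw["synth"])
            if "seed" not in synth:
                synth["seed"] = raw.get("seed", 0)
            for key in ("extent", "years"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            raw["synth"] = SynthConfig(**synth)
        if "extraction" in raw:
            extraction = dict(raw["extraction"])
            for key in ("station_window", "humidity_window"):
                if key in extraction:
                    extraction[key] = tuple(extraction[key])
            raw["extraction"] = ExtractionConfig(**extraction)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    timestamp: str
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str], skipped=False) -> None:
        self.stages[stage] = {
            "skipped": skipped,
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in outputs.items()
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _previous_manifest(out: Path) -> dict | None:
    p = out / "manifest.json"
    if not p.exists():
        return None
    with open(p) as fh:
        return json.load(fh)


def _can_skip(stage: str, previous: dict | None) -> bool:
    if previous is None or stage not in previous.get("stages", {}):
        return False
    entry = previous["stages"][stage]
    for meta in entry["outputs"].values():
        p = Path(meta["path"])
        if not p.exists() or _sha256(p) != meta["sha256"]:
            return False
    return True


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages; returns the manifest (also saved).

    Stage failures raise :class:`StageError`; outputs of completed stages
    are retained and recorded in the manifest before the error propagates.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    previous = _previous_manifest(out) if config.resume else None
    manifest = RunManifest(
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        seed=config.seed,
        config=_config_snapshot(config),
        versions={"lingscape": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
    )
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            runner = _STAGE_RUNNERS[stage]
            if config.resume and _can_skip(stage, previous):
                logger.info("stage %s: outputs unchanged, skipped", stage)
                manifest.stages[stage] = previous["stages"][stage] | {"skipped": True}
                runner(config, out, state, load_only=True)
                continue
            try:
                outputs = runner(config, out, state, load_only=False)
            except Exception as exc:  # noqa: BLE001 - re-tagged per contract
                raise StageError(stage, exc) from exc
            manifest.record(stage, outputs)
    finally:
        manifest.save(out / "manifest.json")
    return manifest


def _config_snapshot(config: RunConfig) -> dict:
    snap = dataclasses.asdict(config)
    return snap


# -- stages --------------------------------------------------------------

def _stage_synth(config: RunConfig, out: Path, state: dict, load_only=False):
    synth_dir = out / "synth"
    if config.synth is None:
        state["input_paths"] = dict(config.inputs)
        return {}
    if load_only:
        state["input_paths"] = _synth_paths(synth_dir)
        return {}
    world = generate_world(config.synth)
    paths = save_world(world, synth_dir)
    state["world"] = world
    state["input_paths"] = paths
    return paths


def _synth_paths(synth_dir: Path) -> dict[str, str]:
    paths = {
        "languages": synth_dir / "languages.csv",
        "stations": synth_dir / "stations.csv",
        "coastline": synth_dir / "coastline.geojson",
        "relatedness": synth_dir / "relatedness.csv",
        "landcover_classes": synth_dir / "landcover_classes.json",
    }
    for name in ("elev", "qa", "biomass", "landcover"):
        paths[f"raster_{name}"] = synth_dir / f"{name}.asc"
    return {k: str(v) for k, v in paths.items()}


def _load_common(state: dict):
    paths = state["input_paths"]
    if "records" not in state:
        state["records"] = read_language_csv(paths["languages"])
    return paths


def _stage_regions(config: RunConfig, out: Path, state: dict, load_only=False):
    paths = _load_common(state)
    regions_path = out / "regions.geojson"
    if load_only:
        with open(regions_path) as fh:
            state["regions"] = regions_from_geojson(json.load(fh))
        return {}
    coastline = load_coastline(paths["coastline"])
    points = [GeoPoint(r.id, r.lon, r.lat) for r in state["records"]]
    regions = build_regions(points, coastline, radius_km=config.radius_km)
    state["regions"] = regions
    with open(regions_path, "w") as fh:
        json.dump(regions_to_geojson(regions), fh)
    table, n_inflated, fraction = inflation_report(regions)
    inflation_path = out / "inflation_report.csv"
    table.to_csv(inflation_path, index=False)
    logger.info(
        "inflation artifact: %d of %d regions (%.1f%%) exceed their own buffer",
        n_inflated, len(regions), 100 * fraction,
    )
    return {"regions": regions_path, "inflation_report": inflation_path}


def _stage_extract(config: RunConfig, out: Path, state: dict, load_only=False):
    paths = _load_common(state)
    master_path = out / "master.csv"
    if load_only:
        state["master"] = pd.read_csv(master_path, dtype={"id": str})
        return {}
    if "regions" not in state:
        raise ValidationError("extract requires the regions stage")
    stations = read_station_csv(paths["stations"])
    stations = filter_station_years(stations, config.extraction.station_window)
    numeric = {
        "elev": (read_ascii_grid(paths["raster_elev"]), "m"),
        "qa": (read_ascii_grid(paths["raster_qa"]), "unitless"),
        "biomass": (read_ascii_grid(paths["raster_biomass"]), "MgHa"),
    }
    with open(paths["landcover_classes"]) as fh:
        class_map = {int(k): v for k, v in json.load(fh).items()}
    landcover = (read_ascii_grid(paths["raster_landcover"], kind="categorical"),
                 class_map)
    summaries = [
        summarize_environment(
            region,
            stations=stations,
            numeric_rasters=numeric,
            landcover=landcover,
            config=config.extraction,
        )
        for region in state["regions"]
    ]
    master = assemble_master_table(state["records"], state["regions"], summaries)
    master.to_csv(master_path, index=False)
    state["master"] = master
    return {"master": master_path}


def _stage_pairwise(config: RunConfig, out: Path, state: dict, load_only=False):
    if load_only:
        return {}
    paths = _load_common(state)
    master = state["master"]
    table = read_relatedness_csv(
        paths["relatedness"], language_ids=master["id"].tolist()
    )
    outputs = {}
    for var in ("ConsHeavy", "CHeavyLog", "v_tavg_dC__avg"):
        if var not in master.columns:
            continue
        values = dict(zip(master["id"], master[var]))
        pairs = pairwise_differences(values, table)
        p = out / f"pairwise_{var}.csv"
        pairs.to_csv(p, index=False)
        outputs[f"pairwise_{var}"] = p
        summary = summarize_by_class(pairs)
        p2 = out / f"pairwise_{var}_by_class.csv"
        summary.to_csv(p2, index=False)
        outputs[f"pairwise_{var}_by_class"] = p2
    return outputs


def _stage_analyze(config: RunConfig, out: Path, state: dict, load_only=False):
    if load_only:
        return {}
    master = state["master"]
    results: dict[str, dict] = {}

    def col(name):
        return master[name].to_numpy(dtype=float) if name in master else None

    # heaviness vs temperature (station-based)
    for y_name, x_name in (
        ("CHeavyLog", "v_tmax_dC__avg"),
        ("ConsHeavy", "v_tavg_dC__avg"),
        ("VowIndex", "v_qa_unitless__average"),
    ):
        x, y = col(x_name), col(y_name)
        if x is None or y is None:
            continue
        try:
            fit = linear_assoc(x, y)
        except ValidationError as exc:
            logger.warning("linear fit %s ~ %s skipped: %s", y_name, x_name, exc)
            continue
        results[f"fit_{y_name}__{x_name}"] = dataclasses.asdict(fit)

    # presence/absence chi-square replications against median splits
    for trait, env in (("FRndV", "v_qa_unitless__average"),
                       ("VelarNas", "v_biomass_MgHa__average")):
        if env not in master.columns:
            continue
        env_vals = master[env].to_numpy(dtype=float)
        trait_vals = (master[trait] == "Yes").to_numpy(dtype=float)
        keep = np.isfinite(env_vals)
        if keep.sum() < 10:
            continue
        high = dichotomize(env_vals[keep], "median")
        res = chi_square_presence(trait_vals[keep], high)
        results[f"chi2_{trait}__{env}"] = {
            "chi2": res.chi2, "p": res.p, "table": res.table.tolist(),
            "expected_minimum": res.expected_minimum,
            "low_expected": res.low_expected,
        }

    # tone-level humidity summary and aspirates/altitude comparison
    if "v_qa_unitless__average" in master.columns:
        summary = group_summary(col("v_qa_unitless__average"), master["ToneOrdinal"])
        p = out / "tone_humidity_groups.csv"
        summary.to_csv(p, index=False)
    if "v_elev_m__average" in master.columns:
        alt = col("v_elev_m__average")
        asp = (master["Aspirates"] == "Yes").to_numpy()
        keep = np.isfinite(alt)
        if keep.sum() >= 4 and asp[keep].any() and (~asp[keep]).any():
            m1, m0, pval = two_group_means(alt[keep], asp[keep])
            results["aspirates_altitude"] = {
                "mean_with": m1, "mean_without": m0, "p": pval,
            }

    corr_vars = [
        v for v in (
            "ConsHeavy", "CHeavyLog", "ObsPct", "VQ", "CTotal",
            "v_tavg_dC__avg", "v_tmax_dC__avg", "v_prcp_mm__avg",
            "v_elev_m__average", "v_qa_unitless__average", "v_biomass_MgHa__average",
        )
        if v in master.columns
    ]
    corr = correlogram(master, corr_vars)
    corr_path = out / "correlogram.csv"
    corr.to_csv(corr_path)

    results_path = out / "analysis.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=2)
    state["analysis"] = results
    return {"analysis": results_path, "correlogram": corr_path}


_STAGE_RUNNERS = {
    "synth": _stage_synth,
    "regions": _stage_regions,
    "extract": _stage_extract,
    "pairwise": _stage_pairwise,
    "analyze": _stage_analyze,
}
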