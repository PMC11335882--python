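"""Configuration-driven orchestration of pipeline stages.

A run configuration (YAML) names an output directory, a seed, the
stages to execute and per-stage parameter overrides.  Stages form a
fixed dependency graph (simulate → fwi → climatology → extent →
correlate); running a stage whose inputs are missing first re-runs the
producing stage.  Every run writes a manifest recording parameters, the
seed, the package version and a checksum for each input and output
file, so deterministic stages are byte-reproducible from the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .climatology import ForestMask, correlate_extent_burn, extent_series, percentile_field
from .fwi import OverwinterParams, SeasonRules, run_fwi_grid
from .geometry import cell_areas_km2
from .io import sha256_file, write_dataset
from .synthetic import GridSpec, WeatherParams, gen_weather

__all__ = ["RunConfig", "ConfigError", "validate_config", "run"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


# stage -> {parameter: type}
STAGE_SCHEMAS: dict[str, dict[str, type]] = {
    "simulate": {
        "nlat": int,
        "nlon": int,
        "lat0": float,
        "lon0": float,
        "year0": int,
        "year1": int,
    },
    "fwi": {"start_temp_c": float, "stop_temp_c": float, "run_days": int},
    "climatology": {"baseline_start": int, "baseline_end": int, "q": float, "min_days": int},
    "extent": {"canopy_threshold": float},
    "correlate": {"min_days": int},
}

# stage -> (input files, output files); inputs must exist or be producible
STAGE_FILES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "simulate": ((), ("weather.nc", "burn_daily.csv")),
    "fwi": (("weather.nc",), ("fwi.nc",)),
    "climatology": (("fwi.nc",), ("q95.nc",)),
    "extent": (("fwi.nc", "q95.nc"), ("extent.csv",)),
    "correlate": (("extent.csv", "burn_daily.csv"), ("correlation.csv",)),
}

PRODUCER = {
    f: stage for stage, (_, outs) in STAGE_FILES.items() for f in outs
}


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_FILES))
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "INFO"


def validate_config(source) -> RunConfig:
    """Parse and validate a YAML config file or dict.

    Every violation is collected; the raised :class:`ConfigError` lists
    all of them at once.  Unknown stages and unknown or mistyped stage
    parameters are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)

    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    known_top = {"outdir", "seed", "stages", "params", "log_level"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown top-level key '{key}'")

    outdir = raw.get("outdir")
    if not outdir:
        errors.append("missing required key 'outdir'")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")

    stages = raw.get("stages", list(STAGE_FILES))
    for stage in stages:
        if stage not in STAGE_FILES:
            errors.append(f"unknown stage '{stage}'")

    params = raw.get("params", {}) or {}
    for stage, overrides in params.items():
        schema = STAGE_SCHEMAS.get(stage)
        if schema is None:
            errors.append(f"params for unknown stage '{stage}'")
            continue
        for key, value in (overrides or {}).items():
            if key not in schema:
                errors.append(f"unknown parameter 'params.{stage}.{key}'")
            elif not isinstance(value, schema[key]) and not (
                schema[key] is float and isinstance(value, int)
            ):
                errors.append(
                    f"parameter 'params.{stage}.{key}' must be {schema[key].__name__},"
                    f" got {type(value).__name__}"
                )

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        outdir=Path(outdir),
        seed=seed,
        stages=list(stages),
        params={k: dict(v or {}) for k, v in params.items()},
        log_level=raw.get("log_level", "INFO"),
    )


# ---------------------------------------------------------------------------
# stage implementations (toy end-to-end chain)
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig) -> None:
    p = cfg.params.get("simulate", {})
    grid = GridSpec(
        nlat=p.get("nlat", 8),
        nlon=p.get("nlon", 8),
        lat0=p.get("lat0", 52.0),
        lon0=p.get("lon0", -118.0),
    )
    year0, year1 = p.get("year0", 1996), p.get("year1", 2002)
    weather = gen_weather(grid, year0, year1, WeatherParams(), seed=cfg.seed)
    write_dataset(weather, cfg.outdir / "weather.nc")

    # synthetic daily burn series for the correlation stage
    rng = np.random.default_rng(cfg.seed + 1)
    times = pd.DatetimeIndex(weather["time"].values)
    burn = pd.DataFrame(
        {
            "date": times,
            "region": "all",
            "area_burned_ha": rng.gamma(0.6, 800.0, len(times)),
        }
    )
    burn.to_csv(cfg.outdir / "burn_daily.csv", index=False)


def _stage_fwi(cfg: RunConfig) -> None:
    p = cfg.params.get("fwi", {})
    rules = SeasonRules(
        start_temp_c=p.get("start_temp_c", 12.0),
        stop_temp_c=p.get("stop_temp_c", 5.0),
        run_days=p.get("run_days", 3),
    )
    weather = xr.load_dataset(cfg.outdir / "weather.nc", engine="scipy")
    fields = run_fwi_grid(weather, rules, OverwinterParams())
    write_dataset(fields, cfg.outdir / "fwi.nc")


def _stage_climatology(cfg: RunConfig) -> None:
    p = cfg.params.get("climatology", {})
    fields = xr.load_dataset(cfg.outdir / "fwi.nc", engine="scipy")
    fields["season_active"] = fields["season_active"].astype(bool)
    years = pd.DatetimeIndex(fields["time"].values).year
    baseline = (
        p.get("baseline_start", int(years.min())),
        p.get("baseline_end", int(years.max()) - 1),
    )
    q = percentile_field(
        fields, baseline, q=p.get("q", 0.95), min_days=p.get("min_days", 50)
    )
    out = xr.Dataset({"q95": q.q95, "n_days": q.n_days})
    out.attrs["baseline_start"], out.attrs["baseline_end"] = baseline
    write_dataset(out, cfg.outdir / "q95.nc")


def _stage_extent(cfg: RunConfig) -> None:
    p = cfg.params.get("extent", {})
    fields = xr.load_dataset(cfg.outdir / "fwi.nc", engine="scipy")
    fields["season_active"] = fields["season_active"].astype(bool)
    qds = xr.load_dataset(cfg.outdir / "q95.nc", engine="scipy")
    from .climatology import PercentileField

    q = PercentileField(
        q95=qds["q95"],
        baseline_years=(int(qds.attrs["baseline_start"]), int(qds.attrs["baseline_end"])),
        n_days=qds["n_days"],
    )
    canopy = xr.ones_like(q.q95.fillna(0.0)) * 0.6
    forest = ForestMask.from_canopy_cover(canopy, p.get("canopy_threshold", 0.2))
    labels = xr.zeros_like(q.q95.fillna(0.0)).astype(int)
    areas = cell_areas_km2(fields["lat"].values, fields["lon"].values)
    ext = extent_series(fields, q, forest, labels, areas, region_names={0: "all"})
    ext.to_csv(cfg.outdir / "extent.csv", index=False)


def _stage_correlate(cfg: RunConfig) -> None:
    p = cfg.params.get("correlate", {})
    ext = pd.read_csv(cfg.outdir / "extent.csv", parse_dates=["date"])
    burn = pd.read_csv(cfg.outdir / "burn_daily.csv", parse_dates=["date"])
    corr = correlate_extent_burn(ext, burn, min_days=p.get("min_days", 3))
    corr.to_csv(cfg.outdir / "correlation.csv", index=False)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fwi": _stage_fwi,
    "climatology": _stage_climatology,
    "extent": _stage_extent,
    "correlate": _stage_correlate,
}


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Missing inputs are recomputed by first running their producing
    stage.  Returns the manifest (also written to ``manifest.json``):
    parameters, seed, package version, and a SHA-256 checksum for every
    input and output file of every executed stage.
    """
    cfg = config
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    executed: list[str] = []

    def ensure(stage: str) -> None:
        if stage in executed:
            return
        inputs, _ = STAGE_FILES[stage]
        for f in inputs:
            if not (cfg.outdir / f).exists():
                ensure(PRODUCER[f])
        try:
            _STAGE_FN[stage](cfg)
        except Exception as exc:  # halt with stage name and cause
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        executed.append(stage)

    order = [s for s in STAGE_FILES if s in cfg.stages]
    for stage in order:
        ensure(stage)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": executed,
        "params": cfg.params,
        "files": {},
    }
    for stage in executed:
        inputs, outputs = STAGE_FILES[stage]
        for f in set(inputs) | set(outputs):
            path = cfg.outdir / f
            if path.exists():
                manifest["files"][f] = sha256_file(path)
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
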