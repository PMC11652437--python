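"""End-to-end orchestration: generate -> process -> expose -> model.

A run is a directory, never overwritten, holding the synthetic study,
per-day exposure and activity tables, the assembled panel(s), model
results per activity-space method, and a manifest with the seed,
config hash and exclusion ledger — enough to reproduce the run
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelerometry import process_accel_day, read_accel_csv
from .config import ActivitySpaceParams, RunConfig, save_config
from .exposures import EnvLayer, derive_day_exposures
from .geo import read_geojson
from .gps import gps_day_valid, impute_gaps, read_gps_csv
from .grids import read_esri_ascii
from .models import assemble_panel, fit_main_model, fit_null_icc, person_mean_center
from .synthetic import generate_study

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_environment", "exposures_for_dir", "activity_for_dir",
           "model_from_tables"]


@dataclasses.dataclass
class _LoadedEnv:
    grid: object
    streets: list
    greenspace_layer: EnvLayer
    park_distance_layer: EnvLayer
    park_layer: EnvLayer
    walkability_layer: EnvLayer


def load_environment(env_dir) -> _LoadedEnv:
    """Rebuild the environment bundle from an ``env/`` directory on disk."""
    env_dir = Path(env_dir)
    grid, green = read_esri_ascii(env_dir / "greenspace.asc")
    _, dist = read_esri_ascii(env_dir / "park_distance.asc")
    _, parks = read_esri_ascii(env_dir / "parks.asc")
    _, walk = read_esri_ascii(env_dir / "walkability.asc")
    streets, _props = read_geojson(env_dir / "streets.geojson")
    return _LoadedEnv(
        grid=grid,
        streets=streets,
        greenspace_layer=EnvLayer(grid, green, "green_pct"),
        park_distance_layer=EnvLayer(grid, dist, "park_distance_m"),
        park_layer=EnvLayer(grid, np.nan_to_num(parks), "park_indicator"),
        walkability_layer=EnvLayer(grid, walk, "walkability"),
    )


def exposures_for_dir(gps_dir, env, config: RunConfig, params: ActivitySpaceParams,
                      homes: dict | None = None) -> pd.DataFrame:
    """Read every GPS day, impute, flag validity, and derive daily exposures."""
    rows = []
    files = sorted(Path(gps_dir).glob("*.csv"))
    if not files:
        log.warning("no GPS files in %s; emitting empty exposure table", gps_dir)
    n_invalid = 0
    for path in files:
        track = impute_gaps(read_gps_csv(path), config.imputation)
        valid, coverage = gps_day_valid(track)
        if not valid:
            n_invalid += 1
            continue
        home = homes.get(track.participant_id) if homes else None
        rec = derive_day_exposures(track, env, params, home=home)
        row = dataclasses.asdict(rec)
        row["date"] = rec.date.isoformat()
        row["gps_coverage_hours"] = coverage
        rows.append(row)
    log.info("GPS: %d days read, %d invalid (<6 h after imputation)", len(files), n_invalid)
    cols = ["participant_id", "wave", "date", "day_type", "method", "bandwidth_or_radius",
            "green_pct", "park_distance_m", "parks_any", "walkability", "gps_coverage_hours"]
    return pd.DataFrame(rows, columns=cols)


def activity_for_dir(accel_dir, config: RunConfig) -> pd.DataFrame:
    """Process every accelerometer day to wear hours, validity, MVPA minutes."""
    rows = []
    files = sorted(Path(accel_dir).glob("*.csv"))
    if not files:
        log.warning("no accelerometer files in %s; emitting empty activity table", accel_dir)
    for path in files:
        rec = process_accel_day(read_accel_csv(path), config.freedson)
        row = dataclasses.asdict(rec)
        row["date"] = rec.date.isoformat()
        rows.append(row)
    cols = ["participant_id", "wave", "date", "day_type", "mvpa_minutes", "wear_hours", "valid"]
    return pd.DataFrame(rows, columns=cols)


def model_from_tables(exposure_df, activity_df, roster, temperature, config: RunConfig):
    """Assemble the panel, center exposures, fit the null-ICC and main models."""
    panel = assemble_panel(exposure_df, activity_df, roster, temperature,
                           log_offset=config.model.log_offset)
    continuous = [e for e in config.model.exposures if e != "parks_any"]
    panel = person_mean_center(panel, continuous + ["parks_any"])
    icc = fit_null_icc(panel)
    result = fit_main_model(panel, config.model)
    return panel, icc, result


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline into a fresh run directory."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FileExistsError(f"run directory {out_dir} exists and is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out_dir / "run.log")
    logging.getLogger().addHandler(fh)

    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    study = _stage("simulate")(generate_study)(syn, out_dir / "study")
    env = study.env
    homes = {
        r["participant_id"]: (float(r["home_x"]), float(r["home_y"]))
        for _, r in study.roster.iterrows()
    }
    study.temperature["date"] = study.temperature["date"].astype(str)

    activity = _stage("activity")(activity_for_dir)(out_dir / "study" / "accel", config)
    activity.to_csv(out_dir / "activity.csv", index=False)

    manifest: dict = {
        "seed": config.seed,
        "dayspace_version": __version__,
        "config_sha256": None,
        "n_days_generated": int(len(study.truth)),
        "methods": {},
    }
    for method in [m.strip() for m in config.activity_space.method.split(",")]:
        params = dataclasses.replace(config.activity_space, method=method)
        exposure = _stage(f"exposures[{method}]")(exposures_for_dir)(
            out_dir / "study" / "gps", env, config, params, homes=homes
        )
        exposure.to_csv(out_dir / f"exposures_{method}.csv", index=False)
        panel, icc, result = _stage(f"model[{method}]")(model_from_tables)(
            exposure, activity, study.roster, study.temperature, config
        )
        panel.to_csv(out_dir / f"panel_{method}.csv", index=False)
        tidy = result.terms.reset_index().rename(columns={"index": "term"})
        tidy.to_csv(out_dir / f"model_{method}.csv", index=False)
        with open(out_dir / f"model_{method}.txt", "w") as fhh:
            fhh.write(_summary_text(method, icc, result))
        manifest["methods"][method] = {
            "n_exposure_days": int(len(exposure)),
            "n_panel_days": int(len(panel)),
            "n_participants": int(result.n_groups),
            "icc_null": float(icc.icc),
            "converged": bool(result.converged),
        }

    save_config(config, out_dir / "config.yaml")
    manifest["config_sha256"] = hashlib.sha256((out_dir / "config.yaml").read_bytes()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fhh:
        json.dump(manifest, fhh, indent=2)
    logging.getLogger().removeHandler(fh)
    return out_dir


def _summary_text(method: str, icc, result) -> str:
    lines = [
        f"Daily MVPA minutes (log-transformed) ~ exposures + covariates, {method} activity space",
        f"n person-days = {result.n_obs}, n participants = {result.n_groups}, "
        f"estimation = {result.method}, converged = {result.converged}",
        f"null-model ICC = {icc.icc:.3f} "
        f"(between var {icc.between_var:.3f}, within var {icc.within_var:.3f})",
        "",
        f"{'term':<28}{'exp(b)':>8}{'95% CI':>18}{'p':>9}",
    ]
    for term, row in result.terms.iterrows():
        ci = f"({row.ci_low:.2f}-{row.ci_high:.2f})"
        lines.append(f"{term:<28}{row.estimate_exp:>8.2f}{ci:>18}{row.p:>9.3g}")
    return "\n".join(lines) + "\n"
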