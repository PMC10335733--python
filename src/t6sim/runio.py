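"""Configuration parsing, result writers, and run metadata.

Scenario configurations are YAML with a documented, strictly validated
schema (unknown keys are rejected with their key path).  Outputs are CSV
time series and snapshot tables written at full double precision plus a
metadata JSON carrying the fully resolved configuration and every RNG
seed, which is sufficient to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from t6sim import __version__
from t6sim.experiments import CompetitionResult, ScenarioConfig
from t6sim.kinetics import KineticParams
from t6sim.mechanics import Arena, MechanicsParams, StrainSpec
from t6sim.population import Population

__all__ = [
    "ConfigError",
    "RunMetadata",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "write_results",
    "read_timeseries",
    "snapshot_frame",
]


class ConfigError(ValueError):
    """A configuration file violates the schema; the message names the key."""


_KINETIC_KEYS = {"p0", "tau_plus", "lambda_plus", "lambda_s", "lambda_f"}
_STRAIN_KEYS = {"name", "kinetics", "r0", "c", "tau_lys"}
_MECH_KEYS = {
    "k_elastic",
    "zeta",
    "zeta_rot",
    "contact_eps",
    "pressure_star",
    "dt_mech",
}
_ARENA_KEYS = {"Lx", "Ly", "boundary", "carrying_capacity", "mech"}
_SCENARIO_KEYS = {
    "arena",
    "strains",
    "mix_ratio",
    "n_init",
    "primed",
    "t_end",
    "dt",
    "n_replicates",
    "seed",
    "measure_window",
    "record_every",
    "k_max",
    "delta_L",
    "init_area_fraction",
}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], path: str) -> None:
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _build(cls, mapping: Mapping[str, Any], path: str):
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any]) -> ScenarioConfig:
    """Validate a nested dict and build a :class:`ScenarioConfig`."""
    _check_keys(data, _SCENARIO_KEYS, "scenario")
    if "arena" not in data or "strains" not in data:
        raise ConfigError("scenario: 'arena' and 'strains' are required")

    arena_d = dict(data["arena"])
    _check_keys(arena_d, _ARENA_KEYS, "arena")
    if "mech" in arena_d:
        mech_d = dict(arena_d["mech"])
        _check_keys(mech_d, _MECH_KEYS, "arena.mech")
        arena_d["mech"] = _build(MechanicsParams, mech_d, "arena.mech")
    arena = _build(Arena, arena_d, "arena")

    strains = []
    for i, strain_d in enumerate(data["strains"]):
        strain_d = dict(strain_d)
        _check_keys(strain_d, _STRAIN_KEYS, f"strains[{i}]")
        if "kinetics" not in strain_d or "name" not in strain_d:
            raise ConfigError(f"strains[{i}]: 'name' and 'kinetics' are required")
        kin_d = dict(strain_d["kinetics"])
        _check_keys(kin_d, _KINETIC_KEYS, f"strains[{i}].kinetics")
        strain_d["kinetics"] = _build(KineticParams, kin_d, f"strains[{i}].kinetics")
        strains.append(_build(StrainSpec, strain_d, f"strains[{i}]"))

    scenario_d = {k: v for k, v in data.items() if k not in ("arena", "strains")}
    if "mix_ratio" in scenario_d and scenario_d["mix_ratio"] is not None:
        scenario_d["mix_ratio"] = tuple(scenario_d["mix_ratio"])
    if "measure_window" in scenario_d and scenario_d["measure_window"] is not None:
        scenario_d["measure_window"] = tuple(scenario_d["measure_window"])
    return _build(
        ScenarioConfig,
        {"arena": arena, "strains": tuple(strains), **scenario_d},
        "scenario",
    )


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigError(f"{path}: empty configuration")
    return config_from_dict(data)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Fully resolved plain-dict form of a configuration (round-trips)."""

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    data = plain(config)
    data["strains"] = [plain(s) for s in config.strains]
    # echo resolved defaults so a written config is self-contained
    data["n_init"] = config.resolved_n_init
    data["measure_window"] = list(config.resolved_window)
    data["mix_ratio"] = list(config.resolved_mix_ratio)
    return data


def save_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


@dataclass
class RunMetadata:
    """Everything needed to reproduce a run bit-for-bit."""

    config: dict
    master_seed: int
    replicate_seeds: list[int]
    version: str = __version__
    wall_time_s: float | None = None
    status: str = "ok"

    @classmethod
    def for_config(cls, config: ScenarioConfig, **kw) -> "RunMetadata":
        children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
        return cls(
            config=config_to_dict(config),
            master_seed=config.seed,
            replicate_seeds=[int(c.entropy) for c in children],
            **kw,
        )


def _timeseries_frame(result: CompetitionResult) -> pd.DataFrame:
    rows = {"time_h": result.times}
    for s, name in enumerate(result.strain_names):
        rows[f"live_{name}"] = result.live[:, s]
        rows[f"lysing_{name}"] = result.lysing[:, s]
        rows[f"area_frac_{name}"] = result.area_frac[:, s]
        rows[f"window_frac_{name}"] = result.window_frac[:, s]
    return pd.DataFrame(rows)


def snapshot_frame(pop: Population, strain_names: list[str]) -> pd.DataFrame:
    """Tabular snapshot of a population (one row per cell)."""
    return pd.DataFrame(
        {
            "id": pop.ids,
            "strain": [strain_names[s] for s in pop.strain],
            "x_um": pop.x,
            "y_um": pop.y,
            "theta_rad": pop.theta,
            "ell_um": pop.ell,
            "radius_um": np.full(len(pop), pop.radius),
            "N": pop.N,
            "G": pop.G.astype(int),
            "status": np.where(pop.lysing, "lysing", "alive"),
            "lysis_clock": pop.lysis_clock,
        }
    )


def write_results(
    results: CompetitionResult | list[CompetitionResult],
    metadata: RunMetadata,
    outdir,
) -> dict[str, Path]:
    """Write time-series CSVs, optional final snapshots, and metadata JSON.

    Numeric columns keep full double precision (``repr``-faithful) so that
    reloaded values compare equal to the in-memory ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(results, CompetitionResult):
        results = [results]
    paths: dict[str, Path] = {}
    for i, result in enumerate(results):
        p = outdir / f"timeseries_rep{i:03d}.csv"
        _timeseries_frame(result).to_csv(p, index=False)
        paths[f"timeseries_rep{i:03d}"] = p
        if result.final_population is not None:
            sp = outdir / f"snapshot_rep{i:03d}.csv"
            snapshot_frame(result.final_population, result.strain_names).to_csv(
                sp, index=False
            )
            paths[f"snapshot_rep{i:03d}"] = sp
    summary = pd.DataFrame(
        {
            "replicate": np.arange(len(results)),
            "phi": [r.phi for r in results],
            "status": [r.status for r in results],
        }
    )
    paths["summary"] = outdir / "summary.csv"
    summary.to_csv(paths["summary"], index=False)
    meta = dataclasses.asdict(metadata)
    meta["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    paths["metadata"] = outdir / "metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_event_log(events, strain_names: list[str], path) -> None:
    """Write a firing event log (one row per fired sheath) as CSV.

    ``events`` are the tuples collected by a simulation run with
    ``log_events=True``; strain indices are resolved to names and a missing
    target (a miss) is left empty.
    """
    rows = pd.DataFrame(
        events,
        columns=["time_h", "shooter_id", "shooter_strain", "result",
                 "target_id", "target_strain"],
    )
    rows["shooter_strain"] = rows["shooter_strain"].map(lambda s: strain_names[s])
    rows["target_strain"] = rows["target_strain"].map(
        lambda s: strain_names[s] if s >= 0 else ""
    )
    rows.loc[rows["target_id"] < 0, "target_id"] = pd.NA
    rows.to_csv(path, index=False)
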