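"""Scenario configuration loading, tabular I/O and provenance capture."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .parameters import (DoseRegimen, ParameterError, default_geometry,
                         load_drug, load_geometry, load_physiology)
from .simulator import SolverOptions, ddi_ratios, pk_metrics, simulate

OBSERVED_COLUMNS = ("subject", "time_h", "conc_ug_per_ml")
RESULT_COLUMNS = ("time_min", "drug", "compartment", "amount_nmol")


class ConfigError(ParameterError):
    """A scenario configuration is malformed; message names path and field."""


def _scenario_root():
    return resources.files("metpbpk") / "data" / "scenarios"


def packaged_scenario_names() -> list:
    return sorted(p.name[:-5] for p in _scenario_root().iterdir()
                  if p.name.endswith(".yaml"))


def load_scenario(name_or_path) -> dict:
    """Load a scenario config from a packaged name or a YAML path."""
    path = _scenario_root() / f"{name_or_path}.yaml"
    try:
        text = path.read_text()
        source = f"packaged:{name_or_path}"
    except (FileNotFoundError, OSError):
        with open(name_or_path) as fh:
            text = fh.read()
        source = str(name_or_path)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{source}: scenario must be a mapping")
    cfg["_source"] = source
    cfg["_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return cfg


def _regimen(cfg: dict, key: str, drug: str, source: str) -> DoseRegimen:
    block = cfg.get(key)
    if not isinstance(block, dict) or "dose_mg" not in block:
        raise ConfigError(f"{source}: field {key}.dose_mg is required")
    return DoseRegimen(drug=drug, dose_mg=float(block["dose_mg"]),
                       times_min=tuple(block.get("times_min", (0.0,))),
                       lag_min=float(block.get("lag_min", 0.0))).validate()


def _solver_options(cfg: dict) -> SolverOptions:
    return SolverOptions(**cfg.get("solver", {}))


def run_scenario(name_or_path, out_dir, *, seed: int = 0) -> dict:
    """Execute a scenario config; writes tidy CSV, metrics JSON and a log.

    Returns the metrics summary dictionary (also written to disk).
    """
    cfg = load_scenario(name_or_path)
    source = cfg["_source"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phys = load_physiology(cfg.get("physiology"))
    geom = load_geometry(cfg.get("geometry"))
    if "victim" not in cfg:
        raise ConfigError(f"{source}: field 'victim' is required")
    victim = load_drug(cfg["victim"], phys)
    victim_reg = _regimen(cfg, "victim_regimen", victim.name, source)
    options = _solver_options(cfg)
    t_window_h = float(cfg.get("t_window_h", 24.0))
    t_start = victim_reg.times_min[0]
    t_end = t_start + t_window_h * 60.0

    perp = perp_reg = None
    if cfg.get("perpetrator"):
        perp = load_drug(cfg["perpetrator"], phys)
        perp_reg = _regimen(cfg, "perp_regimen", perp.name, source)
        t_end = max(t_end, perp_reg.times_min[-1] + 60.0)

    kwargs = {"perpetrator": perp, "perp_regimen": perp_reg} if perp else {}
    combo = simulate(victim, victim_reg, phys, geom, t_end_min=t_end,
                     options=options, **kwargs)
    metrics = {"victim": dataclasses.asdict(
        pk_metrics(combo, t_window_h, t_start_min=t_start))}
    if perp is not None:
        alone = simulate(victim, victim_reg, phys, geom, t_end_min=t_end,
                         options=options)
        ddi = ddi_ratios(pk_metrics(alone, t_window_h, t_start_min=t_start),
                         pk_metrics(combo, t_window_h, t_start_min=t_start))
        metrics["victim_alone"] = dataclasses.asdict(ddi.alone)
        metrics["aucr"] = ddi.aucr
        metrics["cmaxr"] = ddi.cmaxr
        metrics["perpetrator"] = dataclasses.asdict(
            pk_metrics(combo, t_window_h, drug="perpetrator"))

    # tidy trajectories
    frames = []
    for role, arr in combo.amounts.items():
        L = combo.layouts[role]
        prof = combo.profiles[role]
        for name in L.names:
            frames.append(pd.DataFrame({
                "time_min": combo.t_min, "drug": prof.name,
                "compartment": name, "amount_nmol": arr[L[name]]}))
    tidy = pd.concat(frames, ignore_index=True)

    stem = Path(str(name_or_path)).stem
    tidy.to_csv(out / f"{stem}_trajectories.csv", index=False)
    summary = {
        "scenario": source,
        "metrics": metrics,
        "provenance": {"config_sha256": cfg["_sha256"], "seed": seed,
                       "version": __version__},
    }
    with open(out / f"{stem}_metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / f"{stem}.log", "w") as fh:
        fh.write(f"scenario={source}\nsha256={cfg['_sha256']}\n"
                 f"seed={seed}\nversion={__version__}\n"
                 f"t_window_h={t_window_h}\n")
    return summary


def write_observed_csv(dataset, path) -> None:
    """Strict-schema CSV export of a synthetic observed dataset."""
    df = dataset.data
    missing = set(OBSERVED_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"dataset missing columns {sorted(missing)}")
    # %.17g guarantees a lossless float64 round trip through the text file
    df.loc[:, list(OBSERVED_COLUMNS)].to_csv(path, index=False,
                                             float_format="%.17g")


def read_observed_csv(path) -> pd.DataFrame:
    """Read an observed-concentration CSV, validating the header."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in OBSERVED_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"{path}: missing required column {col!r}")
    return df.loc[:, list(OBSERVED_COLUMNS)]


def write_results_csv(result, path) -> None:
    """Tidy per-compartment trajectory export for a SimulationResult."""
    frames = []
    for role, arr in result.amounts.items():
        L = result.layouts[role]
        for name in L.names:
            frames.append(pd.DataFrame({
                "time_min": result.t_min, "drug": result.profiles[role].name,
                "compartment": name, "amount_nmol": arr[L[name]]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
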