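"""File formats and configuration for the pipeline.

CSV is the single tabular interchange format (long-form time courses with
header ``time_d,species,replicate,value``; trajectory exports with header
``time_d,biomass_gDW_L,sucrose_g_L,kno3_g_L,volume_L``), JSON sidecars
carry structured results, and run configuration is a YAML mapping
validated against a documented schema (unknown keys rejected).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import pandas as pd
import yaml

from .estimate import FitResult, TimeCourseDataset, SPECIES
from .kinetics import (
    CultureState,
    FeedStrategy,
    KineticParameters,
    ModelType,
)

__all__ = [
    "ParseError",
    "ConfigError",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "feed_from_config",
    "params_from_config",
]

TIMECOURSE_COLUMNS = ("time_d", "species", "replicate", "value")


class ParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def read_timecourse_csv(
    path, weights: Optional[Dict[str, float]] = None
) -> TimeCourseDataset:
    """Read a long-form time-course CSV into a validated dataset.

    Errors name the offending line (1-based, counting the header).
    """
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing columns {sorted(missing)} "
            f"(expected header {','.join(TIMECOURSE_COLUMNS)})")
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.species not in SPECIES:
            raise ParseError(
                f"{path}:{idx}: unknown species {row.species!r}")
        if not (row.value >= 0):
            raise ParseError(
                f"{path}:{idx}: negative or non-numeric value "
                f"{row.value!r}")
        if not (row.time_d >= 0):
            raise ParseError(f"{path}:{idx}: negative time {row.time_d!r}")
    try:
        return TimeCourseDataset(df, weights=weights)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timecourse_csv(data: TimeCourseDataset, path) -> None:
    data.data.to_csv(path, index=False,
                     columns=list(TIMECOURSE_COLUMNS))


def write_fit_report(fit: FitResult, path) -> None:
    """Machine-readable JSON fit report plus a human-readable table
    (same stem, .txt): parameters, SSE, n, p, df and variance."""
    path = Path(path)
    payload = {
        "model_type": fit.model_type.value,
        "params": dataclasses.asdict(fit.params),
        "objective_sse": fit.objective,
        "n": fit.n,
        "p": fit.p,
        "df": fit.df,
        "variance": fit.variance,
        "n_restarts": fit.n_restarts,
        "seed": fit.seed,
        "converged": fit.converged,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    lines = [
        f"model type        : {fit.model_type.value}",
        f"objective (SSE)   : {fit.objective:.6g}",
        f"data points (n)   : {fit.n}",
        f"parameters (p)    : {fit.p}",
        f"degrees of freedom: {fit.df}",
        f"variance (SSE/df) : {fit.variance:.3f}",
        "",
        "parameter estimates:",
    ]
    for name, value in dataclasses.asdict(fit.params).items():
        lines.append(f"  {name:6s} = {value:.6g}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def read_fit_report(path):
    """Load the JSON fit report back as a FitSummary-compatible object."""
    from .discriminate import FitSummary

    payload = json.loads(Path(path).read_text())
    return FitSummary(
        objective=payload["objective_sse"],
        n=payload["n"],
        p=payload["p"],
        label=payload["model_type"],
    ), KineticParameters(**payload["params"])


# --- configuration -------------------------------------------------------

_TOP_LEVEL_KEYS = {
    "model_type", "dt", "seed", "params", "bounds", "weights",
    "initial_state", "restarts", "feed", "design", "noise_cv",
    "replicates", "horizon", "sampling_interval",
}
_FEED_KEYS = {"v0", "t_feed_start", "t_end", "flow", "feed_s1", "feed_s2"}
_STATE_KEYS = {"x", "s1", "s2", "v"}


def load_config(path) -> Dict[str, Any]:
    """Load and validate a YAML run configuration.

    Schema (all keys optional unless a stage requires them):
      model_type: monod | monod_sigmoid | sigmoid
      dt: float > 0 (integrator step, d)
      seed: int (mandatory for stochastic stages)
      params: {<parameter name>: value}           # kinetic parameters
      bounds: {<parameter name>: [lower, upper]}  # estimation box
      weights: {biomass|sucrose|kno3: W_j > 0}
      initial_state: {x, s1, s2, v}
      restarts: int >= 0
      feed: {v0, t_feed_start, t_end, flow, feed_s1, feed_s2}
      design: {<control>: {min, max, levels}, t_end: float, v_max: float}
      noise_cv, replicates, horizon, sampling_interval  # synthetic data
    Unknown keys anywhere are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "dt" in raw and not (float(raw["dt"]) > 0):
        raise ConfigError(f"{path}: dt must be > 0")
    if "model_type" in raw:
        try:
            ModelType(raw["model_type"])
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    if "feed" in raw:
        unknown = set(raw["feed"]) - _FEED_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown feed keys {sorted(unknown)}")
    if "initial_state" in raw:
        unknown = set(raw["initial_state"]) - _STATE_KEYS
        if unknown:
            raise ConfigError(
                f"{path}: unknown initial_state keys {sorted(unknown)}")
        state = {k: float(v) for k, v in raw["initial_state"].items()}
        if any(v < 0 for v in state.values()):
            raise ConfigError(f"{path}: initial_state values must be >= 0")
    if "weights" in raw:
        unknown = set(raw["weights"]) - set(SPECIES)
        if unknown:
            raise ConfigError(
                f"{path}: unknown weight species {sorted(unknown)}")
        if any(not (float(w) > 0) for w in raw["weights"].values()):
            raise ConfigError(f"{path}: weights must be > 0")
    if "params" in raw:
        params_from_config(raw)  # validates names and invariants
    return dict(raw)


def params_from_config(config: Mapping[str, Any]) -> KineticParameters:
    if "params" not in config:
        raise ConfigError("config has no 'params' block")
    valid = {f.name for f in dataclasses.fields(KineticParameters)}
    unknown = set(config["params"]) - valid
    if unknown:
        raise ConfigError(f"unknown kinetic parameters {sorted(unknown)}")
    try:
        return KineticParameters(
            **{k: float(v) for k, v in config["params"].items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def feed_from_config(config: Mapping[str, Any]) -> FeedStrategy:
    if "feed" not in config:
        raise ConfigError("config has no 'feed' block")
    try:
        return FeedStrategy(**{k: float(v)
                               for k, v in config["feed"].items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def state_from_config(
    config: Mapping[str, Any],
    default: Optional[CultureState] = None,
) -> CultureState:
    if "initial_state" not in config:
        if default is not None:
            return default
        raise ConfigError("config has no 'initial_state' block")
    return CultureState(**{k: float(v)
                           for k, v in config["initial_state"].items()})
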