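"""Configuration and result file handling (YAML config, CSV outputs)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .errors import ConfigError, ParameterError
from .model import TRAJECTORY_COLUMNS, Trajectory
from .params import Parameters, ScenarioConfig
from .synthetic import ObservedSeries

__all__ = [
    "load_config", "save_config", "load_parameters",
    "write_trajectory", "write_observed_series", "read_observed_series",
]


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML/JSON config file into a mapping (empty file -> {})."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return doc


def load_parameters(path: str | Path) -> tuple[Parameters, dict[str, ScenarioConfig]]:
    """Load Parameters (and optional named scenarios) from a config file.

    Schema: an optional ``parameters:`` mapping of Parameters fields
    (missing fields keep their defaults) and an optional ``scenarios:``
    mapping of name -> ScenarioConfig fields.
    """
    doc = load_config(path)
    try:
        params = Parameters.from_dict(doc.get("parameters", {}))
        scenarios = {name: ScenarioConfig.from_dict(cfg or {})
                     for name, cfg in (doc.get("scenarios") or {}).items()}
    except ParameterError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return params, scenarios


def save_config(params: Parameters, path: str | Path,
                scenarios: dict[str, ScenarioConfig] | None = None) -> None:
    doc: dict[str, Any] = {"parameters": params.to_dict()}
    if scenarios:
        doc["scenarios"] = {n: s.to_dict() for n, s in scenarios.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with the documented column order."""
    traj.to_frame().to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)


def write_observed_series(series: ObservedSeries, path: str | Path) -> None:
    """Two-column CSV with a comment header recording provenance."""
    lines = [f"# {json.dumps(series.provenance, sort_keys=True)}",
             "year,contract_rate_pct"]
    lines += [f"{y:g},{r:.6f}" for y, r in zip(series.years, series.rates)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_observed_series(path: str | Path) -> ObservedSeries:
    provenance: dict[str, Any] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                provenance = json.loads(first[1:].strip())
            except json.JSONDecodeError:
                provenance = {"note": first[1:].strip()}
            table = pd.read_csv(fh)
        else:
            fh.seek(0)
            table = pd.read_csv(fh)
    cols = {c.lower(): c for c in table.columns}
    try:
        years = table[cols["year"]].tolist()
        rate_col = cols.get("contract_rate_pct") or cols.get("contract_rate")
        rates = table[rate_col].tolist()
    except KeyError as exc:
        raise ConfigError(
            f"{path}: expected columns year, contract_rate[_pct]") from exc
    return ObservedSeries(years=tuple(years), rates=tuple(rates),
                          provenance=provenance)
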