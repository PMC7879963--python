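"""Readers/writers, fixture-directory round-tripping, and run manifests.

All tabular I/O is UTF-8 CSV with a mandatory header row; configuration is a
single YAML document validated with explicit checks at load.  Every CLI run
writes one JSON manifest recording the command, input/output hashes and the
seed, so reruns can be verified byte-for-byte on their artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SimulationClock, StockFlowSpec, spec_from_dict
from .errors import SpecificationError
from .scenarios import Lever
from .sensitivity import ParameterBound, SensitivityRecord
from .surveillance import SurveillanceSeries
from .toynation import (
    DEFAULT_WINDOW,
    FixtureConfig,
    ToyNation,
    make_surveillance_panel,
    make_toy_nation,
)


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    numeric: tuple[str, ...] = ()


PARAMS_SCHEMA = TableSchema("parameters", ("name", "value"), ("value",))
BOUNDS_SCHEMA = TableSchema(
    "bounds", ("parameter", "default", "low", "high", "note"), ("default", "low", "high")
)
SURVEILLANCE_SCHEMA = TableSchema(
    "surveillance", ("measure", "year", "value", "kind", "source"), ("year", "value")
)
TRAJECTORY_SCHEMA = TableSchema("trajectory", ("measure", "year", "value"), ("year", "value"))


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV against a declared schema; errors name the column and row."""
    frame = pd.read_csv(path, encoding="utf-8", keep_default_na=False, na_values=[])
    for column in schema.columns:
        if column not in frame.columns:
            raise SpecificationError(
                f"{schema.name} table {path}: missing column {column!r}"
            )
    for column in schema.numeric:
        converted = pd.to_numeric(frame[column], errors="coerce")
        bad = converted.isna() & frame[column].astype(str).ne("")
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SpecificationError(
                f"{schema.name} table {path}: non-numeric value in column "
                f"{column!r} at line {row}"
            )
        frame[column] = converted
    if schema is SURVEILLANCE_SCHEMA:
        for measure, group in frame.groupby("measure"):
            years = group["year"].to_numpy()
            if np.any(np.diff(years) <= 0):
                raise SpecificationError(
                    f"surveillance table {path}: years not strictly increasing "
                    f"for measure {measure!r}"
                )
    return frame[list(schema.columns)]


def write_table(path: str | Path, frame: pd.DataFrame, schema: TableSchema) -> None:
    missing = [c for c in schema.columns if c not in frame.columns]
    if missing:
        raise SpecificationError(f"{schema.name} table: missing column(s) {missing}")
    frame[list(schema.columns)].to_csv(path, index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# Generic stock-flow model config (YAML dialect, documented in docs/methods.md)


def load_stockflow_yaml(path: str | Path) -> StockFlowSpec:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise SpecificationError(f"model config {path}: top level must be a mapping")
    for key in ("stocks", "flows"):
        if key not in data:
            raise SpecificationError(f"model config {path}: missing section {key!r}")
    return spec_from_dict(data)


# --------------------------------------------------------------------------
# Fixture directory


def write_fixture_dir(directory: str | Path, config: FixtureConfig) -> list[Path]:
    """Write a self-contained fixture directory; returns the files written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nation = make_toy_nation(config)
    trajectory = nation.base_trajectory()
    panel = make_surveillance_panel(config, trajectory)

    params_frame = pd.DataFrame(
        sorted(nation.params.items()), columns=["name", "value"]
    )
    bounds_frame = pd.DataFrame(
        [(b.parameter, b.default, b.low, b.high, b.note) for b in nation.bounds],
        columns=list(BOUNDS_SCHEMA.columns),
    )
    surveillance_rows = []
    for measure in sorted(panel):
        series = panel[measure]
        for year, value in zip(series.years, series.values):
            surveillance_rows.append((measure, int(year), float(value), series.kind, series.source))
    surveillance_frame = pd.DataFrame(
        surveillance_rows, columns=list(SURVEILLANCE_SCHEMA.columns)
    )
    nation_doc = {
        "population": config.population,
        "seed": int(config.seed),
        "noise": config.noise,
        "clock": {
            "start_year": config.clock.start_year,
            "end_year": config.clock.end_year,
        },
        "window": list(DEFAULT_WINDOW),
        "cost_year": nation.ledger.cost_year,
        "discount_rate": nation.ledger.discount_rate,
        "thresholds": {
            "mape": 0.10,
            "influence": 0.005,
            "persistence_points": 3,
        },
        "levers": {
            name: {param: float(effect) for param, effect in lever.targets.items()}
            for name, lever in nation.levers.items()
        },
        "deviators": {m: [mode, value] for m, (mode, value) in config.deviators.items()},
        "wobblers": dict(config.wobblers),
    }
    files = {
        directory / "parameters.csv": (params_frame, PARAMS_SCHEMA),
        directory / "bounds.csv": (bounds_frame, BOUNDS_SCHEMA),
        directory / "surveillance.csv": (surveillance_frame, SURVEILLANCE_SCHEMA),
    }
    for path, (frame, schema) in files.items():
        write_table(path, frame, schema)
    nation_path = directory / "nation.yaml"
    with open(nation_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(nation_doc, fh, sort_keys=True)
    return [nation_path, *files.keys()]


def load_fixture_dir(directory: str | Path) -> tuple[ToyNation, dict[str, SurveillanceSeries], dict]:
    """Load a fixture directory back into (nation, surveillance panel, raw config)."""
    directory = Path(directory)
    nation_path = directory / "nation.yaml"
    if not nation_path.exists():
        raise SpecificationError(f"fixture directory {directory}: missing nation.yaml")
    with open(nation_path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    clock = SimulationClock(
        start_year=int(doc["clock"]["start_year"]), end_year=int(doc["clock"]["end_year"])
    )
    config = FixtureConfig(
        population=float(doc["population"]),
        clock=clock,
        seed=int(doc["seed"]),
        noise=float(doc["noise"]),
        deviators={m: (str(v[0]), float(v[1])) for m, v in doc.get("deviators", {}).items()},
        wobblers={m: float(v) for m, v in doc.get("wobblers", {}).items()},
    )
    params_frame = read_table(directory / "parameters.csv", PARAMS_SCHEMA)
    params = {str(row["name"]): float(row["value"]) for _, row in params_frame.iterrows()}
    bounds_frame = read_table(directory / "bounds.csv", BOUNDS_SCHEMA)
    bounds = [
        ParameterBound(
            parameter=str(row["parameter"]),
            default=float(row["default"]),
            low=float(row["low"]),
            high=float(row["high"]),
            note=str(row["note"]),
        )
        for _, row in bounds_frame.iterrows()
    ]
    levers = {
        name: Lever(name, {param: float(effect) for param, effect in targets.items()})
        for name, targets in doc.get("levers", {}).items()
    }
    nation = ToyNation(config=config, params=params, levers=levers, bounds=bounds)
    surveillance_frame = read_table(directory / "surveillance.csv", SURVEILLANCE_SCHEMA)
    panel: dict[str, SurveillanceSeries] = {}
    for measure, group in surveillance_frame.groupby("measure"):
        panel[str(measure)] = SurveillanceSeries(
            measure=str(measure),
            years=group["year"].to_numpy(dtype=int),
            values=group["value"].to_numpy(dtype=float),
            kind=str(group["kind"].iloc[0]),
            source=str(group["source"].iloc[0]),
        )
    return nation, panel, doc


# --------------------------------------------------------------------------
# Run manifest


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    inputs: Iterable[str | Path],
    outputs: Iterable[str | Path],
    seed: int | None = None,
    extra: Mapping | None = None,
) -> Path:
    manifest = {
        "command": command,
        "tool_version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    if extra:
        manifest["settings"] = dict(extra)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def records_frame(records: Iterable[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "outcome": r.outcome,
                "base": r.base,
                "low_value": r.low_value,
                "high_value": r.high_value,
                "change_low": r.change_low,
                "change_high": r.change_high,
                "influence": r.influence,
                "failed": r.failed,
                "message": r.message,
            }
            for r in records
        ]
    )
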