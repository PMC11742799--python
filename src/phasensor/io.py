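"""File formats: calibration CSV, model JSON, selection TSV, config YAML.

CSV dialect: UTF-8, comma-separated, header
``time_h,od_mean,od_sd,pha_g_per_l,pha_sd,weight``; decimal point ``.``;
``NA`` (or empty) for missing values.  Only ``od_mean`` is strictly
required — missing optional columns are filled with their defaults
(od_sd 0, weight 1); rows without a PHA value are excluded from
calibration sets but kept when a file is read for estimation.

Model files are JSON with full-precision floats (Python's repr round-trips
binary doubles exactly), so write → read reproduces parameters bit for
bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FitOptions, FittedModel, SelectionTable
from .catalog import get_structure
from .dataset import COLUMNS, CalibrationSet
from .errors import ParseError, ValidationError
from .simulate import SimulationConfig

__all__ = [
    "read_calibration_csv",
    "write_calibration_csv",
    "read_od_csv",
    "write_model_json",
    "read_model_json",
    "write_selection_tsv",
    "read_simulation_yaml",
    "write_estimates_csv",
]

MODEL_SCHEMA_VERSION = 1


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=["NA"], comment="#",
                         float_precision="round_trip")
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if "od_mean" not in df.columns:
        raise ParseError(f"{path}: missing required column 'od_mean'")
    unknown = set(df.columns) - set(COLUMNS)
    if unknown:
        raise ParseError(f"{path}: unknown columns {sorted(unknown)}")
    for col, default in (
        ("time_h", np.nan),
        ("od_sd", 0.0),
        ("pha_g_per_l", np.nan),
        ("pha_sd", 0.0),
        ("weight", 1.0),
    ):
        if col not in df.columns:
            df[col] = default
    try:
        df = df[list(COLUMNS)].astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc
    bad = df.index[~np.isfinite(df["od_mean"])]
    if len(bad):
        raise ParseError(f"{path}: missing od_mean", line=int(bad[0]) + 2)
    return df


def read_calibration_csv(path, label: str | None = None) -> CalibrationSet:
    """Read a labeled calibration CSV; rows without PHA are dropped."""
    df = _read_frame(path)
    df = df.dropna(subset=["pha_g_per_l"]).reset_index(drop=True)
    return CalibrationSet(df, label=label if label is not None else Path(path).stem)


def read_od_csv(path) -> pd.DataFrame:
    """Read an OD series for estimation; PHA column optional and retained."""
    return _read_frame(path)


def write_calibration_csv(data: CalibrationSet, path) -> None:
    data.frame.to_csv(path, index=False, na_rep="NA")


def write_estimates_csv(series, path) -> None:
    series.frame.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------


def _options_digest(seed, xatol, fatol) -> str:
    payload = json.dumps({"seed": seed, "xatol": xatol, "fatol": fatol}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_model_json(model: FittedModel, path, options: FitOptions | None = None) -> None:
    opts = options or FitOptions()
    record = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "structure_id": model.structure.id,
        "structure_name": model.structure.name,
        "formula": model.structure.formula_text,
        "params": {k: float(v) for k, v in model.params.items()},
        "n_points": model.n_points,
        "rss": model.rss,
        "aicc": None if not np.isfinite(model.aicc) else model.aicc,
        "r2": None if not np.isfinite(model.r2) else model.r2,
        "converged": model.converged,
        "n_restarts_used": model.n_restarts_used,
        "od_range": list(model.od_range) if model.od_range else None,
        "data_label": model.label,
        "options_digest": _options_digest(opts.seed, opts.xatol, opts.fatol),
        "fitted_at": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def read_model_json(path) -> FittedModel:
    try:
        record = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        structure = get_structure(int(record["structure_id"]))
        params = {k: float(v) for k, v in record["params"].items()}
    except KeyError as exc:
        raise ParseError(f"{path}: missing field {exc}") from exc
    if set(params) != set(structure.param_names):
        raise ValidationError(
            f"{path}: parameters {sorted(params)} do not match "
            f"model {structure.id} ({structure.param_names})"
        )
    od_range = record.get("od_range")
    return FittedModel(
        structure=structure,
        params=params,
        rss=float(record.get("rss", float("nan"))),
        n_points=int(record.get("n_points", 0)),
        converged=bool(record.get("converged", True)),
        n_restarts_used=int(record.get("n_restarts_used", 0)),
        aicc=float(record["aicc"]) if record.get("aicc") is not None else float("nan"),
        r2=float(record["r2"]) if record.get("r2") is not None else float("nan"),
        od_range=tuple(od_range) if od_range else None,
        label=record.get("data_label", ""),
    )


# ---------------------------------------------------------------------------
# selection TSV and simulation YAML
# ---------------------------------------------------------------------------


def write_selection_tsv(selection: SelectionTable, path) -> None:
    """One row per requested candidate; infeasible fits carry ``inf`` RSS."""
    cols = ["model", "name", "M", "rss", "aicc", "r2", "converged"]
    extra = [c for c in selection.table.columns if c.startswith("param_")]
    out = selection.table[cols + extra].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_simulation_yaml(path) -> SimulationConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping of config fields")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config fields {sorted(unknown)}")
    if "sampling_times" in raw:
        raw["sampling_times"] = tuple(float(t) for t in raw["sampling_times"])
    return SimulationConfig(**raw)


def write_simulation_yaml(config: SimulationConfig, path) -> None:
    d = asdict(config)
    d["sampling_times"] = [float(t) for t in d["sampling_times"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
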