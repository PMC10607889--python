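"""Record CSV serialization, scenario files and report output.

The Record is a 1-Hz CSV with a fixed column order (see
:data:`autotiva.patient.RECORD_COLUMNS`); missing numeric values are
serialized as empty fields. Scenario and controller configuration travel
as one YAML file with ``scenario:``, ``controller:`` and ``population:``
sections whose keys mirror the corresponding dataclass fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .controllers import ControllerConfig
from .evaluation import AdequacyReport
from .patient import RECORD_COLUMNS, PopulationConfig, Scenario

__all__ = [
    "write_record",
    "read_record",
    "load_run_config",
    "write_report",
    "write_meta",
]


def write_record(record: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in record.columns]
    if missing:
        raise ValueError(f"record is missing columns: {missing}")
    record.to_csv(path, index=False, columns=RECORD_COLUMNS, na_rep="")


def read_record(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    df["event"] = df["event"].fillna("").astype(str)
    df["rationale"] = df["rationale"].fillna("").astype(str)
    return df


def _build(cls, data: dict | None, label: str):
    data = data or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {label} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list) and v and isinstance(v[0], list):
            v = [tuple(item) for item in v]
        elif isinstance(v, list) and k in ("bis_band", "remi_bolus_range", "age_range"):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_run_config(path: str | Path) -> tuple[Scenario, ControllerConfig, PopulationConfig]:
    """Parse a scenario YAML into its three config objects."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return (
        _build(Scenario, data.get("scenario"), "scenario"),
        _build(ControllerConfig, data.get("controller"), "controller"),
        _build(PopulationConfig, data.get("population"), "population"),
    )


def write_report(report: AdequacyReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
        fh.write("\n")


def write_meta(meta: dict, path: str | Path) -> None:
    safe = {k: (v if not isinstance(v, float) or v == v else None) for k, v in meta.items()}
    with open(path, "w") as fh:
        json.dump(safe, fh, indent=2, default=str)
        fh.write("\n")
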