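"""Readers, writers and run configuration for the pipeline.

The canonical tabular format is CSV with a documented header; JSON sidecars
carry markers, generating truth and configuration, so every artifact is
inspectable and diff-able.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .battery import BatteryReport

__all__ = ["read_trial_table", "write_trial_table", "write_report", "load_config",
           "REQUIRED_COLUMNS", "log"]

log = logging.getLogger("roambait")

REQUIRED_COLUMNS = ["participant", "group", "condition", "trial_index"]
OUTCOME_COLUMNS = ["zygo_pct", "corr_pct", "valence", "internal_details", "external_details"]
VALID_GROUPS = {"dysphoric", "non-dysphoric"}
VALID_CONDITIONS = {"positive", "negative", "neutral"}


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Mandatory columns: participant, group (dysphoric/non-dysphoric),
    condition (positive/negative/neutral), trial_index.  Outcome columns
    are optional but validated when present (valence in [0, 100], detail
    counts non-negative).  Unknown columns pass through untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    bad_groups = set(df["group"].dropna().unique()) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"{path}: malformed group labels {sorted(bad_groups)}")
    bad_conds = set(df["condition"].dropna().unique()) - VALID_CONDITIONS
    if bad_conds:
        raise ValueError(f"{path}: malformed condition labels {sorted(bad_conds)}")
    if "valence" in df.columns:
        bad = df["valence"].dropna()
        bad = bad[(bad < 0) | (bad > 100)]
        if len(bad):
            raise ValueError(
                f"{path}: valence outside [0, 100] at row(s) {bad.index[:5].tolist()}"
            )
    for col in ("internal_details", "external_details"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative {col}")
    dup = df.duplicated(subset=["participant", "condition", "trial_index"])
    if dup.any():
        raise ValueError(f"{path}: duplicate participant x condition x trial_index rows")
    log.info("read %d trial records (%d participants) from %s",
             len(df), df["participant"].nunique(), path)
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    log.info("wrote %d trial records to %s", len(df), path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_report(report: BatteryReport, out_dir: str | Path) -> list[Path]:
    """Write a battery report: one master JSON plus one CSV per evidence table.

    Every posterior-model-probability column is re-checked to sum to 1
    within its table before writing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    master = {"provenance": report.provenance, "sections": {}}
    for name, section in report.sections.items():
        sec = {k: v for k, v in section.items() if k != "tables"}
        sec["tables"] = {}
        for label, table in section.get("tables", {}).items():
            total = table["PostP"].sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(
                    f"PostP in {name}/{label} sums to {total!r}, not 1"
                )
            csv_path = out / f"{name}__{label}.csv"
            table.to_csv(csv_path, index=False)
            written.append(csv_path)
            sec["tables"][label] = table.to_dict(orient="records")
        master["sections"][name] = _jsonable(sec)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(_jsonable(master), indent=2, allow_nan=False))
    written.append(json_path)
    log.info("wrote report (%d evidence tables) to %s", len(written) - 1, out)
    return written


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
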