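"""CSV readers/writers, config loading and results-schema validation.

CSV dialect is fixed: comma-separated, header row required, UTF-8, "."
decimal; percentages stored as plain numbers on the 0-100 scale.  Readers
validate rows against the trial/participant invariants, reject offending
rows with a logged reason, and hard-error on missing required columns.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import RATING_SCALES, SimulationConfig

__all__ = [
    "read_trials",
    "read_participants",
    "write_table",
    "load_simulation_config",
    "validate_results",
    "TRIAL_COLUMNS",
    "PARTICIPANT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Required trial columns; rating/RT/recall columns may hold missing values.
TRIAL_COLUMNS = (
    "participant_id",
    "event_id",
    "first_estimate",
    "base_rate_shown",
    "second_estimate",
    "recalled_base_rate",
    "rt_first",
    "rt_second",
) + tuple(f"rating_{s}" for s in RATING_SCALES)

PARTICIPANT_COLUMNS = (
    "participant_id",
    "age_group",
    "age",
    "gender",
    "iq",
    "lot_r",
    "dorsal_acc_volume",
    "ventral_acc_volume",
    "tiv",
)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Rows violating an invariant (estimate outside [0, 100], rating
    outside 1..6) are rejected and logged with row numbers; missing
    recall/rating/RT values are allowed and kept as NaN.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    ok = pd.Series(True, index=df.index)
    reasons: list[str] = []
    for col in ("first_estimate", "base_rate_shown", "second_estimate"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 100)
        if bad.any():
            reasons.append(f"{col} outside [0, 100] or non-numeric: rows {list(df.index[bad])}")
        ok &= ~bad
    recall = pd.to_numeric(df["recalled_base_rate"], errors="coerce")
    bad = recall.notna() & ((recall < 0) | (recall > 100))
    if bad.any():
        reasons.append(f"recalled_base_rate outside [0, 100]: rows {list(df.index[bad])}")
    ok &= ~bad
    for scale in RATING_SCALES:
        col = f"rating_{scale}"
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (~vals.isin([1, 2, 3, 4, 5, 6]))
        if bad.any():
            reasons.append(f"{col} outside 1..6: rows {list(df.index[bad])}")
        ok &= ~bad
    n_rejected = int((~ok).sum())
    if n_rejected:
        for reason in reasons:
            logger.warning("%s: rejected rows — %s", path, reason)
        logger.warning("%s: %d of %d rows rejected", path, n_rejected, len(df))
    return df[ok].reset_index(drop=True)


def read_participants(path) -> pd.DataFrame:
    """Read and validate a participant-level CSV."""
    df = pd.read_csv(path)
    _require_columns(df, PARTICIPANT_COLUMNS, path)
    ok = pd.Series(True, index=df.index)
    bad_group = ~df["age_group"].isin(["young", "older"])
    if bad_group.any():
        logger.warning(
            "%s: unknown age_group: rows %s", path, list(df.index[bad_group])
        )
    ok &= ~bad_group
    for col in ("dorsal_acc_volume", "ventral_acc_volume", "tiv"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            logger.warning("%s: non-positive %s: rows %s", path, col, list(df.index[bad]))
        ok &= ~bad
    lotr = pd.to_numeric(df["lot_r"], errors="coerce")
    bad = lotr.isna() | (lotr < 0) | (lotr > 24)
    if bad.any():
        logger.warning("%s: lot_r outside [0, 24]: rows %s", path, list(df.index[bad]))
    ok &= ~bad
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: %d of %d rows rejected", path, n_rejected, len(df))
    return df[ok].reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8, comma-separated CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def load_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config fields")
    return SimulationConfig.from_dict(data)


# --- results schema ---------------------------------------------------------

def _load_schema() -> dict:
    with resources.files("beliefupdate.data").joinpath("results_schema.json").open() as fh:
        return json.load(fh)


def _validate_node(obj, schema: dict, path: str, errors: list[str]) -> None:
    typ = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
    }
    if typ is not None:
        expected = type_map[typ]
        if typ == "number" and isinstance(obj, bool):
            errors.append(f"{path}: expected number, got bool")
            return
        if not isinstance(obj, expected):
            errors.append(f"{path}: expected {typ}, got {type(obj).__name__}")
            return
    if typ == "object":
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _validate_node(obj[key], sub, f"{path}.{key}", errors)
    elif typ == "array" and "items" in schema:
        for i, item in enumerate(obj):
            _validate_node(item, schema["items"], f"{path}[{i}]", errors)


def validate_results(results: dict) -> None:
    """Validate a pipeline results dict against the packaged schema;
    raises ValueError listing every violation."""
    schema = _load_schema()
    errors: list[str] = []
    _validate_node(results, schema, "results", errors)
    if errors:
        raise ValueError("results schema violations: " + "; ".join(errors))
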