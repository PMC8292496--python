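"""CSV/JSON/YAML readers-writers and JSON-lines logging shared by the CLI.

Numeric parsing is locale-independent: only dot-decimal numbers are
accepted, and a malformed field raises with its row number rather than
being silently coerced.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd
import yaml

RAW_COLUMNS = [
    "patient_id", "day", "sex", "age", "weight_kg", "height_cm",
    "inr", "dose_mg", "doses_per_day", "administered",
]

_NUMERIC = {
    "day": int, "age": float, "weight_kg": float, "height_cm": float,
    "inr": float, "dose_mg": float, "doses_per_day": int, "administered": int,
}


class SchemaError(ValueError):
    """Raised when an input file does not match its documented schema."""


def _parse_column(raw: pd.Series, name: str, kind):
    out = []
    for idx, val in raw.items():
        row = idx + 2  # 1-based, after the header line
        if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
            if name == "inr":
                out.append(float("nan"))
                continue
            raise SchemaError(f"row {row}: missing value in column {name!r}")
        try:
            if kind is int:
                f = float(val)
                if f != int(f):
                    raise ValueError
                out.append(int(f))
            else:
                out.append(float(val))
        except (TypeError, ValueError):
            raise SchemaError(
                f"row {row}: cannot parse {val!r} in column {name!r} "
                "(dot-decimal numbers only)") from None
    return out


def read_daily_records(path, allow_duplicates: bool = False) -> pd.DataFrame:
    """Read a raw daily-record CSV, validating the documented schema.

    Set ``allow_duplicates=True`` when reading pre-consolidation event
    tables that legitimately carry several rows per patient-day.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=[""], skipinitialspace=True)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    for name, kind in _NUMERIC.items():
        out[name] = _parse_column(df[name], name, kind)
    out["sex"] = df["sex"]
    bad_sex = ~out["sex"].isin(["M", "F"])
    if bad_sex.any():
        row = int(out.index[bad_sex][0]) + 2
        raise SchemaError(f"row {row}: sex must be M or F")
    bad_adm = ~out["administered"].isin([0, 1])
    if bad_adm.any():
        row = int(out.index[bad_adm][0]) + 2
        raise SchemaError(f"row {row}: administered must be 0 or 1")
    if not allow_duplicates:
        dup = out.duplicated(["patient_id", "day"], keep=False)
        if dup.any():
            pairs = out.loc[dup, ["patient_id", "day"]].drop_duplicates()
            listing = ", ".join(
                f"({p}, day {d})" for p, d in pairs.itertuples(index=False))
            raise SchemaError(f"duplicate patient-days: {listing}")
    return out[RAW_COLUMNS]


def read_windows(path) -> pd.DataFrame:
    from inrcast.preprocess import WINDOW_COLUMNS
    df = pd.read_csv(path)
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"window file missing columns: {missing}")
    return df


def read_chain_cases(path) -> pd.DataFrame:
    from inrcast.preprocess import CHAIN_CASE_COLUMNS
    df = pd.read_csv(path)
    missing = [c for c in CHAIN_CASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"chain-case file missing columns: {missing}")
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


class JsonlLogger:
    """Append-only JSON-lines event log (one object per line)."""

    def __init__(self, path=None):
        self.path = Path(path) if path else None
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, event: str, **fields) -> dict:
        record = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                  "event": event, **fields}
        if self.path:
            with self.path.open("a") as fh:
                fh.write(json.dumps(record) + "\n")
        return record
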