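"""Data preparation: from raw daily inpatient records to training samples.

The raw table has one row per measurement/administration event:

    patient_id, day, sex, age, weight_kg, height_cm, inr, dose_mg,
    doses_per_day, administered

``consolidate_daily`` collapses it to one row per patient-day,
``apply_exclusion_filters`` drops implausible records and ineligible
patients, ``extract_windows`` emits the single-line 5-day samples the
predictor trains on, and ``select_chain_eval_cases`` finds the 8-day
fixed-dose runs used to score chained day-8 predictions.

Filter bounds are strict: a record exactly at a bound (35 kg, 120 kg,
130 cm, 220 cm, INR 10.0, 20 mg/day) is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of a consolidated daily-record table
DAILY_COLUMNS = [
    "patient_id", "day", "sex", "age", "weight_kg", "height_cm",
    "inr", "dose_mg", "doses_per_day",
]

#: columns of the single-line window table (5-day samples)
WINDOW_COLUMNS = (
    ["patient_id", "start_day", "sex", "age", "weight_kg", "height_cm", "bsa"]
    + [f"inr{i}" for i in range(1, 5)]
    + [f"dose{i}" for i in range(1, 5)]
    + ["target_inr"]
)

#: columns of the chain-evaluation case table (8-day fixed-dose runs)
CHAIN_CASE_COLUMNS = (
    ["patient_id", "start_day", "sex", "age", "weight_kg", "height_cm", "bsa"]
    + [f"inr{i}" for i in range(1, 5)]
    + ["dose1", "dose2", "dose3", "fixed_dose", "actual_day8_inr"]
)

STATIC_FEATURES = ["sex", "age", "weight_kg", "height_cm", "bsa"]
SERIES_FEATURES = ["inr", "dose"]


def compute_bsa(height_cm, weight_kg):
    """Mosteller body surface area, sqrt(height * weight / 3600), in m^2.

    Accepts scalars or arrays; raises ``ValueError`` on non-positive input.
    """
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("height and weight must be positive")
    out = np.sqrt(h * w / 3600.0)
    return float(out) if out.ndim == 0 else out


def encode_sex(sex):
    """Map M/F codes to the single numeric input slot (F=0, M=1)."""
    mapping = {"M": 1.0, "F": 0.0, 1: 1.0, 0: 0.0, 1.0: 1.0, 0.0: 0.0}
    s = pd.Series(sex)
    bad = ~s.isin(mapping)
    if bad.any():
        raise ValueError(f"unrecognized sex codes: {sorted(s[bad].unique())}")
    out = s.map(mapping).astype(float)
    return out.to_numpy() if np.ndim(sex) else float(out.iloc[0])


def consolidate_daily(raw: pd.DataFrame, inr_policy: str = "last") -> pd.DataFrame:
    """Collapse raw event rows to one record per patient-day.

    Doses flagged ``administered == 0`` (prescribed but not given)
    contribute nothing to the day's total. Multiple same-day INRs are
    resolved by ``inr_policy``: ``"last"`` (default; the value in hand at
    evening dosing) or ``"mean"``. Static covariates must agree across a
    patient's rows; conflicting duplicates raise.
    """
    if inr_policy not in ("last", "mean"):
        raise ValueError(f"unknown inr_policy {inr_policy!r}")
    df = raw.copy()
    required = set(DAILY_COLUMNS) | {"administered"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    static_cols = ["sex", "age", "weight_kg", "height_cm"]
    nuniq = df.groupby("patient_id")[static_cols].nunique()
    conflicted = nuniq[(nuniq > 1).any(axis=1)]
    if len(conflicted):
        raise ValueError(
            "conflicting static covariates for patients: "
            f"{list(conflicted.index)}"
        )

    dose_given = df["dose_mg"].where(df["administered"].astype(int) == 1, 0.0)
    df = df.assign(_dose_given=dose_given)

    def _one_day(g: pd.DataFrame) -> pd.Series:
        inrs = g["inr"].dropna()
        if inrs.empty:
            inr = np.nan
        elif inr_policy == "last":
            inr = float(inrs.iloc[-1])
        else:
            inr = float(inrs.mean())
        return pd.Series({
            "sex": g["sex"].iloc[0],
            "age": g["age"].iloc[0],
            "weight_kg": g["weight_kg"].iloc[0],
            "height_cm": g["height_cm"].iloc[0],
            "inr": inr,
            "dose_mg": float(g["_dose_given"].sum()),
            "doses_per_day": int(g["doses_per_day"].max()),
        })

    out = (
        df.sort_index()
        .groupby(["patient_id", "day"], sort=True)
        .apply(_one_day, include_groups=False)
        .reset_index()
    )
    return out[DAILY_COLUMNS]


@dataclass
class ExclusionLog:
    """Per-rule attrition accounting for a filtering pass."""

    n_records_in: int = 0
    n_records_out: int = 0
    n_patients_in: int = 0
    n_patients_out: int = 0
    patients_excluded: dict = field(default_factory=dict)
    records_excluded: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_records_in": self.n_records_in,
            "n_records_out": self.n_records_out,
            "n_patients_in": self.n_patients_in,
            "n_patients_out": self.n_patients_out,
            "patients_excluded": dict(self.patients_excluded),
            "records_excluded": dict(self.records_excluded),
        }


def apply_exclusion_filters(records: pd.DataFrame):
    """Drop implausible records and ineligible patients.

    Patient-level exclusions (the whole stay is dropped): weight < 35 or
    > 120 kg, height < 130 or > 220 cm, age < 18 years, any day with two
    or more warfarin administrations. Record-level exclusions: INR > 10.0,
    daily dose > 20 mg. All inequalities are strict; boundary values are
    retained. Returns ``(retained_records, ExclusionLog)``.
    """
    df = records.copy()
    log = ExclusionLog(
        n_records_in=len(df),
        n_patients_in=df["patient_id"].nunique(),
    )

    patient_rules = [
        ("weight_lt_35", df["weight_kg"] < 35.0),
        ("weight_gt_120", df["weight_kg"] > 120.0),
        ("height_lt_130", df["height_cm"] < 130.0),
        ("height_gt_220", df["height_cm"] > 220.0),
        ("age_lt_18", df["age"] < 18),
        ("multiple_daily_doses", df["doses_per_day"] >= 2),
    ]
    dropped = pd.Series(False, index=df["patient_id"].unique())
    for name, mask in patient_rules:
        pats = df.loc[mask, "patient_id"].unique()
        newly = [p for p in pats if not dropped.get(p, False)]
        log.patients_excluded[name] = len(newly)
        dropped.loc[pats] = True
    df = df[~df["patient_id"].map(dropped)]

    record_rules = [
        ("inr_gt_10", df["inr"] > 10.0),
        ("dose_gt_20", df["dose_mg"] > 20.0),
    ]
    keep = pd.Series(True, index=df.index)
    for name, mask in record_rules:
        newly = mask & keep
        log.records_excluded[name] = int(newly.sum())
        keep &= ~mask
    df = df[keep].reset_index(drop=True)

    log.n_records_out = len(df)
    log.n_patients_out = df["patient_id"].nunique()
    return df, log


def _consecutive_runs(days: np.ndarray, length: int):
    """Start indices i such that days[i : i+length] are consecutive."""
    starts = []
    for i in range(len(days) - length + 1):
        if days[i + length - 1] - days[i] == length - 1:
            starts.append(i)
    return starts


def extract_windows(records: pd.DataFrame, window_length: int = 5) -> pd.DataFrame:
    """Emit one single-line sample per eligible 5-day run.

    A run is eligible when the days are consecutive, every day has an INR,
    and every day's dose is positive (zero-dose days — missed
    administrations — break windows). Overlapping windows are allowed;
    windows never span patients. The last day's INR is the target.
    """
    if window_length < 2:
        raise ValueError("window_length must be at least 2")
    rows = []
    for pid, g in records.groupby("patient_id", sort=True):
        g = g.sort_values("day")
        days = g["day"].to_numpy()
        inr = g["inr"].to_numpy(dtype=float)
        dose = g["dose_mg"].to_numpy(dtype=float)
        ok = np.isfinite(inr) & (dose > 0)
        first = g.iloc[0]
        sex = encode_sex(first["sex"])
        bsa = compute_bsa(first["height_cm"], first["weight_kg"])
        for i in _consecutive_runs(days, window_length):
            sl = slice(i, i + window_length)
            if not ok[sl].all():
                continue
            row = {
                "patient_id": pid,
                "start_day": int(days[i]),
                "sex": sex,
                "age": float(first["age"]),
                "weight_kg": float(first["weight_kg"]),
                "height_cm": float(first["height_cm"]),
                "bsa": bsa,
            }
            for k in range(window_length - 1):
                row[f"inr{k + 1}"] = inr[i + k]
                row[f"dose{k + 1}"] = dose[i + k]
            row["target_inr"] = inr[i + window_length - 1]
            rows.append(row)
    cols = (
        ["patient_id", "start_day", "sex", "age", "weight_kg", "height_cm", "bsa"]
        + [f"inr{i}" for i in range(1, window_length)]
        + [f"dose{i}" for i in range(1, window_length)]
        + ["target_inr"]
    )
    return pd.DataFrame(rows, columns=cols)


def select_chain_eval_cases(records: pd.DataFrame) -> pd.DataFrame:
    """Find 8-day runs whose day-4..7 doses are identical.

    These are the stays on which a chained day-8 prediction (from days 1-4
    plus the fixed dose) can be scored against an actually observed day-8
    INR. Requires INRs on days 1-4 and 8 of the run and positive doses on
    days 1-7; the common day-4..7 dose is stored as ``fixed_dose``.
    """
    rows = []
    for pid, g in records.groupby("patient_id", sort=True):
        g = g.sort_values("day")
        days = g["day"].to_numpy()
        inr = g["inr"].to_numpy(dtype=float)
        dose = g["dose_mg"].to_numpy(dtype=float)
        first = g.iloc[0]
        sex = encode_sex(first["sex"])
        bsa = compute_bsa(first["height_cm"], first["weight_kg"])
        for i in _consecutive_runs(days, 8):
            d = dose[i:i + 8]
            v = inr[i:i + 8]
            if not (d[:7] > 0).all():
                continue
            if not (np.isfinite(v[:4]).all() and np.isfinite(v[7])):
                continue
            if not (d[3] == d[4] == d[5] == d[6]):
                continue
            row = {
                "patient_id": pid,
                "start_day": int(days[i]),
                "sex": sex,
                "age": float(first["age"]),
                "weight_kg": float(first["weight_kg"]),
                "height_cm": float(first["height_cm"]),
                "bsa": bsa,
            }
            for k in range(4):
                row[f"inr{k + 1}"] = v[k]
            for k in range(3):
                row[f"dose{k + 1}"] = d[k]
            row["fixed_dose"] = d[3]
            row["actual_day8_inr"] = v[7]
            rows.append(row)
    return pd.DataFrame(rows, columns=CHAIN_CASE_COLUMNS)


@dataclass
class Standardizer:
    """Z-score scaler for the window features.

    Statistics are kept per static feature, per series channel (INR and
    dose values pooled across the four days) and for the target, using the
    sample (n-1) standard deviation. Fit on training data only; transform
    of test data reuses the training statistics.
    """

    means: dict
    sds: dict
    convention: str = "sample"

    FEATURES = STATIC_FEATURES + SERIES_FEATURES + ["target_inr"]

    def _check(self, name):
        if name not in self.means:
            raise KeyError(f"unknown feature {name!r}")

    def transform_value(self, name, x):
        self._check(name)
        return (np.asarray(x, dtype=float) - self.means[name]) / self.sds[name]

    def inverse_value(self, name, z):
        self._check(name)
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]

    def transform_windows(self, windows: pd.DataFrame):
        """Return standardized (X_static, X_series, y) arrays.

        X_static is (n, 5) ordered sex, age, weight, height, BSA;
        X_series is (n, 4, 2) ordered by day with channels (INR, dose);
        y is (n,) standardized target INR (absent target column -> None).
        """
        n = len(windows)
        xs = np.empty((n, 5), dtype=float)
        for j, f in enumerate(STATIC_FEATURES):
            xs[:, j] = self.transform_value(f, windows[f].to_numpy(dtype=float))
        xq = np.empty((n, 4, 2), dtype=float)
        for k in range(4):
            xq[:, k, 0] = self.transform_value(
                "inr", windows[f"inr{k + 1}"].to_numpy(dtype=float))
            xq[:, k, 1] = self.transform_value(
                "dose", windows[f"dose{k + 1}"].to_numpy(dtype=float))
        y = None
        if "target_inr" in windows.columns:
            y = self.transform_value(
                "target_inr", windows["target_inr"].to_numpy(dtype=float))
        return xs, xq, y

    def transform_static(self, static):
        static = np.asarray(static, dtype=float)
        out = np.empty_like(static)
        for j, f in enumerate(STATIC_FEATURES):
            out[..., j] = self.transform_value(f, static[..., j])
        return out

    def transform_series(self, series):
        series = np.asarray(series, dtype=float)
        out = np.empty_like(series)
        out[..., 0] = self.transform_value("inr", series[..., 0])
        out[..., 1] = self.transform_value("dose", series[..., 1])
        return out

    def inverse_target(self, z):
        return self.inverse_value("target_inr", z)

    def to_json(self) -> str:
        return json.dumps(
            {
                "convention": self.convention,
                "features": {
                    f: {"mean": self.means[f], "sd": self.sds[f]}
                    for f in self.FEATURES
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Standardizer":
        obj = json.loads(text)
        feats = obj["features"]
        return cls(
            means={f: feats[f]["mean"] for f in feats},
            sds={f: feats[f]["sd"] for f in feats},
            convention=obj.get("convention", "sample"),
        )


def fit_standardizer(windows: pd.DataFrame) -> Standardizer:
    """Fit a :class:`Standardizer` on a training window table.

    Raises on fewer than two samples or any zero-variance feature — a
    constant column cannot be z-scored and silently adding an epsilon
    would hide a degenerate cohort.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 training samples")
    means, sds = {}, {}
    for f in STATIC_FEATURES:
        v = windows[f].to_numpy(dtype=float)
        means[f], sds[f] = float(v.mean()), float(v.std(ddof=1))
    pooled = {
        "inr": np.concatenate(
            [windows[f"inr{k}"].to_numpy(dtype=float) for k in range(1, 5)]),
        "dose": np.concatenate(
            [windows[f"dose{k}"].to_numpy(dtype=float) for k in range(1, 5)]),
        "target_inr": windows["target_inr"].to_numpy(dtype=float),
    }
    for f, v in pooled.items():
        means[f], sds[f] = float(v.mean()), float(v.std(ddof=1))
    zero = [f for f in means if sds[f] <= 0.0]
    if zero:
        raise ValueError(f"zero-variance features: {zero}")
    return Standardizer(means=means, sds=sds)
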