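"""Chain calculation: autoregressive rollout of the day-5 predictor.

Given a patient's real INRs for days 1-4 and real doses for days 1-3, a
virtual fixed dose is assumed from day 4 onward. The day-5 INR is
predicted from the days 1-4 window; the window then slides one day, the
prediction is fed back as the day-5 INR together with the fixed dose, and
the day-6 INR is predicted from days 2-5 — and so on for the horizon.
Repeating the rollout over a grid of candidate doses yields the
individualized dose-INR table a clinician reads to pick a maintenance
dose.

Predicted INRs are fed back on the raw INR scale (the predictor
standardizes internally), and chained predictions are never clipped:
values outside the plausible INR range are flagged in the table metadata
rather than truncated, so divergence stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: INR above which a chained prediction is flagged as out of range
INR_FLAG_LIMIT = 10.0


@dataclass
class ChainInput:
    """Real patient history feeding a chain calculation.

    ``static``: (sex, age, weight, height, BSA); ``inrs``: observed INRs
    for days 1-4; ``doses``: administered doses for days 1-3 (the day-4
    dose is the virtual one); ``horizon``: number of days to predict
    (default 4, i.e. days 5-8).
    """

    static: np.ndarray
    inrs: np.ndarray
    doses: np.ndarray
    horizon: int = 4

    def __post_init__(self):
        self.static = np.asarray(self.static, dtype=float)
        self.inrs = np.asarray(self.inrs, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.static.shape != (5,):
            raise ValueError("static must have exactly 5 values")
        if self.inrs.shape != (4,):
            raise ValueError("need exactly 4 real INRs (days 1-4)")
        if self.doses.shape != (3,):
            raise ValueError("need exactly 3 real doses (days 1-3)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if np.any(self.doses <= 0):
            raise ValueError("real doses must be positive")

    @classmethod
    def from_case_row(cls, row, horizon: int = 4) -> "ChainInput":
        """Build from one row of a chain-evaluation case table."""
        return cls(
            static=np.array([row["sex"], row["age"], row["weight_kg"],
                             row["height_cm"], row["bsa"]], dtype=float),
            inrs=np.array([row[f"inr{i}"] for i in range(1, 5)], dtype=float),
            doses=np.array([row[f"dose{i}"] for i in range(1, 4)], dtype=float),
            horizon=horizon,
        )


@dataclass
class DoseInrTable:
    """The clinician-facing grid: one row per candidate fixed dose.

    ``frame`` has columns ``dose_mg, day5, ..., day{4+H}``; ``metadata``
    records the grid, horizon, seed and any out-of-range flags.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def day_columns(self):
        return [c for c in self.frame.columns if c.startswith("day")]


def default_dose_grid() -> np.ndarray:
    """Candidate fixed doses 1.0-8.0 mg inclusive in 0.5-mg steps (15 values)."""
    return np.round(np.arange(2, 17) * 0.5, 1)


def chain_predict(predictor, chain_input: ChainInput, fixed_dose: float
                  ) -> np.ndarray:
    """Roll the predictor forward under a fixed virtual dose.

    Step 1 predicts day 5 from days 1-4 with the day-4 dose set to
    ``fixed_dose``; each later step slides the 4-day window one day,
    appending the previous prediction and the fixed dose. Returns the
    ``horizon`` predicted INRs in day order (days 5, 6, ...).
    """
    if fixed_dose <= 0:
        raise ValueError("fixed_dose must be positive")
    inr_win = list(chain_input.inrs)
    dose_win = list(chain_input.doses) + [float(fixed_dose)]
    preds = np.empty(chain_input.horizon)
    for h in range(chain_input.horizon):
        series = np.column_stack([inr_win, dose_win])
        pred = predictor.predict_day5(chain_input.static, series)
        preds[h] = pred
        inr_win = inr_win[1:] + [pred]
        dose_win = dose_win[1:] + [float(fixed_dose)]
    return preds


def generate_dose_table(predictor, chain_input: ChainInput,
                        grid: np.ndarray | None = None) -> DoseInrTable:
    """Chain-predict at every grid dose and assemble the dose-INR table."""
    grid = default_dose_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("dose grid must be positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    days = [f"day{5 + h}" for h in range(chain_input.horizon)]
    rows = np.vstack([chain_predict(predictor, chain_input, d) for d in grid])
    frame = pd.DataFrame(rows, columns=days)
    frame.insert(0, "dose_mg", grid)
    flagged = [
        float(d) for d, r in zip(grid, rows)
        if np.any(r > INR_FLAG_LIMIT) or np.any(r <= 0)
    ]
    metadata = {
        "grid": [float(d) for d in grid],
        "horizon": int(chain_input.horizon),
        "out_of_range_doses": flagged,
        "model_seed": getattr(predictor, "seed", None),
    }
    return DoseInrTable(frame=frame, metadata=metadata)


def convergence_diagnostic(table: DoseInrTable, threshold: float = 0.1
                           ) -> pd.DataFrame:
    """Max absolute day-to-day change per dose row over the predicted days.

    Under repeated fixed dosing the predicted INR should settle toward a
    dose-dependent steady state, so this diagnostic should be small; rows
    exceeding ``threshold`` are flagged as not converged.
    """
    days = table.day_columns
    if len(days) < 2:
        raise ValueError("need a horizon of at least 2 days")
    vals = table.frame[days].to_numpy(dtype=float)
    max_step = np.max(np.abs(np.diff(vals, axis=1)), axis=1)
    return pd.DataFrame({
        "dose_mg": table.frame["dose_mg"].to_numpy(),
        "max_abs_step": max_step,
        "converged": max_step <= threshold,
    })
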