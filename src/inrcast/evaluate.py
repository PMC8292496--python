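"""Accuracy bands, outlier rates and two-proportion comparisons.

The clinical accuracy metric is the fraction of predictions whose
absolute error is *less than* a threshold (0.2, 0.25, 0.3 INR — changes
within +/-0.3 rarely alter management), plus outlier rates (error
*greater than* 0.5 or 1.0) and the mean +/- sd of absolute error. Two
within-band proportions (e.g. model vs physicians) are compared with the
uncorrected pooled two-proportion z-test, equivalent to the 1-df
chi-square test without continuity correction; Fisher's exact test is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from inrcast.chain import ChainInput, chain_predict

WITHIN_THRESHOLDS = (0.2, 0.25, 0.3)
BEYOND_THRESHOLDS = (0.5, 1.0)


@dataclass
class EvalReport:
    """Within/beyond band counts and absolute-error summary for n pairs."""

    n: int
    within: dict = field(default_factory=dict)   # threshold -> count
    beyond: dict = field(default_factory=dict)   # threshold -> count
    mae: float = float("nan")
    mae_sd: float = float("nan")

    def fraction_within(self, t: float) -> float:
        return self.within[t] / self.n if self.n else float("nan")

    def fraction_beyond(self, t: float) -> float:
        return self.beyond[t] / self.n if self.n else float("nan")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "within": {
                str(t): {"count": int(c),
                         "fraction": self.fraction_within(t)}
                for t, c in self.within.items()
            },
            "beyond": {
                str(t): {"count": int(c),
                         "fraction": self.fraction_beyond(t)}
                for t, c in self.beyond.items()
            },
            "mae": self.mae,
            "mae_sd": self.mae_sd,
        }


def accuracy_bands(predicted, actual,
                   within_thresholds=WITHIN_THRESHOLDS,
                   beyond_thresholds=BEYOND_THRESHOLDS,
                   inclusive: bool = False) -> EvalReport:
    """Score predictions against observations with the banded metric.

    "Within t" counts |pred - actual| < t (strict, per the success
    definition); "beyond t" counts |pred - actual| > t. Set
    ``inclusive=True`` to use <= / >= for sensitivity analysis. The
    absolute-error sd uses the sample (n-1) convention.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-d arrays")
    if predicted.size == 0:
        raise ValueError("need at least one prediction")
    err = np.abs(predicted - actual)
    # errors within 1e-9 of a threshold count as exactly at it, so that a
    # difference that is 0.3 up to float representation is not "within 0.3"
    def _at(t):
        return np.isclose(err, t, rtol=0.0, atol=1e-9)

    if inclusive:
        within = {t: int(((err <= t) | _at(t)).sum()) for t in within_thresholds}
        beyond = {t: int(((err >= t) | _at(t)).sum()) for t in beyond_thresholds}
    else:
        within = {t: int(((err < t) & ~_at(t)).sum()) for t in within_thresholds}
        beyond = {t: int(((err > t) & ~_at(t)).sum()) for t in beyond_thresholds}
    sd = float(err.std(ddof=1)) if err.size > 1 else float("nan")
    return EvalReport(n=err.size, within=within, beyond=beyond,
                      mae=float(err.mean()), mae_sd=sd)


@dataclass
class ProportionComparison:
    """Two-sided comparison of k1/n1 vs k2/n2."""

    k1: int
    n1: int
    k2: int
    n2: int
    statistic: float
    p_value: float
    test_name: str

    def to_dict(self) -> dict:
        return {
            "k1": self.k1, "n1": self.n1, "k2": self.k2, "n2": self.n2,
            "statistic": self.statistic, "p_value": self.p_value,
            "test": self.test_name,
        }


def compare_proportions(k1: int, n1: int, k2: int, n2: int,
                        method: str = "z") -> ProportionComparison:
    """Two-sided test of equal proportions.

    ``method="z"`` (default) is the pooled-variance two-proportion z-test
    with no continuity correction, whose squared statistic equals the
    uncorrected 1-df chi-square; ``method="fisher"`` uses Fisher's exact
    test. The p-value is returned at full precision.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("totals must be >= 1")
        if not (0 <= k <= n):
            raise ValueError("successes must satisfy 0 <= k <= n")
    if method == "z":
        p1, p2 = k1 / n1, k2 / n2
        pool = (k1 + k2) / (n1 + n2)
        var = pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2)
        if var == 0.0:
            z = 0.0
        else:
            z = (p1 - p2) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        return ProportionComparison(k1, n1, k2, n2, float(z), float(min(p, 1.0)),
                                    "two-proportion z (pooled, uncorrected)")
    if method == "fisher":
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        res = stats.fisher_exact(table, alternative="two-sided")
        return ProportionComparison(k1, n1, k2, n2, float(res[0]),
                                    float(res[1]), "Fisher exact")
    raise ValueError(f"unknown method {method!r}")


def persistence_predictions(windows: pd.DataFrame) -> np.ndarray:
    """The naive baseline: predict the day-5 INR equals the day-4 INR."""
    return windows["inr4"].to_numpy(dtype=float)


def evaluate_chain(predictor, cases: pd.DataFrame, horizon: int = 4,
                   **band_kwargs) -> EvalReport:
    """Score chained day-(4+horizon) predictions on fixed-dose cases.

    Each case supplies days 1-4 (INRs, doses 1-3), the fixed day-4..7
    dose, and the observed day-8 INR; the chain is rolled with that fixed
    dose and the final prediction is scored with :func:`accuracy_bands`.
    """
    if len(cases) == 0:
        return EvalReport(n=0,
                          within={t: 0 for t in WITHIN_THRESHOLDS},
                          beyond={t: 0 for t in BEYOND_THRESHOLDS})
    preds = np.empty(len(cases))
    for i, (_, row) in enumerate(cases.iterrows()):
        ci = ChainInput.from_case_row(row, horizon=horizon)
        preds[i] = chain_predict(predictor, ci, float(row["fixed_dose"]))[-1]
    actual = cases["actual_day8_inr"].to_numpy(dtype=float)
    return accuracy_bands(preds, actual, **band_kwargs)
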