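import numpy as np
import pandas as pd
import pytest

from inrcast import (
    NetworkConfig,
    apply_exclusion_filters,
    consolidate_daily,
    extract_windows,
    fit_predictor,
    generate_cohort,
    select_chain_eval_cases,
)


def make_records(rows):
    """Build a raw daily-record frame from (pid, day, inr, dose) tuples."""
    return pd.DataFrame([
        {"patient_id": pid, "day": day, "sex": "F", "age": 60,
         "weight_kg": 70.0, "height_cm": 165.0, "inr": inr, "dose_mg": dose,
         "doses_per_day": 1, "administered": 1}
        for pid, day, inr, dose in rows
    ])


def preprocess_cohort(records):
    daily = consolidate_daily(records)
    kept, _ = apply_exclusion_filters(daily)
    return extract_windows(kept), select_chain_eval_cases(kept)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient cohort plus its windows and chain cases."""
    records, truth = generate_cohort(120, seed=42)
    windows, cases = preprocess_cohort(records)
    return {"records": records, "truth": truth,
            "windows": windows, "cases": cases}


@pytest.fixture(scope="session")
def small_predictor(small_cohort):
    """A quickly trained predictor for functional (non-accuracy) tests."""
    cfg = NetworkConfig(seed=7, max_epochs=15, early_stop_patience=5)
    return fit_predictor(small_cohort["windows"], cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
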