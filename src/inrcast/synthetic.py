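"""Virtual warfarin inpatient cohorts from a mechanistic PK/PD model.

Each simulated patient couples a one-compartment oral pharmacokinetic
model (first-order absorption and elimination, analytic superposition of
daily doses) to an indirect-response pharmacodynamic model: plasma
warfarin inhibits clotting-factor synthesis through an Emax function,
factor activity relaxes toward its inhibited steady state with a
first-order turnover rate, and PT INR is a fixed monotone function of
factor activity, ``INR = baseline * activity**(-gamma)``. The turnover
step gives the multi-day lag between a dose change and its INR effect
that makes warfarin titration hard; the Emax link makes steady-state INR
strictly increasing in the maintained dose.

Dosing follows a titration policy that mimics inpatient practice: daily
proportional adjustment in 0.5-mg steps while the INR is out of range
during the first days, then a maintenance dose held for several days —
which is what produces both varied-dose training windows and the 8-day
fixed-dose runs used to score chained predictions.

Time resolution is one day: doses are given at the start of each day and
the INR is sampled each morning before dosing, so day 1 shows the
baseline INR. Observed INRs add Gaussian measurement noise to the
noiseless trajectory and are reported to 2 decimals like laboratory
values. All randomness derives from a single cohort seed through
per-patient substreams, so patient i is reproducible regardless of cohort
size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class PkpdParams:
    """Latent per-patient parameters (ground truth for one simulated patient).

    Units: ka, ke-related rates in 1/day; cl in L/day; v in L; ec50 in
    mg/L; emax is the maximal fractional inhibition of synthesis (<= 1);
    kout in 1/day is the clotting-factor turnover rate (about a 2-day
    half-life at the default, giving the multi-day INR delay); gamma is
    the exponent of the activity-to-INR link.
    """

    ka: float = 12.0
    cl: float = 5.5
    v: float = 14.0
    ec50: float = 1.0
    emax: float = 0.9
    kout: float = 0.35
    baseline_inr: float = 1.0
    gamma: float = 1.5

    @property
    def ke(self) -> float:
        return self.cl / self.v

    def validate(self) -> "PkpdParams":
        for name in ("ka", "cl", "v", "ec50", "kout", "baseline_inr", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.emax <= 1.0):
            raise ValueError("emax must be in (0, 1]")
        if self.ka <= self.ke:
            raise ValueError("absorption must be faster than elimination")
        return self


@dataclass
class PopulationConfig:
    """Population distribution for cohort generation.

    Static covariates are drawn uniformly inside the preprocessing filter
    bounds; latent PK/PD parameters are log-normal around the
    :class:`PkpdParams` defaults with the stated coefficients of
    variation; clearance carries allometric weight scaling and a mild
    age decline. ``noise_sd`` is the INR measurement noise (INR units).
    """

    age_range: tuple = (18, 90)
    weight_range: tuple = (40.0, 110.0)
    height_range: tuple = (140.0, 190.0)
    sex_p_male: float = 0.5
    cl_sd: float = 0.30
    v_sd: float = 0.15
    ec50_sd: float = 0.30
    kout_sd: float = 0.20
    baseline_sd: float = 0.03
    cl_weight_exp: float = 0.75
    cl_age_slope: float = 0.005
    noise_sd: float = 0.10
    start_dose: float = 5.0
    chronic_fraction: float = 0.5
    chronic_burnin_days: int = 15
    chronic_misadjust_sd: float = 0.20
    titration_step: float = 0.5
    titration_gain: float = 0.75
    max_dose: float = 20.0
    min_dose: float = 0.5
    hold_days: int = 4
    target_ranges: tuple = ((1.5, 2.0), (1.8, 2.3), (2.0, 2.5), (2.5, 3.0))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        for key in ("age_range", "weight_range", "height_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "target_ranges" in d:
            d["target_ranges"] = tuple(tuple(t) for t in d["target_ranges"])
        return cls(**d)


@dataclass
class SimulatedPatient:
    """One virtual stay: statics, latent truth, dosing and trajectories."""

    patient_id: str
    sex: str
    age: float
    weight_kg: float
    height_cm: float
    params: PkpdParams
    dosing: np.ndarray          # mg/day, day 1..n
    inr_true: np.ndarray        # noiseless INR, day 1..n
    inr_obs: np.ndarray         # observed INR (true + noise), day 1..n
    target_range: tuple = (2.0, 2.5)
    seed: int | None = None


def _concentration_at(params: PkpdParams, doses, t: float) -> float:
    """Plasma concentration (mg/L) at time t days; dose d given at t = d-1."""
    ka, ke, v = params.ka, params.ke, params.v
    c = 0.0
    for d, dose in enumerate(doses):
        dt = t - d
        if dt <= 0 or dose == 0:
            continue
        c += (dose / v) * (ka / (ka - ke)) * (np.exp(-ke * dt) - np.exp(-ka * dt))
    return c


def _inh(params: PkpdParams, c: float) -> float:
    return params.emax * c / (params.ec50 + c)


def _advance_activity(params: PkpdParams, a: float, c_mid: float) -> float:
    """One-day turnover update with day-average concentration c_mid."""
    a_ss = 1.0 - _inh(params, c_mid)
    return a_ss + (a - a_ss) * np.exp(-params.kout)


def _inr_of_activity(params: PkpdParams, a: float) -> float:
    return params.baseline_inr * a ** (-params.gamma)


def simulate_trajectory(params: PkpdParams, dosing) -> np.ndarray:
    """Noiseless INR for days 1..len(dosing) under the given dosing."""
    params.validate()
    dosing = np.asarray(dosing, dtype=float)
    if np.any(dosing < 0):
        raise ValueError("doses must be non-negative")
    n = len(dosing)
    inr = np.empty(n)
    a = 1.0
    for day in range(1, n + 1):
        inr[day - 1] = _inr_of_activity(params, a)  # sampled before dosing
        c_mid = _concentration_at(params, dosing[:day], day - 0.5)
        a = _advance_activity(params, a, c_mid)
    return inr


def simulate_patient(params: PkpdParams, dosing, n_days: int,
                     seed=None, noise_sd: float = 0.10,
                     patient_id: str = "SIM", sex: str = "F",
                     age: float = 60.0, weight_kg: float = 70.0,
                     height_cm: float = 165.0) -> SimulatedPatient:
    """Simulate one patient under a fully specified dosing sequence."""
    dosing = np.asarray(dosing, dtype=float)
    if len(dosing) != n_days:
        raise ValueError("dosing length must equal n_days")
    inr_true = simulate_trajectory(params, dosing)
    rng = np.random.default_rng(seed)
    inr_obs = inr_true + rng.normal(0.0, noise_sd, size=n_days)
    return SimulatedPatient(
        patient_id=patient_id, sex=sex, age=age, weight_kg=weight_kg,
        height_cm=height_cm, params=params, dosing=dosing,
        inr_true=inr_true, inr_obs=inr_obs,
        seed=seed if isinstance(seed, int) else None,
    )


def titration_policy(inrs, target_range, current_dose: float,
                     step: float = 0.5, gain: float = 1.5,
                     min_dose: float = 0.5, max_dose: float = 20.0) -> float:
    """Proportional dose adjustment in fixed steps.

    If the latest INR is inside the target range the dose is unchanged;
    otherwise the dose moves by ``gain * (range midpoint - INR)`` snapped
    to the step grid (at least one step in the indicated direction),
    clamped to [min_dose, max_dose].
    """
    low, high = target_range
    if low >= high:
        raise ValueError("target range must be non-empty")
    inr = float(np.asarray(inrs, dtype=float).ravel()[-1])
    if low <= inr <= high:
        return current_dose
    mid = 0.5 * (low + high)
    delta = gain * (mid - inr)
    n_steps = int(round(delta / step))
    if n_steps == 0:
        n_steps = 1 if delta > 0 else -1
    new = current_dose + n_steps * step
    return float(min(max(new, min_dose), max_dose))


def draw_params(pop: PopulationConfig, age: float, weight_kg: float,
                rng: np.random.Generator) -> PkpdParams:
    """Draw latent parameters with covariate effects and log-normal IIV."""
    base = PkpdParams()
    cl_cov = (weight_kg / 70.0) ** pop.cl_weight_exp
    cl_cov *= max(0.3, 1.0 - pop.cl_age_slope * (age - 50.0))
    return PkpdParams(
        ka=base.ka,
        cl=base.cl * cl_cov * np.exp(rng.normal(0.0, pop.cl_sd)),
        v=base.v * (weight_kg / 70.0) * np.exp(rng.normal(0.0, pop.v_sd)),
        ec50=base.ec50 * np.exp(rng.normal(0.0, pop.ec50_sd)),
        emax=base.emax,
        kout=base.kout * np.exp(rng.normal(0.0, pop.kout_sd)),
        baseline_inr=base.baseline_inr * np.exp(rng.normal(0.0, pop.baseline_sd)),
        gamma=base.gamma,
    ).validate()


def maintenance_dose(params: PkpdParams, target_mid: float) -> float:
    """Analytic daily dose whose steady state sits at ``target_mid`` INR."""
    a_target = (params.baseline_inr / target_mid) ** (1.0 / params.gamma)
    inh = 1.0 - a_target
    if inh <= 0:
        return 0.0
    if inh >= params.emax:
        return float("inf")
    c = params.ec50 * inh / (params.emax - inh)
    return c * params.cl


def _simulate_stay(pop: PopulationConfig, params: PkpdParams,
                   target_range, n_days: int, rng: np.random.Generator,
                   chronic: bool):
    """Online simulation: each day's dose reacts to the observed INRs.

    Doses may change daily during the first three titration days; from
    day 4 onward the dose is reassessed only every ``hold_days`` days and
    held in between (the clinician settles on a maintenance dose), which
    yields the fixed day-4..7 runs the chain evaluation needs.

    A ``chronic`` patient is already on warfarin at admission: their
    pre-admission dose (their analytic maintenance requirement, imperfectly
    adjusted) is run for a burn-in period before day 1, so they enter the
    stay near their individual steady state rather than warfarin-naive.
    """
    burn = pop.chronic_burnin_days if chronic else 0
    if chronic:
        req = maintenance_dose(params, 0.5 * sum(target_range))
        req *= np.exp(rng.normal(0.0, pop.chronic_misadjust_sd))
        pre_dose = min(max(round(req / pop.titration_step) *
                           pop.titration_step, pop.min_dose), pop.max_dose)
        dose = pre_dose
    else:
        dose = pop.start_dose
    pre = np.full(burn, dose)
    dosing = np.empty(n_days)
    inr_true = np.empty(n_days)
    inr_obs = np.empty(n_days)
    a = 1.0
    for t in range(1, burn + 1):
        c_mid = _concentration_at(params, pre[:t], t - 0.5)
        a = _advance_activity(params, a, c_mid)
    for day in range(1, n_days + 1):
        inr_true[day - 1] = _inr_of_activity(params, a)
        inr_obs[day - 1] = round(
            inr_true[day - 1] + rng.normal(0.0, pop.noise_sd), 2)
        if day > 1 and (day <= 3 or (day - 4) % pop.hold_days == 0):
            dose = titration_policy(
                inr_obs[:day], target_range, dose,
                step=pop.titration_step, gain=pop.titration_gain,
                min_dose=pop.min_dose, max_dose=pop.max_dose)
        dosing[day - 1] = dose
        hist = np.concatenate([pre, dosing[:day]])
        c_mid = _concentration_at(params, hist, burn + day - 0.5)
        a = _advance_activity(params, a, c_mid)
    return dosing, inr_true, inr_obs, pre


def generate_cohort(n_patients: int, n_days: int = 11,
                    pop: PopulationConfig | None = None, seed: int = 1):
    """Generate a cohort; returns ``(records, truth)``.

    ``records`` is a daily-record table conforming to the preprocessing
    input schema (one administered dose row per patient-day); ``truth``
    maps patient id to the latent parameters, dosing, noiseless
    trajectory and target range — the ground truth against which chained
    predictions can be scored.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    pop = pop or PopulationConfig()
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    rows = []
    truth = {}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i + 1:05d}"
        sex = "M" if rng.random() < pop.sex_p_male else "F"
        age = float(np.round(rng.uniform(*pop.age_range), 0))
        weight = float(np.round(rng.uniform(*pop.weight_range), 1))
        height = float(np.round(rng.uniform(*pop.height_range), 1))
        params = draw_params(pop, age, weight, rng)
        target = pop.target_ranges[rng.integers(len(pop.target_ranges))]
        chronic = bool(rng.random() < pop.chronic_fraction)
        dosing, inr_true, inr_obs, pre = _simulate_stay(
            pop, params, target, n_days, rng, chronic)
        for day in range(1, n_days + 1):
            rows.append({
                "patient_id": pid, "day": day, "sex": sex, "age": age,
                "weight_kg": weight, "height_cm": height,
                "inr": inr_obs[day - 1], "dose_mg": dosing[day - 1],
                "doses_per_day": 1, "administered": 1,
            })
        truth[pid] = {
            "sex": sex, "age": age, "weight_kg": weight, "height_cm": height,
            "target_range": list(target),
            "chronic": chronic,
            "params": asdict(params),
            "pre_admission_dosing": pre.tolist(),
            "dosing": dosing.tolist(),
            "inr_true": inr_true.tolist(),
        }
    records = pd.DataFrame(rows)
    return records, truth


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2)


def truth_from_json(text: str) -> dict:
    return json.loads(text)


def oracle_day8(truth_patient: dict, fixed_dose: float,
                fixed_from_day: int = 4, day: int = 8) -> float:
    """True INR on ``day`` when dosing is fixed from ``fixed_from_day``.

    Re-integrates the same PK/PD equations with the patient's real doses
    before ``fixed_from_day`` and ``fixed_dose`` from then on — the
    ground-truth counterpart of the chain calculation.
    """
    params = PkpdParams(**truth_patient["params"])
    pre = list(truth_patient.get("pre_admission_dosing", []))
    real = list(truth_patient["dosing"])[: fixed_from_day - 1]
    dosing = pre + real + [float(fixed_dose)] * (day - len(real))
    return float(simulate_trajectory(params, dosing)[len(pre) + day - 1])
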