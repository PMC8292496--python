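# inrcast

Warfarin dose decision support: predict an inpatient's 5th-day
prothrombin time INR (PT INR) from the first four days of INR/dose
history, and roll that predictor forward under virtual fixed dosing to
produce the individualized **dose–INR table** a clinician reads when
choosing a maintenance dose.

Warfarin's effect on the INR is delayed by days (it inhibits
clotting-factor synthesis, not activity), sensitivity varies several-fold
between patients, and the therapeutic window is narrow — so maintenance
doses are usually found by days of inpatient trial and error. `inrcast`
is aimed at the people building and evaluating decision-support tools for
that titration loop.

## The model

One training sample is a 5-day window of a consolidated, filtered
inpatient stay:

- **static branch** — sex, age, weight, height, BSA
  (= √(height·weight/3600)) through dense ReLU layers (2 × 16),
- **sequence branch** — the 4 × 2 day-ordered series of (INR, dose) for
  days d..d+3 through 5 stacked LSTM layers of 32 units,
- branches concatenated, then a dense ReLU head (4 × 32) with one linear
  output: the day-(d+4) PT INR.

All variables are z-scored with training-set statistics; the loss is mean
absolute error, optimized with Adam, with early stopping on a held-out
20% validation split. The network is implemented in pure numpy
(hand-written backprop, verified against finite differences), so a fixed
seed reproduces training bit-for-bit.

The **chain calculation** turns the one-step model into a dosing tool:
with real INRs for days 1–4, real doses for days 1–3 and an assumed fixed
dose from day 4 on, the day-5 prediction is fed back into the window to
predict day 6, then day 7 and 8. Repeating this for each candidate dose
(1.0–8.0 mg in 0.5-mg steps) yields the dose–INR table.

Because no compatible public dataset exists, the package ships a
mechanistic PK/PD cohort simulator (one-compartment kinetics, Emax
inhibition of clotting-factor synthesis, turnover delay, titration-style
dosing with both newly started and chronic-maintenance patients) that
supplies training/testing data and exact ground truth. See
`docs/methods.md` for the science and every default.

## Worked example

Simulate a 300-patient cohort, preprocess it, train, and generate a
dose–INR table for one patient:

```
$ inrcast simulate --n 300 --seed 7 --out cohort.csv --truth truth.json
wrote 3300 records for 300 patients

$ inrcast preprocess --records cohort.csv --out-windows windows.csv --out-cases cases.csv
3300 daily records -> 3300 retained -> 2100 windows, 825 chain cases

$ inrcast train --windows windows.csv --seed 7 --out model/
trained on 2100 windows; best val MAE (standardized) 0.2231
```

Patient `P00002` is a chronic user admitted on 2.5 mg/day with INRs
1.56, 1.77, 1.69, 1.96 over days 1–4:

```
$ inrcast table --model model/ --patient patient.csv --out table.csv
 dose_mg  day5  day6  day7  day8
    1.00  1.79  1.79  1.79  1.79
    1.50  1.80  1.81  1.81  1.81
    2.00  1.82  1.84  1.84  1.83
    2.50  1.83  1.86  1.87  1.86
    3.00  1.84  1.88  1.89  1.88
    ...
    7.50  2.00  2.23  2.36  2.41
    8.00  2.02  2.26  2.43  2.51
```

Each row answers: *if this patient takes the row's dose every day from
day 4, what INR should we expect on days 5–8?* Predictions stabilize
within each row (convergence) and the settled value increases with dose,
so a clinician targeting, say, 2.0–2.5 would read off 5.0–6.0 mg. The
rows are produced by the chained rollout — accuracy on day 8 is lower
than on day 5, which `inrcast evaluate` quantifies (within-0.2/0.25/0.3
bands, outlier rates, MAE, and the persistence baseline that predicts
tomorrow's INR equals today's).

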