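# Methods

## The prediction problem

Warfarin dosing is a sequential decision problem: the PT INR responds to
dose changes with a lag of several days (warfarin inhibits clotting-factor
*synthesis*, so the effect is filtered through factor turnover), and
sensitivity varies several-fold between patients. `inrcast` addresses the
one-step version of the problem — predict tomorrow-plus-three's INR (the
5th-day value) from the previous four days of (INR, dose) pairs plus five
static covariates — and then composes that predictor with itself to answer
the counterfactual question clinicians actually care about: *if I fix the
dose at x mg from today on, where will the INR settle?*

## Data preparation

Raw inpatient event rows are consolidated to one record per patient-day:
doses flagged as not administered contribute nothing, multiple same-day
INRs resolve to the last measurement of the day by default (the value in
hand at evening dosing; a mean policy is available since source systems
differ). Exclusions mirror routine plausibility screening, with strict
inequalities throughout: patients with weight < 35 or > 120 kg, height
< 130 or > 220 cm, age < 18, or any day with two or more warfarin
administrations are dropped entirely; single records with INR > 10.0 or
daily dose > 20 mg are dropped. Values exactly at a bound are retained.
Every filtering pass returns a per-rule exclusion log so cohort attrition
is reproducible.

Training samples are overlapping 5-day windows: days d..d+3 supply the
4x2 (INR, dose) series and the statics (sex, age, weight, height,
Mosteller BSA = sqrt(height x weight / 3600)), day d+4 supplies the
target. A window requires consecutive days, an INR every day, and a
positive dose every day — zero-dose days (missed administrations) break
windows, because the predictor is deliberately not trained on missed-dose
dynamics. Chain evaluation cases are 8-day runs whose day-4..7 doses are
identical; the day-8 INR is the held-out truth for the rolled-out
prediction.

All features are z-scored with statistics fitted on training data only
(sample, n-1, standard deviation; the convention is recorded in the
serialized scaler). The INR and dose series channels are pooled across
the four days; the target is scaled separately so predictions can be
inverse-transformed exactly.

## The predictor

Two branches: the five statics pass through 2 dense ReLU layers of 16
units; the series passes through 5 stacked LSTM layers of 32 units
(intermediate layers emit full sequences, the last emits its final hidden
state). The concatenated 48-vector passes through 4 dense ReLU layers of
32 units and a final linear unit — the standardized day-5 INR. The
network is small (~43k parameters) and is implemented directly in numpy
(float64) with hand-written backpropagation through time; gradients are
verified against central finite differences in the test suite, and the
stacked forward pass against an independently unrolled cell.

Training: mean absolute error on standardized targets, Adam at 1e-3,
batch 64, at most 200 epochs. A seeded random 20% of samples is held out;
training stops once validation MAE has not improved for 10 epochs and the
best-validation weights are restored. With one seed the whole fit is
bit-reproducible. Defaults that matter:

| parameter | default | why |
|---|---|---|
| LSTM layers x units | 5 x 32 | deeper/wider stacks overfit this low-dimensional series |
| static branch | 2 x 16 | five inputs need little capacity |
| head | 4 x 32 + linear 1 | enough mixing of the two branches |
| loss | MAE | matches the clinical within-band metric better than MSE |
| validation fraction | 0.20 | by sample; a by-patient split is a config choice away |
| patience | 10 epochs | validation MAE is noisy at the measurement-noise floor |

## Chain calculation and dose tables

The rollout feeds predictions back on the raw INR scale: step 1 predicts
day 5 from days 1–4 with the day-4 dose replaced by the virtual fixed
dose; each later step slides the window, appending the previous
prediction and the fixed dose. The dose-INR table evaluates the rollout
on the default grid 1.0–8.0 mg inclusive in 0.5-mg steps (15 rows) for
days 5–8. Chained predictions are never clipped; implausible values
(INR > 10 or <= 0) are flagged in the table metadata instead, so
divergence is visible rather than masked. A convergence diagnostic
reports the maximum day-to-day change per row. The horizon defaults to 4
days and is configurable upward, with the caveat that error compounds at
each step.

## The cohort simulator

No public cohort with this structure exists, so the package carries a
mechanistic generator that is also the ground-truth oracle for chained
predictions.

*Pharmacokinetics.* One-compartment oral model, analytic superposition of
daily doses: ka = 12/day (absorption effectively complete within hours),
V = 14 L x (weight/70), CL = 5.5 L/day with allometric weight scaling
(exponent 0.75), a mild age decline (0.5%/year from age 50) and
log-normal inter-individual variability (CV 30%).

*Pharmacodynamics.* Day-average concentration inhibits clotting-factor
synthesis through an Emax model (Emax 0.9, EC50 1.0 mg/L, CV 30%); factor
activity relaxes toward its inhibited steady state with turnover rate
kout = 0.35/day (about a 2-day half-life, CV 20%). INR is sampled each
morning before dosing as baseline x activity^(-1.5), baseline ~= 1.0.
This is the minimal mechanism that yields the three qualitative features
the real data shows: a multi-day lag between a dose change and its
maximal INR effect, convergence to a steady INR under repeated fixed
dosing, and a steady state strictly increasing in dose. Measurement noise
is Gaussian, sd 0.1 INR, and observed values are reported to 2 decimals
like laboratory results.

*Dosing behavior.* Half of the virtual patients are warfarin-naive at
admission and start at 5 mg/day; the other half are chronic users
admitted on their (imperfectly adjusted, log-normal sd 0.20) maintenance
dose, simulated to near steady state through a 15-day pre-admission
burn-in. Without the chronic stratum the cohort contains almost no doses
below ~4 mg — everyone is up-titrating from the same starting dose — and
the 1.0–8.0 mg table grid would probe dose regions the data never
covers; real multi-year inpatient cohorts are dominated by patients
already on individualized maintenance doses spanning that full range.
Titration follows a proportional policy in 0.5-mg steps (gain 0.75 mg per
INR unit of error, no change inside the target range, clamped to
0.5–20 mg): daily adjustment on days 2–3, then reassessment every 4 days
with the dose held in between, which mirrors maintenance prescribing and
is what produces 8-day runs with fixed day-4..7 doses. The gain was set
by inspecting simulated trajectories: at 1.5 the virtual clinician
overshoots the target band, at 0.75 cohort INRs approach their target by
day ~10 without ringing. Target ranges are drawn per patient from the
four common clinical bands (1.5–2.0 through 2.5–3.0). Stays default to
11 days.

Per-patient substreams are spawned from a single cohort seed, so patient
i is byte-reproducible regardless of cohort size.

*What the simulator does not emulate:* pharmacogenomics (CYP2C9/VKORC1),
drug–drug and diet interactions, non-warfarin determinants of INR
(hepatic dysfunction, vitamin K status), missing measurements, intra-day
kinetics, and the real cohorts' marginal covariate distributions (which
are not publicly available). Accuracy measured on this cohort therefore
bounds what the architecture can extract from clean, mechanistically
generated data; it does not certify performance on hospital data.

## Evaluation

The clinical metric is banded accuracy: |prediction − actual| strictly
less than 0.2 / 0.25 / 0.3 INR, plus outlier rates (> 0.5, > 1.0) and
mean ± sd (n−1) absolute error. Errors within 1e-9 of a threshold are
treated as exactly at it, so a difference that equals the threshold up to
float representation is never counted as within. Proportions are compared
with the pooled two-proportion z-test without continuity correction
(z² equals the uncorrected 1-df chi-square); Fisher's exact test is
available. The naive persistence forecast (day-5 INR = day-4 INR) is the
baseline every trained model must beat.

The study size used by the acceptance script and end-to-end tests —
2,000 training patients and a disjoint 500-patient test cohort (seed
offset 1,000,000), 11-day stays — gives ~14,000 training windows, which
is past the point where validation loss stops improving with more data at
this noise level, while a full run (simulate, preprocess, train,
evaluate, 500 dose tables) completes in a couple of minutes.

## Numerical and degenerate-input choices

- Zero-variance features fail standardizer fitting loudly; no epsilon.
- Non-finite training loss aborts with the epoch in the message.
- LSTM forget-gate biases initialize to 1; other biases to 0; kernels
  Glorot-uniform from the model seed.
- The validation split is by sample, not by patient; overlapping windows
  from one patient can land on both sides. That makes validation loss an
  optimistic estimate of generalization to new patients, which is why all
  reported accuracy comes from a disjoint test cohort.
- Model bundles embed config and scaler hashes; a mismatched pair is
  refused at load.

## Known limitations

- The simulator's PK/PD parameters are plausible for racemic warfarin but
  are not fitted to any dataset; absolute accuracy numbers on synthetic
  cohorts are not comparable to accuracy on hospital data.
- The chain rollout assumes the one-step predictor is valid under
  counterfactual doses; confounding by indication (doses react to INRs)
  is only partly broken by the variation in per-patient target ranges and
  admission states.
- Horizon-4 rollout compounds one-step error; day-8 accuracy is
  systematically below day-5 accuracy and degrades further for longer
  horizons.
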