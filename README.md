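# cardiocirc

Age- and sex-dependent circadian modelling of the heart period (RR
interval), with a virtual-trial layer for drug-induced QT prolongation.

Heart rate follows a ~24 h circadian rhythm: RR intervals lengthen at
night and shorten by day, with level and swing depending on age and
sex. Anyone simulating cardiac drug effects at the population level —
e.g. in-silico thorough-QT (TQT) studies — needs that rhythm as a
per-subject attribute, because heart rate both modulates the QT
interval and interferes with the apparent drug effect. `cardiocirc`
provides the statistical machinery end to end: a cosinor regression of
log RR, a long-memory autoregressive residual process, fitting with
cluster-robust inference, virtual-cohort simulation, and a triplicate
virtual-trial harness with both ΔQTcF baseline corrections.

## The model

On the log scale, for Sex ∈ {0 = female, 1 = male}, Age in years and
clock hour H:

    log RR = β₀ + β₁·Sex + β₂·Age + β₃·Age²
             + β₄·sin(2πH/24) + β₅·cos(2πH/24)
             + β₆·sin(2πH/24)·Sex + β₇·cos(2πH/24)·Sex + ε,   ε ~ N(0, σ)

with RR in ms. A reference coefficient set estimated from 24-h
recordings of 18 healthy adults ships as `DEFAULT_COEFFICIENTS`
(σ = 0.15). Within-subject residuals are serially dependent and are
modelled as a stationary AR(P) process with P = 180 at the one-minute
step (innovation SD τ = 0.096); random RR series are generated as
`exp(predicted log RR + AR noise)`.

The drug layer combines the Hill inhibition factor
`1/(1 + (IC50/C)^n)`, Fridericia's correction
`QTcF = QT/(RR/1000)^(1/3)`, a pluggable QT engine (a simple surrogate
ships as default; detailed cell-level electrophysiology can be plugged
in behind the same contract), and the two baseline corrections used in
TQT practice: single pooled baseline (ΔQTcF) and individualised
time-matched baseline (ΔQTcF_i).

## Worked example

`examples/virtual_qt_trial.py` runs a triplicate virtual study of
moxifloxacin at its free Cmax (3.8 µM against an IKr IC50 of 29 µM —
an 11.6% channel block):

```
moxifloxacin 3.8 uM vs IKr IC50 29.0 uM -> inhibition 0.1159
simulated 720 QT observations (3 trials x 20 subjects x 6 times x 2 arms)

hour   dQTcF (single-point)    dQTcF_i (individualised)
   4     5.78 +/- 10.49 ms        5.79 +/-  0.00 ms
   8     5.79 +/- 10.89 ms        5.79 +/-  0.00 ms
  12     5.81 +/- 11.30 ms        5.79 +/-  0.00 ms
  16     5.84 +/- 11.43 ms        5.79 +/-  0.00 ms
  20     5.79 +/- 11.09 ms        5.79 +/-  0.00 ms
  24     5.76 +/- 10.57 ms        5.79 +/-  0.00 ms
```

Each subject is observed drug-free and on-drug at six clock times with
circadian RR from the model. The individualised correction pairs each
on-drug QTcF with the same subject's drug-free QTcF at the same hour,
so per-subject offsets cancel exactly — a flat, tight ~5.8 ms drug
effect. The single-point correction subtracts one pooled baseline and
keeps the full between-subject spread (±11 ms) plus circadian drift in
its hourly means.

Other examples: `evaluate_model.py` (the deterministic curve and its
95% prediction bands), `simulate_cohort.py` (virtual subjects,
day/night RR summaries), `fit_and_recover.py` (simulate → refit →
compare, with cluster-robust CIs and the AR(180) residual fit),
`validate_sparse.py` (the ambulatory validation pathway:
HR → RR → goodness of fit).

## Command line

```bash
cardiocirc synth dense --seed 1 --out cohort/      # beat-level synthetic cohort
cardiocirc fit --data rr.csv --order 180 --out model.yaml
cardiocirc validate --model model.yaml --data rr.csv --out metrics.json
cardiocirc simulate --n 20 --sex-ratio 0.5 --age 20 50 --seed 42 --out sim.csv
cardiocirc trial --drug examples/moxifloxacin.yaml --seed 7 --out trial.csv
```

RR CSVs have columns `subject_id, sex, age, hour, rr_ms` (optional
`elapsed_hour` for recordings crossing midnight); ambulatory CSVs use
`hr_bpm`. Model YAML is flat `beta0..beta7, sigma` plus an optional
`ar` block.

## Scope notes

The QT engine contract deliberately excludes cell-level
electrophysiology (ventricular-fibre pseudo-ECG simulation) and
population physiology generators; see `docs/methods.md` for the full
model description, estimator choices, surrogate-engine semantics and
limitations.
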