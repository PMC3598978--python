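# Methods

## The model

`cardiocirc` models the beat-to-beat RR interval (ms) of healthy adults
as log-normal around a deterministic circadian mean:

```
log RR = b0 + b1·Sex + b2·Age + b3·Age² + b4·sin(2πH/24) + b5·cos(2πH/24)
         + b6·sin(2πH/24)·Sex + b7·cos(2πH/24)·Sex + ε,
```

with Sex ∈ {0 female, 1 male}, Age in years (entered raw, uncentred —
the quadratic coefficient is therefore tiny, ~3e-4), H the clock hour,
and ε a zero-mean residual with marginal SD σ on the log scale.  A
single 24-h harmonic is used; the sex interactions let amplitude and
phase differ between men and women.  The shipped reference coefficient
set (`DEFAULT_COEFFICIENTS`) was estimated from 24-h recordings of 18
healthy adults (5 men 26–45 y, 13 women 20–50 y), RR thinned to one
sample per minute; its σ is 0.15.

Hours outside [0, 24) are reduced mod 24 rather than rejected: the
model is periodic by construction.  Age is accepted as any non-negative
real; the curve is smooth even though training ages were integers.

Within a subject the residuals are strongly serially dependent.  They
are modelled as a stationary AR(P) process

```
ε_t = Σ_{p=1..P} α_p ε_{t-p} + η,   η ~ N(0, τ),
```

at the one-minute time step.  Only a large order (P = 180, a 3-hour lag
window) captures the long memory; the innovation SD is τ = 0.096.

### The default AR coefficient vector

The order and innovation SD of the reference AR fit are known, but not
the 180 individual α's.  `default_ar_model()` therefore constructs a
long-memory α vector from the truncated AR(∞) expansion of a
fractional-differencing filter (1−B)^d, whose weights
π_j = d·Γ(j−d)/(Γ(j+1)Γ(1−d)) decay hyperbolically — the canonical
parametric form for long-memory dependence.  The memory parameter d is
solved by bisection (exact stationary variance via the Yule–Walker
equations) so that the marginal SD of the residual process equals the
regression σ = 0.15 given τ = 0.096.  This enforces the internal
consistency requirement that the AR structure account for the whole
residual variance; the package warns if a *fitted* (σ, τ, α) triple is
materially inconsistent.  The default model is calibrated for 1-minute
grids; simulation takes one AR transition per grid point regardless of
the grid's physical spacing, which is a declared convention, not a
claim about other time scales.

## Simulation

Random RR series are generated in three steps: draw the AR noise
(Gaussian innovations, burn-in of 10·P discarded steps in lieu of exact
stationary initialisation — ample for these decay rates), evaluate the
circadian mean log RR at the chosen time points, add and exponentiate.
Reproducibility: one root seed; per-subject child streams derived as
`SeedSequence([seed, crc32(subject_id)])`, so cohorts are reproducible
and independent of simulation order.  Virtual cohorts use a
deterministic sex split (`round(n·sex_ratio)` males) and uniform ages
over the requested range (only ranges, not full age distributions, are
specified for the source cohorts).

## Estimation

* **Point estimates** are OLS on log RR — the Gaussian ML estimator.
  σ is the residual SD with denominator n−k.
* **Inference** clusters on subject: each subject contributes ~1440
  highly autocorrelated observations, so naive SEs are wildly
  optimistic.  The default covariance is the bias-reduced CR2 cluster
  sandwich (leverage adjustment (I−H_gg)^{−1/2} applied to each
  cluster's scores, computed with k×k algebra per cluster) with t(G−1)
  reference distributions.  The classical CR1 flavour is available;
  with only ~18 clusters and a nearly collinear intercept/age/age²
  block, CR1 t-intervals were found to undercover (≈86–88% instead of
  95% in simulation at the study size), while CR2 restores 92–96% —
  the standard few-cluster recommendation, and the reason it is the
  default.
* **Model reduction** starts from a saturated specification (23 hourly
  dummies, sex, age, age², and all pairwise hour/sex/age interactions)
  and removes one term per refit: the largest-p term with cluster-
  robust p > α (default 0.05), never removing a term while a surviving
  term depends on it (interactions before main effects, age² before
  age, intercept never).  The final cosinor form replaces the hourly
  dummies by one sine/cosine pair.
* **Robust refit**: Huber M-estimation (tuning constant 1.345, via
  statsmodels RLM) of the final form as an outlier-stability check.
* **AR residual fit**: pooled conditional least squares — per-subject
  lag matrices stacked so lagged predictors never cross a subject
  boundary, a single pooled α vector, τ from the innovation RMS with
  denominator (rows − P).  Yule–Walker is the obvious alternative; CLS
  was chosen because it extends to subject-segmented data without bias
  from per-subject mean removal.  Subjects shorter than P are excluded
  with a warning.  Stationarity of a fitted α vector is checked via
  the companion-polynomial roots (warning, not failure).
* **Goodness of fit**: R² is computed on the log scale (the modelling
  scale, and invariant to multiplicative rescaling); RMSE and MAPE on
  the millisecond scale, where they are clinically read.
  MAPE = 100·mean(|obs−pred|/obs).
* **Prediction bands** use the marginal σ only (exp(μ ± z·σ)).  A band
  accounting for AR-correlated residuals would be wider at short
  horizons conditional on history; the marginal band is the
  unconditional statement and matches how the reference bands are
  drawn.

## Preprocessing

Dense beat streams are thinned to one RR per whole minute: for each
minute tick after recording start, the beat whose onset is nearest the
tick is kept (earlier beat on ties).  The rule (as opposed to
first-after-tick or interpolation) is a declared convention pinned by a
brute-force oracle test; output values are always actual input beats.
Sparse ambulatory heart-rate readings convert via RR = 60000/HR.
Recordings crossing midnight carry a monotone elapsed-time axis; clock
hour is taken mod 24 only at model evaluation.  CSV (header, UTF-8,
'.' decimal) is the only interchange format; archival ECG annotation
files are expected as pre-exported text RR lists.

## Synthetic cohorts

`make_dense_cohort` emulates 24-h beat-to-beat streams by cumulative-
time advance: the next beat occurs one RR after the current one, the
circadian mean is evaluated at the running clock time, and the AR noise
advances one step per *beat* (a fixture convention recorded in the
manifest — at ~900 ms/beat the effective AR time step is ~1 s, not
1 min).  Default composition mirrors the dense source cohort (18
subjects, 5 men 26–45 y, 13 women 20–50 y); ~1e5 beats/subject/24 h.
`make_sparse_cohort` uses the ambulatory schedule (every 15 min
08:00–22:00, every 30 min overnight: 56 + 20 = 76 ticks), reports
HR = 60000/RR, and thins readings independently with probability
1 − 71/76 (redrawn into the observed 35–99 range) to match the
validation cohort's mean of 71 readings.  `make_minute_cohort` samples
directly on the 1-min modelling grid — the representation the
regression actually sees — and is the workhorse for recovery studies.

What the generators deliberately do **not** emulate: ectopic beats and
measurement artifacts, heart-rate-variability microstructure
(respiratory sinus arrhythmia, spectral bands), cuff errors, or
non-log-normal tails.  Passing recovery tests therefore demonstrate
internal statistical correctness of the estimators under the model's
own assumptions, not robustness to real-data pathologies (the Huber
refit covers gross outliers only).

## The drug-trial layer

Channel block is the Hill factor `1/(1 + (IC50/C)^n)`; QTc uses
Fridericia's cube-root correction `QTcF = QT/(RR/1000)^(1/3)`.  The
trial layer needs a QT engine — a callable `(rr_ms, inhibition map,
subject offset) → qt_ms`, positive and non-decreasing in IKr block.
Detailed cell-level electrophysiology is out of scope behind this
contract; for anyone plugging in a ventricular-fibre pseudo-ECG engine,
the reference fibre configuration is: Δx = 0.01 mm, Δt = 0.01 ms,
D = 0.0016 cm²/ms, 50:30:20 endo/mid/epicardial cells, 10,000 ms of
simulated time, first and last QRS excluded.

The shipped surrogate is deliberately minimal: drug-free
QT = QTc0·(RR/1000)^(1/3) + subject offset, so drug-free offset-free
QTcF is exactly QTc0 (default 400 ms) at every RR; the per-subject
offset (default SD 10 ms, drawn once per subject per trial, identical
in both arms) stands in for inter-individual QTc variability.  Only the
IKr entry of the inhibition map feeds the surrogate — at moxifloxacin's
free Cmax the INa/ICa blocks are negligible — though the contract
passes the full map.  The drug term has two placements
(`drug_effect`): `"qtcf"` (default) adds `gain·block` on the corrected
scale, making the individualised drug effect exactly heart-rate
independent; `"qt"` adds it to raw QT, so the QTcF effect scales as
`1/(RR/1000)^(1/3)` (≈6.1 ms instead of 5.8 ms at RR 848 ms with the
defaults).  The default was chosen so that the flat-ΔQTcF_i behaviour
expected of an individualised correction holds by construction; with
the `"qt"` placement the single-point vs individualised across-hours
variance contrast becomes a coin flip at trial size (both corrections
then share the same circadian 1/∛RR term and differ only by mean-zero
offset noise — measured ~52% across seeds).

Trial design: `n_trials` independent replicates (default 3) of
`n_per_trial` subjects (default 20, sex ratio 0.5, ages uniform
20–50 y) observed at hours 4, 8, 12, 16, 20, 24 (24 ≡ 0 by
periodicity).  RR at each hour comes from the circadian simulator and
is shared by the baseline (zero concentration) and on-drug arms — the
drug is assumed not to change heart rate.  Default drug gain 50 ms per
unit block yields ≈5.8 ms ΔQTcF_i at moxifloxacin's 11.6% IKr block,
the clinically familiar sensitivity range.

Baseline corrections: ΔQTcF subtracts the baseline QTcF pooled over
all subjects *and all times* within each trial replicate (pooling over
times is this package's reading of "average baseline from all
subjects"; per-replicate pooling keeps the triplicate trials
independent).  ΔQTcF_i subtracts each subject's own drug-free QTcF at
the same hour in the same trial; additive subject offsets cancel
exactly in this pairing.  Summaries are per-hour mean ± SD.

## Numerical details and edge cases

* σ = 0 and τ = 0 are accepted (noiseless limits) even though fitted
  values are strictly positive.
* Singular designs raise naming the collinear terms (pivoted-QR
  identification); estimation requires ≥2 subjects because sex/age are
  between-subject.
* Minute resampling of a d-minute recording yields floor(d) samples;
  empty series pass through empty.
* AR simulation refuses non-stationary α vectors, reporting the
  largest characteristic root.
* The CR2 leverage eigenvalues are clipped to [0, 1−1e−10]; the
  λ→0 limit of the adjustment factor is taken analytically.
* Duplicate (subject, hour) ambulatory rows are kept with a warning;
  malformed CSV rows are reported with 1-based file line numbers.

## Problem sizes

Recovery and coverage studies run at the source-study size — 18
subjects × 1440 one-minute samples — with 100 replicates for coverage;
AR round-trip checks use series of 5e4 points; trial checks use the
default 3×20 design.  These sizes make every check reproducible on a
laptop in minutes while matching the conditions the reference estimates
came from.

## Known limitations

* The package treats the reference coefficients as exact; no
  uncertainty is propagated from the original estimation.
* No mixed-effects extension: between-subject dependence enters only
  through cluster-robust SEs and the AR residual process.
* The surrogate QT engine is a trial-machinery stand-in, not an
  electrophysiological model; absolute ΔQTcF magnitudes depend on its
  gain setting, and only the correction-method *contrast* is a
  structural prediction.
* Only one sine/cosine harmonic is supported — deliberately, as the
  final reference model contains exactly one pair.
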