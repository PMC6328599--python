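# Methods

## Problem and data model

A meal is an ordered event stream on a meal-local clock (seconds from the
first event): bites with weighed mass (g) and a food identity, chewing
sequences (start, end, chew count), swallow times, and — optionally — a
chewing-sensor amplitude trace whose bout windows align one-to-one with the
chewing sequences. Food composition (energy density in kcal/g, liquid flag)
converts consumed mass to energy. The two dependent quantities are exact by
construction: meal mass is the sum of bite masses, and energy is the sum
over foods of consumed mass × energy density.

## Durations and pauses

Three denominators are used by the rate features:

* **meal duration** — first event time to last event time;
* **eating duration** — meal duration minus total pause duration;
* **chewing duration** — sum of chewing-sequence durations.

Pauses need a definition of an *ingestion bout*: here, a bout runs from a
bite to the later of its chewing-sequence end and its last following swallow
before the next bite; pauses are the gaps between consecutive bouts. This
makes `total_pause_du + eating_du = meal_du` an exact identity (tested), and
guarantees chewing ≤ eating ≤ meal since chewing sequences lie inside bouts.

## The 57-feature registry

Features are fixed in a canonical registry (version 1.0), partitioned
6 bite / 15 chew / 9 swallow / 4 pause / 23 sensor. Instantaneous bite and
swallow frequencies (IBF/ISF) are reciprocals of successive inter-event
intervals; per-sequence chew counts, durations and rates are summarised by
mean/SD/variance. All SDs/variances are **sample** statistics (n − 1), the
default of the common statistical packages; `sd² = var` is an enforced
internal-consistency invariant.

The 23 sensor features are the meal-level **average** and **total** of 11
per-bout descriptors plus the bout count. The per-bout registry — mean
crossings, mean inter-crossing duration, Shannon entropy, waveform length,
mean |amplitude|, amplitude variance, autocorrelation period, power, power
in dB, spectral energy, spectral peak frequency — covers all sensor features
that appear in published meal-intake model tables (`avg_pwr`, `avg_pwr_dB`,
`avg_Waveform_Length`, `avg_Total_Entropy`, `avg_var_Amplitude`,
`avg_zero_crossings`, `avg_Spectral_energy`); the avg/total/count split
beyond those named is this package's documented convention.

Numerical choices for the sensor descriptors:

* entropy: natural-log Shannon entropy of a 100-bin amplitude histogram,
  with 0·log 0 := 0 and entropy 0 for a constant bout;
* crossings are crossings of the *bout mean*, with crossing times linearly
  interpolated for the inter-crossing duration;
* autocorrelation period: lag of the first local maximum of the (unnormalised)
  autocorrelation after lag 0; 0 if none exists;
* spectral energy is normalised to equal Σx² (Parseval); the spectral peak
  excludes the DC bin; `pwr_dB` of a zero-power bout is imputed at −120 dB.

Degenerate cases are imputed as 0 with a logged warning (IBF/ISF with < 2
events, SD/variance over < 2 items, chew features of a liquid-only meal, all
23 sensor features when there are no bouts) so that every meal yields a
finite 57-vector for modeling.

## Regression, cross-validation, selection

Models are multiple linear regressions **through the origin** (a meal with
no events has zero intake, so the intercept is fixed at 0). Inference
conventions: df = n − p (no intercept consumes a degree of freedom),
two-sided p-values from the central t distribution, root MSE =
√(SSE/(n−p)), and the **uncentered** adjusted R²
(1 − (1 − R²ᵤ)·n/(n−p) with R²ᵤ = 1 − SSE/Σy²), the standard convention for
no-intercept models. Final fits go through statsmodels OLS; the LOSO inner
loop uses a plain least-squares solve for speed. Both are checked against a
hand-built normal-equations oracle in the tests.

Leave-one-subject-out CV holds out *all* meals of one subject per fold;
predictions are strictly out-of-fold (a corruption/permutation leakage test
enforces this). Forward selection greedily adds the pool feature that
minimises the mean LOSO APE, requires strict improvement, caps at 6
features, and breaks ties in registry order so it is deterministic.
Selection runs once on the whole dataset and precedes the reported CV
errors; this mirrors common practice but means the reported MAPE is mildly
optimistic, since every fold's feature set has seen the full data. A
`nested=True` option re-selects inside each fold for a leakage-free
estimate.

**Post-selection inference caveat.** Coefficient CIs from a forward-selected
model are optimistic: selection conditions on the noise realisation. In the
package's own calibration study (60 simulated cohorts), the 95 % CI of the
bite-count coefficient covered the generating value in 80 % of runs when
extra selected features were allowed, versus nominal (100 % observed)
coverage when the model was restricted to the generating structure. The
recovery checks therefore fit the bite family with `max_features=1` and
verify separately that selection ranks `total_bite` first.

## Agreement statistics

Differences are estimated − actual. LOA = bias ± 1.96·SD with 1.96 used
literally; CIs as in the README. Negative model predictions are kept (no
flooring) so the agreement statistics describe the unconstrained linear
model. All meals of all subjects are pooled into one Bland–Altman analysis;
with four meals per subject this ignores within-subject correlation and
slightly understates the interval widths — a known caveat of the pooled
convention.

## Synthetic cohort generator

The generator emulates a laboratory study design: 28 subjects × 4 meals
(defaults), a small mixed solid/liquid food library with realistic energy
densities, and subject-level eating-style parameters drawn once per subject
**before** any meal draws (so adding meals never perturbs subject
parameters; all randomness flows from one seeded generator).

Defaults (units): chew rate ~ Normal(1.4, 0.15) Hz; mean bite mass
lognormal with mean 10 g, between-subject SD 2 g, within-meal CV 0.3; pause
means lognormal around 6 s with pauses i.i.d. exponential within meals (the
simplest memoryless gap model); bites per meal ~ Poisson around a subject
mean near 22; chews per sequence = round(2.5 · hardness · bite mass) plus
Poisson jitter, so total chews couple positively with meal mass; 1–3
swallows follow each sequence; liquid bites produce a swallow but no chewing
sequence. Meal mass is the bite count × subject mean bite mass plus
meal-level Gaussian noise (default SD 30 g, ≈ 12 % of a typical 250 g meal),
distributed over bites — so mass is linearly coupled to bite count, which is
the signal the regression stage must recover. The sensor trace is a
sinusoid at the subject's chewing rate (random phase per bout, 10 %
raised-cosine edge taper, subject-specific amplitude) plus white noise,
sampled at 100 Hz — ample for chewing at 1–2 Hz; a flat-envelope bout has
mean power exactly amplitude²/2, which the tests exploit.

The **recovery study condition** sets the between-subject bite-mass SD to 0,
making total mass = 10 g × bite count + i.i.d. noise exactly; the pooled
zero-intercept model is then the true data-generating process and CI
coverage is nominal.

What the generator does **not** emulate: real jaw-motion waveform shape and
artefacts, annotation errors, meal-type (breakfast/lunch/dinner) structure,
demographic covariates, or the empirical food-frequency distribution.
Passing tests therefore validate the *machinery* — feature definitions,
selection, CV, inference, agreement formulas — not the field accuracy of
intake estimation, whose published errors depend on real data this package
does not ship.

## Problem sizes

The test suite and acceptance script use 28 × 4 cohorts (112 meals) for
cohort-level checks, 20 independent seeds for the recovery coverage study,
100 randomised meals for brute-force feature equivalence and 50 random
instances for the regression oracle; smaller toy sets (4–6 subjects) drive
the fold-by-fold and selection oracles. These sizes keep every Monte-Carlo
check's sampling error well below its decision margin.

## Known limitations

* Forward selection is not nested inside CV by default (see caveat above).
* The 23-sensor-feature composition beyond the published model names is a
  package convention, as is the annotation CSV dialect.
* Pooled Bland–Altman over repeated meals per subject (see above).
* APE is undefined for a zero actual intake; callers must exclude such meals.
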