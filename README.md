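# mealmetry

Meal-level **mass and energy intake estimation** from eating-microstructure
annotations (bites, chews, swallows, pauses) and a wearable chewing-sensor
signal.

Objective assessment of how much people eat is a long-standing problem:
self-report is biased, and weighed food records do not scale outside the
laboratory. An alternative is to model intake from the *microstructure* of a
meal — the timed pattern of bites, chewing sequences, swallows and pauses
observable from video annotation or from a jaw-motion (piezoelectric strain)
sensor worn below the ear. `mealmetry` implements that analysis end to end
for researchers in ingestive behaviour and dietary assessment:

1. **Simulate** cohorts of annotated meals (default 28 subjects × 4 meals,
   mixed solid/liquid foods with known energy density, subject-specific
   eating styles) so the whole pipeline is testable without access to a
   laboratory dataset.
2. **Extract** the canonical **57 independent features** per meal:
   6 bite, 15 chew, 9 swallow, 4 pause and 23 sensor features
   (per-chewing-bout EMG-style descriptors such as waveform length, mean
   crossings, entropy, signal power and spectral peak, averaged and totalled
   over the meal).
3. **Model** the two dependent quantities — total mass *M* (g) and energy
   *E* (kcal) — with multiple linear regression **through the origin**,

   ŷ = Σₖ βₖ xₖ   (no intercept),

   where the features xₖ are chosen by greedy **forward selection**
   minimising the mean absolute percentage error

   APEᵢⱼ = |(ŷᵢⱼ − yᵢⱼ)/yᵢⱼ| × 100 %

   of **leave-one-subject-out (LOSO)** cross-validated predictions (subject
   *i*, meal *j*). Five model families are built per target: *full* (all 57
   features), *bite*, *chew*, *swallow* and *sensor*.
4. **Evaluate** agreement with Bland–Altman statistics: bias
   (mean of ŷ − y), limits of agreement LOA = bias ± 1.96·SD, and the
   t-based 95 % confidence intervals
   bias ± t₍ₙ₋₁₎·√(SD²/n) and LOA ± t₍ₙ₋₁₎·√(3·SD²/n).

## Worked example

```python
from mealmetry import (SyntheticConfig, generate_cohort, features_table,
                       build_model_family)
from mealmetry.agreement import evaluate

records, targets = generate_cohort(
    SyntheticConfig(n_subjects=28, meals_per_subject=4, seed=42))
table = features_table(records)          # 112 meals x (57 features + targets)

result = build_model_family(table, family="bite", target="mass_g")
print("selected features:", result.trace.selected)
print(result.fit.coefficient_table().round(3))

report = evaluate(table.subject_id, table.meal_id,
                  result.loso_estimates, table.mass_g)
print(f"MAPE  {report.mape_mean:.1f}% +/- {report.mape_sd:.1f}%")
print(f"bias  {report.bias:.1f} g (SD {report.bias_sd:.1f} g)")
print(f"LOA   ({report.loa_lower:.1f}, {report.loa_upper:.1f}) g")
```

prints

```
selected features: ['total_bite', 'avg_biteRate_Tmeal', 'sd_IBF']
                    Coefficient       SE  t value  P value
total_bite               10.923    0.406   26.924    0.000
avg_biteRate_Tmeal     -514.315  146.935   -3.500    0.001
sd_IBF                  112.021   37.053    3.023    0.003
MAPE  17.3% +/- 14.1%
bias  -1.8 g (SD 46.2 g)
LOA   (-92.3, 88.6) g
```

Reading this: the bite-family model estimates roughly **10.9 g of intake per
bite** (the dominant, highly significant term), with small corrections from
bite rate and bite-timing variability. Out-of-fold (LOSO) predictions are on
average 17 % off the weighed meal mass, essentially unbiased (−1.8 g), and
for 95 % of meals the estimation error falls between −92 g and +89 g.

The same pipeline is available from the shell:

```bash
mealmetry run --seed 42 --out results_dir                 # full pipeline
mealmetry simulate --seed 1 --out sim_dir                 # stage by stage
mealmetry extract --annotations sim_dir/annotations.csv \
    --foods sim_dir/foods.csv --sensor-dir sim_dir/sensors --out features.csv
```

`run` writes the feature table, per-(family, target) model reports
(coefficients with SE/t/p, adjusted uncentered R², root MSE, MAPE, bias,
LOA and CIs), forward-selection traces and Bland–Altman plot data, all as
plain CSV/JSON.

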