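# snaq

Brief food-group-serving dietary analysis for pregnancy.

Full item-level nutrient analysis of a dietary record is slow and needs
specialist software; a brief alternative is to code each eating occasion as a
number of standard servings of the seven food groups of the Australian Guide
to Healthy Eating (AGTHE) and estimate nutrients from average per-serving
composition. `snaq` implements that pipeline for dietitians and nutrition
researchers working with multi-day records from pregnant women:

* **Estimation** — mean daily servings per food group (averaged over the days
  actually recorded) are mapped through a per-serving composition table to
  daily energy (kJ) and five key pregnancy micronutrients: iron, calcium,
  folate (dietary folate equivalents), iodine and zinc. Doses of micronutrient
  supplements are added when the analysis condition includes them; synthetic
  folic acid converts to DFE at 1.7 µg/µg.
* **Adequacy** — each micronutrient intake *x* is classified against the
  pregnancy Nutrient Reference Values into the ordinal classes
  *x* < EAR, EAR ≤ *x* < RDI, *x* ≥ RDI
  (EAR/RDI defaults: iron 22/27 mg, calcium 840/1000 mg, folate 520/600 µg,
  iodine 160/220 µg, zinc 9/11 mg). Food-group intakes are compared with the
  AGTHE pregnancy targets (grains ≥ 8.5, vegetables ≥ 5, fruit ≥ 2, meat
  ≥ 3.5, dairy ≥ 2.5 servings/day; spreads/oils and discretionary foods
  within 0–2.5).
* **Relative validity** — agreement with a reference method over the same
  participants: Spearman ρ on raw intakes (midranks, two-sided t
  approximation on n−2 df) and Cohen kappa κ = (p₀ − pₑ)/(1 − pₑ) on
  adequacy classes (1000 kJ bins for energy), with the asymptotic null-SE
  z-test p-value. A constant classification on either side reports
  "constants — no statistics computed" instead of a kappa.
* **Synthetic cohorts** — a seeded generator draws per-day servings from
  lognormal distributions parameterized by cohort median/IQR, assigns a daily
  prenatal supplement to a random subset, and produces a paired reference
  method profile with configurable multiplicative bias and noise, so the whole
  pipeline runs end to end without participant data.

The bundled per-serving composition table is a documented stand-in with
plausible group averages (energies match the AGTHE standard-serving bands);
replace it with your own table via `--composition` / `load_composition` for
real analyses.

## Worked example

`python examples/03_relative_validity.py` simulates a 25-participant, 3-day
cohort (seed 42) and prints the agreement table between the brief method and
the simulated reference method:

```
        condition    nutrient          rho (P)              kappa (P) agreement
 with_supplements      energy    0.719 (0.000)          0.219 (0.009) fair
 with_supplements        iron    0.892 (0.000)          0.826 (0.000) almost perfect
 ...
        food_only        iron    0.737 (0.000)   constants (no stats) -
```

Each row pairs the two methods for one nutrient under one supplement
condition: ρ measures rank agreement of raw intakes, κ chance-corrected
agreement of the adequacy classifications. The food-only iron row is
degenerate because every simulated intake falls below the 22 mg EAR on both
methods — both classifications are constant, so no kappa exists.

The other examples cover single-record nutrient estimation
(`01_estimate_nutrients.py`), the cohort food-group summary
(`02_cohort_summary.py`) and per-participant feedback
(`04_participant_feedback.py`).

## Command line

```sh
snaq defaults                       # print bundled NRV/AGTHE/composition tables
snaq simulate --seed 42 --out sim/  # synthetic records + paired profiles
snaq analyze  --records sim/records.csv --supplement-uses sim/supplement_uses.csv \
              --out report.json
snaq validate --method-a sim/snaq_profiles.csv --method-b sim/reference_profiles.csv \
              --out table.json
snaq feedback --records sim/records.csv --supplement-uses sim/supplement_uses.csv \
              --participant P001
```

JSON outputs carry unrounded numbers; rounding happens only in text
rendering. Exit codes: 0 success, 1 data/validation error, 2 usage error.

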