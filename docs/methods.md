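# Methods

## The estimation model

The brief method deliberately trades item-level detail for speed: every
eating occasion is coded as servings of the seven AGTHE food groups, and a
participant's daily intake of nutrient *n* is estimated as

    intake_n = Σ_g s_g · c_{g,n}  +  [supplements included] Σ_p d_p · u_{p,n}

where `s_g` is the mean daily servings of group *g*, `c_{g,n}` the mean
content of *n* in one standard serving of *g*, `d_p` the mean daily doses of
supplement product *p* and `u_{p,n}` its per-dose content. The model is
linear and monotone by construction: adding servings can never lower an
estimated intake, and food-only estimates are additive across records.

Averaging uses the number of *distinct days actually recorded* as the
denominator (a 2-day record divides by 2); days with no entry for a group
contribute zero servings of that group. Records with fewer than `min_days`
(default 2) distinct days are excluded before analysis — a single day cannot
support a usual-intake average — and are reported with the reason rather
than silently dropped.

Supplemental folic acid is converted to dietary folate equivalents at the
standard fortificant factor of 1.7 µg DFE per µg folic acid (configurable at
load). Supplement energy defaults to zero, which makes the energy estimate
identical under both supplement conditions.

## Reference tables

Pregnancy EAR/RDI defaults: iron 22/27 mg, calcium 840/1000 mg, folate
520/600 µg DFE, iodine 160/220 µg, zinc 9/11 mg per day. AGTHE pregnancy
serving targets: grains ≥ 8.5, vegetables ≥ 5, fruit ≥ 2, meat ≥ 3.5, dairy
≥ 2.5; unsaturated spreads/oils and discretionary foods 0–2.5 (ranges
inclusive at both ends). Both tables are replaceable via JSON files.

The per-serving composition table has no authoritative published source at
the food-group level, so the bundled `data/composition.csv` is a stand-in:
energy per serving sits inside the AGTHE standard-serving bands (grains
500 kJ, vegetables 100–350 kJ, fruit 350 kJ, meat and dairy 500–600 kJ,
spreads/oils 250 kJ, discretionary 600 kJ — enforced at load, as a warning by
default and an error under `--strict`, with a 20% tolerance because
user-supplied tables may legitimately deviate), and the micronutrient
densities are chosen so that intakes at typical serving levels land in
realistic ranges (e.g. ~300 mg calcium per dairy serving). How a
consumption-weighted average over an actual food database would differ is
unknowable here; every downstream test is written against the bundled
fixture, not against an unpublished truth.

## Adequacy classification

Class boundaries follow the class definitions literally: `< EAR`,
`≥ EAR and < RDI`, `≥ RDI`, applied to unrounded intakes. Energy has no EAR
in this framework and is never classified. The classification is monotone in
intake and the three classes partition the intake axis, so cohort class
percentages always sum to 100.

## Agreement statistics

Spearman ρ assigns midranks to ties and computes the Pearson correlation of
the rank vectors; the two-sided p-value uses `t = ρ·√((n−2)/(1−ρ²))` on
n−2 df, matching mainstream statistical software at cohort sizes of ~25.
`|ρ| = 1` reports a p-value at the machine floor. An exact permutation
p-value (all n! pairings) is available for n ≤ 8 and doubles as a test
oracle. A constant input vector raises a degenerate-input error rather than
returning a number.

Cohen kappa is unweighted by default (a linear-weights point estimate is
available but off by default). The p-value tests κ = 0 with the asymptotic
null standard error

    SE₀² = [pₑ + pₑ² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)] / [n (1 − pₑ)²]

and a two-sided normal tail on z = κ/SE₀; the implementation agrees with
statsmodels' `cohens_kappa` to machine precision on both the estimate and
the p-value. If either classification is constant the result is flagged
degenerate and no kappa is reported. If the two methods' label supports are
disjoint (pₑ = 0, κ = 0, SE₀ = 0) the p-value is reported as 1. Energy is
binned into half-open 1000 kJ intervals `[k·1000, (k+1)·1000)` anchored at
0 kJ before computing kappa, with the label set the union of bins observed
by either method; adequacy crosstabs are always 3×3.

Interpretation uses the Landis–Koch ladder (≤0 poor, ≤0.20 slight, ≤0.40
fair, ≤0.60 moderate, ≤0.80 substantial, ≤1 almost perfect), banding the
kappa rounded to two decimals — the resolution at which the scale's edges
are stated — so κ = 0.803 reads "substantial".

## Cohort summaries

Food-group summaries report mean, sample SD (n−1 denominator; undefined and
rendered blank for a single participant, never 0), median and quartiles by
linear interpolation between order statistics (the common default of
mainstream statistics software; the original choice is undocumented, so it
is configurable via numpy's percentile machinery), and the count and
percentage meeting each AGTHE target.

## The synthetic cohort generator

The generator emulates a small pregnancy cohort keeping 3-day records; its
defaults are the study-like conditions under which the test suite runs:

* **Servings** — per group and day, independent lognormal draws. The
  lognormal is the simplest nonnegative right-skewed family that can be
  parameterized by a median and IQR; defaults are the observed cohort
  medians/quartiles (grains 4.7 (3.6–6.5), vegetables 2.2 (1.2–3.5), fruit
  1.7 (0.9–2.5), meat 1.9 (1.4–2.9), dairy 1.8 (1.3–2.7), spreads/oils
  2.0 (0.5–3.0), discretionary 3.5 (2.4–3.9) servings/day). The fit is
  `μ = ln(median)`, `σ = (ln p75 − ln p25)/(2 · 0.6744897…)`. A two-parameter
  lognormal reproduces the median and the quartile *ratio* exactly for any
  input, and all three quartiles exactly when the inputs are log-symmetric
  (i.e. genuinely lognormal quartiles); the observed cohort quartiles are
  mildly asymmetric, so the fitted p25/p75 differ from the inputs (the
  discretionary row fits to 2.75/4.46 against 2.4/3.9). A per-group point
  mass at zero (`zero_prob`) is available for subgroups whose lower quartile
  is zero. Note the wide spreads/oils IQR implies a heavy tail (σ ≈ 1.3), so
  its simulated mean well exceeds its median.
* **Supplements** — each participant is a supplement user with probability
  0.6 (chosen once as a realistic prenatal-supplement prevalence; the source
  cohort reports supplement-influenced medians but no prevalence), and users
  take exactly one dose of the bundled prenatal product every day.
* **Reference method** — per nutrient, the reference observation is the
  brief method's food-level estimate times a systematic bias times
  `exp(σ_ref · Z)` lognormal noise (default σ_ref = 0.15), with the
  supplement contribution added unperturbed, since both methods read the
  same declared doses. Multiplicative error on nutrients is the simplest
  model producing rank-preserving, magnitude-shifted disagreement. Default
  biases are the ratio of the two methods' observed food-only medians:
  energy 0.92, iron 1.24, calcium 0.91, folate 1.28, iodine 1.05, zinc 1.0.
* **Determinism** — all draws come from numpy's PCG64 generator seeded from
  a single integer; replicate seeds derive from a `SeedSequence` and are
  masked to 31 bits. Identical seeds give byte-identical outputs.

What the generator does *not* emulate: item-level food coding,
under-reporting, day-of-week effects, or shared portion-estimation error
between the methods (the true inter-method error structure is unknowable
from summary statistics — σ_ref and the biases are free parameters, not
estimates). Passing tests therefore demonstrate the pipeline's correctness
and its qualitative behaviour under a plausible error model, not the
quantitative agreement one would measure on real records.

## Monte-Carlo checks and problem sizes

`recovery_experiment` reruns simulate → validity per replicate and
summarizes the ρ/κ distributions. The suite verifies the noise-free limit
(σ_ref = 0, bias 1 ⇒ ρ = 1 and κ = 1 or degenerate in all 50 replicates at
n = 25) and monotone degradation (mean ρ strictly decreasing across
σ_ref ∈ {0.05, 0.2, 0.5}, 50 replicates of n = 25 each) — sizes chosen to
match the study-scale cohort while keeping the full suite in a few seconds.
Statistical oracles run ≥200 random instances at n ≤ 12 against naive
brute-force implementations at 1e−12 absolute tolerance.

## Known limitations

* Group-level averaging cannot represent foods outside the seven groups
  (spreads like yeast extract, condiments, fortified drinks), which is the
  main source of folate underestimation in food-only analyses; the 100 µg
  folate in a 5 g serving of Vegemite (19% of the pregnancy EAR) is the
  canonical example.
* The bundled composition table is illustrative, not authoritative.
* Kappa p-values use asymptotic normality, optimistic at n = 25 with sparse
  classes; the degenerate flag protects only the fully constant case.
* No energy requirement is evaluated (no EAR exists for energy here), and no
  Bland–Altman or intraclass-correlation analysis is provided.
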