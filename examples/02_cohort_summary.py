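"""Cohort food-group summary against the AGTHE pregnancy targets.

Simulates a 25-participant, 3-day cohort at the default study-like
serving distributions, then prints each food group's mean (SD), median
(IQR) daily servings and the share of the cohort meeting its AGTHE
target. Core groups have minimum targets; spreads/oils and discretionary
foods have 0-2.5 serving ceilings.
"""

from snaq import SyntheticConfig, mean_daily_servings, simulate_cohort, summarize_cohort
from snaq.composition import default_targets

cohort = simulate_cohort(SyntheticConfig(seed=42))
servings = [mean_daily_servings(r) for r in cohort.records]
summaries = summarize_cohort(servings, default_targets())

print(f"{'group':>14} {'mean (SD)':>12} {'median (IQR)':>18} {'target':>8} {'meeting':>8}")
for s in summaries:
    print(
        f"{s.group.value:>14} {s.mean:5.1f} ({s.sd:3.1f}) "
        f"{s.median:6.1f} ({s.iqr[0]:3.1f}-{s.iqr[1]:3.1f}) "
        f"{s.target.describe():>8} {s.n_meeting:3d} ({s.pct_meeting:3.0f}%)"
    )
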