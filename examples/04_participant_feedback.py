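"""Render one participant's dietary feedback summary.

Takes the first participant of a simulated cohort and prints the text
summary a dietitian would relay back: each food group's mean daily
servings against its AGTHE target with the gap in servings, and each key
nutrient's intake with its adequacy class and percentage of the
pregnancy EAR.
"""

from snaq import SyntheticConfig, build_feedback, mean_daily_servings, render_feedback_text, simulate_cohort
from snaq.composition import default_nrv, default_targets

cohort = simulate_cohort(SyntheticConfig(seed=42))
record = cohort.records[0]
profile = cohort.snaq_with_supplements[0]

summary = build_feedback(
    record.participant_id,
    mean_daily_servings(record),
    profile,
    default_targets(),
    default_nrv(),
)
print(render_feedback_text(summary))
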