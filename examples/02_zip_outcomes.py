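"""From raw food logs to zip-level outcome measures.

Generates synthetic participant logs for two zip codes, classifies
them, and aggregates to mean daily entries per category plus the
overweight/obesity fraction (share of participants with BMI > 25).
"""

from dietscape import (
    RuleSet,
    SimConfig,
    attach_participants,
    classify_entries,
    filter_participants,
    gen_food_logs,
    gen_zip_table,
    participant_rates,
    zip_outcomes,
)

cfg = SimConfig(n_zips=2, participants_per_zip=80, active_days_mean=20, seed=4)
_, true_outcomes, _ = gen_zip_table(cfg)
entries, participants = gen_food_logs(true_outcomes, cfg)
print(f"generated {len(entries)} log entries for {len(participants)} participants")

labels = classify_entries(entries, RuleSet.default())
summaries = filter_participants(
    attach_participants(participant_rates(labels), participants), min_days=10
)
outcomes = zip_outcomes(summaries, min_participants=30)
print(outcomes.round(3).to_string(index=False))
print(
    "\nmean_* columns are mean daily logged entries per participant in each "
    "category; overweight_fraction is the share of BMI reporters above 25."
)
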