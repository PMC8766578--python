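"""Classify free-text food-log entries and audit classifier precision.

Builds a tiny food-log table, applies the three keyword classifiers
(fresh fruit & vegetables, fast food, sugary non-diet soda) and runs a
precision audit on the soda predictions.
"""

import pandas as pd

from dietscape import RuleSet, classify_entries, estimate_precision

logs = pd.DataFrame(
    [
        ("p1", "2015-01-01", "Coca Cola", "Diet Cherry Coke, 8oz"),
        ("p1", "2015-01-01", "Pepsi", "Cherry, 12oz can"),
        ("p1", "2015-01-02", "McDonald's", "Big Mac"),
        ("p2", "2015-01-01", "", "Banana"),
        ("p2", "2015-01-01", "Tropicana", "Orange Juice"),
        ("p2", "2015-01-02", "Dole", "Baby Spinach, 2 cups"),
    ],
    columns=["participant_id", "log_date", "brand", "description"],
)

rules = RuleSet.default()
labels = classify_entries(logs, rules)
print(labels[["brand", "description", "is_fv", "is_fastfood", "is_soda"]].to_string(index=False))

# Audit: sample predicted soda positives and compare to manual verdicts.
soda = labels[labels["is_soda"]]
precision = estimate_precision(soda, [True] * len(soda), sample_size=50, seed=0)
print(f"\nsoda classifier precision on audited sample: {precision:.2f}")
print(
    "\nEach row shows one logged entry and its three independent labels; "
    "note the diet soda and the juice are counted in no category."
)
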