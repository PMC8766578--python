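"""Food-environment covariates: crosswalk weighting and fast-food access.

Shows the population-weighted tract-to-zip aggregation on a two-tract
zip and the capped nearest-restaurant fast-food access measure.
"""

import numpy as np
import pandas as pd

from dietscape import fastfood_access, food_desert_flag, grocery_access, tract_to_zip

# A zip overlapping a 2,500-person food-desert tract and a 7,500-person
# non-desert tract has a weighted food-desert measure of 25%.
tracts = pd.DataFrame(
    {"tract_id": ["A", "B"], "population": [2500, 7500], "food_desert": [1, 0],
     "beyond_half_mile_frac": [0.9, 0.3]}
)
xwalk = pd.DataFrame({"zip": ["10001", "10001"], "tract_id": ["A", "B"]})
desert = tract_to_zip(tracts, xwalk, "food_desert")["10001"]
beyond = tract_to_zip(tracts, xwalk, "beyond_half_mile_frac")["10001"]
print(f"weighted food-desert measure: {100 * desert:.1f}%  (flag at 50%: {food_desert_flag(desert)})")
print(f"grocery access (fraction within 0.5 miles): {grocery_access(beyond):.3f}")

# Fast-food access: chain share among the nearest restaurants within 40 km.
rng = np.random.default_rng(0)
n = 400
biz = pd.DataFrame(
    {
        "latitude": 40 + rng.uniform(-0.1, 0.1, n),
        "longitude": -100 + rng.uniform(-0.1, 0.1, n),
        "is_restaurant": True,
        "is_fastfood_chain": rng.random(n) < 0.05,
    }
)
ff = fastfood_access((40.0, -100.0), biz, max_n=1000, max_km=40.0)
print(f"fast-food access near (40, -100): {ff:.3f}")
print(
    "\nThe 25% worked example shows person-weighted aggregation through the "
    "crosswalk; fast-food access is the chain fraction among nearby restaurants."
)
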