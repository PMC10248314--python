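"""Score a small cohort with the default five-component battery.

Builds three hand-checkable examinee profiles, recodes each raw score
onto the 0-3 level-of-failure scale, sums the levels into the index
total, and trichotomizes it into Pass / Borderline / Fail.
"""

import pandas as pd

from erdodi import default_battery, score_cohort

battery = default_battery()
cohort = pd.DataFrame(
    {
        # intact profile / mixed marginal failures / pervasive failures
        "CD": [10, 6, 5],
        "RCFT_Copy": [34.0, 28.0, 24.0],
        "FMS_WCST": [0, 3, 4],
        "RDS": [12, 8, 6],
        "RH_CVLT": [15, 13, 12],
    }
)

scored = score_cohort(cohort, battery)
print(scored[[c for c in scored.columns if c.startswith("level_")]
             + ["ei_total", "ei_band"]].to_string(index=False))
print()
print(
    "Each level column is that indicator's failure level (0 = passed the\n"
    "most liberal cutoff, 3 = failed the ultra-conservative one); ei_total\n"
    "sums them (0-15) and ei_band applies the standard bands:\n"
    "Pass <= 1, Borderline 2-3, Fail >= 4."
)
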