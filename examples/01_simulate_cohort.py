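"""Generate a synthetic two-group clinical cohort.

Builds the default specs — 281 adults with a confirmed autism diagnosis
(ASD+) and 119 with the diagnosis ruled out (ASD-), matching the
published scale means/SDs, correlations, sex ratios and item
reliabilities — and writes an item-level CSV.
"""

import numpy as np

from alexidom import default_group_specs, generate_cohort
from alexidom.io import write_cohort_csv

specs = default_group_specs()
cohort = generate_cohort(specs, seed=7)
write_cohort_csv(cohort, "cohort.csv")

print(f"cohort: {len(cohort)} participants "
      f"({(cohort.group == 'ASD+').sum()} ASD+, "
      f"{(cohort.group == 'ASD-').sum()} ASD-)")
n_missing = int(cohort.filter(regex="^(aq|tas)_").isna().sum().sum())
print(f"missing item responses: {n_missing} "
      "(sparse, like the clinical questionnaires)")
print(cohort[["id", "group", "age", "sex", "piq", "viq"]].head(3).to_string(
    index=False))
# Each row also carries 50 AQ items (1-4), 20 TAS-20 items (1-5) and
# 21 BDI items (0-3); scoring them recovers the group-level structure.
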