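"""Dominance analysis: which trait explains depressive symptoms?

Correlated predictors make standardized coefficients hard to compare.
General dominance weights average each predictor's incremental R2 over
all 2^p subset models (stratified by subset size); they sum exactly to
the full-model R2, so GDW / R2 is a predictor's share of explained
variance. Bootstrap percentile CIs use whole-case resampling (B = 100,
the replication-mode default).
"""

from alexidom import default_group_specs, dominance_analysis, generate_cohort, score_cohort
from alexidom.regression import STUDY_PREDICTORS

scored = score_cohort(generate_cohort(default_group_specs(), seed=7))
for group in ("ASD+", "ASD-"):
    sub = scored[scored.group == group].copy()
    sub["sex"] = (sub["sex"] == "male").astype(float)
    res = dominance_analysis(sub[list(STUDY_PREDICTORS)],
                             sub["bdi"].to_numpy(), B=100, seed=42)
    print(f"\n{group}: R2 = {res.r2_full:.3f} "
          f"(sum of GDWs = {res.gdw.sum():.3f})")
    print(res.table().sort_values("rank").to_string(
        index=False, float_format="%.3f"))
# In both groups DIF (difficulties identifying feelings) takes the top
# rank with roughly half of the explained variance, ahead of autism
# traits (AQ) — the study's central result, recovered from synthetic
# cohorts with the published correlation structure.
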