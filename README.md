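# alexidom

Dominance analysis of autism and alexithymia traits as predictors of
depressive symptoms in adults referred for autism diagnostics — a
complete, tested implementation of the analysis chain, plus a seeded
synthetic-cohort generator so every stage can be exercised end to end
without access to the (non-public) clinical data.

## The problem

Adults with autism spectrum disorder (ASD) report markedly elevated
depression rates. Autism traits (AQ) and alexithymia traits (TAS-20:
DIF *difficulties identifying feelings*, DDF *difficulties describing
feelings*, EOT *externally oriented thinking*) are strongly correlated,
so standardized regression coefficients alone cannot say which trait
*matters more* for depressive symptoms (BDI). Dominance analysis
resolves this: for a model with p predictors, fit all 2^p subset
models and average each predictor's incremental R² over all subsets of
a given size, then over sizes:

GDW_j = (1/p) Σ_{s=0}^{p−1} mean_{|S|=s, j∉S} [ R²(S∪{j}) − R²(S) ]

The general dominance weights (GDWs) sum exactly to the full-model R²
(they are the Shapley decomposition of R²), so GDW_j / R² is the share
of explained variance attributable to predictor j, and predictors can
be ranked on it. The package implements the full study protocol around
this statistic: questionnaire scoring with published keys and cut-offs,
group-mean imputation and eligibility filtering, group contrasts
(pooled t, Levene, Yates-corrected χ², Pearson/Fisher-z with Bonferroni
adjustment), a standardized 8-predictor OLS with assumption diagnostics
and HC3 heteroscedasticity-consistent errors selected via the
Breusch–Pagan test, and whole-case bootstrap percentile CIs for the
GDWs.

The synthetic-data module is first-class: it generates two-group
cohorts (ASD+ n = 281, ASD− n = 119) whose scale moments, 5×5
correlation structure, sex ratios, item-level reliabilities
(Cronbach's α) and sparse missingness match the published study
summaries, at both the latent-scale and raw-item level.

## Worked example

```python
from alexidom import default_group_specs, generate_cohort, score_cohort, dominance_analysis
from alexidom.regression import STUDY_PREDICTORS

scored = score_cohort(generate_cohort(default_group_specs(), seed=7))
sub = scored[scored.group == "ASD+"].copy()
sub["sex"] = (sub["sex"] == "male").astype(float)
res = dominance_analysis(sub[list(STUDY_PREDICTORS)], sub["bdi"].to_numpy(),
                         B=100, seed=42)
print(f"R2 = {res.r2_full:.3f} (sum of GDWs = {res.gdw.sum():.3f})")
print(res.table().sort_values("rank").head(3).to_string(index=False,
                                                        float_format="%.3f"))
```

prints

```
R2 = 0.252 (sum of GDWs = 0.252)
predictor   gdw  share  rank  ci_low  ci_high
      dif 0.123  0.487     1   0.061    0.169
       aq 0.070  0.276     2   0.035    0.114
      ddf 0.016  0.062     3   0.009    0.028
```

DIF holds the top rank with ~49% of the explained variance — on a
synthetic cohort carrying the published correlation structure, the
analysis recovers the study's central finding: difficulties identifying
feelings outweigh autism traits in explaining depressive symptoms. The
GDWs sum exactly to R² (the defining identity of the decomposition),
and the bracketing [ci_low, ci_high] are percentile bootstrap bounds
over B = 100 whole-case resamples.

The `examples/` directory walks through each capability (simulation,
scoring/eligibility, descriptives, robust regression, dominance, full
pipeline); each script prints its results with a line on what they
mean. A thin CLI mirrors the pipeline stages:

```bash
alexidom simulate --seed 7 --out cohort.csv
alexidom score --in cohort.csv --out scored.csv
alexidom analyze --seed 11 --out-dir reports   # tables + JSON + run log
```

## Layout

- `src/alexidom/cohort.py` — group specs, PSD repair, latent cohorts, item disaggregation, missingness
- `src/alexidom/scoring.py` — AQ/TAS-20/BDI scoring, imputation, eligibility, Cronbach's α
- `src/alexidom/descriptives.py` — t/Levene/χ²/Pearson-with-Fisher-CI, Bonferroni
- `src/alexidom/regression.py` — standardized OLS, diagnostics, HC3, model F
- `src/alexidom/dominance.py` — all-subsets R², GDWs, bootstrap CIs, dominance relations
- `src/alexidom/pipeline.py` / `cli.py` — orchestrated study replica and CLI
- `docs/methods.md` — model assumptions, calibration details, design choices, limitations
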