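# Methods

## Study design being replicated

The analysis concerns adults referred to an outpatient clinic for
autism diagnostics, split by the diagnostic outcome: a confirmed-ASD
group (ASD+, n = 281) and a ruled-out group (ASD−, n = 119). Each
participant contributes three self-report instruments — the 50-item AQ
(autism traits, items answered 1 = agree … 4 = disagree, dichotomised
and summed 0–50), the 20-item TAS-20 (alexithymia; 1–5 Likert, three
subscales DIF/DDF/EOT, reverse-keyed items 4, 5, 10, 18, 19) and the
21-item BDI (depressive symptoms, items 0–3, total 0–63) — plus age,
sex, and performance/verbal IQ. The question is the *relative
importance* of autism vs. alexithymia traits for depressive symptoms,
answered by dominance analysis of the standardized model
BDI ~ age + sex + PIQ + VIQ + AQ + DIF + DDF + EOT per group.

The raw clinical data are not public. The package therefore ships a
generator that emulates the published summary structure, and every
statistical stage is validated on synthetic cohorts plus closed-form /
brute-force oracles.

## Synthetic cohort model

**Latent scales.** Per group, (BDI, AQ, DIF, DDF, EOT) are drawn from a
multivariate normal with the published means, SDs, and 5×5 correlation
matrix (both published matrices are PSD; a nearest-PSD repair with
eigenvalue clipping at 1e-8 and diagonal rescaling guards user-edited
configs). Age is truncated normal (≥ 18 years; adult clinic), PIQ and
VIQ are independent normals, sex is Bernoulli with the group's male
fraction (219/281, 81/119). Correlations of demographics with the five
scales are not published and default to zero rather than invented
structure. IQ is *not* truncated at 70 by the generator: the
eligibility filter downstream is responsible for that exclusion, as in
the clinical protocol.

**Items.** Each instrument (sub)scale uses a one-factor equicorrelated
model. The mean inter-item correlation implied by a target Cronbach's
alpha is the Spearman–Brown inversion r = α / (k − α(k−1)). Item
latents are x_i = λF + s·q_{π(i)}, where F is the participant's
standardized latent scale score and the residuals are a per-participant
random permutation of fixed stratified normal quantiles (exact zero
sum, unit mean square). Two consequences matter:

* the item-latent *sum* equals kλF exactly, so the discretised item sum
  tracks the latent scale score with r ≈ 0.97–0.99 for every
  instrument — including the dichotomised AQ, where independent
  residuals would cap this correlation near √α ≈ 0.93;
* the exchangeable residuals carry pairwise correlation −1/(k−1), which
  the loading formula absorbs: u = λ² = (1 + (k−1)r) / (k·λ_d²), with
  λ_d the closed-form linear attenuation of the thresholded item
  (computed from the category probabilities and densities). λ is capped
  at 1 (identical items) because the linear attenuation model breaks
  down as r → 1, where discretisation noise is shared by the items
  rather than independent.

Items are discretised by normal-quantile thresholds at half-integer
category boundaries whose location is solved (Brent root find) so the
*expected item sum matches the target scale mean*; the threshold scale
and the loading are resolved by a short fixed point. This automatically
produces the right skew of real BDI item responses (most mass at 0–1),
answering the open design question about item-level skew without an
extra parameter. AQ items are generated on the endorsement (0/1) scale,
where the published α = .86 applies, with the uninformative within-side
split into the two adjacent raw categories drawn 50/50 and the raw
response direction set by the published agree/disagree key.

Realized reliabilities at n = 10 000 land within ±0.03 of the targets
(AQ .86, DIF .85, DDF .74, EOT .60; BDI is not published and defaults
to .88, a typical value for the instrument). Known limitation: with
homogeneous item difficulties, matching the mean *and* alpha of a
bounded item sum fixes its variance, so scored SDs deviate from the
latent targets (AQ inflates to ~7.5 vs 6.1; BDI compresses to ~8.2 vs
10.4 through floor clipping). Correlation structure — what the
standardized regression and dominance analysis consume — is preserved
(scored scales correlate > 0.95 with their latents); absolute variance
scale is not interpreted by any downstream stage. The generator also
does not model diagnostic referral dynamics, comorbidity beyond the
printed moments, or longitudinal change, so passing tests speak to the
statistical machinery, not to clinical validity of simulated
individuals.

**Missingness.** Item cells of AQ and TAS-20 go missing independently
at rate 0.002 (matching the published missing-item census, ~0.25% of
cells; no BDI missingness is reported), capped at 3 per instrument so
default cohorts remain eligible; a configurable count of forced
ineligible rows (≥ 4 missing) exercises the exclusion path. An optional
heteroscedastic mode makes the BDI noise SD linear in standardized DIF
(slope 0.8, normalised to preserve the marginal variance on average)
to exercise the robust-error selection rule.

**Determinism.** One master seed; each (group, stage) pair uses
`SeedSequence(master, spawn_key=(group_index, stage_index))`. Identical
seed and spec give bitwise-identical cohorts.

## Scoring and eligibility

Scoring follows the published protocol exactly: AQ responses 1–2 on
agree-keyed items (3–4 on disagree-keyed) score 1 and are summed; the
autism-trait flag is strict (> 32). TAS reverse items map r → 6 − r;
DIF = {1,3,6,7,9,13,14}, DDF = {2,4,11,12,17}, EOT = {5,8,10,15,16,18,
19,20}; the clinical-alexithymia flag is inclusive (total ≥ 61, the
conventional reading of the published cut-off). BDI bands: 11–17
mild-moderate, ≥ 18 clinical. The TAS key and AQ endorsement key are
not printed in the study report; the published instruments' standard
keys are shipped as editable configuration.

Missing items are imputed by per-item means within diagnostic group.
For the AQ this happens on the recoded 0/1 scale by default (AQ totals
are sums of recoded items, so fractional totals are legal); imputation
on the raw 1–4 scale is available behind a flag, as is scale-level
(rather than item-level) imputation semantics via the group-mean
transform. Eligibility applies, in order: total IQ > 70 strict (the
composite is the mean of PIQ and VIQ when no composite column exists),
fewer than four missing items per instrument (counted pre-imputation on
AQ and TAS-20), and exclusion of AQ totals more than 3 SD *below* the
analysis-set mean — low side only, matching the protocol's single
excluded low outlier. Because the generated AQ sum is left-skewed
(endorsement near ceiling), default synthetic cohorts typically lose a
handful of rows to this rule, which is the filter working as specified.

## Descriptive statistics

Group contrasts use Student's t with pooled variance; the sign
convention is (ASD− minus ASD+), reproducing the published table where
ASD+ scoring higher on IQ yields a negative t. Cohen's d uses the
pooled SD. Levene's test is the classic mean-centred form (the report
says "Levene tests", not the median-centred Brown–Forsythe;
configurable). The 2×2 sex-by-group test applies the Yates continuity
correction by default: the published χ² = 3.832 is reproduced only with
the correction (the classic statistic is 4.34), which settles the
unstated choice. Pearson correlations carry t-based p-values and
Fisher-z CIs (atanh(r) ± z/√(n−3)); the Bonferroni family defaults to
m = 10 (all pairs of the five scales of interest per group). The
published correlation table's caption and its printed p-values are
mutually inconsistent about adjustment (the ASD− DIF p of .006 matches
the *unadjusted* value), so the module always reports both `p_raw` and
`p_adjusted` and does not guess which the table shows.

## Regression and robust errors

All predictors — including the 0/1 sex indicator — and the outcome are
z-scored with n−1 SDs, making every coefficient a per-SD effect
(documented consequence for sex: its β is not a male–female mean
difference). Fitting uses statsmodels' stable pseudoinverse OLS, never
explicit normal-equation inversion; rank-deficient designs are rejected
with the dependent columns named. Diagnostics mirror the protocol:
share of internally studentized residuals beyond |2| (adequate < 5%),
Durbin–Watson in input row order (cross-sectional data have no natural
order; the statistic is reported for protocol completeness), VIF per
predictor, and a Breusch–Pagan test. The BP variant is the Koenker
(studentized) LM form by default — n·R² from regressing e² on the
design, χ²(k) — robust to non-normal errors; the classic form is
available and the choice is logged. A significant BP (p < .05, strict
at the boundary) switches reported standard errors to HC3:
(XᵀX)⁻¹ Xᵀ diag(e_i²/(1−h_ii)²) X (XᵀX)⁻¹, with leverage-1 points
rejected. Coefficients themselves remain plain OLS (the standard
sandwich approach — only the errors are robustified); coefficient
p-values use the t distribution with n−k−1 df in both error models.
On homoscedastic simulations (n = 1000, 1000 replicates) HC3 intervals
cover the true slopes at 95.1% and the BP test rejects at 4.9% — the
calibration the acceptance script recomputes.

## Dominance analysis

Subset R² values are computed from the sample correlation matrix,
R²(S) = r_Syᵀ C_SS⁻¹ r_Sy — algebraically identical to per-subset OLS
with intercept, and cheap enough that the 2^p enumeration (guarded at
p ≤ 20) and the bootstrap are exact rather than approximated. General
dominance weights use size-stratified averaging (the established
convention, and the one that satisfies the Σ GDW = R² identity the
method is built on; the identity is asserted to 1e-10 in tests and
verified against an independent brute-force enumeration for p ≤ 4).
All eight predictors enter the enumeration symmetrically — the
published table prints GDWs for the four control variables too — with
a fixed-covariate mode available but off. Subset fits use plain OLS R²
even when the full model reports HC3 errors (heteroscedasticity
consistency concerns standard errors, not R²). Ranks break ties by
canonical predictor order and set an explicit tie flag, never silently.

Bootstrap CIs resample whole cases; each replicate recomputes the full
subset map. The interval is the percentile interval with numpy's linear
interpolation (the original report does not state the interval type).
B = 100 matches the study's replication mode and is the default;
B ≥ 1000 is recommended for stable percentiles and the docstring says
so. Degenerate resamples (constant columns or singular subsets) are
redrawn with a bounded, logged count. Coverage of percentile intervals
for known population GDWs (orthogonal designs) is 94–97% at n = 400–500
in the test-suite simulations.

Dominance relations (complete / conditional / general) are reported per
ordered pair; complete dominance requires the incremental contribution
to be at least as large over *every* common subset and strictly larger
in at least one, so exactly exchangeable predictors yield no relation
rather than a spurious one.

## Pipeline and provenance

`run_analysis` composes the stages for item-level or pre-scored input
(exactly one of a CSV path or simulation overrides), drops group labels
outside the two analysis groups (mirroring the excluded ambiguous
diagnoses), and emits three tables plus a run log carrying the package
version, master seed, per-group bootstrap seeds, exclusion census
(always reconciling input n = retained + excluded + dropped), the
plain/HC3 decision with its BP p-value, and every under-specified
methodological choice (BP variant, Bonferroni m, bootstrap interval
type, imputation scale, sex coding, IQ composite) so a replication run
is auditable. Output JSON is byte-identical across reruns of the same
config and seed.

## Problem sizes in the test suite

Simulation-based checks are sized for a single CPU while keeping
Monte-Carlo error well inside their assertion bands: moment recovery at
n = 100 000; reliability recovery at n = 10 000; end-to-end mean
recovery at n = 5000 per group (the ±0.5 band is a generator check, and
group-mean sampling error at the study's own n would be of the same
order as the band); HC3 coverage and BP type-I at 1000 replicates of
n = 1000; GDW-vs-brute-force on 100 random well-conditioned datasets;
DIF-ranks-first recovery over 200 seeded cohorts of n = 281; bootstrap
coverage over 200 outer replicates at B = 400, n = 400; the
heteroscedasticity-driven robust-selection rate over 12 pipeline runs
(with the per-decision BP power exercised separately at the regression
level).

## Known limitations

* Scored AQ/BDI variances deviate from the latent targets (see above);
  a heterogeneous-difficulty item model could match variance, alpha and
  mean simultaneously at the cost of the equicorrelated design.
* The generator draws demographics independent of the scales; any true
  age/sex/IQ structure in the clinical population is absent, so control
  variables carry only noise GDWs in synthetic cohorts.
* Percentile bootstrap intervals at B = 100 are noticeably noisy; the
  default exists for replication fidelity, not as a recommendation.
* Cross-sectional, self-report design: nothing here supports causal or
  clinical inference; the package replicates an analysis, not a study.
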