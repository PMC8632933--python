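# Methods

## The phenotyping scheme

Cerebral small vessel disease (CSVD) presents on MRI through three common
parenchymal markers — white-matter hyperintensities (WMH), lacunes, and
cerebral microbleeds (CMB) — that co-occur in combinations reflecting two
distinct microvasculopathies: arteriosclerosis/lipohyalinosis and cerebral
amyloid angiopathy (CAA). The package implements a rule-based stratification
of a stroke-free, non-demented middle-to-old-aged population into a control
group and four CSVD types, applied in a fixed decision order:

1. **CMB present?** Bleeding phenotypes are decided by topography:
   *mixed* CMB (any deep and/or infratentorial microbleed, with or without
   lobar ones) → **type 3**, suggesting arteriosclerotic microangiopathy;
   *strictly lobar* CMB → **type 4**, suggesting CAA. The bleeding branch
   takes precedence regardless of WMH burden or lacunes.
2. **Severe WMH?** Severity means a WMH/total-intracranial-volume (TIV)
   ratio *strictly above* a threshold. Without CMB, severe WMH alone is
   **type 1**; severe WMH with at least one lacune is **type 2**.
3. Neither → **control**.

The severity threshold is either recomputed as the cohort median of the
WMH/TIV ratio (`threshold_mode="cohort_median"`) or fixed
(`threshold_mode="fixed"`, default 0.0007 = 0.07%, the reference cohort's
median). Threshold provenance is explicit in the configuration because a
fixture or subgroup cannot reproduce another cohort's median. Ties at the
threshold are *not* severe (the definition is a strict inequality).

A subject with a lacune but neither CMB nor severe WMH is assigned nowhere
by the scheme; the classifier labels such subjects control and raises
`lacune_only_flag`. The reference population contained no such subject, and
the flag makes them auditable rather than silently absorbed.

The **simple CSVD burden score** (0–3) awards one point each for any
lacune (regardless of WMH severity), severe WMH, and any CMB. The original
0–4 variant additionally counts dilated perivascular spaces; those are not
assessed here, so only the 0–3 score is implemented. Deep CMB subregions
(basal ganglia, thalamus, etc.) are collapsed into a single deep count:
the scheme needs only lobar versus deep/infratentorial presence.

## Survival analysis

Mortality is summarised as events per 100 person-years by CSVD type and by
burden score (display rounding half-away-from-zero to one decimal), with
Kaplan–Meier curves and the k-group log-rank test (via `lifelines`).
Group contrasts come from Cox proportional-hazards models
(`statsmodels` `PHReg`) with the exposure encoded as indicator contrasts
against the control group (or score 0/1 as appropriate) and Wald 95%
confidence intervals, `exp(beta ± 1.96·se)`. Efron tie handling is the
default — follow-up is continuous, so ties are rare — with Breslow
available for cross-checking against other software; `PHReg` was chosen
over `lifelines`' Cox fitter precisely because it implements both.

Three model tiers are reported: crude (exposure only), age/sex-adjusted,
and fully adjusted (age, sex, hypertension, diabetes, dyslipidemia,
smoking). Adjusting additionally for follow-up time — which some analyses
report — is statistically degenerate because follow-up *is* the outcome
timescale: each death has, by construction, the minimum covariate value in
its own risk set, so the partial likelihood is monotone in that
coefficient and diverges. The option exists behind an explicit flag
(`include_followup_covariate`, default off) and warns when enabled; all
default reports use the conventional model.

**Proportional-hazards check.** The PH assumption is tested with an
exposure × log(time) interaction: each subject's follow-up is episode-split
at the distinct event times, the interaction block is added to the design,
and a joint Wald chi-square on that block gives the p-value. Under
simulated proportional hazards the test rejects at ≈ the nominal 5% rate,
and it detects a hazard ratio growing ∝ t² at n = 1000 in the majority of
replicates (both calibrations are in the test suite).

**Age-matched controls.** Because CSVD groups are older than controls, the
contrasts are re-estimated against an age-matched control subset: greedy
1:1 nearest-neighbour matching on age, without replacement, caliper 2
years, visiting exposed subjects in a seeded random order with seeded
tie-breaks (deterministic given the seed). Exposed subjects with no
control inside the caliper are left unmatched and logged in the match
table. The matching method, ratio and caliper are design choices — no
particular algorithm is canonical here — selected for determinism and
auditability; both are configurable.

**Group comparisons.** Continuous variables: Kruskal–Wallis omnibus test;
when p < 0.05, pairwise Dunn post-hoc z-tests on pooled ranks
(tie-corrected) with Bonferroni adjustment. Dunn/Bonferroni was chosen for
consistency with the rank-based omnibus test; the post-hoc family is
configurable in principle and flagged as a deviation risk since published
tables rarely state it. Categorical variables: chi-square test of
independence, with Fisher's exact test for 2×2 tables whenever any
expected cell count is below 5 (the conventional operationalisation of
"when appropriate"). Within-subgroup mortality associations (e.g. within
type 4) are univariate Cox fits per factor — age dichotomised at the
subgroup median, sex, each risk factor, severe WMH, lacune presence,
CMB ≥ 2, and score categories against score 1 — with zero-event levels
flagged unstable rather than suppressed: sparse subgroups genuinely
produce estimates like HR ≈ 0 with CIs spanning several orders of
magnitude, and the flag is the honest representation.

## The synthetic cohort generator

No public record-level data exist for this population, so the package
ships a generator that emulates the study's statistical structure.
Generation is **group-first**: the phenotype is assigned from the group
prevalence vector (default 335/249/52/61/38 scaled to probabilities), and
markers are then drawn *conditionally on the group* so that
classification round-trips exactly — published tables report conditional
marker frequencies per group, not a joint generative model, so this is
the only faithful direction.

- WMH/TIV ratios: log-normal within the severe/non-severe strata,
  truncated away from the 0.0007 threshold on the correct side
  (inverse-CDF truncation, no boundary atoms). Types 1–2 are always
  severe; type 3 is severe with probability 0.803 and has ≥ 1 lacune with
  probability 0.426; type 4: 0.579 and 0.132; controls are never severe
  and have no markers.
- Lacune and CMB counts: zero-truncated Poisson with means matching the
  group profiles (type 3 total CMB mean ≈ 2.7 with at least one deep or
  infratentorial bleed; type 4 lobar-only mean ≈ 1.2).
- Demographics: per-group Gaussian age (57.9 ± 5.9 control up to
  67.8 ± 9.2 for type 2) and Bernoulli risk factors at the per-group
  prevalences. Age and markers are independent *within* group (their
  within-group correlation is unreported); between-group age confounding
  is present by construction and is what the adjusted models remove.
  Systolic BP, LDL and HbA1c are per-group Gaussian draws for
  descriptive-table exercises only; they do not enter the hazard.
- Survival: death time from a constant baseline hazard
  λ₀ · exp(linear predictor), right-censored at an independent follow-up
  drawn Normal(5.7, 0.7) years, clipped to [0.5, 8]. A Weibull shape
  parameter (default 1 = exponential) supports PH-violation experiments.
  The linear predictor uses log hazard ratios: group effects
  {type 1: ln 1.0, type 2: ln 2.4, type 3: ln 1.6, type 4: ln 5.0} (the
  adjusted contrasts reported for this design), and covariate effects
  chosen once as epidemiologically typical all-cause-mortality gradients
  — age ln(1.09)/year about a reference age of 60, male ln(1.5),
  hypertension ln(1.3), diabetes ln(1.5), smoking ln(1.5), dyslipidemia 0.
  λ₀ = 0.0074/year makes the control group's crude rate land near 0.9 per
  100 person-years under those effects.

What passing tests on this generator do **not** show: the real cohort's
within-group age–marker correlation, any non-exponential baseline, missing
covariate data, or informative censoring. Parameter-recovery results are
internal-consistency checks of the estimation machinery, not external
validation of the published effect estimates, which would require the
original record-level data.

### The deterministic reference fixture

`build_table1_fixture()` constructs a fixed 735-subject cohort, without
random marker draws, that reproduces the published marginal tables when
classified at the fixed 0.07% threshold: group counts 335/249/52/61/38,
score-category counts 335/275/97/28, 62 deaths (8.4%), the type-by-score
cross-tabs (type 3: 10/27/24; type 4: 16/18/4), per-type severe-WMH and
lacune counts, and per-type event counts and person-year totals. Follow-up
times are spread evenly (± up to 2 years) within each type×score cell so
they sum exactly to the cell's person-years while the groups' observation
windows overlap — disjoint windows would make group contrasts inestimable
in a Cox model — and deaths are assigned to the earliest (shortest
follow-up) subjects in each cell. Demographics use deterministic
normal-quantile spreads around the per-group means, permuted with a fixed
seed so they are not aligned with follow-up order.

Two cells of the source tables are internally inconsistent, and the
fixture resolves them explicitly rather than silently:

1. **Type-1 person-years.** The per-type person-year totals sum to 3685
   while the per-score totals sum to 4185 for the same subjects; the
   500-PY gap sits entirely in the type-1 row (914 printed, ≈ 1419 implied
   by 249 subjects × 5.7 y mean follow-up, and ≈ 1414 implied by the
   score-1 total). Both partitions cannot hold at once. The fixture
   reproduces the per-*type* rows exactly (every printed
   events/person-years/rate triple is self-consistent) and the per-score
   rows for scores 0, 2 and 3; its score-1 person-years are 1059, not the
   printed 1559. The discrepancy is reproduced, documented, and not
   resolved.
2. **Type-4 marker marginals.** Severe WMH 22, lacune 5 and score
   categories 16/18/4 are mutually incompatible (marker points sum to 65,
   score points to 64). The fixture keeps the score cross-tab and the
   severe count (each printed twice) and carries 4 lacune subjects instead
   of 5.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to give adequate Monte-Carlo
precision: parameter recovery at n = 20,000 over 20 seeds (type-4 events
number in the hundreds per replicate, putting the per-seed standard error
of the log-HR near 0.08); confidence-interval coverage at n = 1,000 over
200 replicates with an elevated baseline hazard (0.03/year) so that every
contrast has enough events for Wald intervals to be meaningful; PH-check
calibration over 150 replicates of two-group exponential data. The
acceptance script reports the mean recovered type-4 hazard ratio over 20
independent child seeds spawned from the command-line seed.

Other numerical conventions: sample medians use linear interpolation;
rates are rounded half-away-from-zero for display only (all arithmetic is
on unrounded values); Cox convergence failures raise with the backend's
diagnostics, while complete separation (a level with zero events) returns
the fit with inflated CIs plus a warning; the log-rank and Kruskal–Wallis
statistics on fully degenerate inputs (identical groups, all values tied)
return 0 with p = 1 rather than erroring.

## Known limitations

- The classifier consumes precomputed marker summaries (WMH volume, TIV,
  counts); image segmentation and visual CMB rating are upstream,
  published-tool steps outside this package.
- Perivascular spaces, and hence the 0–4 burden score, are out of scope.
- All-cause mortality only; no competing-risks or cause-specific models.
- Complete-case covariate handling; rows with missing adjustment
  covariates abort the fit rather than being imputed.
- Wald confidence intervals throughout (profile-likelihood intervals are
  not implemented; published tables rarely state which was used).
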