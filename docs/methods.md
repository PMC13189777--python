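# Methods

## The PhenoAge model

PhenoAge scores a clinical biomarker panel in three steps. A linear
predictor aggregates the markers,

```
xb = −19.907 + Σⱼ wⱼ·xⱼ ,
```

with the Levine 2018 weights over albumin (g/L, −0.0336), creatinine
(µmol/L, +0.0095), fasting glucose (mmol/L, +0.1953), ln CRP (mg/dL,
+0.0954), lymphocyte % (−0.0120), MCV (fL, +0.0268), RDW (%, +0.3306),
ALP (U/L, +0.00188), WBC (10³ cells/µL, +0.0554) and chronological age
(years, +0.0804). A Gompertz model converts `xb` into the probability of
death within a 120-month horizon,

```
M = 1 − exp(−e^{xb} · (e^{γ·120} − 1)/γ),   γ = 0.0076927 per month,
```

and an affine-log-log inversion places that risk on an age scale,

```
PhenoAge = 141.50225 + ln(−0.00553 · ln(1 − M)) / 0.09165 .
```

These constants are not re-estimated here; they ship as a versioned YAML
coefficient file (`phenodelta/data/levine2018.yaml`) whose SHA-256 is
logged at load, and users may point the scorer at an alternative file.
Units are converted at ingest via an explicit conversion table (albumin
g/dL→g/L, creatinine mg/dL→µmol/L, glucose mg/dL→mmol/L, …) because unit
mistakes are the dominant failure mode for this score.

**The 6-marker reduction.** Panels lacking CRP, RDW, ALP and lymphocyte %
(the Taiwan Biobank case) use a reduced specification that keeps the
intercept and the six remaining weights verbatim and simply drops the four
missing terms. The reduced score therefore lives on a shifted scale; the
sex-specific linear mappings

```
PhenoAge = 45.846752 + 1.068403 · 6markerPhenoAge   (men)
PhenoAge = 46.527973 + 1.023272 · 6markerPhenoAge   (women)
```

absorb that offset. An internal consistency check: a healthy 50-year-old
male panel yields a 6-marker score near 1.2 years, which the mapping
places at ≈ 47 years — the mapping intercepts sit near 46 precisely
because the dropped terms contribute ≈ +3.8 to `xb` (≈ 41 years on the
age scale) for typical values.

**Numerics.** Since
`ln(−ln(1−M)) = xb + ln((e^{120γ}−1)/γ)`, the composed score is *affine*
in `xb`. All internal compositions therefore work in log-survival space
(`ln(1−M) = −e^{xb}·(e^{120γ}−1)/γ`), which never overflows and avoids
the catastrophic cancellation of forming `1 − M` near `M → 1`. The public
`mortality_risk`/`phenoage_from_risk` functions expose the literal risk
scale and agree with the affine path to float precision throughout the
physiological range (risk saturates to 1.0 in double precision only for
`xb ≳ −1.7`, far above any real panel).

The outcome is **ΔPhenoAge** = PhenoAge(follow-up) − PhenoAge(baseline),
a within-individual change over the observation window; it is distinct
from phenotypic age *acceleration* (PhenoAge − chronological age at one
visit). Chronological age is decimal years, (survey date − birth
date)/365.25 when dates are available.

## Stage 1: partial-correlation screen

For each factor, both the factor and ΔPhenoAge are residualized by OLS on
an intercept plus the covariates (sex and ΔAge in the pooled main run);
`r` is the Pearson correlation of the residuals. Inference follows the
standard partial-correlation conventions: `t = r·√((n−2−k)/(1−r²))` on
`n−2−k` degrees of freedom, and a Fisher-z 95% CI with standard error
`1/√(n−3−k)` and critical value 1.96 (the z-vs-t distinction is
negligible at the sample sizes this is designed for and immaterial for
selection, which uses p only). No multiple-testing correction is applied
by default — the screen is deliberately exploratory, selecting at raw
p < 0.05 — but Bonferroni and Benjamini–Hochberg switches exist on the
estimator. Rows with any missing factor/outcome/covariate are dropped
once, globally, with counts logged; constant factor columns are excluded
with a warning. Ordinal 1–5 and 1–3 questionnaire items are treated as
numeric scores. Biomarker-level analyses (a factor against one PhenoAge
component, adjusting for age) reuse the same operation with different
column declarations — there is no separate code path.

## Stage 2: exact best-subset AIC selection

Candidates are the stage-1 selections; ΔAge is forced into every model;
fits are sex-stratified OLS (so sex is not a covariate here). The search
minimizes the full Gaussian AIC

```
AIC = n·ln(RSS/n) + n·(ln 2π + 1) + 2·(k + 2),
```

where `k` counts non-intercept predictors and the +2 counts the intercept
and error variance — the convention of R's `AIC()` on `lm` objects, so
values are directly comparable to standard software (statsmodels omits
the variance parameter; its AIC is exactly 2 lower). Exactness over all
`2^p` subsets (p ≤ 30 enforced) is the contract: the default
branch-and-bound prunes a branch with included set *I* and undecided set
*U* when `AIC(RSS(I∪U), |I|)` — a valid lower bound, since RSS is
monotone non-increasing in the predictor set and the penalty is monotone
in size — cannot beat the incumbent; an exhaustive path exists and the
two are property-tested to agree. Candidates are explored in decreasing
marginal-RSS-reduction order, which makes the bound bite early (typical
runs evaluate tens of subsets out of thousands). Subset RSS values come
from Cholesky solves on precomputed Gram matrices. Ties (within 1e−9 of
AIC) break toward fewer predictors, then lexicographic label order —
parsimony first, then determinism.

Diagnostics: coefficient standard errors use the unbiased variance
`RSS/(n−k−1)`; VIFs are `1/(1−R²ⱼ)` from regressing each selected
predictor on the others plus intercept, with perfect collinearity flagged
as `inf` rather than raised. Reported p-values are the selected model's
naive t-tests; selection-adjusted inference is intentionally not
attempted, matching common practice for this design.

## The synthetic cohort generator

The generator exists so every stage can be exercised and calibrated
without access-controlled data. Its defaults encode the study conditions
of the Taiwan Biobank follow-up sample it emulates: n = 69,462 with
36.5% men; per-sex follow-up gaps from truncated normals (men mean 4.91,
SD 1.51; women 4.88/1.53; bounds 1.6–15.9 years) whose location is solved
so the *truncated* mean equals the target; baseline ages ≈ N(50, 11)
truncated to [21, 90]; the 43-factor roster with published marginals —
five obesity-index changes (published means; change SDs are not published
and are fixed at realistic tracking values, e.g. 1.2 kg/m² for ΔBMI),
seventeen 1–5 diet items and a 1–7 education score as rounded-and-clipped
normals matched to published means/SDs, three 3-level ordinal items and
twelve binary exposures at published per-sex prevalences, and a 4-level
exercise-pattern categorical expanded into mutually exclusive indicators.

The outcome is assembled forward: ΔPhenoAge = per-sex intercept +
Σ βⱼ·xⱼ + N(0, σ²) with the published sex-specific regression
coefficients planted by default, σ = 3.3 years (chosen so the planted
male model's adjusted R² lands near the published ≈ 25%), and the
intercept derived from the configured marginal means so mean ΔPhenoAge
matches the published 4.75 (men)/4.61 (women).

**Biomarker back-fill.** Baseline panels are drawn from physiological
truncated normals; follow-up MCV/WBC/albumin/creatinine drift slightly;
follow-up glucose is then *solved* so that scoring both panels reproduces
the planted ΔPhenoAge exactly. Because the composed score is affine in
`xb` and glucose carries a positive weight, the inversion is a
one-dimensional linear solve — the round-trip error is machine precision,
well inside the 0.01-year contract. If the solved glucose would fall
below 0.3 mmol/L, baseline glucose is raised by the deficit, which (by
the same affinity) raises the solved follow-up value by exactly the same
amount and leaves ΔPhenoAge untouched.

**What the generator does not emulate.** Factors are drawn independently
(an optional Gaussian-copula block can correlate chosen continuous
factors; its parameters are user-supplied, never asserted as population
truth). Real questionnaire items are correlated, real biomarker dynamics
are not a one-marker perturbation, and the real ΔPhenoAge distribution is
not Gaussian (its published negative-change fractions, 7.8%/6.7%, are
smaller than a normal model with the published mean/SD would give).
Passing tests therefore demonstrate the *machinery* — calibration,
exactness, recovery — under a faithful marginal structure, not
distributional realism of any real cohort.

## Validation design and problem sizes

- *Search exactness*: branch-and-bound equals exhaustive enumeration (hard
  set equality) on 50 random instances with ≤ 12 candidates.
- *Screen calibration*: type-I error of the p < 0.05 screen over 2,000
  null replicates at n = 1,000 sits inside the binomial 95% band around
  0.05; Fisher-z CI coverage is checked near 95% on correlated data.
- *Recovery*: 100 replicates of a single-sex n = 25,000 cohort (the male
  stratum size) with the published male pattern planted. A planted factor
  is *detectable* when its implied partial correlation — computed
  analytically from the configured variances — exceeds 0.02 in magnitude;
  nine of the thirteen planted effects clear that bar (the four weakest,
  e.g. diet17 at ρ ≈ 0.012, correspond to published |t| ≈ 2.1–2.6 and sit
  below any reasonable power threshold at this n). Each detectable factor
  must survive both stages in ≥ 90% of replicates, and refitting the
  generating predictor set must land each coefficient within 3 estimated
  SEs of its planted value in ≥ 95%. Requiring *all* detectable factors
  jointly in one replicate has an expected success rate of ≈ 0.85 from
  the per-factor powers alone (0.95–1.00 each), so the contract is
  per-factor — a joint bar of 0.90 would be unattainable by construction,
  not by defect.
- Note on AIC and noise predictors: AIC admits an irrelevant predictor
  whenever its squared t-statistic exceeds 2, i.e. with probability
  ≈ P(χ²₁ > 2) ≈ 0.157. Best-subset selections therefore *expect* an
  occasional noise predictor (≈ 1.4 per model when nine noise candidates
  are offered); the tests assert this honest behavior rather than perfect
  support identification, which no AIC-based selector can deliver.

## Degenerate inputs and edge policies

Missing required markers raise an error naming the marker; non-positive
CRP with CRP covered is a domain error; risks outside (0,1) are domain
errors while the nearest-representable boundary values evaluate finitely.
Rank-deficient covariate or design matrices raise errors naming the first
offending column. A zero-RSS fit yields AIC = −∞ with a warning (a
perfect fit legitimately dominates selection). `best_subset` refuses more
than 30 candidates with guidance rather than attempting an infeasible
search.
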