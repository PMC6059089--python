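# Methods

`ectogas` reimplements a veterinary clinical-pathology analysis chain for
venous blood gas panels measured in free-living ectotherms with a handheld
point-of-care analyzer: temperature correction of the 37 °C instrument
panel, seasonal reference-interval construction, and information-theoretic
ranking of physiologic/environmental predictor models.  A seeded synthetic
cohort generator reproduces the statistical structure such a field study
assumes, so every stage can be validated against known truth.

## Temperature correction

Handheld analyzers warm blood to 37 °C before measuring.  In a closed
sample this shifts pH, pO2 and pCO2 away from their values at the animal's
own (environmental) temperature, so panels are corrected back to the mean
daily air temperature T_A at the capture site:

    pH(T_A)   = pH_I − 0.0147·(T_A−37) + 0.0065·(7.4−pH_I)·(T_A−37)
    pO2(T_A)  = pO2_I · 10^(−0.0058·(T_A−37))
    pCO2(T_A) = pCO2_I · 10^(0.0019·(T_A−37))

Bicarbonate and total CO2 are not corrected but *recalculated* from the
corrected pH and pCO2 through Henderson–Hasselbalch with a
temperature-dependent CO2 solubility and apparent dissociation constant
(cubic polynomials in T_A derived for sea turtles):

    HCO3⁻(T_A) = αCO2 · pCO2(T_A) · 10^(pH(T_A) − pKa)
    TCO2(T_A)  = HCO3⁻(T_A) + αCO2 · pCO2(T_A)

Numerical notes:

* **pKa log-term grouping.**  The pKa expression ends in a log of a
  quotient whose published typesetting is ambiguous.  We adopt

      pKa = poly(T_A) − log10[(1.011 + 10^(pH+0.011·T_A−10.241)) /
                              (1 + 10^(pH+0.001·T_A−8.889))]

  — the only grouping of the published constants that forms a
  dimensionless quotient and yields physiologic pKa values (5.8–6.5 over
  pH 6.8–8.0, T_A 5–40 °C).  The quotient lives in one function
  (`pka_log_quotient`) so an alternative reading can be swapped in.  All
  logs and exponentials in the block are base 10.
* **pO2 exponent sign.**  As published, corrected pO2 *rises* as
  temperature falls.  Implemented exactly as printed; no sign "fix".
* **Base excess** cannot be recalculated without hemoglobin and passes
  through as raw instrument output, as does lactate.
* Exact identities hold by construction and are asserted in tests:
  TCO2 − HCO3⁻ = αCO2·pCO2 exactly, and
  log10(HCO3⁻/(αCO2·pCO2)) = pH − pKa to machine precision.
* Missing instrument fields propagate: an output is absent iff an input
  it depends on is absent.  Physiologic-window violations warn rather than
  error (field data contain extremes); only non-finite temperature is a
  hard error.

## Eligibility screening

Two screens gate the statistics, mirroring the two distinct exclusion
events such a study performs:

1. **Health screen** — animals whose exam codes indicate an active disease
   process (defaults: open-mouth breathing; the ocular-swelling/nasal-
   discharge/diarrhea combination; necrotic shell fracture) are excluded
   from reference intervals only.  Healed shell lesions and asymmetrical
   nares do not exclude.  The code list is configuration.
2. **Cross-analyte outlier screen** — Horn's screen is run per analyte
   within each season; an animal flagged on ≥ 2 analytes (configurable) is
   interpreted as genuinely pathologic and excluded from both modelling
   and reference intervals.  Animals flagged on a single analyte are
   retained; the flagged value is handled per-analyte downstream.

Every exclusion carries machine-readable reasons and is logged, so the
per-partition n of each report row can be audited from the run manifest.

## Reference intervals

Per analyte × season, on reference-eligible animals with non-missing
values:

1. **Horn's outlier screen**: Box–Cox transform (λ by maximum likelihood
   over a grid [−3, 3], step 0.05; data with values ≤ 0 are shifted by
   1 − min first), then Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR on the
   transformed scale.  One pass, no iteration.  Constant vectors and
   n < 3 retain everything.
2. **Descriptives and normality**: mean, SD, median, range; the
   distribution label is gated by Shapiro–Wilk at α = 0.05, with the
   Kolmogorov–Smirnov statistic (against a fitted normal) reported but
   not gating; n < 8 gets no label.
3. **Nonparametric 95% interval** via the rank-index estimator p·(n+1)
   with linear interpolation, clamped to the observed range — chosen
   because at n ≈ 40 the interval can legitimately coincide with the
   sample min/max.
4. **90% percentile-bootstrap CIs** on each bound (5000 with-replacement
   resamples by default; each analyte × season cell has its own RNG
   stream derived from the seed, so perturbing one cell never changes
   another row).
5. **WCI/WRI** per bound — CI width over interval width; a ratio above
   0.2 flags the partition as needing a larger sample.

Partitions under the minimum n (default 20, configurable) report
descriptive statistics only.  The bootstrap resamples the post-outlier
data.  Report rounding follows per-analyte conventions (pH 2 dp,
pressures/integer analytes 0–1 dp).

Measured properties (validated in the suite; reproduced by
`scripts/acceptance.py`): the quantile estimator is within 0.002 of the
true 2.5/97.5 percentiles for a uniform sample at n = 10 000; the 90%
bootstrap CI for the lower bound covers the true normal 2.5% quantile in
≈ 92% of Monte-Carlo replicates at n = 120 (slight over-coverage is
characteristic of percentile bootstraps of interpolated extreme
quantiles); Horn's screen flags an 8-SD contaminant of a unit Gaussian in
100% of replicates while flagging ≈ 1–2% of clean Gaussian points
(pooled).  On a *single* unlucky small sample the Tukey fences can flag
several points at once (up to ~15% of an n = 40 sample when the sample
IQR is small by chance) — specificity statements here are pooled rates,
not per-sample worst cases.

## Predictor models and AICc ranking

Each corrected analyte is regressed by OLS on candidates from
{activity, season, PCV}; the fixed default set is

    Null | Activity | Season | PCV + Season | Activity + PCV + Season

Season replaces air temperature in candidates because T_A is strongly
correlated with season and sits downstream of it in the causal diagram.
Continuous predictor pairs with Pearson |r| > 0.5 are barred from
co-occurring.  All candidates for one analyte share a complete-case
dataset (rows missing the response or *any* candidate predictor are
dropped first).  Ranking uses

    AICc = −2·lnL + 2k + 2k(k+1)/(n−k−1),   w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)

with the Gaussian log-likelihood −n/2·(ln 2π + ln(RSS/n) + 1) and k
counting intercept, slopes, factor dummies and the residual variance
(Null → k = 2, full additive model with a 3-level season → k = 6).  Ties
in AICc break toward smaller k.  Dummy coding uses spring and bright as
reference levels, matching the direction in which quiet/summer offsets
are usually reported.

Effect estimates come from multivariable fits with adjustment sets from
the causal diagram (configurable, since a published diagram's full arrow
set is rarely machine-readable): season and activity are treated as
exogenous (unadjusted), T_A adjusts for season, PCV adjusts for season
and T_A.  Season contrasts are pairwise differences of model-adjusted
season means — under the additive dummy-coded fit these are linear
combinations of the season coefficients, with t-based SEs from the
coefficient covariance.  No multiplicity adjustment by default.

## Synthetic cohort generator

The generator defines the validation conditions; its defaults emulate a
~100-animal, three-season field study:

| component | default | basis |
|---|---|---|
| n per season | 40 / 42 / 20 (spring/summer/fall) | study design; reproduces the fall minimum-n gating |
| T_A means (°C) | 19.18 / 24.65 / 16.83, SD 2.5 within season | summer−spring +5.47 °C, summer−fall +7.82 °C contrasts; overall mean ≈ 21 °C |
| quiet fraction | 0.673 | observed activity mix |
| PCV (%) | 21.7 + 7.0·summer + 2.3·fall + 0.2·(T_A anomaly) + N(0, 7.3²), clipped to (1, 60] | summer−spring +7%, overall mean 25%, r(PCV, T_A) ≈ 0.3 |
| pH | 7.62 − 0.13·summer + 0.09·fall − 0.19·quiet − 0.01·(PCV−25) + N(0, 0.14²) | quiet effect −0.19; summer lowest |
| pO2 (mmHg) | 63.3 − 9.3·quiet − 0.8·(PCV−25) + N(0, 18²), floor 1 | quiet effect −9.3; no season effect |
| pCO2 (mmHg) | 22.7 + 10·summer − 7.5·fall + 15·quiet + 0.8·(PCV−25) + N(0, 10²), floor 1 | quiet +15, summer−spring +10, summer−fall +17.5 |
| lactate (mmol/l) | 4.97 + 2.36·summer − 0.36·fall + 0.08·(PCV−25) + N(0, 2.2²), floor 0.1 | summer−spring +2.36, summer−fall +2.72 |
| BE (mmol/l) | 1.9 − 3.07·summer + 1.64·fall − 0.3·(PCV−25) + N(0, 4.5²) | summer−spring −3.07, summer−fall −4.71 |
| missingness | PCV 2%, activity 4%, BE 2%, lactate 1% per field, independent | instrument-error pattern |
| outliers | 3% of animals, 2 analytes displaced by 8 residual SDs | the multi-analyte pathologic animals the screen must catch |

Key design choices:

* **True values are generated on the corrected scale** and mapped to
  instrument (37 °C) scale by exact algebraic inversion of the correction
  formulas, so the correction stage is exercised nontrivially and
  validated by a round-trip identity (< 1e−10).  Instrument HCO3/TCO2 are
  regenerated at 37 °C from instrument pH/pCO2 via the same
  Henderson–Hasselbalch machinery, making them formula-consistent rather
  than imitating any device's undisclosed internal algorithm.
* **HCO3⁻ and TCO2 are derived, not drawn.**  The corrected-panel
  identities make them deterministic functions of (pH, pCO2, T_A) — as on
  a real analyzer — so their seasonal structure is emergent.  Configured
  linear models exist only for the five freely drawn analytes.
* **BE is drawn from its own linear model** with the published season
  offsets rather than as an HCO3-linked surrogate; the metabolic-axis
  correlation with HCO3⁻ therefore arises only through shared
  season/PCV structure, not through shared residuals.  This trades one
  kind of realism for exact control of the generating BE effect sizes.
* **Residual SDs are not published** and are backed out of per-season
  marginal SDs net of the explained components; the lactate residual SD
  (2.2) is additionally kept small enough that the additive-Gaussian
  surrogate respects the strictly positive range real lactate data show.
  Effects are additive with Gaussian residuals because the analysis fits
  Gaussian GLMs — model-consistency over realism.
* **Outlier displacement is directed away from physical floors**: a
  downward 8-SD shift that would clip at a floor (lactate 0.1 mmol/l,
  pressures 1 mmHg) is sent upward instead, since a floor-clipped value
  is not the gross pathologic extreme the injection represents.
* Activity is drawn independently of season and PCV; the borderline
  PCV–activity association real data show is *not* emulated.  There is
  no site/spatial structure, no repeated measures, and no disease-state
  simulation beyond outlier injection — passing tests therefore say
  nothing about those features of real data.

Measured end-to-end behavior at the defaults: the generating lactate
model (PCV + Season) or the full additive model ranks first in ~100% of
replicates at n = 400/season; generating quiet-activity effects fall in
their fitted 95% CIs at ~95% of replicates; injected outlier animals are
excluded by the cross-analyte screen in ~92–94% of cases (Horn's Box–Cox
step occasionally accommodates one of the two displaced analytes as skew
in partitions of 20–42 animals).

## Pipeline and determinism

`run_pipeline` composes the stages in fixed order (correct → screen →
reference intervals → models → effects) as a pure function of (input,
config, seed): report CSVs are byte-identical across reruns; the JSON
manifest additionally records a wall-clock timestamp and reconciling
per-stage counts.  Data CSVs (cohort, truth, corrected) are written at
17 significant digits so values round-trip exactly; report tables use
per-analyte rounding.

## Problem sizes

The default study replica uses 102 animals.  Validation sizes: 10 000
random panels for the correction identities; n = 10 000 for quantile
consistency; 500 Monte-Carlo replicates × 2000 resamples for bootstrap
coverage; 200 replicates for Horn sensitivity/specificity; 100 replicates
at 400/season for model and effect recovery; 1000 random small designs
for the OLS/AICc oracles.  These sizes make the full validation run in
about two minutes on one CPU.

## Known limitations

* The correction coefficients are taken from sea-turtle and human-derived
  sources as published; no species-specific re-estimation is attempted,
  and the pKa quotient grouping is a documented interpretation of an
  ambiguously typeset formula.
* The KS normality test is reported without a Lilliefors correction and
  never gates the distribution label.
* Bootstrap resampling is unstratified.
* Reference intervals are nonparametric only (no robust or parametric
  variants) and partitioned by season only.
* The generator's marginal means approximate, rather than exactly match,
  a real cohort's printed descriptives, because intercepts are anchored
  at the reference stratum and PCV is centered at 25%.
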