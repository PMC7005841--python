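# Methods

## Scope and data model

The package models one year of a blocked grassland diversity × management
experiment. The observational unit is the *sward*: one main plot (with a
sown community of D species drawn from a 60-species pool split into
grasses/small herbs/tall herbs/legumes = 16/12/20/12) under one of five
management regimes, defined by cuts per year h and N fertilization
(kg N ha⁻¹ a⁻¹): extensive (1, 0), less intensive (2, 0), intensive
(2, 100), highly intensive (4, 100), very highly intensive (4, 200). With
82 plots (richness replicates 16/16/16/16/14/4 for D = 1/2/4/8/16/60) in 4
blocks this yields 410 swards. (Field descriptions of this layout sometimes
count 390 subplots; the cross product of 82 plots × 5 regimes is 410 and
that is what the generator produces.)

Per cut, a sward carries biomass (g DM m⁻²) and raw chemistry: 24 h
fermentation gas (mL day⁻¹), crude protein, ether extract, NDF and ash
(g kg⁻¹ DM), plus first-cut incubation inputs (mg NH₃-N of blank and
sample, mg sample N, mg DM) for utilizable crude protein.

## Nutritive-value equations

ME and NEL (MJ kg⁻¹ DM) are second-order polynomials in gas production with
linear CP and EE terms (coefficients in `gqay.chemistry`); CP = 6.25 × N;
OM = 1000 − ash; uCP = (NH₃-N_blank + N_sample − NH₃-N_sample)/DM ×
6.25 × 1000. Milk production potential divides NEL by the energy
requirement per kg milk. That constant is not part of the gas-test
equation set; the default of **3.2 MJ NEL kg⁻¹ milk** is a standard feed
evaluation value and reproduces the observed correspondence between ME
yields of ~9.6 MJ m⁻² and milk-potential yields of ~1.8 kg m⁻²; treat it as
a calibration parameter (`nel_per_kg_milk`), not ground truth.

A note on ME vs NEL: the NEL equation has the slightly larger gas² term, so
ME > NEL is not a termwise-dominance identity; it holds for gas production
below ≈886 mL day⁻¹, three orders above what a 200 mg sample produces, and
the property test asserts it on a realistic domain (gas ≤ 200).

Negative uCP values (possible when measured ammonia exceeds blank + sample
N) are physically impossible, so they are returned unclipped but flagged
with a warning and caught by table validation rather than silently fixed.

## Annual aggregation

Chemistry is analysed for the first and last cut of the year; interior cuts
of four-cut regimes get linearly interpolated quality, indexed by cut
number (harvest dates are not in the data model; the monotone within-year
trends make linear-in-index a reasonable stand-in). uCP is measured at the
first cut only: its annual value is the first-cut content and its yield
uses first-cut biomass, flagged as such in the annual table.

Swards with a missing cut or any cut below `min_biomass` are dropped before
aggregation. "Very small" is not a quantified field criterion; the default
threshold is 1 g DM m⁻², configurable, and the dropped-sward report (ids,
reasons, per-richness histogram) makes the choice auditable.

Annual biomass yield is the sum over cuts; annual quality is the
biomass-weighted mean; quality-adjusted yield is Σ biomassₖ·qualityₖ/1000,
the factor 10⁻³ converting g DM to kg DM so ME yield lands in MJ m⁻² a⁻¹.
By construction qa = biomass_yield × quality / 1000 exactly.

## The diversity mixed model

For an annual response y (biomass yield, quality, quality-adjusted yield,
or revenue):

    y = α_M + β_{D×M} f(D) + β_{L×M} L + β_FG FG + β_G G + β_H H
        + u_B + u_P + e

* f(D): diversity transform, default √D; candidates √D, D, D + D², log D,
  1/D are compared by AIC/BIC on ML fits of the identical observation set.
* Cell-means coding: one intercept α_M and one slope β_{D×M} per regime, so
  slopes read directly as per-management diversity effects; fitted values
  are invariant to this coding choice.
* L is legume presence (0/1); the robustness variant replaces it with
  √(legume share). Covariate terms that are constant in a given data set
  (e.g. no legumes anywhere) are dropped automatically and recorded.
* u_B, u_P: random intercepts for block and for plot nested in block
  (nesting matches the field layout); estimation by REML through
  statsmodels MixedLM (ML for information criteria), optimizer sequence
  lbfgs → powell.
* Residuals are allowed to be heteroscedastic across regimes (annual sums
  of h per-cut residuals have variance ∝ h). Reported inference therefore
  uses a plot-clustered sandwich covariance: bread X'V⁻¹X with V the
  estimated marginal covariance, meat from per-plot score contributions,
  finite-sample factor G/(G−1)·(n−1)/(n−k) and t/F references with G−1
  degrees of freedom (G = 82 plot clusters) — the standard convention of
  cluster-robust regression software. Model-based SEs are also reported.
* Multiple testing: per-management slope tests are Bonferroni-corrected
  within the response family (n = 6 for the six quality variables, n = 1
  for biomass yield); significance is starred at family levels 5%/1%/0.1%.
  Equality of slopes between regimes uses pairwise robust Wald tests (all
  10 pairs).
* Predictions fix random effects at zero and hold FG/L/G/H at their sample
  means; because the model is linear in these covariates this equals
  averaging predictions over the observed covariate distribution.
* Degenerate input: exactly noise-free data make the mixed likelihood
  unbounded, so `fit()` detects a perfect OLS fit (mean squared residual
  ≤ 10⁻¹² × response variance) and returns the OLS solution with zero
  variance components instead of invoking the optimizer.

## Synthetic-data generator

The generator is the package's study-condition definition, not a tuning
knob. Annual biomass expectation follows the mixed-model structure above
with defaults (g DM m⁻² a⁻¹): intercepts 250/300/350/380/420 and √D slopes
60/80/110/100/110 from extensive to very highly intensive, legume effects
40–70, FG +10, grass +30, tall herbs +10; σ_B = 30, σ_P = 50, and per-cut
residual σ_e = 60 (per-cut biomass = annual mean/h + residual, so annual
residual variance grows with cutting frequency — the heteroscedasticity the
robust covariance addresses). These magnitudes give monoculture yields of
~400 g m⁻² rising to ~1200 g m⁻² at 60 species, in line with temperate
hay-meadow experiments.

Chemistry is simulated on the measured scale so the estimation equations
are exercised end to end: first-cut baselines gas 45 mL day⁻¹, CP 160,
EE 25, NDF 450, ash 90 g kg⁻¹, with per-cut trends −3/−10/0/+20/+5
(sign-constrained: energy/protein may only fall across cuts, fiber/ash only
rise) and sward-level noise SDs 2/10/3/25/8. Because noise enters as a
sward-level offset and the trend is deterministic, within-year quality
trends are strictly monotone for every simulated sward. Incubation inputs
are back-computed from a target uCP level (140 ± 10 g kg⁻¹) at 200 mg DM.
Diversity is given no direct effect on chemistry by default — quality is
approximately constant in D, so diversity moves quality-adjusted yield
through biomass, the regime the model-recovery tests probe.

What the generator does *not* emulate: species identities and
complementarity/selection mechanisms (only functional-group composition
matters downstream), calendar dates, weather, weeding dynamics, species
loss over years, spatial autocorrelation, and soil gradients. Passing tests
therefore demonstrate correctness of the estimation machinery under the
assumed data-generating process, not ecological validity of any particular
field result.

## Economics

Revenue values the milk-potential yield at 0.31 Euro kg⁻¹ after converting
kg m⁻² to kg ha⁻¹ (×10⁴). Variable costs are itemized from task rates
(hours × 13 Euro h⁻¹ + litres × 0.75 Euro l⁻¹) and fertilizer prices; the
PK compound is purchased to satisfy the binding nutrient (max of the P and
K requirements). Ledgers are computed at full precision; whole-Euro figures
round half-up. Management-switch totals follow the cost-table convention of
summing per-item rounded values (one fertilizer step 165, application 9,
one cut 77), so less→intensive reports −174 and less→very highly intensive
−(2·165 + 9 + 2·77) = −493 Euro ha⁻¹ a⁻¹, while the full-precision totals
(−173.70, −493.63) remain available. The fertilizer-application task is
charged only on a 0 → nonzero fertilization transition. Seed-mixture prices
(1203/229/104 Euro ha⁻¹ for diverse/price-adjusted standard/standard
mixtures) are survey means taken as configuration inputs.

The management↔diversity equivalence inverts the revenue model: given the
fixed-effects revenue gap between two regimes at D₀ and the base regime's
√D slope, D* solves β(√D* − √D₀) = gap, clipped to [1, 60] with an
extrapolation flag; a non-positive slope is reported as "no solution"
rather than extrapolated. The Welch two-sample test (unequal variances,
Welch–Satterthwaite df) is provided for comparing predicted revenue samples
between regimes; with two zero-variance samples it returns t = 0, p = 1
when means agree and p = 0 otherwise.

## Monte-Carlo problem sizes and numerical choices

Calibration checks in the test suite use the full 82-plot/410-sward design:
500 replicates for slope recovery (mean estimate within 2 Monte-Carlo SEs
of truth per regime), 200 strong-signal replicates (default generator with
σ_e = 20, σ_B = σ_P = 10) for the transform race, and 200 null replicates ×
10 pairs = 2,000 pairwise Wald tests for type-I error. Identity and
equation checks are exact to printed precision or machine tolerance.

All randomness flows from a single master seed through named SeedSequence
substreams (block effects, plot effects, residuals, chemistry), so equal
seeds give byte-identical output tables. Simulated cut biomass is truncated
at zero with a logged warning; truncation is negligible at the default
noise levels (a few cuts per 1,000).

## Known limitations

* Reproducing the field study's coefficient values requires the deposited
  field data; the package validates methodology (identities, recovery,
  calibration), not field numbers.
* The NEL→milk constant and the biomass filter threshold are calibration
  choices, documented above.
* Single-year analysis only; no spatial covariance beyond block/plot
  intercepts; no profit optimization or risk analysis.
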