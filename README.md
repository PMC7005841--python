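# gqay — quality-adjusted yield and bioeconomics of managed grasslands

`gqay` is a Python package for analysing grassland biodiversity experiments
from the per-cut harvest up to farm economics. It targets the question of
whether sown plant diversity pays off agronomically and economically across
management intensities (cutting frequency × N fertilization), by chaining:

1. **Synthetic experiment** (`gqay.experiment`) — a replacement-series
   design of 82 plots in 4 blocks, sown richness D ∈ {1, 2, 4, 8, 16, 60}
   with replicates {16, 16, 16, 16, 14, 4}, crossed with five management
   regimes from extensive (1 cut, 0 N) to very highly intensive (4 cuts,
   200 kg N ha⁻¹ a⁻¹), giving 410 swards; plus a generator for per-cut
   biomass and raw forage chemistry with block/plot random effects and
   monotone within-year quality trends.
2. **Forage chemistry** (`gqay.chemistry`) — gas-test estimation equations
   for metabolizable energy, ME = 3.16 + 0.0695·g + 0.000730·g² +
   0.00732·CP + 0.02052·EE, and net energy for lactation, NEL = 1.64 +
   0.0269·g + 0.00078·g² + 0.0051·CP + 0.01325·EE (MJ kg⁻¹ DM, g in
   mL day⁻¹), CP = 6.25 × N, utilizable crude protein from the incubation
   ammonia balance, organic matter = 1000 − ash, and milk production
   potential = NEL / 3.2 MJ kg⁻¹ milk.
3. **Annual aggregation** (`gqay.aggregate`) — sward filtering, linear
   interpolation of interior-cut quality, and the annual quantities
   biomass yield = Σ biomassₖ, quality = Σ qualityₖ · biomassₖ / Σ biomassₖ,
   quality-adjusted yield = Σ biomassₖ · qualityₖ / 1000.
4. **Diversity effects** (`gqay.diversity`) — a statsmodels-style
   `DiversityModel` / `DiversityResults` pair fitting the linear mixed model

   y = α_M + β_{D×M} √D + β_{L×M} L + β_FG FG + β_G G + β_H H + u_B + u_P + e

   with REML, per-management diversity slopes, plot-clustered robust
   standard errors, Bonferroni-corrected per-management inference, pairwise
   Wald tests of slope equality, AIC/BIC races across diversity transforms
   (√D, D, D + D², log D, 1/D) and fixed-effects prediction grids.
5. **Bioeconomics** (`gqay.economics`) — milk revenues (0.31 Euro kg⁻¹,
   per-ha conversion), itemized variable-cost ledgers of fertilization,
   cutting, reseeding and fresh hay transfer, management-switch costs, and
   the diversity change equivalent in revenue to a management switch.

`gqay.pipeline.run_all` ties the stages into one seeded, provenance-stamped
run; the `gqay` CLI exposes each stage (`gqay run --seed 1 --out runs/exp1`).

## Worked example

```python
from gqay.experiment import SimulationParams, build_design, build_swards, simulate_cuts
from gqay.chemistry import add_quality_columns
from gqay.aggregate import filter_swards, aggregate_annual
from gqay.diversity import DiversityModel
from gqay.economics import management_switch_cost_euro, equivalent_diversity_change

plots = build_design(seed=1)
cuts = simulate_cuts(build_swards(plots), SimulationParams(seed=1))
kept, dropped = filter_swards(add_quality_columns(cuts))
annual = aggregate_annual(kept)

res = DiversityModel(annual, "qa_me").fit()       # metabolizable-energy yield
print(res.effect_table(n_tests=6))
print(res.predict_grid([1, 16, 60], average_managements=True))
```

prints (seed 1):

```
           management  slope  se_robust  p_raw significance
            extensive  0.560      0.089  0.000          ***
       less_intensive  0.746      0.080  0.000          ***
            intensive  0.966      0.076  0.000          ***
     highly_intensive  0.885      0.083  0.000          ***
very_highly_intensive  0.964      0.072  0.000          ***
 richness  predicted management
     1.00       4.65    average
    16.00       7.12    average
    60.00      10.21    average
```

Each slope is the gain in annual metabolizable-energy yield (MJ m⁻² a⁻¹)
per unit √(species number) under one management regime; all five are
positive and significant after Bonferroni correction for the six-variable
quality family. The prediction grid shows the management-averaged ME yield
rising from 4.65 MJ m⁻² a⁻¹ in monocultures to 10.21 MJ m⁻² a⁻¹ at 60
species under this simulation's parameters.

Valuing the milk potential yield and comparing management with diversity:

```python
annual["revenue"] = annual["qa_milk_potential"] * 1e4 * 0.31   # Euro/ha/a
rev = DiversityModel(annual, "revenue").fit()
eq = equivalent_diversity_change(rev, "less_intensive", "intensive", 1.0)
print(eq.revenue_gap, eq.d_star)                       # 575 Euro/ha/a, 5.6
print(management_switch_cost_euro("less_intensive", "intensive"))  # -174
```

i.e. in this simulated experiment, intensifying from a two-cut unfertilized
to a two-cut fertilized regime is worth about +575 Euro ha⁻¹ a⁻¹ — the same
revenue effect as raising diversity from 1 to ~6 species — while the switch
itself costs 174 Euro ha⁻¹ a⁻¹ in fertilizer and application.

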