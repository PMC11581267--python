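# exante

Multi-criteria *ex-ante* impact assessment of agricultural technologies.

Research programs that develop improved crop varieties and management
practices for dryland farming systems must decide, before any money is
spent, which candidate technologies to prioritize. `exante` evaluates each
candidate on three outcome criteria and combines them into a single ranking:

1. **Benefit-cost ratio (BCR)** — the discounted economic surplus generated
   by adoption of the technology divided by discounted research and
   dissemination costs,

   BCR = Σₜ ΔESₜ/(1+r)ᵗ ÷ Σₜ Cₜ/(1+r)ᵗ,  t = 1…25, r = 10 %,

   where the yearly surplus follows a closed-economy, linear, parallel-shift
   market model: ΔES = K·P₀·Q₀·(1 + ½·K·Z), Z = ε/(ε+η), with the per-unit
   supply shift K combining the yield gain and per-hectare cost change,
   scaled by the probability of research success and the adoption fraction.
2. **Poverty reduction** — the surplus of the year of maximum adoption is
   converted to a proportional agricultural-productivity gain and passed
   through the country's poverty elasticity:
   ΔP = (ΔES_T / AgGDP) · (ΔP/P)/(ΔY/Y) · P.
3. **Child-malnutrition change** — the percent of malnourished children
   under five follows a recursion in per-capita kilocalorie availability
   (elasticity −25.24 on the log-ratio), the female/male life-expectancy
   ratio (−71.755094), female secondary enrollment (−0.219831) and safe-water
   access; a technology enters through the kcal channel only.

Criteria weights are region-specific: the region's share of agriculture in
GDP, poverty headcount and child-stunting rate are divided by the same
indicators for its reference region (sub-Saharan Africa or South Asia) and
normalized to sum to one. **TOPSIS** then ranks the technologies by relative
closeness C⁺ = S⁻/(S⁻+S⁺) to the best-on-every-criterion point.

The intended users are agricultural economists and research-program planners
doing priority setting; all inputs are plain CSV tables and the package
ships a seeded synthetic-study generator so the full pipeline runs without
any external data.

## Worked example

```bash
exante generate study --seed 0     # writes technologies.csv, macro.csv,
                                   # nutrition.csv, indicators.csv, config.yaml
exante rank study/config.yaml --out study/out
```

which prints (abridged):

```
Ex-ante multi-criteria technology assessment
============================================================
Environment:    semi-arid-west-central-africa
Technologies:   12
Horizon:        25 years  (discount rate 10%)
Weights:        BCR 0.39 | poverty 0.28 | nutrition 0.33

                      crop      bcr  poverty_reduction  malnutrition_change  ...  closeness  rank
T007-sorghum       sorghum  20.1392        147785.0126          -22171.3643  ...     0.8477     1
T000-cowpea-dt-icm  cowpea  15.2020        180792.7386          -28460.0136  ...     0.8044     2
T002-chickpea     chickpea  16.0154        130474.1116          -24894.6121  ...     0.7618     3
...
```

Reading the first row: every research dollar spent on the sorghum technology
returns about US$20 of discounted economic surplus; at full adoption it
lifts ≈148,000 people out of poverty and reduces the number of malnourished
children by ≈22,000; its closeness index 0.85 makes it the region's
top-ranked technology under the regional weights (0.39, 0.28, 0.33). The
second technology is the fully published exemplar: drought-tolerant cowpea
with 70 % yield gain, 80 % success probability, 10 % cost saving and 40 %
maximum adoption within 10 years. `study/out/` receives `ranking.csv` and a
JSON report; `exante sweep` re-ranks under alternative weight vectors.

The same pipeline is available as a library:

```python
from exante import ExAnteModel
results = ExAnteModel.from_tables("study/config.yaml").fit()
print(results.summary())
results.sensitivity([results.weights])   # weight-sensitivity re-ranking
```

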