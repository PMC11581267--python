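# Methods

## Scope and model structure

`exante` ranks candidate agricultural technologies for a target
agro-ecological environment by three outcome criteria — benefit-cost ratio
of the research investment, poverty reduction, and change in child
malnutrition — combined with TOPSIS under region-specific criteria weights.
`ExAnteModel` holds the data and settings; `fit()` runs
criteria → weights → TOPSIS and returns `AssessmentResults`.

## Adoption

Adoption of a technology is a deterministic path over years t = 1…horizon:
zero until release (`release_lag` years after research starts), then a ramp
reaching the ceiling `max_adoption` (a fraction of crop acreage) after
`years_to_max` years, then a plateau. The default ramp is linear — the
simplest monotone shape consistent with an expert-stated "maximum adoption
within N years" — with a logistic S-curve available via
`adoption_shape="logistic"` (symmetric, covering ~1–99 % of the ceiling over
the ramp, forced to 0 before release and to the ceiling at the ramp end so
both shapes share their endpoints).

## Economic surplus and BCR

The surplus model is the standard closed-economy, linear supply/demand,
parallel-shift form. The per-unit (price-relative) downward supply shift in
year t is

    K_t = [ yield_gain/ε − cost_change/(1 + yield_gain) ] · p_success · A_t

clamped at zero: yield gains shift supply out in proportion to 1/ε, a
per-hectare cost change converts to a per-unit cost change through the
yield factor, and both are discounted by the probability of research success
and the adoption fraction A_t. Yearly surplus per country is
ΔES_t = K_t·P₀·Q₀·(1 + ½·K_t·Z), Z = ε/(ε+η), summed over the countries of
the environment. Assumptions: no trade linkages or price transmission
between regions, no seasonal price dynamics, constant baseline quantities
and elasticities over the horizon.

Costs are the two named components: research outlays
(`research_cost_per_year` for the first `research_years` years) plus
dissemination charged per adopted hectare each year
(`dissemination_cost_per_ha` × A_t × total crop area). Charging
dissemination on the adopted area every year (rather than as lump sums) is
a declared design choice; it makes dissemination effort track the extension
footprint.

BCR discounts both streams at rate r (default 0.10, the conventional rate
for this literature) over t = 1…T with T = 25 years, both configurable.

## Poverty

ΔP = (ΔES_T / AgGDP) · elasticity · P, evaluated per country in the year
maximum adoption is reached (T = release_lag + years_to_max) and summed.
The surplus share of agricultural GDP and the poverty elasticity
((%ΔP)/(%ΔY), ≤ 0) are both per-unit quantities, so the product is taken on
fractions; expressing both in percent gives the identical number. The
ranking criterion is people lifted out of poverty, −ΔP, so that larger is
better.

## Child malnutrition

The percent of malnourished children under five follows

    PMC_t = PMC_{t−1} + e_k·ln(PcKcal_t/PcKcal_{t−1})
            + c_l·ΔLfExp_t + c_s·ΔSchl_t + c_w·ΔWater_t,

clamped to [0, 100]; MC_t = PopC_t·PMC_t/100. Defaults: e_k = −25.24,
c_l = −71.755094, c_s = −0.219831. The safe-water coefficient has no
published estimate; it defaults to 0 (channel off) with a logged warning
rather than inventing a value.

A technology enters through calories only: its extra production
(yield_gain · p_success · A_t · baseline production, summed over countries)
is converted to kcal/capita/day via a crop energy density (default
3.5 × 10⁶ kcal/tonne, typical of dry cereals and grain legumes,
configurable) divided by total population × 365. This transparent linkage
deliberately replaces a global multi-market projection model: it captures
the direct availability channel and nothing else (no price-mediated
substitution between crops, no acreage reallocation — hence no technology
can worsen malnutrition here, which full market models do produce for
non-staple crops).

Both the baseline and the scenario recursion are anchored at the same
year-zero covariate levels (the baseline's first-year values), so a
first-year calorie shift registers; with each path anchored to itself, a
uniform shift would cancel out of the log-ratio. The criterion is
ΔMC = MC_scenario(T) − MC_baseline(T), negative = improvement.

## Weights and TOPSIS

Weights are indicator ratios (region ÷ reference region: AgGDP share of
GDP, poverty headcount, child stunting) normalized to sum to one. Ratios
and weights are carried unrounded internally; two-decimal rounding happens
only in reports.

TOPSIS: vector normalization r_ij = a_ij/√Σᵢa_ij² (signs preserved, so a
criterion column mixing improvements and deteriorations keeps its signs);
weighting v_ij = w_j·r_ij; ideal solutions per criterion direction (BCR and
poverty reduction are benefit criteria — column max is ideal; malnutrition
change is a cost criterion — column min is ideal); Euclidean distances S±;
closeness C⁺ = S⁻/(S⁻+S⁺); ranking by descending closeness with
competition (shared-minimum) ranks for ties. A degenerate single-technology
matrix is its own positive ideal and gets closeness 1 with a logged
warning. An all-zero criterion column is an error (normalization
undefined), named after the offending criterion.

## Synthetic studies

The generator emulates the structure of expert-elicited technology tables
and macro/nutrition baselines. Draws are uniform within bounds — the
original parameters came from an expert panel with no reported
distributions, so uniform-within-plausible-bounds is the declared choice —
from a single PCG64 generator per table, seeded from the config (the macro
table uses a fixed offset of the seed so the two tables do not alias).
Default bounds: yield gains 10–70 %, success probabilities 0.5–0.95,
adoption ceilings 10–60 % reached in 5–15 years, research budgets
US$0.1–0.5M/yr for 5–10 years, dissemination US$10–100/ha; country
baselines with production 50–500 kt, prices US$200–800/t, elasticities
0.3–1.2, agricultural GDP US$0.5–5bn, 0.5–5M poor, poverty elasticities
−1.2…−0.3. The nutrition baseline is time-constant (2,300 kcal/cap/day,
20 % malnourished, 3M children under five, 20M people), mirroring a
constant-climate baseline. The published drought-tolerant cowpea profile
(70 % yield gain, 80 % success, −10 % cost, 40 % ceiling in 10 years,
US$300k/yr × 10, US$50/ha) is embedded verbatim as the first profile when
`include_exemplar` is set.

What passing tests on these studies do show: the arithmetic of every stage,
the published worked numbers that are reproducible from printed inputs
(weight rows, the worked TOPSIS distance/closeness), and the pipeline's
invariances and determinism. What they do not show: agreement with any
region's actual headline results, which depend on unpublished technology
tables and external macro data; synthetic parameter draws are independent
across fields, whereas real expert elicitations correlate costs, adoption
and yield effects.

The default study size used by the bundled fixture and the acceptance
script is 12 technologies × 3 countries over a 25-year horizon — large
enough to exercise ties, ramps and multi-country aggregation while keeping
the whole suite fast.

## Numerical choices

- K is clamped at ≥ 0; PMC is clamped to [0, 100] each year (it is a
  percentage; the recursion itself is unbounded).
- BCR requires strictly positive discounted costs; an all-zero cost stream
  is an error rather than an infinite ratio.
- All criterion values, weights and TOPSIS quantities are float64
  throughout; rounding only at serialization (default 4 decimals,
  configurable).
- CSV round-trips write floats with `%.17g` and read with pandas'
  round-trip parser, so a written study reloads bit-identically.
- Ranks are computed as 1 + (number of strictly better technologies),
  which implements competition ranking including ties.

## Limitations

- Closed-economy surplus: no cross-region price transmission, trade, or
  seasonal price fluctuation; countries are not price-takers on a world
  market.
- The malnutrition linkage is availability-only (see above); coefficient
  values are taken as given, not re-estimated, and the safe-water channel
  is off by default.
- Covariates other than calories are held at baseline in technology
  scenarios; income and population growth are not modelled.
- Weight derivation assumes the three indicators are commensurable after
  ratio-normalization; no elicitation (e.g. pairwise comparison) is
  offered.
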