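"""Economic surplus, benefit-cost ratio and poverty outcome.

A technology shifts the crop supply curve down by a per-unit amount ``K``
(the vertical shift expressed as a fraction of the baseline price).  Under a
closed economy with linear supply and demand and a parallel shift, the
change in total economic surplus in a country is

    ΔES = K · P0 · Q0 · (1 + 0.5 · K · Z),     Z = ε / (ε + η),

with ε the supply elasticity, η the (absolute) demand elasticity, P0 the
baseline producer price and Q0 baseline production.  The per-unit shift
combines the yield gain and the per-hectare cost change, discounted by the
probability of research success and the adoption fraction of the year:

    K_t = [ yield_gain/ε − cost_change/(1 + yield_gain) ] · p_success · A_t,

clamped at zero (a technology cannot shift supply upward here).

Benefits and costs are discounted at rate ``r`` over years t = 1..T and
their ratio is the benefit-cost ratio (BCR).  The poverty outcome converts
the surplus of the year of maximum adoption into a proportional agricultural
productivity gain and applies the country's poverty elasticity:

    ΔP = (ΔES_T / AgGDP) · elasticity · P.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import AdoptionPath, CountryBaseline, EnvironmentMacro, SurplusOutcome, TechnologyProfile

__all__ = [
    "build_adoption_path",
    "surplus_stream",
    "surplus_stream_by_country",
    "cost_stream",
    "compute_bcr",
    "compute_poverty_change",
    "evaluate_technology",
    "DEFAULT_HORIZON",
    "DEFAULT_DISCOUNT_RATE",
]

DEFAULT_HORIZON = 25
DEFAULT_DISCOUNT_RATE = 0.10


def build_adoption_path(
    profile: TechnologyProfile,
    horizon: int = DEFAULT_HORIZON,
    shape: str = "linear",
) -> AdoptionPath:
    """Yearly adoption fractions for years 1..horizon.

    Adoption is zero through the release lag, then ramps to ``max_adoption``
    over ``years_to_max`` years and plateaus.  ``shape`` selects the ramp:
    ``"linear"`` (default) or ``"logistic"`` (symmetric S-curve reaching
    99 % of the ceiling at the ramp end).
    """
    ramp_end = profile.release_lag + profile.years_to_max
    if horizon < ramp_end:
        raise ValueError(
            f"horizon ({horizon} years) is shorter than the adoption ramp end "
            f"(release_lag + years_to_max = {ramp_end} years)"
        )
    t = np.arange(1, horizon + 1, dtype=float)
    if shape == "linear":
        frac = (t - profile.release_lag) / profile.years_to_max
        frac = np.clip(frac, 0.0, 1.0)
    elif shape == "logistic":
        # midpoint at ramp centre; steepness set so the curve covers ~1%..99%
        # of the ceiling between release and ramp end
        mid = profile.release_lag + profile.years_to_max / 2.0
        k = 2.0 * np.log(99.0) / profile.years_to_max
        frac = 1.0 / (1.0 + np.exp(-k * (t - mid)))
        frac[t <= profile.release_lag] = 0.0
        frac[t >= ramp_end] = 1.0
        frac = np.maximum.accumulate(frac)
    else:
        raise ValueError(f"unknown adoption-curve shape: {shape!r}")
    return AdoptionPath(values=tuple(profile.max_adoption * frac))


def _k_shift(profile: TechnologyProfile, supply_elasticity: float) -> float:
    """Per-unit supply shift before adoption/success scaling, clamped at 0."""
    k = (
        profile.yield_gain / supply_elasticity
        - profile.cost_change / (1.0 + profile.yield_gain)
    )
    return max(k, 0.0)


def surplus_stream_by_country(
    profile: TechnologyProfile,
    macro: EnvironmentMacro,
    path: AdoptionPath,
) -> dict[str, np.ndarray]:
    """Yearly surplus (USD) per country over the path's horizon."""
    adoption = path.as_array()
    out: dict[str, np.ndarray] = {}
    for c in macro.countries:
        if c.supply_elasticity <= 0 or c.demand_elasticity <= 0:
            raise ValueError(f"non-positive elasticity for country {c.country!r}")
        k_t = _k_shift(profile, c.supply_elasticity) * profile.prob_success * adoption
        z = c.supply_elasticity / (c.supply_elasticity + c.demand_elasticity)
        out[c.country] = k_t * c.price * c.production * (1.0 + 0.5 * k_t * z)
    return out


def surplus_stream(
    profile: TechnologyProfile,
    macro: EnvironmentMacro,
    path: AdoptionPath,
) -> np.ndarray:
    """Total yearly economic surplus (USD), summed over countries."""
    per_country = surplus_stream_by_country(profile, macro, path)
    return np.sum(list(per_country.values()), axis=0)


def cost_stream(
    profile: TechnologyProfile,
    macro: EnvironmentMacro,
    path: AdoptionPath,
) -> np.ndarray:
    """Yearly research plus dissemination costs (USD).

    Research costs run at ``research_cost_per_year`` for the first
    ``research_years`` years; dissemination costs are per-hectare charges on
    the area adopted each year, summed over countries.
    """
    adoption = path.as_array()
    t = np.arange(1, len(adoption) + 1)
    research = np.where(t <= profile.research_years, profile.research_cost_per_year, 0.0)
    total_area = sum(c.area for c in macro.countries)
    dissemination = profile.dissemination_cost_per_ha * adoption * total_area
    return research + dissemination


def compute_bcr(
    surplus_by_year: Sequence[float],
    costs_by_year: Sequence[float],
    r: float = DEFAULT_DISCOUNT_RATE,
) -> float:
    """Discounted benefit-cost ratio over years t = 1..T."""
    benefits = np.asarray(surplus_by_year, dtype=float)
    costs = np.asarray(costs_by_year, dtype=float)
    if benefits.shape != costs.shape:
        raise ValueError("surplus and cost streams must have equal length")
    t = np.arange(1, len(benefits) + 1)
    disc = (1.0 + r) ** t
    pv_costs = float(np.sum(costs / disc))
    if pv_costs <= 0:
        raise ValueError("discounted costs are zero; benefit-cost ratio undefined")
    return float(np.sum(benefits / disc)) / pv_costs


def compute_poverty_change(
    total_surplus_at_T: float,
    ag_gdp: float,
    poverty_elasticity: float,
    poor_count: float,
) -> float:
    """Change in the number of poor people at the year of maximum adoption.

    Negative = poverty reduced.  The surplus share of agricultural GDP and
    the elasticity are both per-unit quantities, so the product is taken on
    fractions directly.
    """
    if ag_gdp <= 0:
        raise ValueError("agricultural GDP must be strictly positive")
    if poor_count < 0:
        raise ValueError("poor_count must be non-negative")
    return (total_surplus_at_T / ag_gdp) * poverty_elasticity * poor_count


def evaluate_technology(
    profile: TechnologyProfile,
    macro: EnvironmentMacro,
    horizon: int = DEFAULT_HORIZON,
    discount_rate: float = DEFAULT_DISCOUNT_RATE,
    adoption_shape: str = "linear",
) -> SurplusOutcome:
    """Full surplus evaluation of one technology in one environment.

    The poverty outcome is evaluated in the year maximum adoption is reached
    (T = release_lag + years_to_max) and summed over countries.
    """
    path = build_adoption_path(profile, horizon, shape=adoption_shape)
    per_country = surplus_stream_by_country(profile, macro, path)
    surplus = np.sum(list(per_country.values()), axis=0)
    costs = cost_stream(profile, macro, path)
    bcr = compute_bcr(surplus, costs, discount_rate)
    t_max = profile.release_lag + profile.years_to_max  # 1-based year
    poverty = sum(
        compute_poverty_change(
            per_country[c.country][t_max - 1],
            c.ag_gdp,
            c.poverty_elasticity,
            c.poor_count,
        )
        for c in macro.countries
    )
    return SurplusOutcome(
        tech_id=profile.tech_id,
        surplus_by_year=tuple(float(x) for x in surplus),
        costs_by_year=tuple(float(x) for x in costs),
        bcr=bcr,
        discount_rate=discount_rate,
        poverty_change=float(poverty),
    )
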