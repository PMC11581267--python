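"""Domain types for the ex-ante impact-assessment pipeline.

All tabular inputs (technology parameter tables, per-country macro baselines,
nutrition covariate paths, regional indicator rows) are validated into the
pydantic models below before any computation runs.  Numeric conventions:

* rates and shares are fractions unless a field name says ``percent``
  (``yield_gain=0.70`` means a 70 % yield gain);
* ``cost_change`` is the fractional change in per-hectare production cost,
  negative for a cost saving;
* ``poverty_elasticity`` is (%ΔP / %ΔY), expected non-positive: productivity
  growth reduces poverty;
* monetary values are in US dollars.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "TechnologyProfile",
    "CountryBaseline",
    "EnvironmentMacro",
    "AdoptionPath",
    "SurplusOutcome",
    "NutritionCoefficients",
    "NutritionPath",
    "MalnutritionResult",
    "IndicatorSet",
    "CriteriaWeights",
    "DecisionMatrix",
    "TopsisResult",
    "Direction",
]

Direction = Literal["benefit", "cost"]


class TechnologyProfile(BaseModel):
    """Adoption, agronomic and cost parameters for one candidate technology.

    One row of an expert-elicited technology table: what the technology is
    expected to do to yields and per-hectare costs, how likely the research is
    to succeed, how fast and how widely farmers adopt it, and what developing
    and disseminating it costs.
    """

    model_config = ConfigDict(frozen=True)

    tech_id: str
    crop: str
    environment: str
    yield_gain: float = Field(gt=-1.0)
    cost_change: float
    prob_success: float = Field(ge=0.0, le=1.0)
    max_adoption: float = Field(ge=0.0, le=1.0)
    years_to_max: int = Field(ge=1)
    release_lag: int = Field(ge=0)
    research_cost_per_year: float = Field(ge=0.0)
    research_years: int = Field(ge=0)
    dissemination_cost_per_ha: float = Field(ge=0.0)


class CountryBaseline(BaseModel):
    """Baseline crop-market and poverty data for one country.

    ``production`` and ``price`` set the pre-technology market size for the
    target crop; supply and demand elasticities shape how a supply shift is
    split between producer and consumer surplus; ``ag_gdp``, ``poor_count``
    and ``poverty_elasticity`` drive the surplus-to-poverty conversion.
    """

    model_config = ConfigDict(frozen=True)

    country: str
    production: float = Field(ge=0.0)  # tonnes/yr
    area: float = Field(ge=0.0)  # ha
    price: float = Field(ge=0.0)  # USD/tonne
    supply_elasticity: float = Field(gt=0.0)
    demand_elasticity: float = Field(gt=0.0)  # absolute value
    ag_gdp: float = Field(ge=0.0)  # USD
    poor_count: float = Field(ge=0.0)  # persons
    poverty_elasticity: float  # (%ΔP)/(%ΔY), expected <= 0


class EnvironmentMacro(BaseModel):
    """All country baselines for one target (agro-ecological) environment."""

    model_config = ConfigDict(frozen=True)

    environment: str
    countries: tuple[CountryBaseline, ...] = Field(min_length=1)


class AdoptionPath(BaseModel):
    """Yearly adoption fractions, year 1 through the horizon."""

    model_config = ConfigDict(frozen=True)

    values: tuple[float, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_path(self) -> "AdoptionPath":
        arr = np.asarray(self.values)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("adoption fractions must lie in [0, 1]")
        if np.any(np.diff(arr) < -1e-12):
            raise ValueError("adoption path must be non-decreasing")
        return self

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


class SurplusOutcome(BaseModel):
    """Economic-surplus results for one technology in one environment."""

    model_config = ConfigDict(frozen=True)

    tech_id: str
    surplus_by_year: tuple[float, ...]  # USD, summed over countries
    costs_by_year: tuple[float, ...]  # USD, research + dissemination
    bcr: float = Field(ge=0.0)
    discount_rate: float
    poverty_change: float  # persons at t = T; negative = poverty reduced

    @model_validator(mode="after")
    def _check_streams(self) -> "SurplusOutcome":
        if len(self.surplus_by_year) != len(self.costs_by_year):
            raise ValueError("surplus and cost streams must have equal length")
        if any(c < 0 for c in self.costs_by_year):
            raise ValueError("cost stream must be non-negative")
        return self


class NutritionCoefficients(BaseModel):
    """Coefficients of the child-malnutrition projection recursion.

    The kcal term is an elasticity applied to the log-ratio of successive
    per-capita calorie availability; the remaining coefficients multiply
    first differences of their covariates.  ``water_coef`` has no published
    estimate and must be supplied by the user (default 0, i.e. the safe-water
    channel is switched off).
    """

    model_config = ConfigDict(frozen=True)

    kcal_elasticity: float = Field(default=-25.24, lt=0.0)
    lfexp_coef: float = Field(default=-71.755094, lt=0.0)
    schl_coef: float = Field(default=-0.219831, lt=0.0)
    water_coef: float = 0.0


class NutritionPath(BaseModel):
    """Yearly covariates of the malnutrition recursion for one country.

    ``pckcal`` is kcal/capita/day; ``lfexp_ratio`` the female/male life
    expectancy ratio; ``schl`` percent female secondary enrollment; ``water``
    the share with safe water access; ``popc`` the under-five population.
    ``pmc0`` is the percent of malnourished children in the year before the
    path starts.
    """

    model_config = ConfigDict(frozen=True)

    years: tuple[int, ...] = Field(min_length=1)
    pckcal: tuple[float, ...]
    lfexp_ratio: tuple[float, ...]
    schl: tuple[float, ...]
    water: tuple[float, ...]
    popc: tuple[float, ...]
    pmc0: float = Field(ge=0.0, le=100.0)

    @model_validator(mode="after")
    def _check_lengths(self) -> "NutritionPath":
        n = len(self.years)
        for name in ("pckcal", "lfexp_ratio", "schl", "water", "popc"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"covariate '{name}' length != number of years")
        if any(k <= 0 for k in self.pckcal):
            raise ValueError("per-capita kcal must be strictly positive")
        if any(p < 0 for p in self.popc):
            raise ValueError("under-5 population must be non-negative")
        return self

    def with_pckcal(self, pckcal: Sequence[float]) -> "NutritionPath":
        """Copy of this path with the kcal sequence replaced (scenario path)."""
        return self.model_copy(update={"pckcal": tuple(float(k) for k in pckcal)})


class MalnutritionResult(BaseModel):
    """Projected malnutrition outcomes along one covariate path."""

    model_config = ConfigDict(frozen=True)

    pmc_by_year: tuple[float, ...]  # percent, clamped to [0, 100]
    mc_by_year: tuple[float, ...]  # children

    @model_validator(mode="after")
    def _check(self) -> "MalnutritionResult":
        if len(self.pmc_by_year) != len(self.mc_by_year):
            raise ValueError("pmc and mc series must have equal length")
        if any(p < 0 or p > 100 for p in self.pmc_by_year):
            raise ValueError("PMC outside [0, 100]")
        return self


class IndicatorSet(BaseModel):
    """Regional indicators used to weight the three criteria.

    The share of agriculture in GDP proxies the importance of the
    benefit-cost criterion, poverty headcount that of the poverty criterion,
    and child stunting that of the nutrition criterion.  All in percent.
    """

    model_config = ConfigDict(frozen=True)

    region: str
    ag_gdp_share: float = Field(ge=0.0, le=100.0)
    poverty_headcount: float = Field(ge=0.0, le=100.0)
    child_stunting: float = Field(ge=0.0, le=100.0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.ag_gdp_share, self.poverty_headcount, self.child_stunting]
        )


class CriteriaWeights(BaseModel):
    """Normalized weights (BCR, poverty, nutrition); non-negative, sum 1."""

    model_config = ConfigDict(frozen=True)

    w_bcr: float = Field(ge=0.0)
    w_poverty: float = Field(ge=0.0)
    w_nutrition: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check_sum(self) -> "CriteriaWeights":
        total = self.w_bcr + self.w_poverty + self.w_nutrition
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.w_bcr, self.w_poverty, self.w_nutrition])

    @classmethod
    def from_array(cls, w: Sequence[float]) -> "CriteriaWeights":
        w = list(w)
        if len(w) != 3:
            raise ValueError(f"expected 3 weights, got {len(w)}")
        return cls(w_bcr=w[0], w_poverty=w[1], w_nutrition=w[2])


class DecisionMatrix(BaseModel):
    """Raw criterion values a_ij for I technologies and 3 criteria.

    Column order is (BCR, poverty reduction, malnutrition change).  The
    poverty column holds people lifted out of poverty (larger is better,
    a benefit criterion); the malnutrition column holds the signed change in
    malnourished children (more negative is better, a cost criterion).
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    tech_ids: tuple[str, ...] = Field(min_length=1)
    criteria: tuple[str, str, str] = ("bcr", "poverty_reduction", "malnutrition_change")
    directions: tuple[Direction, Direction, Direction] = ("benefit", "benefit", "cost")
    a: tuple[tuple[float, float, float], ...]

    @model_validator(mode="after")
    def _check_shape(self) -> "DecisionMatrix":
        if len(self.a) != len(self.tech_ids):
            raise ValueError("one row of criterion values per technology required")
        arr = np.asarray(self.a, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("decision matrix contains non-finite cells")
        return self

    def as_array(self) -> np.ndarray:
        return np.asarray(self.a, dtype=float)


class TopsisResult(BaseModel):
    """Full TOPSIS trace: normalized/weighted matrices, ideals, distances,
    closeness indices and competition ranks (ties share the minimum rank)."""

    model_config = ConfigDict(frozen=True)

    tech_ids: tuple[str, ...]
    r: tuple[tuple[float, float, float], ...]
    v: tuple[tuple[float, float, float], ...]
    v_plus: tuple[float, float, float]
    v_minus: tuple[float, float, float]
    s_plus: tuple[float, ...]
    s_minus: tuple[float, ...]
    closeness: tuple[float, ...]
    rank: tuple[int, ...]

    @model_validator(mode="after")
    def _check(self) -> "TopsisResult":
        n = len(self.tech_ids)
        for name in ("r", "v", "s_plus", "s_minus", "closeness", "rank"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field '{name}' length != number of technologies")
        if any(c < -1e-12 or c > 1 + 1e-12 for c in self.closeness):
            raise ValueError("closeness index outside [0, 1]")
        return self
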