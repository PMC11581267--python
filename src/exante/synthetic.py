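"""Seeded synthetic study generator.

Emulates the structure of expert-elicited technology parameter tables and
the macro/nutrition baselines the pipeline consumes, so every stage can be
exercised without any external download.  Parameters are drawn uniformly
within configurable bounds (the original tables came from an expert panel;
no distributions were published, so uniform-within-plausible-bounds is the
declared choice).  All draws come from one ``numpy.random.Generator``
(PCG64) seeded from the config, so a study is fully reproducible from its
seed.

The one fully published technology — drought-tolerant cowpea with
integrated crop management for semi-arid West and Central Africa: 70 %
yield gain, 80 % chance of success, 10 % per-hectare cost reduction, 40 %
maximum adoption reached 10 years after release, US$300,000/yr research for
10 years and US$50/ha dissemination — can be embedded verbatim as the first
profile via ``include_exemplar``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import CountryBaseline, EnvironmentMacro, NutritionPath, TechnologyProfile

__all__ = ["GeneratorConfig", "COWPEA_EXEMPLAR", "generate_technologies", "generate_macro", "generate_nutrition_paths", "generate_study"]

COWPEA_EXEMPLAR = TechnologyProfile(
    tech_id="T000-cowpea-dt-icm",
    crop="cowpea",
    environment="semi-arid-west-central-africa",
    yield_gain=0.70,
    cost_change=-0.10,
    prob_success=0.80,
    max_adoption=0.40,
    years_to_max=10,
    release_lag=0,
    research_cost_per_year=300_000.0,
    research_years=10,
    dissemination_cost_per_ha=50.0,
)

CROPS = (
    "sorghum", "pearl-millet", "finger-millet", "groundnut",
    "cowpea", "chickpea", "lentil", "pigeon-pea", "soybean",
)

#: default uniform bounds per parameter; plausible for dryland crop
#: improvement programs of this kind
DEFAULT_TECH_RANGES: dict[str, tuple[float, float]] = {
    "yield_gain": (0.10, 0.70),
    "cost_change": (-0.15, 0.05),
    "prob_success": (0.50, 0.95),
    "max_adoption": (0.10, 0.60),
    "years_to_max": (5, 15),
    "release_lag": (0, 5),
    "research_cost_per_year": (1e5, 5e5),
    "research_years": (5, 10),
    "dissemination_cost_per_ha": (10.0, 100.0),
}

DEFAULT_COUNTRY_RANGES: dict[str, tuple[float, float]] = {
    "production": (5e4, 5e5),  # tonnes/yr
    "area": (5e4, 5e5),  # ha
    "price": (200.0, 800.0),  # USD/tonne
    "supply_elasticity": (0.3, 1.2),
    "demand_elasticity": (0.3, 1.2),
    "ag_gdp": (5e8, 5e9),  # USD
    "poor_count": (5e5, 5e6),  # persons
    "poverty_elasticity": (-1.2, -0.3),
}

DEFAULT_NUTRITION_BASELINE: dict[str, float] = {
    "pmc0": 20.0,  # percent malnourished at start
    "popc": 3e6,  # under-5 population
    "pckcal": 2300.0,  # kcal/capita/day
    "lfexp_ratio": 1.05,
    "schl": 40.0,  # percent female secondary enrollment
    "water": 60.0,  # percent with safe water
    "population": 2e7,  # total population, for the production→kcal linkage
}

_INT_FIELDS = {"years_to_max", "release_lag", "research_years"}


class GeneratorConfig(BaseModel):
    """Configuration for one synthetic study."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0)
    n_technologies: int = Field(default=12, ge=1)
    n_countries: int = Field(default=3, ge=1)
    environment: str = "semi-arid-west-central-africa"
    include_exemplar: bool = True
    tech_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_TECH_RANGES)
    )
    country_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_RANGES)
    )
    nutrition_baseline: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_NUTRITION_BASELINE)
    )

    @model_validator(mode="after")
    def _check_ranges(self) -> "GeneratorConfig":
        for name, ranges in (("tech_ranges", self.tech_ranges), ("country_ranges", self.country_ranges)):
            for field, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ValueError(f"{name}[{field!r}]: low {lo} > high {hi}")
        for field in ("prob_success", "max_adoption"):
            lo, hi = self.tech_ranges.get(field, (0, 1))
            if lo < 0 or hi > 1:
                raise ValueError(f"tech_ranges[{field!r}] must stay within [0, 1]")
        for field in ("supply_elasticity", "demand_elasticity"):
            lo, _ = self.country_ranges.get(field, (1, 1))
            if lo <= 0:
                raise ValueError(f"country_ranges[{field!r}] must be strictly positive")
        return self


def _draw(rng: np.random.Generator, ranges: Mapping[str, tuple[float, float]], field: str) -> float:
    lo, hi = ranges[field]
    if field in _INT_FIELDS:
        return int(rng.integers(int(lo), int(hi) + 1))
    return float(rng.uniform(lo, hi))


def generate_technologies(cfg: GeneratorConfig) -> list[TechnologyProfile]:
    """Draw ``n_technologies`` profiles; deterministic for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    profiles: list[TechnologyProfile] = []
    if cfg.include_exemplar:
        profiles.append(
            COWPEA_EXEMPLAR.model_copy(update={"environment": cfg.environment})
        )
    i = len(profiles)
    while len(profiles) < cfg.n_technologies:
        crop = CROPS[int(rng.integers(0, len(CROPS)))]
        kwargs = {f: _draw(rng, cfg.tech_ranges, f) for f in DEFAULT_TECH_RANGES}
        profiles.append(
            TechnologyProfile(
                tech_id=f"T{i:03d}-{crop}",
                crop=crop,
                environment=cfg.environment,
                **kwargs,
            )
        )
        i += 1
    return profiles


def generate_macro(cfg: GeneratorConfig) -> EnvironmentMacro:
    """Draw per-country macro baselines; deterministic for a given seed."""
    # offset stream so macro draws do not alias the technology draws
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    countries = [
        CountryBaseline(
            country=f"country-{chr(ord('A') + i)}",
            **{f: _draw(rng, cfg.country_ranges, f) for f in DEFAULT_COUNTRY_RANGES},
        )
        for i in range(cfg.n_countries)
    ]
    return EnvironmentMacro(environment=cfg.environment, countries=tuple(countries))


def generate_nutrition_paths(cfg: GeneratorConfig, horizon: int) -> NutritionPath:
    """Constant baseline covariate paths over the horizon.

    The baseline holds every covariate at its configured level (the
    constant-climate, no-technology baseline), so the baseline projection
    keeps the malnutrition share at its starting value.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    nb = cfg.nutrition_baseline
    const = lambda key: tuple(float(nb[key]) for _ in range(horizon))  # noqa: E731
    return NutritionPath(
        years=tuple(range(1, horizon + 1)),
        pckcal=const("pckcal"),
        lfexp_ratio=const("lfexp_ratio"),
        schl=const("schl"),
        water=const("water"),
        popc=const("popc"),
        pmc0=float(nb["pmc0"]),
    )


def generate_study(
    cfg: GeneratorConfig, horizon: int = 25
) -> tuple[list[TechnologyProfile], EnvironmentMacro, NutritionPath]:
    """One complete synthetic study: technologies, macro, nutrition baseline."""
    return (
        generate_technologies(cfg),
        generate_macro(cfg),
        generate_nutrition_paths(cfg, horizon),
    )
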