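"""Child-malnutrition projection.

The percent of malnourished children under five (PMC) evolves by a
first-order recursion in four covariates: per-capita kilocalorie
availability (entering through the log-ratio of successive years, scaled by
an elasticity), the female/male life-expectancy ratio, percent female
secondary-school enrollment, and the share of the population with safe
water (each entering through its first difference):

    PMC_t = PMC_{t-1}
            + kcal_elasticity · ln(PcKcal_t / PcKcal_{t-1})
            + lfexp_coef · (LfExp_t − LfExp_{t-1})
            + schl_coef · (Schl_t − Schl_{t-1})
            + water_coef · (Water_t − Water_{t-1}),

clamped to [0, 100] each year.  The count of malnourished children is
MC_t = PopC_t · PMC_t / 100.

A technology enters only through the kcal channel: its extra production is
converted to additional kcal per capita per day and added to the baseline
kcal path, all other covariates held at baseline.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .types import MalnutritionResult, NutritionCoefficients, NutritionPath

__all__ = [
    "project_malnutrition",
    "kcal_shift_from_production",
    "delta_malnourished",
    "DEFAULT_KCAL_PER_TONNE",
]

logger = logging.getLogger(__name__)

# Typical metabolizable energy of dry cereals and grain legumes
# (~3,500 kcal per kg of dry grain). Configurable wherever it is used.
DEFAULT_KCAL_PER_TONNE = 3.5e6

_warned_water = False


def project_malnutrition(
    path: NutritionPath,
    coefs: NutritionCoefficients | None = None,
    initial: Mapping[str, float] | None = None,
) -> MalnutritionResult:
    """Run the malnutrition recursion along one covariate path.

    ``initial`` optionally supplies the year-zero covariate levels (keys
    ``pckcal``, ``lfexp_ratio``, ``schl``, ``water``) against which the first
    year's increments are taken; it defaults to the path's own first-year
    values, so a constant path is a fixed point of the recursion.  When
    comparing a technology scenario against a baseline, pass the baseline's
    year-zero levels for both runs so that a first-year covariate shift
    registers.
    """
    if coefs is None:
        coefs = NutritionCoefficients()
    global _warned_water
    if coefs.water_coef == 0.0 and not _warned_water:
        _warned_water = True
        logger.warning(
            "water_coef is 0: the safe-water channel of the malnutrition "
            "recursion is switched off (no published coefficient)"
        )
    kcal = np.asarray(path.pckcal, dtype=float)
    if np.any(kcal <= 0):
        raise ValueError("per-capita kcal must be strictly positive everywhere")
    lfexp = np.asarray(path.lfexp_ratio, dtype=float)
    schl = np.asarray(path.schl, dtype=float)
    water = np.asarray(path.water, dtype=float)
    popc = np.asarray(path.popc, dtype=float)

    n = len(kcal)
    pmc = np.empty(n)
    prev_pmc = path.pmc0
    init = dict(initial) if initial else {}
    prev_kcal = float(init.get("pckcal", kcal[0]))
    prev_lfexp = float(init.get("lfexp_ratio", lfexp[0]))
    prev_schl = float(init.get("schl", schl[0]))
    prev_water = float(init.get("water", water[0]))
    if prev_kcal <= 0:
        raise ValueError("initial per-capita kcal must be strictly positive")
    for t in range(n):
        step = (
            prev_pmc
            + coefs.kcal_elasticity * np.log(kcal[t] / prev_kcal)
            + coefs.lfexp_coef * (lfexp[t] - prev_lfexp)
            + coefs.schl_coef * (schl[t] - prev_schl)
            + coefs.water_coef * (water[t] - prev_water)
        )
        pmc[t] = min(max(step, 0.0), 100.0)
        prev_pmc = pmc[t]
        prev_kcal, prev_lfexp, prev_schl, prev_water = kcal[t], lfexp[t], schl[t], water[t]

    mc = popc * pmc / 100.0
    return MalnutritionResult(
        pmc_by_year=tuple(float(x) for x in pmc),
        mc_by_year=tuple(float(x) for x in mc),
    )


def kcal_shift_from_production(
    extra_production: Sequence[float] | float,
    kcal_per_tonne: float,
    population: float,
    baseline_pckcal: Sequence[float],
) -> np.ndarray:
    """Scenario per-capita kcal path from a stream of extra production.

    ``extra_production`` is tonnes/yr (scalar or per-year); the increment per
    person per day is extra_production · kcal_per_tonne / (population · 365),
    added to the baseline path elementwise.
    """
    if population <= 0:
        raise ValueError("population must be strictly positive")
    baseline = np.asarray(baseline_pckcal, dtype=float)
    extra = np.broadcast_to(
        np.asarray(extra_production, dtype=float), baseline.shape
    )
    return baseline + extra * kcal_per_tonne / (population * 365.0)


def delta_malnourished(
    baseline: MalnutritionResult,
    scenario: MalnutritionResult,
    T: int,
) -> float:
    """Scenario-minus-baseline malnourished children in year T (1-based).

    Negative = the technology reduces child malnutrition.
    """
    if len(baseline.mc_by_year) != len(scenario.mc_by_year):
        raise ValueError("baseline and scenario projections have mismatched horizons")
    if not 1 <= T <= len(baseline.mc_by_year):
        raise ValueError(f"year T={T} outside projection horizon")
    return scenario.mc_by_year[T - 1] - baseline.mc_by_year[T - 1]
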