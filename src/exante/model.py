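"""Model/Results interface for the full assessment.

``ExAnteModel`` bundles the data of one target environment — candidate
technology profiles, per-country macro baselines, the nutrition covariate
path and the regional indicator rows — with the model settings (horizon,
discount rate, adoption-curve shape, nutrition coefficients).  ``fit()``
evaluates the three outcome criteria per technology, derives the criteria
weights from the indicator ratios, runs TOPSIS and returns an
``AssessmentResults`` carrying the criterion table, the weights, the full
TOPSIS trace and a ``summary()`` report.  Weight-sensitivity re-ranking
hangs off the results object.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .mcdm import derive_criteria_weights, indicator_ratios, topsis
from .nutrition import (
    DEFAULT_KCAL_PER_TONNE,
    delta_malnourished,
    kcal_shift_from_production,
    project_malnutrition,
)
from .surplus import (
    DEFAULT_DISCOUNT_RATE,
    DEFAULT_HORIZON,
    build_adoption_path,
    evaluate_technology,
)
from .types import (
    CriteriaWeights,
    DecisionMatrix,
    EnvironmentMacro,
    IndicatorSet,
    NutritionCoefficients,
    NutritionPath,
    TechnologyProfile,
    TopsisResult,
)

__all__ = ["ExAnteModel", "AssessmentResults"]


class ExAnteModel:
    """Multi-criteria ex-ante impact assessment for one target environment.

    Parameters
    ----------
    technologies
        Candidate technology profiles to rank.
    macro
        Per-country economic and poverty baselines of the environment.
    nutrition_path
        Baseline covariate path of the malnutrition recursion.
    region, reference
        Indicator rows of the target region and its reference region; the
        three criteria weights are the normalized region/reference indicator
        ratios.  Pass ``weights`` instead to fix them directly.
    horizon, discount_rate, adoption_shape
        Evaluation horizon in years, discount rate for the benefit-cost
        ratio, and adoption-ramp shape ("linear" or "logistic").
    nutrition_coefs, kcal_per_tonne, population
        Recursion coefficients, crop energy density (kcal/tonne) and total
        population for the production→kcal linkage.
    """

    def __init__(
        self,
        technologies: Sequence[TechnologyProfile],
        macro: EnvironmentMacro,
        nutrition_path: NutritionPath,
        region: IndicatorSet | None = None,
        reference: IndicatorSet | None = None,
        *,
        weights: CriteriaWeights | None = None,
        horizon: int = DEFAULT_HORIZON,
        discount_rate: float = DEFAULT_DISCOUNT_RATE,
        adoption_shape: str = "linear",
        nutrition_coefs: NutritionCoefficients | None = None,
        kcal_per_tonne: float = DEFAULT_KCAL_PER_TONNE,
        population: float | None = None,
    ) -> None:
        if not technologies:
            raise ValueError("at least one technology profile is required")
        if weights is None and (region is None or reference is None):
            raise ValueError(
                "either indicator rows (region and reference) or explicit "
                "weights must be provided"
            )
        if len(nutrition_path.years) < horizon:
            raise ValueError(
                f"nutrition covariate path ({len(nutrition_path.years)} years) "
                f"is shorter than the horizon ({horizon} years)"
            )
        self.technologies = list(technologies)
        self.macro = macro
        self.nutrition_path = nutrition_path
        self.region = region
        self.reference = reference
        self.fixed_weights = weights
        self.horizon = horizon
        self.discount_rate = discount_rate
        self.adoption_shape = adoption_shape
        self.nutrition_coefs = nutrition_coefs or NutritionCoefficients()
        self.kcal_per_tonne = kcal_per_tonne
        self.population = population

    @classmethod
    def from_tables(cls, config: "_io.RunConfig | str | Path") -> "ExAnteModel":
        """Build a model from CSV tables referenced by a run configuration."""
        cfg = _io.load_config(config) if isinstance(config, (str, Path)) else config
        technologies = _io.read_technologies(cfg.technologies)
        macro = _io.read_macro(cfg.macro)
        nutrition = _io.read_nutrition_covariates(
            cfg.nutrition_covariates, pmc0=cfg.nutrition.pmc0
        )
        indicators = _io.read_indicators(cfg.indicators)
        for name in (cfg.region, cfg.reference_region):
            if name not in indicators:
                raise ValueError(
                    f"{cfg.indicators}: no indicator row for region {name!r}"
                )
        return cls(
            technologies,
            macro,
            nutrition,
            region=indicators[cfg.region],
            reference=indicators[cfg.reference_region],
            horizon=cfg.horizon,
            discount_rate=cfg.discount_rate,
            adoption_shape=cfg.adoption_shape,
            nutrition_coefs=cfg.nutrition.coefficients,
            kcal_per_tonne=cfg.nutrition.kcal_per_tonne,
            population=cfg.nutrition.population,
        )

    # ---- criterion evaluation ------------------------------------------

    def _nutrition_criterion(self, profile: TechnologyProfile) -> float:
        """Change in malnourished children at the year of maximum adoption.

        The technology's extra production (yield gain × success probability ×
        adoption share of baseline production, summed over countries) is
        converted to extra kcal/capita/day on top of the baseline path; the
        recursion is run under both paths and differenced at T.
        """
        path = build_adoption_path(profile, self.horizon, shape=self.adoption_shape)
        total_production = sum(c.production for c in self.macro.countries)
        extra = (
            profile.yield_gain
            * profile.prob_success
            * path.as_array()
            * total_production
        )
        population = (
            self.population
            if self.population is not None
            else _default_population()
        )
        scenario_kcal = kcal_shift_from_production(
            extra, self.kcal_per_tonne, population, self.nutrition_path.pckcal
        )
        # both runs are anchored at the baseline's year-zero covariates so a
        # first-year kcal shift from the technology registers in the recursion
        anchor = {
            "pckcal": self.nutrition_path.pckcal[0],
            "lfexp_ratio": self.nutrition_path.lfexp_ratio[0],
            "schl": self.nutrition_path.schl[0],
            "water": self.nutrition_path.water[0],
        }
        baseline = project_malnutrition(
            self.nutrition_path, self.nutrition_coefs, initial=anchor
        )
        scenario = project_malnutrition(
            self.nutrition_path.with_pckcal(scenario_kcal),
            self.nutrition_coefs,
            initial=anchor,
        )
        t_max = profile.release_lag + profile.years_to_max
        return delta_malnourished(baseline, scenario, t_max)

    def criteria_table(self) -> pd.DataFrame:
        """Per-technology criterion values: BCR, people lifted out of poverty
        (−ΔP), and change in malnourished children (ΔMC)."""
        rows = []
        for profile in self.technologies:
            outcome = evaluate_technology(
                profile,
                self.macro,
                horizon=self.horizon,
                discount_rate=self.discount_rate,
                adoption_shape=self.adoption_shape,
            )
            rows.append(
                {
                    "tech_id": profile.tech_id,
                    "crop": profile.crop,
                    "bcr": outcome.bcr,
                    "poverty_reduction": -outcome.poverty_change,
                    "malnutrition_change": self._nutrition_criterion(profile),
                }
            )
        return pd.DataFrame(rows).set_index("tech_id")

    def weights(self) -> CriteriaWeights:
        if self.fixed_weights is not None:
            return self.fixed_weights
        ratios = indicator_ratios(self.region, self.reference)
        return derive_criteria_weights(ratios)

    def fit(self) -> "AssessmentResults":
        """Evaluate all criteria, derive weights, run TOPSIS."""
        table = self.criteria_table()
        weights = self.weights()
        matrix = DecisionMatrix(
            tech_ids=tuple(table.index),
            a=tuple(
                (row.bcr, row.poverty_reduction, row.malnutrition_change)
                for row in table.itertuples()
            ),
        )
        return AssessmentResults(self, table, weights, matrix, topsis(matrix, weights))


def _default_population() -> float:
    from .synthetic import DEFAULT_NUTRITION_BASELINE

    return DEFAULT_NUTRITION_BASELINE["population"]


class AssessmentResults:
    """Fitted assessment: criterion values, weights, TOPSIS trace, ranking."""

    def __init__(
        self,
        model: ExAnteModel,
        criteria: pd.DataFrame,
        weights: CriteriaWeights,
        matrix: DecisionMatrix,
        topsis_result: TopsisResult,
    ) -> None:
        self.model = model
        self.criteria = criteria
        self.weights = weights
        self.decision_matrix = matrix
        self.topsis = topsis_result

    # ---- views ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: criterion values, per-criterion ranks, closeness
        index and final rank, ordered by final rank."""
        df = self.criteria.copy()
        # per-criterion competition ranks; malnutrition: more negative = better
        df["rank_bcr"] = _competition_rank(df["bcr"].to_numpy())
        df["rank_poverty"] = _competition_rank(df["poverty_reduction"].to_numpy())
        df["rank_nutrition"] = _competition_rank(-df["malnutrition_change"].to_numpy())
        df["closeness"] = self.topsis.closeness
        df["rank"] = self.topsis.rank
        return df.sort_values(["rank", "closeness"], ascending=[True, False])

    def summary(self) -> str:
        """Human-readable report of weights and the ranked technologies."""
        w = self.weights
        df = self.to_frame()
        lines = [
            "Ex-ante multi-criteria technology assessment",
            "=" * 60,
            f"Environment:    {self.model.macro.environment}",
            f"Technologies:   {len(df)}",
            f"Horizon:        {self.model.horizon} years  "
            f"(discount rate {self.model.discount_rate:.0%})",
            f"Weights:        BCR {w.w_bcr:.2f} | poverty {w.w_poverty:.2f} "
            f"| nutrition {w.w_nutrition:.2f}",
            "",
            df.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_report(self, precision: int | None = None, **metadata) -> dict:
        """JSON-ready report: per-technology record plus run metadata."""
        if precision is None:
            precision = 4
        df = self.to_frame().round(precision)
        return {
            "environment": self.model.macro.environment,
            "weights": {
                "bcr": round(self.weights.w_bcr, precision),
                "poverty": round(self.weights.w_poverty, precision),
                "nutrition": round(self.weights.w_nutrition, precision),
            },
            "technologies": df.reset_index().to_dict(orient="records"),
            "metadata": {"version": _version(), **metadata},
        }

    # ---- sensitivity ----------------------------------------------------

    def rerank(self, weights: CriteriaWeights) -> TopsisResult:
        """Re-run only the TOPSIS stage under different criteria weights."""
        return topsis(self.decision_matrix, weights)

    def sensitivity(self, weight_grid: Sequence[CriteriaWeights]) -> pd.DataFrame:
        """Rank trajectories across a grid of weight vectors.

        Returns one row per technology with a rank column per weighting
        (labelled by the weight triple).
        """
        if not weight_grid:
            raise ValueError("empty weight grid")
        out = pd.DataFrame(index=pd.Index(self.topsis.tech_ids, name="tech_id"))
        for w in weight_grid:
            res = self.rerank(w)
            label = f"w=({w.w_bcr:.2f},{w.w_poverty:.2f},{w.w_nutrition:.2f})"
            out[label] = res.rank
        return out

    # ---- plotting -------------------------------------------------------

    def plot_closeness(self, ax=None):
        """Horizontal bar chart of closeness indices, best technology on top."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.35 * len(self.topsis.tech_ids) + 1))
        df = self.to_frame().sort_values("closeness")
        ax.barh(df.index, df["closeness"], color="tab:green")
        ax.set_xlabel("closeness index $C^+$")
        ax.set_xlim(0, 1)
        ax.set_title(f"TOPSIS ranking — {self.model.macro.environment}")
        return ax


def _competition_rank(values: np.ndarray) -> np.ndarray:
    """Descending competition ranks (ties share the minimum rank)."""
    return 1 + np.sum(values[None, :] > values[:, None], axis=1)


def _version() -> str:
    from . import __version__

    return __version__
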