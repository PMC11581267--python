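"""Readers, writers and run configuration.

All tabular interfaces are plain CSV with one header row whose column names
match the domain-type field names; configuration is YAML (or JSON — YAML is
a superset here).  Read errors name the file, row and field involved.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .nutrition import DEFAULT_KCAL_PER_TONNE
from .types import (
    CountryBaseline,
    EnvironmentMacro,
    IndicatorSet,
    NutritionCoefficients,
    NutritionPath,
    TechnologyProfile,
)

__all__ = [
    "RunConfig",
    "load_config",
    "read_technologies",
    "write_technologies",
    "read_macro",
    "write_macro",
    "read_nutrition_covariates",
    "write_nutrition_covariates",
    "read_indicators",
    "write_indicators",
    "write_fixture",
    "config_hash",
]

TECH_COLUMNS = [
    "tech_id", "crop", "environment", "yield_gain", "cost_change",
    "prob_success", "max_adoption", "years_to_max", "release_lag",
    "research_cost_per_year", "research_years", "dissemination_cost_per_ha",
]
MACRO_COLUMNS = [
    "environment", "country", "production", "area", "price",
    "supply_elasticity", "demand_elasticity", "ag_gdp", "poor_count",
    "poverty_elasticity",
]
NUTRITION_COLUMNS = ["year", "pckcal", "lfexp_ratio", "schl", "water", "popc"]
INDICATOR_COLUMNS = ["region", "ag_gdp_share", "poverty_headcount", "child_stunting"]


class NutritionConfig(BaseModel):
    """Nutrition-stage settings not carried by the covariate CSV."""

    model_config = ConfigDict(frozen=True)

    pmc0: float = Field(ge=0.0, le=100.0)
    population: float = Field(gt=0.0)
    kcal_per_tonne: float = Field(default=DEFAULT_KCAL_PER_TONNE, gt=0.0)
    coefficients: NutritionCoefficients = NutritionCoefficients()


class RunConfig(BaseModel):
    """Everything one ranking run needs: input paths and model settings."""

    model_config = ConfigDict(frozen=True)

    technologies: Path
    macro: Path
    nutrition_covariates: Path
    indicators: Path
    region: str
    reference_region: str
    horizon: int = Field(default=25, ge=1)
    discount_rate: float = Field(default=0.10, ge=0.0)
    adoption_shape: str = "linear"
    nutrition: NutritionConfig
    report_precision: int = Field(default=4, ge=0)
    seed: int = 0

    def resolve(self, base: Path) -> "RunConfig":
        """Resolve relative input paths against ``base``."""
        upd = {
            f: (base / getattr(self, f))
            for f in ("technologies", "macro", "nutrition_covariates", "indicators")
            if not Path(getattr(self, f)).is_absolute()
        }
        return self.model_copy(update=upd) if upd else self


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration; relative paths resolve against the
    config file's directory."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"invalid run config {path}: {exc}") from exc
    return cfg.resolve(path.parent)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a run configuration, for report metadata."""
    payload = cfg.model_dump(mode="json")
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:12]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _validate_rows(df: pd.DataFrame, model: type[BaseModel], path: Path | str) -> list[Any]:
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(model.model_validate(row.to_dict()))
        except ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(p) for p in first["loc"]) or "?"
            raise ValueError(
                f"{path}, row {idx + 2}, field {field!r}: {first['msg']}"
            ) from exc
    return out


def read_technologies(path: str | Path) -> list[TechnologyProfile]:
    df = _read_csv(path, TECH_COLUMNS)
    return _validate_rows(df[TECH_COLUMNS], TechnologyProfile, path)


def write_technologies(profiles: Iterable[TechnologyProfile], path: str | Path) -> None:
    pd.DataFrame([p.model_dump() for p in profiles])[TECH_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_macro(path: str | Path, environment: str | None = None) -> EnvironmentMacro:
    df = _read_csv(path, MACRO_COLUMNS)
    envs = df["environment"].unique()
    if environment is None:
        if len(envs) != 1:
            raise ValueError(
                f"{path}: multiple environments {list(envs)}; pass one explicitly"
            )
        environment = envs[0]
    sub = df[df["environment"] == environment]
    if sub.empty:
        raise ValueError(f"{path}: no rows for environment {environment!r}")
    countries = _validate_rows(
        sub[MACRO_COLUMNS].drop(columns="environment"), CountryBaseline, path
    )
    return EnvironmentMacro(environment=environment, countries=tuple(countries))


def write_macro(macro: EnvironmentMacro, path: str | Path) -> None:
    rows = [
        {"environment": macro.environment, **c.model_dump()} for c in macro.countries
    ]
    pd.DataFrame(rows)[MACRO_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_nutrition_covariates(path: str | Path, pmc0: float) -> NutritionPath:
    df = _read_csv(path, NUTRITION_COLUMNS).sort_values("year")
    try:
        return NutritionPath(
            years=tuple(int(y) for y in df["year"]),
            pckcal=tuple(df["pckcal"]),
            lfexp_ratio=tuple(df["lfexp_ratio"]),
            schl=tuple(df["schl"]),
            water=tuple(df["water"]),
            popc=tuple(df["popc"]),
            pmc0=pmc0,
        )
    except ValidationError as exc:
        raise ValueError(f"{path}: {exc.errors()[0]['msg']}") from exc


def write_nutrition_covariates(path_obj: NutritionPath, path: str | Path) -> None:
    pd.DataFrame(
        {
            "year": path_obj.years,
            "pckcal": path_obj.pckcal,
            "lfexp_ratio": path_obj.lfexp_ratio,
            "schl": path_obj.schl,
            "water": path_obj.water,
            "popc": path_obj.popc,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_indicators(path: str | Path) -> dict[str, IndicatorSet]:
    df = _read_csv(path, INDICATOR_COLUMNS)
    rows = _validate_rows(df[INDICATOR_COLUMNS], IndicatorSet, path)
    return {r.region: r for r in rows}


def write_indicators(indicators: Iterable[IndicatorSet], path: str | Path) -> None:
    pd.DataFrame([i.model_dump() for i in indicators])[INDICATOR_COLUMNS].to_csv(
        path, index=False, float_format="%.17g"
    )


#: published 2014/16-2015 indicator rows for one dryland region and its
#: reference region (percent): AgGDP share, poverty headcount, child stunting
FIXTURE_INDICATORS = (
    IndicatorSet(
        region="semi-arid-west-central-africa",
        ag_gdp_share=22.0,
        poverty_headcount=46.0,
        child_stunting=39.0,
    ),
    IndicatorSet(
        region="sub-saharan-africa",
        ag_gdp_share=16.0,
        poverty_headcount=47.0,
        child_stunting=33.0,
    ),
)


def write_fixture(outdir: str | Path, cfg: "GeneratorConfig | None" = None, horizon: int = 25) -> RunConfig:
    """Write a complete toy study (tables + run config) to ``outdir``.

    Defaults to the 12-technology, 3-country seeded study with the published
    cowpea exemplar first and the semi-arid West-and-Central-Africa indicator
    rows.  Returns the run configuration (also written as config.yaml).
    """
    from .synthetic import GeneratorConfig, generate_study

    if cfg is None:
        cfg = GeneratorConfig(seed=0)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    technologies, macro, nutrition = generate_study(cfg, horizon)
    write_technologies(technologies, outdir / "technologies.csv")
    write_macro(macro, outdir / "macro.csv")
    write_nutrition_covariates(nutrition, outdir / "nutrition.csv")
    write_indicators(FIXTURE_INDICATORS, outdir / "indicators.csv")
    run_cfg = RunConfig(
        technologies=outdir / "technologies.csv",
        macro=outdir / "macro.csv",
        nutrition_covariates=outdir / "nutrition.csv",
        indicators=outdir / "indicators.csv",
        region=FIXTURE_INDICATORS[0].region,
        reference_region=FIXTURE_INDICATORS[1].region,
        horizon=horizon,
        nutrition=NutritionConfig(
            pmc0=cfg.nutrition_baseline["pmc0"],
            population=cfg.nutrition_baseline["population"],
        ),
        seed=cfg.seed,
    )
    payload = run_cfg.model_dump(mode="json")
    # store paths relative to the config file for a relocatable fixture
    for key in ("technologies", "macro", "nutrition_covariates", "indicators"):
        payload[key] = Path(payload[key]).name
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return run_cfg
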