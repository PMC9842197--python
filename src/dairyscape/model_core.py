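"""Domain state types and the yearly scheduler.

One model tick is one calendar year.  Each year the twelve submodels run in a
fixed order: farms first decide whether to quit, released land is reallocated
on the tenure market, farms adapt management intensity and land use, herds and
production follow, manure is traded and spread, milk is sold, the government
levies taxes, pays subsidies and inspects nitrogen compliance, and finally the
books are settled.  Milk producer prices for the year are drawn (log-normally
around their means) before the first submodel so that all within-year
decisions see current prices.

State-variable counting convention: immutable identifiers and geometry
(``farm_id``, ``field_id``, field ``x``/``y``, the farmstead location) and
bookkeeping caches derivable from history (``loss_streak``,
``years_since_switch``) are not state variables.  The canonical state-variable
registries (`FARM_STATE_VARS`, `FIELD_STATE_VARS`, `GOVERNANCE_STATE_VARS`)
hold exactly 7, 8 and 14 names.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dfield
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .params import (
    INTERFACE_SETTING_NAMES,
    PRESET_PARAM_NAMES,
    InterfaceSettings,
    ModelParams,
)


class IntensityClass(enum.IntEnum):
    """Management intensity, ordered from very extensive (1) to very intensive (4).

    Classes 1-2 sell at the organic milk price, classes 3-4 at the
    conventional price.
    """

    VERY_EXTENSIVE = 1
    EXTENSIVE = 2
    INTENSIVE = 3
    VERY_INTENSIVE = 4

    @property
    def organic(self) -> bool:
        return self <= IntensityClass.EXTENSIVE


FARM_STATE_VARS: tuple[str, ...] = (
    "intensity",
    "n_cows",
    "liquidity",
    "profit_last_year",
    "milk_output",
    "fields_held",
    "active",
)

FIELD_STATE_VARS: tuple[str, ...] = (
    "owner",
    "land_use",
    "soil_fertility",
    "norg_applied",
    "fodder_yield",
    "habitat_index",
    "area",
    "tenure",
)

GOVERNANCE_STATE_VARS: tuple[str, ...] = (
    "ghg_tax_rate",
    "nitrate_tax_rate",
    "subsidy_base",
    "subsidy_extensive_bonus",
    "conversion_ban",
    "norg_limit",
    "norg_deduction_fraction",
    "norg_check_fraction",
    "milk_price_conventional",
    "milk_price_organic",
    "subsidies_paid",
    "tax_revenue",
    "n_farms_checked",
    "net_spending",
)

LAND_USES = ("grassland", "arable", "fallow")
TENURES = ("owned", "rented")


@dataclass
class FarmState:
    """One dairy farm agent."""

    farm_id: int
    intensity: IntensityClass
    home_xy: tuple[float, float]
    n_cows: int = 0
    liquidity: float = 0.0
    profit_last_year: float = 0.0
    milk_output: float = 0.0
    fields_held: set[int] = dfield(default_factory=set)
    active: bool = True
    # bookkeeping caches (derivable from history, not counted as state vars)
    loss_streak: int = 0
    years_since_switch: int = 0


@dataclass
class FieldState:
    """One agricultural field patch."""

    field_id: int
    x: float
    y: float
    owner: int | None
    land_use: str
    soil_fertility: float
    area: float
    norg_applied: float = 0.0
    fodder_yield: float = 0.0
    habitat_index: float = 1.0
    tenure: str = "owned"


@dataclass
class GovernanceState:
    """Policy levers, current-year price draws and fiscal accumulators."""

    ghg_tax_rate: float = 0.0
    nitrate_tax_rate: float = 0.0
    subsidy_base: float = 0.0
    subsidy_extensive_bonus: float = 0.0
    conversion_ban: bool = False
    norg_limit: float = 170.0
    norg_deduction_fraction: float = 0.0
    norg_check_fraction: float = 0.0
    milk_price_conventional: float = 0.0
    milk_price_organic: float = 0.0
    subsidies_paid: float = 0.0
    tax_revenue: float = 0.0
    n_farms_checked: int = 0
    net_spending: float = 0.0


@dataclass
class WorldState:
    """Complete simulation state: fields, farms, governance and the RNG stream."""

    year: int
    fields: dict[int, FieldState]
    farms: dict[int, FarmState]
    governance: GovernanceState
    rng: np.random.Generator
    params: ModelParams
    settings: InterfaceSettings
    es_norms: dict[str, float]
    records: list["ReporterRecord"] = dfield(default_factory=list)
    scratch: dict[str, Any] = dfield(default_factory=dict)

    def total_area(self) -> float:
        return sum(f.area for f in self.fields.values())

    def active_farms(self) -> list[FarmState]:
        return [f for fid, f in sorted(self.farms.items()) if f.active]


#: Fixed reporter CSV header, one row per simulated year.
REPORTER_COLUMNS: tuple[str, ...] = (
    "year",
    "es_climate_regulation",
    "es_soil_fertility",
    "es_habitat_provisioning",
    "es_water_quality",
    "es_food_provisioning",
    "es_joint",
    "es_regulating",
    "total_milk_t",
    "milk_intensive_t",
    "total_cows",
    "n_active_farms",
    "n_farms_class1",
    "n_farms_class2",
    "n_farms_class3",
    "n_farms_class4",
    "profit_per_ha_class1",
    "profit_per_ha_class2",
    "profit_per_ha_class3",
    "profit_per_ha_class4",
    "subsidies_paid_eur",
    "tax_revenue_eur",
    "net_spending_eur",
    "total_ghg_t",
    "total_n_surplus_kg",
    "grassland_ha",
    "arable_ha",
    "fallow_ha",
    "mean_soil_fertility",
)


@dataclass
class ReporterRecord:
    """Per-year model outputs (one row of the reporter table)."""

    year: int
    es_climate_regulation: float
    es_soil_fertility: float
    es_habitat_provisioning: float
    es_water_quality: float
    es_food_provisioning: float
    es_joint: float
    es_regulating: float
    total_milk_t: float
    milk_intensive_t: float
    total_cows: int
    n_active_farms: int
    n_farms_class1: int
    n_farms_class2: int
    n_farms_class3: int
    n_farms_class4: int
    profit_per_ha_class1: float
    profit_per_ha_class2: float
    profit_per_ha_class3: float
    profit_per_ha_class4: float
    subsidies_paid_eur: float
    tax_revenue_eur: float
    net_spending_eur: float
    total_ghg_t: float
    total_n_surplus_kg: float
    grassland_ha: float
    arable_ha: float
    fallow_ha: float
    mean_soil_fertility: float


def records_to_frame(records: list[ReporterRecord]) -> pd.DataFrame:
    """Reporter records as a DataFrame with the fixed column order."""
    rows = [{c: getattr(r, c) for c in REPORTER_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=list(REPORTER_COLUMNS))


#: The twelve yearly submodels, in execution order.
SUBMODELS: tuple[str, ...] = (
    "exit_decision",
    "tenure_market",
    "intensity_adaptation",
    "land_use_change",
    "herd_update",
    "fodder_production",
    "manure_accrual",
    "manure_market",
    "nitrogen_application",
    "milk_production",
    "governance_accounts",
    "account_settlement",
)


def list_submodels() -> list[str]:
    """Names of the 12 yearly submodels in execution order."""
    return list(SUBMODELS)


def parameter_registry(
    params: ModelParams, settings: InterfaceSettings
) -> tuple[list[str], list[str]]:
    """The (pre-set, interface) parameter name lists — lengths (43, 5)."""
    del params, settings  # registries are fixed; arguments kept for symmetry
    return list(PRESET_PARAM_NAMES), list(INTERFACE_SETTING_NAMES)


def init_model(
    params: ModelParams,
    settings: InterfaceSettings,
    seed: int,
    lever_overrides: dict[str, Any] | None = None,
) -> WorldState:
    """Build a year-0 world from parameters, interface settings and a seed.

    ``lever_overrides`` set governance lever fields directly, on top of the
    preset bindings (levers compose; presets are sugar).
    """
    from . import ecosystem_services, governance, world_builder

    if len(PRESET_PARAM_NAMES) != 43 or len(params.as_dict()) != 43:
        raise ConfigurationError("pre-set registry must hold exactly 43 parameters")
    if len(INTERFACE_SETTING_NAMES) != 5:
        raise ConfigurationError("interface registry must hold exactly 5 settings")

    rng = np.random.default_rng(seed)
    if settings.world_setup == "random":
        fields, farms = world_builder.build_random_world(params, rng)
    else:
        if not settings.world_file:
            raise InputError("world_setup='from_file' requires a world_file path")
        fields, farms = world_builder.load_world_file(settings.world_file, params)

    gov = governance.apply_preset(settings, params)
    for name, value in (lever_overrides or {}).items():
        if name not in governance.LEVER_NAMES:
            raise ConfigurationError(f"unknown governance lever {name!r}")
        setattr(gov, name, bool(value) if name == "conversion_ban" else float(value))
    gov.milk_price_conventional = params.milk_price_conventional_mean
    gov.milk_price_organic = params.milk_price_organic_mean

    norms = ecosystem_services.compute_normalizers(fields, params)
    return WorldState(
        year=0,
        fields=fields,
        farms=farms,
        governance=gov,
        rng=rng,
        params=params,
        settings=settings,
        es_norms=norms,
    )


def step_year(world: WorldState) -> WorldState:
    """Run one full annual cycle in place; append the year's reporter record."""
    from . import annual_cycle, ecosystem_services

    world.scratch = {}
    annual_cycle.draw_milk_prices(world.governance, world.params, world.rng)
    for name in SUBMODELS:
        getattr(annual_cycle, name)(world)
    world.year += 1
    es = ecosystem_services.es_vector(world)
    world.records.append(_make_record(world, es))
    return world


def run(world: WorldState, n_years: int) -> list[ReporterRecord]:
    """Simulate ``n_years`` annual cycles; return the reporter records (years 1..n)."""
    if n_years < 0:
        raise InputError(f"n_years must be >= 0, got {n_years}")
    for _ in range(n_years):
        step_year(world)
    return list(world.records[-n_years:]) if n_years else []


def simulate(
    params: ModelParams | None = None,
    settings: InterfaceSettings | None = None,
    seed: int = 0,
    n_years: int = 30,
    lever_overrides: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: init, run, and return the reporter table."""
    world = init_model(
        params or ModelParams(), settings or InterfaceSettings(), seed, lever_overrides
    )
    return records_to_frame(run(world, n_years))


def _make_record(world: WorldState, es) -> ReporterRecord:
    from .ecosystem_services import joint_es_index, regulating_es_index

    farms = world.active_farms()
    statements = world.scratch.get("statements", {})
    class_counts = {lvl: 0 for lvl in (1, 2, 3, 4)}
    class_profit: dict[int, list[float]] = {lvl: [] for lvl in (1, 2, 3, 4)}
    for farm in farms:
        class_counts[int(farm.intensity)] += 1
        area = sum(world.fields[fid].area for fid in farm.fields_held)
        stmt = statements.get(farm.farm_id)
        if stmt is not None and area > 0:
            class_profit[int(farm.intensity)].append(stmt.profit / area)

    milk_total = sum(f.milk_output for f in farms)
    milk_intensive = sum(f.milk_output for f in farms if f.intensity >= 3)
    by_use = {use: 0.0 for use in LAND_USES}
    fert_weighted = 0.0
    for fld in world.fields.values():
        by_use[fld.land_use] += fld.area
        fert_weighted += fld.soil_fertility * fld.area
    total_area = world.total_area()

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    return ReporterRecord(
        year=world.year,
        es_climate_regulation=es.climate_regulation,
        es_soil_fertility=es.soil_fertility,
        es_habitat_provisioning=es.habitat_provisioning,
        es_water_quality=es.water_quality,
        es_food_provisioning=es.food_provisioning,
        es_joint=joint_es_index(es),
        es_regulating=regulating_es_index(es),
        total_milk_t=milk_total,
        milk_intensive_t=milk_intensive,
        total_cows=sum(f.n_cows for f in farms),
        n_active_farms=len(farms),
        n_farms_class1=class_counts[1],
        n_farms_class2=class_counts[2],
        n_farms_class3=class_counts[3],
        n_farms_class4=class_counts[4],
        profit_per_ha_class1=_mean(class_profit[1]),
        profit_per_ha_class2=_mean(class_profit[2]),
        profit_per_ha_class3=_mean(class_profit[3]),
        profit_per_ha_class4=_mean(class_profit[4]),
        subsidies_paid_eur=world.governance.subsidies_paid,
        tax_revenue_eur=world.governance.tax_revenue,
        net_spending_eur=world.governance.net_spending,
        total_ghg_t=world.scratch.get("total_ghg", 0.0),
        total_n_surplus_kg=world.scratch.get("total_n_surplus", 0.0),
        grassland_ha=by_use["grassland"],
        arable_ha=by_use["arable"],
        fallow_ha=by_use["fallow"],
        mean_soil_fertility=fert_weighted / total_area if total_area else 0.0,
    )
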