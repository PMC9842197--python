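"""Policy levers, taxes, subsidies, nitrogen inspections and fiscal accounts.

Five substantive policy instruments exist — a GHG tax, a nitrate tax, a
subsidy bonus for extensive grassland, a grassland-conversion ban, and an
organic-nitrogen (Norg) limit enforced by random farm inspections.  Presets
bind the three interface sliders to lever fields; levers can also be set
directly and freely combined (presets are pure sugar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .model_core import FarmState, GovernanceState, WorldState
from .params import InterfaceSettings, ModelParams

#: Preset names: 5 single-policy presets plus 'none' and 'combined'.
PRESET_NAMES = (
    "none",
    "ghg_tax",
    "nitrate_tax",
    "extensive_subsidy",
    "conversion_ban",
    "norg_limit",
    "combined",
)
SINGLE_POLICY_PRESETS = ("ghg_tax", "nitrate_tax", "extensive_subsidy",
                         "conversion_ban", "norg_limit")

#: Governance lever fields settable directly (bypassing presets).
LEVER_NAMES = (
    "ghg_tax_rate",
    "nitrate_tax_rate",
    "subsidy_base",
    "subsidy_extensive_bonus",
    "conversion_ban",
    "norg_limit",
    "norg_deduction_fraction",
    "norg_check_fraction",
)


@dataclass(frozen=True)
class SliderBinding:
    lever: str
    lo: float
    hi: float


#: Documented slider semantics per preset: slider name -> lever and range.
PRESET_BINDINGS: dict[str, dict[str, SliderBinding]] = {
    "none": {},
    "ghg_tax": {"policy_param_a": SliderBinding("ghg_tax_rate", 0.0, 500.0)},
    "nitrate_tax": {"policy_param_a": SliderBinding("nitrate_tax_rate", 0.0, 50.0)},
    "extensive_subsidy": {
        "policy_param_a": SliderBinding("subsidy_extensive_bonus", 0.0, 1000.0)
    },
    "conversion_ban": {},  # no sliders; the ban is simply switched on
    "norg_limit": {
        "policy_param_a": SliderBinding("norg_limit", 0.0, 500.0),
        "policy_param_b": SliderBinding("norg_deduction_fraction", 0.0, 1.0),
        "policy_param_c": SliderBinding("norg_check_fraction", 0.0, 1.0),
    },
    "combined": {
        "policy_param_a": SliderBinding("ghg_tax_rate", 0.0, 500.0),
        "policy_param_b": SliderBinding("subsidy_extensive_bonus", 0.0, 1000.0),
        "policy_param_c": SliderBinding("norg_check_fraction", 0.0, 1.0),
    },
}


def apply_preset(settings: InterfaceSettings, params: ModelParams) -> GovernanceState:
    """Build a GovernanceState with levers set from the preset's slider bindings.

    All levers not bound by the preset stay neutral: zero tax rates, zero
    bonus, no ban, and a Norg limit at the uptake threshold with zero check
    fraction (so it has no effect until checks are enabled).
    """
    if settings.policy_preset not in PRESET_NAMES:
        raise ConfigurationError(
            f"unknown policy preset {settings.policy_preset!r}; "
            f"valid: {PRESET_NAMES}"
        )
    gov = GovernanceState(
        subsidy_base=params.subsidy_base,
        norg_limit=params.n_uptake_threshold,
        milk_price_conventional=params.milk_price_conventional_mean,
        milk_price_organic=params.milk_price_organic_mean,
    )
    if settings.policy_preset == "conversion_ban":
        gov.conversion_ban = True
    if settings.policy_preset == "combined":
        gov.conversion_ban = True
        gov.norg_deduction_fraction = 0.5
    for slider, binding in PRESET_BINDINGS[settings.policy_preset].items():
        value = float(getattr(settings, slider))
        if not binding.lo <= value <= binding.hi:
            raise ConfigurationError(
                f"{slider}={value} outside [{binding.lo}, {binding.hi}] "
                f"for preset {settings.policy_preset!r} ({binding.lever})"
            )
        setattr(gov, binding.lever, value)
    return gov


def compute_ghg_tax(emissions: float, rate: float) -> float:
    """Tax (EUR) on ``emissions`` t CO2-eq at ``rate`` EUR/t."""
    if emissions < 0 or rate < 0:
        raise ValueError("emissions and rate must be non-negative")
    return emissions * rate


def compute_nitrate_tax(n_surplus: float, rate: float) -> float:
    """Tax (EUR) on nitrogen applied beyond the uptake threshold (kg N)."""
    if n_surplus < 0 or rate < 0:
        raise ValueError("surplus and rate must be non-negative")
    return n_surplus * rate


def compute_subsidies(
    farm: FarmState, world: WorldState, governance: GovernanceState
) -> float:
    """Area payment plus the extensive-grassland bonus for classes 1-2."""
    if not farm.active:
        return 0.0
    from .annual_cycle import farm_area

    total_ha = farm_area(world, farm)
    amount = governance.subsidy_base * total_ha
    if farm.intensity.organic:
        amount += governance.subsidy_extensive_bonus * farm_area(
            world, farm, "grassland"
        )
    return amount


def norg_inspection(
    world: WorldState,
    governance: GovernanceState,
    rng: np.random.Generator,
    subsidies_by_farm: dict[int, float],
) -> dict[int, float]:
    """Inspect a random share of farms; over-limit farms lose part of their subsidies.

    ``floor(check_fraction * n_active)`` farms are sampled uniformly without
    replacement.  A sampled farm whose mean applied Norg per hectare exceeds
    the limit is deducted ``deduction_fraction`` of its subsidies (never more
    than the subsidies themselves).  When the sample is empty the RNG is not
    consumed.
    """
    active_ids = sorted(f.farm_id for f in world.active_farms())
    k = int(math.floor(governance.norg_check_fraction * len(active_ids)))
    if k <= 0:
        return {}
    sampled = rng.choice(np.array(active_ids), size=k, replace=False)
    governance.n_farms_checked += k
    n_rate = world.scratch.get("n_rate", {})
    deductions: dict[int, float] = {}
    for farm_id in sorted(int(i) for i in sampled):
        if n_rate.get(farm_id, 0.0) > governance.norg_limit:
            sub = subsidies_by_farm.get(farm_id, 0.0)
            deductions[farm_id] = min(
                governance.norg_deduction_fraction * sub, sub
            )
    return deductions


def fiscal_update(
    governance: GovernanceState, taxes: float, subsidies: float
) -> GovernanceState:
    """Accumulate fiscal flows; maintain net_spending = subsidies - taxes."""
    if taxes < 0 or subsidies < 0:
        raise ValueError("fiscal flows must be non-negative")
    governance.tax_revenue += taxes
    governance.subsidies_paid += subsidies
    governance.net_spending = governance.subsidies_paid - governance.tax_revenue
    return governance
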