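"""The twelve yearly submodels: farm decisions, markets, production, accounts.

Each submodel has two layers: a pure, unit-testable core operating on single
farms/fields or explicit supply/demand maps, and a thin ``<submodel>(world)``
wrapper that the scheduler dispatches by name (see
:data:`dairyscape.model_core.SUBMODELS`).  All iteration over farms and fields
is in ascending key order and every tie-break is explicit, so a run is a pure
function of (parameters, settings, seed).

Structural constants
--------------------
A few quantities are fixed model structure rather than registry parameters:

``HERD_SOIL_FLOOR``
    Herds scale with ``0.5 + 0.5 * fertility`` of the farm's grassland: even
    degraded grass supports half the nominal stocking rate.
``ARABLE_MARGIN_PER_HA``
    Gross margin of cash cropping (EUR/ha/yr) against which intensive farms
    weigh grassland-to-arable conversion.
``MAX_CONVERSION_FRACTION``
    Share of a farm's grassland convertible to arable per year (whole fields;
    at least one field converts in a profitable year).
``ARABLE_HABITAT_INDEX`` / ``FALLOW_HABITAT_INDEX``
    Habitat value of cropped and abandoned fields.
``FODDER_PER_COW_T``
    Dry-matter intake of one cow (t/yr), converting supported stocking into
    field fodder yield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AccountingError
from .model_core import (
    FarmState,
    FieldState,
    GovernanceState,
    IntensityClass,
    WorldState,
)
from .params import ModelParams
from .world_builder import NEIGHBOR_DISTANCE

HERD_SOIL_FLOOR = 0.5
ARABLE_MARGIN_PER_HA = 1800.0
MAX_CONVERSION_FRACTION = 0.1
ARABLE_HABITAT_INDEX = 0.05
FALLOW_HABITAT_INDEX = 1.0
FODDER_PER_COW_T = 5.0


@dataclass(frozen=True)
class ManureTransfer:
    """One manure-market transaction (buyer pays seller ``amount * price``)."""

    seller: int
    buyer: int
    amount: float  # kg N
    price: float  # EUR/kg N

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("transfer amount must be positive")
        if self.seller == self.buyer:
            raise ValueError("seller and buyer must differ")


@dataclass
class ProfitStatement:
    """A farm's yearly books; ``profit`` must satisfy the balance identity."""

    milk_revenue: float = 0.0
    subsidies: float = 0.0
    variable_costs: float = 0.0
    fixed_costs: float = 0.0
    rent: float = 0.0
    taxes: float = 0.0
    deductions: float = 0.0
    manure_trade_net: float = 0.0
    profit: float = 0.0

    def balance(self) -> float:
        return (
            self.milk_revenue
            + self.subsidies
            + self.manure_trade_net
            - self.variable_costs
            - self.fixed_costs
            - self.rent
            - self.taxes
            - self.deductions
        )

    def consistent(self, tol: float = 1e-6) -> bool:
        scale = max(1.0, abs(self.milk_revenue), abs(self.profit))
        return abs(self.profit - self.balance()) <= tol * scale


# ---------------------------------------------------------------------------
# shared farm/field helpers

def herd_factor(fertility: float) -> float:
    """Stocking multiplier from grassland fertility: 0.5 at fertility 0, 1 at 1."""
    return HERD_SOIL_FLOOR + (1.0 - HERD_SOIL_FLOOR) * fertility


def farm_fields(world: WorldState, farm: FarmState) -> list[FieldState]:
    return [world.fields[fid] for fid in sorted(farm.fields_held)]


def farm_area(world: WorldState, farm: FarmState, land_use: str | None = None) -> float:
    return sum(
        f.area
        for f in farm_fields(world, farm)
        if land_use is None or f.land_use == land_use
    )


def mean_grass_fertility(world: WorldState, farm: FarmState) -> float:
    """Area-weighted fertility of the farm's grassland (1.0 if it holds none)."""
    area = fert = 0.0
    for f in farm_fields(world, farm):
        if f.land_use == "grassland":
            area += f.area
            fert += f.soil_fertility * f.area
    return fert / area if area > 0 else 1.0


def expected_margin_per_ha(
    world: WorldState, farm: FarmState, cls: IntensityClass
) -> float:
    """Myopic expected profit per grassland hectare at class ``cls``.

    Uses current-year prices and policy levers; ignores fixed costs (sunk at
    the margin) and assumes the farm's own manure stays on-farm, so expected
    taxes and inspection penalties enter the comparison even where trading
    could later offload the surplus.
    """
    p = world.params
    gov = world.governance
    cls = IntensityClass(cls)
    f = herd_factor(mean_grass_fertility(world, farm))
    cows_per_ha = p.per_class("stocking_rate")[int(cls)] * f
    price = gov.milk_price_organic if cls.organic else gov.milk_price_conventional
    milk_margin = cows_per_ha * (
        p.per_class("milk_yield")[int(cls)] * price
        - p.per_class("variable_cost")[int(cls)]
    )
    subsidy = gov.subsidy_base + (gov.subsidy_extensive_bonus if cls.organic else 0.0)
    ghg_tax = cows_per_ha * p.per_class("ghg_per_cow")[int(cls)] * gov.ghg_tax_rate
    n_rate = cows_per_ha * p.manure_n_per_cow
    nitrate_tax = max(0.0, n_rate - p.n_uptake_threshold) * gov.nitrate_tax_rate
    norg_penalty = 0.0
    if n_rate > gov.norg_limit:
        norg_penalty = (
            gov.norg_check_fraction * gov.norg_deduction_fraction * subsidy
        )
    return milk_margin + subsidy - ghg_tax - nitrate_tax - norg_penalty


# ---------------------------------------------------------------------------
# submodel 1: exit decision

def decide_exit(farm: FarmState, params: ModelParams) -> bool:
    """True iff liquidity fell below the exit floor or losses ran too long."""
    return (
        farm.liquidity < params.exit_liquidity_threshold
        or farm.loss_streak >= params.max_loss_years
    )


def exit_decision(world: WorldState) -> None:
    released: list[int] = []
    for farm in world.active_farms():
        if decide_exit(farm, world.params):
            farm.active = False
            farm.n_cows = 0
            farm.milk_output = 0.0
            for fid in sorted(farm.fields_held):
                world.fields[fid].owner = None
                released.append(fid)
            farm.fields_held = set()
    world.scratch["released"] = sorted(released)


# ---------------------------------------------------------------------------
# submodel 2: land tenure market

def tenure_market(world: WorldState) -> WorldState:
    """Reallocate fields released by exits; unclaimed fields fall fallow.

    Single clearing round: adjacency is snapshotted at market opening, each
    offered field goes to the highest bidder among active farms holding an
    adjacent field whose expected margin exceeds the rent.  Ties break by
    farmstead distance, then lower farm key.  Winners hold the field as
    rented land.
    """
    offered = world.scratch.get("released", [])
    if not offered:
        return world
    holdings = {
        farm.farm_id: set(farm.fields_held) for farm in world.active_farms()
    }
    bids = {
        farm.farm_id: expected_margin_per_ha(world, farm, farm.intensity)
        for farm in world.active_farms()
    }
    for fid in offered:
        fld = world.fields[fid]
        best = None  # (bid, -distance, -farm_id) maximized
        for farm in world.active_farms():
            if bids[farm.farm_id] <= world.params.land_rent:
                continue
            near = any(
                math.hypot(world.fields[h].x - fld.x, world.fields[h].y - fld.y)
                <= NEIGHBOR_DISTANCE + 1e-9
                for h in holdings[farm.farm_id]
            )
            if not near:
                continue
            hx, hy = farm.home_xy
            key = (bids[farm.farm_id], -math.hypot(hx - fld.x, hy - fld.y), -farm.farm_id)
            if best is None or key > best[0]:
                best = (key, farm.farm_id)
        if best is not None:
            winner = world.farms[best[1]]
            fld.owner = winner.farm_id
            fld.tenure = "rented"
            winner.fields_held.add(fid)
        else:
            fld.owner = None
            fld.land_use = "fallow"
            fld.habitat_index = FALLOW_HABITAT_INDEX
            fld.norg_applied = 0.0
            fld.fodder_yield = 0.0
            fld.tenure = "owned"
    return world


# ---------------------------------------------------------------------------
# submodel 3: intensity adaptation

def adapt_intensity(farm: FarmState, world: WorldState) -> IntensityClass:
    """Switch to the most profitable class if the gain beats conversion cost.

    Ties keep the current class; switching resets the inertia clock.
    """
    p = world.params
    farm.years_since_switch += 1
    if farm.years_since_switch < p.intensity_switch_inertia:
        return farm.intensity
    margins = {
        cls: expected_margin_per_ha(world, farm, cls) for cls in IntensityClass
    }
    best = max(margins, key=lambda c: (margins[c], -int(c)))
    if best != farm.intensity and margins[best] - margins[farm.intensity] > p.conversion_cost:
        farm.intensity = best
        farm.years_since_switch = 0
    return farm.intensity


def intensity_adaptation(world: WorldState) -> None:
    habitat = world.params.per_class("habitat_index")
    for farm in world.active_farms():
        adapt_intensity(farm, world)
        for fld in farm_fields(world, farm):
            if fld.land_use == "grassland":
                fld.habitat_index = habitat[int(farm.intensity)]


# ---------------------------------------------------------------------------
# submodel 4: land-use change

def convert_land_use(world: WorldState) -> WorldState:
    """Intensive farms convert some grassland to arable when cropping pays.

    Blocked entirely while the conversion ban is active.  Candidates are the
    farm's least fertile grassland fields; the yearly converted area is
    bounded by ``MAX_CONVERSION_FRACTION`` of the farm's grassland (whole
    fields, at least one in a profitable year).
    """
    if world.governance.conversion_ban:
        return world
    p = world.params
    for farm in world.active_farms():
        if farm.intensity < IntensityClass.INTENSIVE:
            continue
        gain = ARABLE_MARGIN_PER_HA - expected_margin_per_ha(world, farm, farm.intensity)
        if gain <= p.conversion_cost:
            continue
        grass = [f for f in farm_fields(world, farm) if f.land_use == "grassland"]
        if not grass:
            continue
        budget = MAX_CONVERSION_FRACTION * sum(f.area for f in grass)
        grass.sort(key=lambda f: (f.soil_fertility, f.field_id))
        converted = 0.0
        for i, fld in enumerate(grass):
            if i > 0 and converted + fld.area > budget + 1e-9:
                break
            fld.land_use = "arable"
            fld.habitat_index = ARABLE_HABITAT_INDEX
            converted += fld.area
    return world


land_use_change = convert_land_use


# ---------------------------------------------------------------------------
# submodel 5: herd sizing

def update_herd(farm: FarmState, world: WorldState) -> int:
    """``floor(stocking_rate * grassland_ha * (0.5 + 0.5 * fertility))``."""
    p = world.params
    grass_ha = farm_area(world, farm, "grassland")
    f = herd_factor(mean_grass_fertility(world, farm))
    farm.n_cows = int(math.floor(p.per_class("stocking_rate")[int(farm.intensity)] * grass_ha * f))
    return farm.n_cows


def herd_update(world: WorldState) -> None:
    for farm in world.active_farms():
        update_herd(farm, world)


# ---------------------------------------------------------------------------
# submodel 6: fodder production

def produce_fodder(field: FieldState, intensity: IntensityClass, params: ModelParams) -> float:
    """Fodder yield (t dry matter): area x supported stocking x soil response.

    The yield-soil response parameter ``r`` splits yield into a fixed share
    ``1 - r`` and a share ``r`` scaling linearly with fertility.  Fallow
    fields yield nothing.
    """
    if field.land_use == "fallow" or field.owner is None:
        field.fodder_yield = 0.0
        return 0.0
    r = params.yield_soil_response
    rate = params.per_class("stocking_rate")[int(intensity)]
    field.fodder_yield = (
        FODDER_PER_COW_T * rate * field.area * ((1.0 - r) + r * field.soil_fertility)
    )
    return field.fodder_yield


def fodder_production(world: WorldState) -> None:
    for farm in world.active_farms():
        for fld in farm_fields(world, farm):
            produce_fodder(fld, farm.intensity, world.params)


# ---------------------------------------------------------------------------
# submodel 7: manure accrual

def accrue_manure(farm: FarmState, params: ModelParams) -> float:
    """Organic nitrogen produced by the herd (kg N)."""
    return farm.n_cows * params.manure_n_per_cow


def manure_accrual(world: WorldState) -> None:
    world.scratch["manure"] = {
        farm.farm_id: accrue_manure(farm, world.params)
        for farm in world.active_farms()
    }


# ---------------------------------------------------------------------------
# submodel 8: manure market

def match_manure(
    surpluses: dict[int, float],
    capacities: dict[int, float],
    positions: dict[int, tuple[float, float]],
    price: float,
) -> list[ManureTransfer]:
    """Greedy distance-ordered matching of manure surplus to spare capacity.

    Seller-buyer pairs are served in order of increasing farmstead distance
    (ties: lower seller key, then lower buyer key); each pair transfers the
    minimum of remaining surplus and remaining capacity.
    """
    remaining_s = {k: v for k, v in surpluses.items() if v > 1e-9}
    remaining_b = {k: v for k, v in capacities.items() if v > 1e-9}
    pairs = sorted(
        (
            (math.dist(positions[s], positions[b]), s, b)
            for s in remaining_s
            for b in remaining_b
            if s != b
        ),
    )
    transfers: list[ManureTransfer] = []
    for _, s, b in pairs:
        amount = min(remaining_s.get(s, 0.0), remaining_b.get(b, 0.0))
        if amount <= 1e-9:
            continue
        transfers.append(ManureTransfer(seller=s, buyer=b, amount=amount, price=price))
        remaining_s[s] -= amount
        remaining_b[b] -= amount
    return transfers


def manure_market(world: WorldState) -> list[ManureTransfer]:
    """Clear the manure market; adjust per-farm nitrogen and trade cashflows."""
    p = world.params
    manure = world.scratch.get("manure", {})
    surpluses: dict[int, float] = {}
    capacities: dict[int, float] = {}
    positions: dict[int, tuple[float, float]] = {}
    for farm in world.active_farms():
        spread_ha = farm_area(world, farm) - farm_area(world, farm, "fallow")
        uptake = p.n_uptake_threshold * spread_ha
        have = manure.get(farm.farm_id, 0.0)
        if have > uptake:
            surpluses[farm.farm_id] = have - uptake
        elif uptake > have:
            capacities[farm.farm_id] = uptake - have
        positions[farm.farm_id] = farm.home_xy
    transfers = match_manure(surpluses, capacities, positions, p.manure_price)
    trade_net: dict[int, float] = {}
    for t in transfers:
        manure[t.seller] = manure.get(t.seller, 0.0) - t.amount
        manure[t.buyer] = manure.get(t.buyer, 0.0) + t.amount
        trade_net[t.seller] = trade_net.get(t.seller, 0.0) + t.amount * t.price
        trade_net[t.buyer] = trade_net.get(t.buyer, 0.0) - t.amount * t.price
    world.scratch["manure"] = manure
    world.scratch["manure_trade_net"] = trade_net
    world.scratch["transfers"] = transfers
    return transfers


# ---------------------------------------------------------------------------
# submodel 9: nitrogen application and soil update

def apply_n_and_update_soil(
    field: FieldState, n_rate: float, extensive: bool, params: ModelParams
) -> float:
    """Record applied N (kg/ha) on the field and update its fertility.

    Fertility gains at the gain rate under extensive management within the
    uptake threshold, and loses proportionally to the excess above the
    threshold; the result is clamped to [0, 1].
    """
    if n_rate < 0:
        raise ValueError("applied nitrogen must be non-negative")
    field.norg_applied = n_rate
    excess = max(0.0, n_rate - params.n_uptake_threshold)
    if excess > 0:
        field.soil_fertility -= params.soil_loss_rate * excess
    elif extensive and field.land_use == "grassland":
        field.soil_fertility += params.soil_gain_rate
    field.soil_fertility = min(1.0, max(0.0, field.soil_fertility))
    return field.soil_fertility


def nitrogen_application(world: WorldState) -> None:
    p = world.params
    manure = world.scratch.get("manure", {})
    n_rate_by_farm: dict[int, float] = {}
    n_surplus_by_farm: dict[int, float] = {}
    for farm in world.active_farms():
        spread_fields = [
            f for f in farm_fields(world, farm) if f.land_use != "fallow"
        ]
        spread_ha = sum(f.area for f in spread_fields)
        total_n = manure.get(farm.farm_id, 0.0)
        rate = total_n / spread_ha if spread_ha > 0 else 0.0
        extensive = farm.intensity.organic
        for fld in spread_fields:
            apply_n_and_update_soil(fld, rate, extensive, p)
        n_rate_by_farm[farm.farm_id] = rate
        n_surplus_by_farm[farm.farm_id] = max(
            0.0, total_n - p.n_uptake_threshold * spread_ha
        )
    # abandoned land slowly recovers
    for fld in world.fields.values():
        if fld.land_use == "fallow":
            fld.norg_applied = 0.0
            fld.soil_fertility = min(1.0, fld.soil_fertility + p.soil_gain_rate)
    world.scratch["n_rate"] = n_rate_by_farm
    world.scratch["n_surplus"] = n_surplus_by_farm
    world.scratch["total_n_surplus"] = sum(n_surplus_by_farm.values())


# ---------------------------------------------------------------------------
# submodel 10: milk production and sale

def produce_and_sell_milk(
    farm: FarmState, governance: GovernanceState, params: ModelParams
) -> tuple[float, float]:
    """Milk output (t) and revenue (EUR) at the class's price level."""
    milk = farm.n_cows * params.per_class("milk_yield")[int(farm.intensity)]
    price = (
        governance.milk_price_organic
        if farm.intensity.organic
        else governance.milk_price_conventional
    )
    farm.milk_output = milk
    return milk, milk * price


def milk_production(world: WorldState) -> None:
    revenue: dict[int, float] = {}
    for farm in world.active_farms():
        _, revenue[farm.farm_id] = produce_and_sell_milk(
            farm, world.governance, world.params
        )
    world.scratch["milk_revenue"] = revenue
    world.scratch["production_done"] = True


# ---------------------------------------------------------------------------
# yearly price draw (runs before submodel 1; not itself a submodel)

def draw_milk_prices(
    governance: GovernanceState, params: ModelParams, rng: np.random.Generator
) -> GovernanceState:
    """Draw the two price levels: ``mean * exp(eps)``, ``eps ~ N(0, volatility)``.

    With zero volatility the prices equal their means and the RNG is not
    consumed.  Draw order: conventional, then organic.
    """
    vol = params.milk_price_volatility
    if vol < 0:
        raise ValueError("volatility must be non-negative")
    if vol == 0:
        governance.milk_price_conventional = params.milk_price_conventional_mean
        governance.milk_price_organic = params.milk_price_organic_mean
    else:
        governance.milk_price_conventional = params.milk_price_conventional_mean * math.exp(
            rng.normal(0.0, vol)
        )
        governance.milk_price_organic = params.milk_price_organic_mean * math.exp(
            rng.normal(0.0, vol)
        )
    return governance


# ---------------------------------------------------------------------------
# submodel 11: governance accounts (taxes, subsidies, inspections, fisc)

def governance_accounts(world: WorldState) -> None:
    from . import governance as gov_mod

    p = world.params
    gov = world.governance
    revenue = world.scratch.get("milk_revenue", {})
    trade_net = world.scratch.get("manure_trade_net", {})
    n_surplus = world.scratch.get("n_surplus", {})

    subsidies_by_farm = {
        farm.farm_id: gov_mod.compute_subsidies(farm, world, gov)
        for farm in world.active_farms()
    }
    deductions = gov_mod.norg_inspection(world, gov, world.rng, subsidies_by_farm)

    statements: dict[int, ProfitStatement] = {}
    total_ghg = 0.0
    for farm in world.active_farms():
        emissions = farm.n_cows * p.per_class("ghg_per_cow")[int(farm.intensity)]
        total_ghg += emissions
        taxes = gov_mod.compute_ghg_tax(emissions, gov.ghg_tax_rate)
        taxes += gov_mod.compute_nitrate_tax(
            n_surplus.get(farm.farm_id, 0.0), gov.nitrate_tax_rate
        )
        rented_ha = sum(
            f.area for f in farm_fields(world, farm) if f.tenure == "rented"
        )
        stmt = ProfitStatement(
            milk_revenue=revenue.get(farm.farm_id, 0.0),
            subsidies=subsidies_by_farm[farm.farm_id],
            variable_costs=farm.n_cows * p.per_class("variable_cost")[int(farm.intensity)],
            fixed_costs=p.fixed_cost_per_farm,
            rent=p.land_rent * rented_ha,
            taxes=taxes,
            deductions=deductions.get(farm.farm_id, 0.0),
            manure_trade_net=trade_net.get(farm.farm_id, 0.0),
        )
        stmt.profit = stmt.balance()
        statements[farm.farm_id] = stmt
        gov_mod.fiscal_update(gov, taxes, stmt.subsidies - stmt.deductions)
    world.scratch["statements"] = statements
    world.scratch["total_ghg"] = total_ghg


# ---------------------------------------------------------------------------
# submodel 12: account settlement

def settle_accounts(farm: FarmState, statement: ProfitStatement) -> FarmState:
    """Book the year's profit into liquidity; track the loss streak."""
    if not statement.consistent():
        raise AccountingError(
            f"profit {statement.profit} violates the balance identity "
            f"(expected {statement.balance()})"
        )
    farm.profit_last_year = statement.profit
    farm.liquidity += statement.profit
    farm.loss_streak = farm.loss_streak + 1 if statement.profit < 0 else 0
    return farm


def account_settlement(world: WorldState) -> None:
    statements = world.scratch.get("statements", {})
    for farm in world.active_farms():
        settle_accounts(farm, statements[farm.farm_id])
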