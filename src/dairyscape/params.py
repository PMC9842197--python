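"""Parameter registries: the 43 pre-set model parameters and 5 interface settings.

The model separates *pre-set* parameters — biophysical and economic constants a
scenario normally leaves untouched — from the small set of *interface* settings
a user chooses per run (world construction and the active policy preset with
its three sliders).  Both registries are fixed-length and validated: a
configuration naming an unknown key, or a registry of the wrong size, raises
:class:`~dairyscape.errors.ConfigurationError`.

Per-intensity-class parameters use suffixes ``_c1`` .. ``_c4`` for the four
management classes (1 = very extensive .. 4 = very intensive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import yaml

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class ParamSpec:
    name: str
    default: float
    unit: str
    doc: str
    kind: type = float  # float or int


#: The 43 pre-set model parameters.  Order is the canonical registry order.
PRESET_PARAM_SPECS: tuple[ParamSpec, ...] = (
    # per-class milk yields
    ParamSpec("milk_yield_c1", 5.0, "t/cow/yr", "milk yield, very extensive"),
    ParamSpec("milk_yield_c2", 6.0, "t/cow/yr", "milk yield, extensive"),
    ParamSpec("milk_yield_c3", 8.0, "t/cow/yr", "milk yield, intensive"),
    ParamSpec("milk_yield_c4", 10.0, "t/cow/yr", "milk yield, very intensive"),
    # per-class stocking rates
    ParamSpec("stocking_rate_c1", 0.8, "cows/ha", "stocking rate, very extensive"),
    ParamSpec("stocking_rate_c2", 1.2, "cows/ha", "stocking rate, extensive"),
    ParamSpec("stocking_rate_c3", 1.8, "cows/ha", "stocking rate, intensive"),
    ParamSpec("stocking_rate_c4", 2.4, "cows/ha", "stocking rate, very intensive"),
    # per-class variable costs
    ParamSpec("variable_cost_c1", 1200.0, "EUR/cow/yr", "variable cost, very extensive"),
    ParamSpec("variable_cost_c2", 1500.0, "EUR/cow/yr", "variable cost, extensive"),
    ParamSpec("variable_cost_c3", 2000.0, "EUR/cow/yr", "variable cost, intensive"),
    ParamSpec("variable_cost_c4", 3000.0, "EUR/cow/yr", "variable cost, very intensive"),
    # per-class habitat indices of managed grassland
    ParamSpec("habitat_index_c1", 0.8, "fraction", "grassland habitat index, very extensive"),
    ParamSpec("habitat_index_c2", 0.6, "fraction", "grassland habitat index, extensive"),
    ParamSpec("habitat_index_c3", 0.3, "fraction", "grassland habitat index, intensive"),
    ParamSpec("habitat_index_c4", 0.15, "fraction", "grassland habitat index, very intensive"),
    # per-class greenhouse-gas emission factors
    ParamSpec("ghg_per_cow_c1", 3.0, "t CO2-eq/cow/yr", "GHG emissions per cow, very extensive"),
    ParamSpec("ghg_per_cow_c2", 3.3, "t CO2-eq/cow/yr", "GHG emissions per cow, extensive"),
    ParamSpec("ghg_per_cow_c3", 3.8, "t CO2-eq/cow/yr", "GHG emissions per cow, intensive"),
    ParamSpec("ghg_per_cow_c4", 4.2, "t CO2-eq/cow/yr", "GHG emissions per cow, very intensive"),
    # scalars
    ParamSpec("manure_n_per_cow", 120.0, "kg N/cow/yr", "organic nitrogen excreted per cow"),
    ParamSpec("n_uptake_threshold", 170.0, "kg N/ha/yr", "plant nitrogen uptake capacity per hectare"),
    ParamSpec("soil_gain_rate", 0.01, "1/yr", "fertility gain under extensive, within-threshold management"),
    ParamSpec("soil_loss_rate", 0.002, "1/(kg N/ha)/yr", "fertility loss per kg/ha of excess nitrogen"),
    ParamSpec("yield_soil_response", 0.5, "fraction", "share of fodder yield that scales with soil fertility"),
    ParamSpec("fixed_cost_per_farm", 15000.0, "EUR/yr", "fixed cost of running a farm"),
    ParamSpec("land_rent", 250.0, "EUR/ha/yr", "yearly rent for tenured fields"),
    ParamSpec("manure_price", 0.5, "EUR/kg N", "price buyers pay on the manure market"),
    ParamSpec("milk_price_volatility", 0.1, "sd of log price", "yearly log-normal milk price fluctuation"),
    ParamSpec("milk_price_conventional_mean", 380.0, "EUR/t", "mean conventional milk producer price"),
    ParamSpec("milk_price_organic_mean", 500.0, "EUR/t", "mean organic milk producer price"),
    ParamSpec("exit_liquidity_threshold", 0.0, "EUR", "liquidity below which a farm exits"),
    ParamSpec("max_loss_years", 3, "yr", "consecutive loss years triggering exit", int),
    ParamSpec("initial_liquidity", 30000.0, "EUR", "starting liquidity per farm"),
    ParamSpec("intensity_switch_inertia", 3, "yr", "years between intensity switches", int),
    ParamSpec("conversion_cost", 500.0, "EUR/ha", "per-hectare cost of switching intensity or land use"),
    ParamSpec("initial_farm_count", 12, "farms", "number of farms placed at setup", int),
    ParamSpec("world_width", 10, "fields", "grid width of the random world", int),
    ParamSpec("world_height", 10, "fields", "grid height of the random world", int),
    ParamSpec("field_area", 2.0, "ha", "area of each grid field"),
    ParamSpec("initial_soil_fertility_min", 0.4, "fraction", "lower bound of initial soil fertility"),
    ParamSpec("initial_soil_fertility_max", 0.9, "fraction", "upper bound of initial soil fertility"),
    ParamSpec("subsidy_base", 300.0, "EUR/ha/yr", "area payment to every active farm"),
)

PRESET_PARAM_NAMES: tuple[str, ...] = tuple(s.name for s in PRESET_PARAM_SPECS)
_SPEC_BY_NAME: dict[str, ParamSpec] = {s.name: s for s in PRESET_PARAM_SPECS}

#: The 5 interface settings chosen per run.
INTERFACE_SETTING_SPECS: tuple[ParamSpec, ...] = (
    ParamSpec("world_setup", 0, "enum {random, from_file}", "world construction mode", str),
    ParamSpec("policy_preset", 0, "enum (see governance.PRESET_NAMES)", "active policy preset", str),
    ParamSpec("policy_param_a", 0.0, "preset-dependent", "first policy slider"),
    ParamSpec("policy_param_b", 0.0, "preset-dependent", "second policy slider"),
    ParamSpec("policy_param_c", 0.0, "preset-dependent", "third policy slider"),
)

INTERFACE_SETTING_NAMES: tuple[str, ...] = tuple(s.name for s in INTERFACE_SETTING_SPECS)

WORLD_SETUPS = ("random", "from_file")


class ModelParams:
    """Validated mapping of the 43 pre-set parameters.

    Construct with a mapping of overrides; unknown names raise
    ``ConfigurationError``.  Values are attribute-accessible
    (``params.land_rent``) and per-class families are available through
    :meth:`per_class`.
    """

    __slots__ = ("_values",)

    def __init__(self, overrides: Mapping[str, Any] | None = None):
        values = {s.name: s.kind(s.default) for s in PRESET_PARAM_SPECS}
        for key, val in (overrides or {}).items():
            if key not in values:
                raise ConfigurationError(f"unknown pre-set parameter {key!r}")
            kind = _SPEC_BY_NAME[key].kind
            values[key] = int(round(val)) if kind is int else float(val)
        if len(values) != 43:
            raise ConfigurationError(
                f"pre-set registry must hold exactly 43 parameters, got {len(values)}"
            )
        object.__setattr__(self, "_values", values)

    def __getattr__(self, name: str):
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str):
        return self._values[name]

    def as_dict(self) -> dict[str, Any]:
        return dict(self._values)

    def per_class(self, prefix: str) -> dict[int, float]:
        """Return a ``{class_level: value}`` map for a ``<prefix>_c1..c4`` family."""
        return {lvl: self._values[f"{prefix}_c{lvl}"] for lvl in (1, 2, 3, 4)}

    def replace(self, **overrides) -> "ModelParams":
        merged = self.as_dict()
        merged.update(overrides)
        return ModelParams(merged)

    def __eq__(self, other):
        return isinstance(other, ModelParams) and self._values == other._values

    def __repr__(self):
        return f"ModelParams({self._values!r})"


@dataclass
class InterfaceSettings:
    """The five user-chosen settings: world construction and policy sliders.

    ``world_file`` is auxiliary plumbing for ``world_setup='from_file'`` and is
    not counted among the five settings.
    """

    world_setup: str = "random"
    policy_preset: str = "none"
    policy_param_a: float = 0.0
    policy_param_b: float = 0.0
    policy_param_c: float = 0.0
    world_file: str | None = field(default=None, compare=True)

    def __post_init__(self):
        if self.world_setup not in WORLD_SETUPS:
            raise ConfigurationError(
                f"world_setup must be one of {WORLD_SETUPS}, got {self.world_setup!r}"
            )

    def as_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in INTERFACE_SETTING_NAMES}


def validate_names(names: Iterable[str], *, allow_levers: bool = True) -> None:
    """Check that every name resolves against a registry (used by experiment designs)."""
    from .governance import LEVER_NAMES  # deferred: governance imports params

    valid = set(PRESET_PARAM_NAMES) | set(INTERFACE_SETTING_NAMES)
    if allow_levers:
        valid |= set(LEVER_NAMES)
    for name in names:
        if name not in valid:
            raise ConfigurationError(f"name {name!r} does not resolve against any registry")


def load_config(path) -> tuple[ModelParams, InterfaceSettings, dict[str, Any]]:
    """Read a YAML config with ``preset:``, ``interface:`` and optional ``levers:`` sections.

    Unknown sections or keys are errors.  Returns ``(params, settings,
    lever_overrides)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config {path} must be a mapping")
    unknown = set(raw) - {"preset", "interface", "levers"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    params = ModelParams(raw.get("preset") or {})
    iface = dict(raw.get("interface") or {})
    unknown = set(iface) - set(INTERFACE_SETTING_NAMES) - {"world_file"}
    if unknown:
        raise ConfigurationError(f"unknown interface settings: {sorted(unknown)}")
    settings = InterfaceSettings(**iface)
    levers = dict(raw.get("levers") or {})
    from .governance import LEVER_NAMES

    unknown = set(levers) - set(LEVER_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown governance levers: {sorted(unknown)}")
    return params, settings, levers
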