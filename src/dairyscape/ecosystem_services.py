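"""The five ecosystem-service indices and their aggregates.

Each index is a fraction in [0, 1], computed per year after the production
submodels:

* **climate regulation** — 1 minus GHG emissions relative to the landscape
  maximum;
* **soil fertility** — area-weighted mean field fertility;
* **habitat provisioning** — area-weighted mean habitat index (fallow land
  counts as pristine habitat, value 1);
* **water quality** — 1 minus nitrogen surplus relative to the landscape
  maximum (nitrate retention);
* **food provisioning** — milk output relative to the landscape maximum.

The ``*_max`` normalizers are frozen at model setup from a hypothetical
all-very-intensive, fertility-1 configuration of the same landscape, so that
indices are comparable across years and policy settings.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .errors import InputError, SequencingError
from .model_core import FieldState, WorldState
from .params import ModelParams


@dataclass(frozen=True)
class ESVector:
    """The five ecosystem-service components, each in [0, 1]."""

    climate_regulation: float
    soil_fertility: float
    habitat_provisioning: float
    water_quality: float
    food_provisioning: float

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.climate_regulation,
                self.soil_fertility,
                self.habitat_provisioning,
                self.water_quality,
                self.food_provisioning,
            ]
        )


ES_COMPONENTS = tuple(f.name for f in dc_fields(ESVector))


def compute_normalizers(
    fields: dict[int, FieldState], params: ModelParams
) -> dict[str, float]:
    """Landscape maxima under all-very-intensive, fertility-1 management."""
    total_area = sum(f.area for f in fields.values())
    cows_max = params.stocking_rate_c4 * total_area
    return {
        "emissions_max": cows_max * params.ghg_per_cow_c4,
        "milk_max": cows_max * params.milk_yield_c4,
        "n_surplus_max": max(
            0.0, cows_max * params.manure_n_per_cow - params.n_uptake_threshold * total_area
        ),
    }


def _clamp(x: float) -> float:
    return min(1.0, max(0.0, x))


def es_vector(world: WorldState) -> ESVector:
    """The year's five-component ecosystem-service vector."""
    if not world.scratch.get("production_done"):
        raise SequencingError(
            "es_vector requires the production submodels to have run this year"
        )
    norms = world.es_norms
    total_area = world.total_area()
    soil = habitat = 0.0
    for fld in world.fields.values():
        soil += fld.soil_fertility * fld.area
        habitat += fld.habitat_index * fld.area
    milk = sum(f.milk_output for f in world.active_farms())
    ghg = world.scratch.get("total_ghg", 0.0)
    surplus = world.scratch.get("total_n_surplus", 0.0)
    return ESVector(
        climate_regulation=_clamp(
            1.0 - ghg / norms["emissions_max"] if norms["emissions_max"] > 0 else 1.0
        ),
        soil_fertility=_clamp(soil / total_area if total_area else 0.0),
        habitat_provisioning=_clamp(habitat / total_area if total_area else 1.0),
        water_quality=_clamp(
            1.0 - surplus / norms["n_surplus_max"] if norms["n_surplus_max"] > 0 else 1.0
        ),
        food_provisioning=_clamp(
            milk / norms["milk_max"] if norms["milk_max"] > 0 else 0.0
        ),
    )


def joint_es_index(es: ESVector, weights=None) -> float:
    """Weighted mean of the five components (default: equal weights)."""
    w = np.ones(5) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (5,) or (w < 0).any():
        raise InputError("weights must be five non-negative numbers")
    if w.sum() == 0:
        raise InputError("weights must not all be zero")
    return float(np.average(es.as_array(), weights=w))


def regulating_es_index(es: ESVector) -> float:
    """Mean of the four non-food (regulating and supporting) components."""
    return joint_es_index(es, weights=[1, 1, 1, 1, 0])
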