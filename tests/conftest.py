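import numpy as np
import pytest

from dairyscape.ecosystem_services import compute_normalizers
from dairyscape.governance import apply_preset
from dairyscape.model_core import FarmState, FieldState, IntensityClass, WorldState
from dairyscape.params import InterfaceSettings, ModelParams


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def small_params():
    """A 4x4 world with 4 farms and no price noise: fast, fully deterministic."""
    return ModelParams(
        {
            "world_width": 4,
            "world_height": 4,
            "initial_farm_count": 4,
            "field_area": 1.0,
            "milk_price_volatility": 0.0,
        }
    )


def build_world(params, field_specs, farm_specs, settings=None, seed=0):
    """Hand-build a WorldState from explicit field and farm dicts.

    field_specs: {field_id: dict(x, y, owner, land_use=..., fertility=..., area=...)}
    farm_specs: {farm_id: dict(intensity, home_xy, liquidity=..., cows=...)}
    """
    fields = {}
    for fid, fs in field_specs.items():
        fields[fid] = FieldState(
            field_id=fid,
            x=fs["x"],
            y=fs["y"],
            owner=fs.get("owner"),
            land_use=fs.get("land_use", "grassland"),
            soil_fertility=fs.get("fertility", 1.0),
            area=fs.get("area", 1.0),
            habitat_index=fs.get("habitat", 0.5),
        )
    farms = {}
    for aid, spec in farm_specs.items():
        farms[aid] = FarmState(
            farm_id=aid,
            intensity=IntensityClass(spec["intensity"]),
            home_xy=spec["home_xy"],
            liquidity=spec.get("liquidity", params.initial_liquidity),
            n_cows=spec.get("cows", 0),
            fields_held={
                fid for fid, fs in field_specs.items() if fs.get("owner") == aid
            },
        )
    settings = settings or InterfaceSettings()
    gov = apply_preset(settings, params)
    return WorldState(
        year=0,
        fields=fields,
        farms=farms,
        governance=gov,
        rng=np.random.default_rng(seed),
        params=params,
        settings=settings,
        es_norms=compute_normalizers(fields, params),
    )


@pytest.fixture
def build_world_fn():
    return build_world
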