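"""World construction: random grid worlds and file-based landscapes.

Two world versions exist.  The *random* version lays out a ``width x height``
grid of equal-area fields, places the initial farms on randomly chosen home
fields and allocates every field to the nearest farmstead.  The *from_file*
version reads a plain CSV describing field positions, areas, initial land use,
fertility and ownership — a stand-in for landscapes digitized from real field
maps.

Coordinates are expressed in units of the grid spacing (one field edge);
adjacency is the 4-neighborhood, i.e. fields within distance 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .model_core import FarmState, FieldState, IntensityClass
from .params import ModelParams

#: Distance (in grid-spacing units) within which two fields are neighbors.
NEIGHBOR_DISTANCE = 1.0

WORLD_FILE_COLUMNS = (
    "field_id",
    "x",
    "y",
    "area",
    "initial_land_use",
    "initial_soil_fertility",
    "initial_owner",
)


def build_random_world(
    params: ModelParams, rng: np.random.Generator
) -> tuple[dict[int, FieldState], dict[int, FarmState]]:
    """Generate the grid world: random farm placement, nearest-farm allocation.

    Field ids run row-major over the grid; soil fertility is drawn uniformly
    in the configured range (one draw per field in id order); every field
    starts as owned grassland; intensity classes are assigned round-robin
    over the four classes in farm-id order.
    """
    width, height = params.world_width, params.world_height
    n_fields = width * height
    n_farms = params.initial_farm_count
    if n_farms > n_fields:
        raise ConfigurationError(
            f"cannot place {n_farms} farms on {n_fields} fields"
        )

    fertility = rng.uniform(
        params.initial_soil_fertility_min, params.initial_soil_fertility_max, n_fields
    )
    home_ids = np.sort(rng.choice(n_fields, size=n_farms, replace=False))

    farms: dict[int, FarmState] = {}
    for farm_id, home in enumerate(home_ids):
        x, y = float(home % width), float(home // width)
        farms[farm_id] = FarmState(
            farm_id=farm_id,
            intensity=IntensityClass(farm_id % 4 + 1),
            home_xy=(x, y),
            liquidity=params.initial_liquidity,
        )

    fields: dict[int, FieldState] = {}
    habitat = params.per_class("habitat_index")
    for fid in range(n_fields):
        x, y = float(fid % width), float(fid // width)
        owner = _nearest_farm(x, y, farms)
        farms[owner].fields_held.add(fid)
        fields[fid] = FieldState(
            field_id=fid,
            x=x,
            y=y,
            owner=owner,
            land_use="grassland",
            soil_fertility=float(fertility[fid]),
            area=params.field_area,
            habitat_index=habitat[int(farms[owner].intensity)],
            tenure="owned",
        )
    return fields, farms


def _nearest_farm(x: float, y: float, farms: dict[int, FarmState]) -> int:
    """Farm whose farmstead is nearest to (x, y); ties go to the lower farm key."""
    best_key, best_d = None, math.inf
    for farm_id in sorted(farms):
        hx, hy = farms[farm_id].home_xy
        d = math.hypot(x - hx, y - hy)
        if d < best_d - 1e-12:
            best_key, best_d = farm_id, d
    return best_key


def load_world_file(
    path, params: ModelParams
) -> tuple[dict[int, FieldState], dict[int, FarmState]]:
    """Read a world CSV; farms are inferred from the distinct owner keys.

    Validation errors name the offending row (1-based data row).  A blank
    owner means the field is fallow, and vice versa.
    """
    table = pd.read_csv(
        path, dtype={"initial_owner": "string"}, float_precision="round_trip"
    )
    missing = set(WORLD_FILE_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"world file missing columns: {sorted(missing)}")
    extra = set(table.columns) - set(WORLD_FILE_COLUMNS)
    if extra:
        raise InputError(f"world file has unknown columns: {sorted(extra)}")

    if table["field_id"].duplicated().any():
        dup = int(table.loc[table["field_id"].duplicated(), "field_id"].iloc[0])
        raise InputError(f"duplicate field_id {dup} in world file")

    fields: dict[int, FieldState] = {}
    owners_seen: dict[int, list[int]] = {}
    for i, row in enumerate(table.itertuples(index=False), start=1):
        fert = float(row.initial_soil_fertility)
        if not 0.0 <= fert <= 1.0:
            raise InputError(f"row {i}: soil fertility {fert} outside [0, 1]")
        area = float(row.area)
        if area <= 0:
            raise InputError(f"row {i}: area must be positive, got {area}")
        use = str(row.initial_land_use)
        if use not in ("grassland", "arable", "fallow"):
            raise InputError(f"row {i}: unknown land_use {use!r}")
        raw_owner = row.initial_owner
        owner = None if pd.isna(raw_owner) or str(raw_owner).strip() == "" else int(raw_owner)
        if (owner is None) != (use == "fallow"):
            raise InputError(f"row {i}: blank owner and land_use 'fallow' must coincide")
        if pd.isna(row.x) or pd.isna(row.y):
            raise InputError(f"row {i}: coordinates are required")
        fid = int(row.field_id)
        fields[fid] = FieldState(
            field_id=fid,
            x=float(row.x),
            y=float(row.y),
            owner=owner,
            land_use=use,
            soil_fertility=fert,
            area=area,
            habitat_index=1.0 if use == "fallow" else 0.0,  # refreshed below
            tenure="owned",
        )
        if owner is not None:
            owners_seen.setdefault(owner, []).append(fid)

    farms: dict[int, FarmState] = {}
    habitat = params.per_class("habitat_index")
    for idx, owner in enumerate(sorted(owners_seen)):
        held = sorted(owners_seen[owner])
        home_field = fields[held[0]]
        farms[owner] = FarmState(
            farm_id=owner,
            intensity=IntensityClass(idx % 4 + 1),
            home_xy=(home_field.x, home_field.y),
            liquidity=params.initial_liquidity,
            fields_held=set(held),
        )
    from .annual_cycle import ARABLE_HABITAT_INDEX, FALLOW_HABITAT_INDEX

    for fld in fields.values():
        if fld.land_use == "grassland":
            fld.habitat_index = habitat[int(farms[fld.owner].intensity)]
        elif fld.land_use == "arable":
            fld.habitat_index = ARABLE_HABITAT_INDEX
        else:
            fld.habitat_index = FALLOW_HABITAT_INDEX
    return fields, farms


def save_world_file(fields: dict[int, FieldState], path) -> None:
    """Write fields in the world-file CSV schema (round-trips with the loader)."""
    rows = []
    for fid in sorted(fields):
        fld = fields[fid]
        rows.append(
            {
                "field_id": fld.field_id,
                "x": fld.x,
                "y": fld.y,
                "area": fld.area,
                "initial_land_use": fld.land_use,
                "initial_soil_fertility": fld.soil_fertility,
                "initial_owner": "" if fld.owner is None else fld.owner,
            }
        )
    pd.DataFrame(rows, columns=list(WORLD_FILE_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def neighbors(
    field_id: int, fields: dict[int, FieldState], threshold: float = NEIGHBOR_DISTANCE
) -> set[int]:
    """Field keys within ``threshold`` distance (4-neighborhood on the grid)."""
    if field_id not in fields:
        raise KeyError(f"unknown field id {field_id}")
    home = fields[field_id]
    out = set()
    for fid, fld in fields.items():
        if fid == field_id:
            continue
        if math.hypot(fld.x - home.x, fld.y - home.y) <= threshold + 1e-9:
            out.add(fid)
    return out
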