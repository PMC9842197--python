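"""Experiment tooling: factorial sweeps, policy-setting search, sensitivity.

Three analysis patterns are supported, mirroring how simulation platforms
expose them:

* :func:`run_sweep` — full-factorial execution over declared parameter/lever
  values with seeded replications (a BehaviorSpace-style experiment runner);
* :func:`run_search` — optimization of a reporter-derived objective over a
  lattice of policy-lever settings (grid / random / hill-climbing);
* :func:`oat_sensitivity` — one-at-a-time elasticities of reporters with
  respect to pre-set parameters.

Replication ``r`` of every design point runs with seed ``base_seed + r``, so
contrasts between settings are common-random-number comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .governance import LEVER_NAMES
from .model_core import REPORTER_COLUMNS, init_model, records_to_frame, run
from .params import (
    INTERFACE_SETTING_NAMES,
    PRESET_PARAM_NAMES,
    InterfaceSettings,
    ModelParams,
    validate_names,
)


@dataclass
class SweepDesign:
    """A full-factorial experiment: varied names -> explicit value lists."""

    varying: dict[str, list] = field(default_factory=dict)
    replications: int = 1
    n_years: int = 30
    base_seed: int = 0
    reporters: list[str] = field(default_factory=lambda: ["total_milk_t"])
    params: ModelParams = field(default_factory=ModelParams)
    settings: InterfaceSettings = field(default_factory=InterfaceSettings)
    lever_overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.replications < 1:
            raise ConfigurationError("replications must be >= 1")
        validate_names(self.varying)
        bad = set(self.reporters) - set(REPORTER_COLUMNS)
        if bad:
            raise ConfigurationError(f"unknown reporters: {sorted(bad)}")


@dataclass
class SearchSpec:
    """Objective and lattice for a policy-setting search."""

    objective: str
    maximize: bool = True
    space: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    method: str = "grid"
    budget: int = 100
    replications: int = 1
    n_years: int = 30
    base_seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    settings: InterfaceSettings = field(default_factory=InterfaceSettings)
    lever_overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.budget < 1:
            raise InputError("budget must be >= 1")
        if self.method not in ("grid", "random", "hill_climb"):
            raise ConfigurationError(f"unknown search method {self.method!r}")
        if self.objective not in REPORTER_COLUMNS:
            raise ConfigurationError(f"unknown objective reporter {self.objective!r}")
        validate_names(self.space)
        for name, (lo, hi, step) in self.space.items():
            if step <= 0 or hi < lo:
                raise ConfigurationError(f"bad lattice for {name}: ({lo}, {hi}, {step})")


def _apply_point(
    params: ModelParams,
    settings: InterfaceSettings,
    levers: Mapping[str, Any],
    point: Mapping[str, Any],
) -> tuple[ModelParams, InterfaceSettings, dict[str, Any]]:
    """Route each varied name to the registry it lives in."""
    p_over, s_over, l_over = {}, {}, dict(levers)
    for name, value in point.items():
        if name in PRESET_PARAM_NAMES:
            p_over[name] = value
        elif name in INTERFACE_SETTING_NAMES:
            s_over[name] = value
        elif name in LEVER_NAMES:
            l_over[name] = value
        else:  # pragma: no cover - designs are pre-validated
            raise ConfigurationError(f"unresolvable name {name!r}")
    new_params = params.replace(**p_over) if p_over else params
    new_settings = (
        InterfaceSettings(**{**settings.as_dict(), "world_file": settings.world_file, **s_over})
        if s_over
        else settings
    )
    return new_params, new_settings, l_over


def _simulate_point(
    design, point: Mapping[str, Any], seed: int
) -> pd.DataFrame:
    params, settings, levers = _apply_point(
        design.params, design.settings, design.lever_overrides, point
    )
    world = init_model(params, settings, seed, levers)
    return records_to_frame(run(world, design.n_years))


def run_sweep(design: SweepDesign) -> pd.DataFrame:
    """Full factorial over ``varying`` x replications; one row per run per year."""
    names = list(design.varying)
    combos = list(itertools.product(*(design.varying[n] for n in names))) or [()]
    rows = []
    run_id = 0
    for combo in combos:
        point = dict(zip(names, combo))
        for rep in range(design.replications):
            seed = design.base_seed + rep
            table = _simulate_point(design, point, seed)
            for _, year_row in table.iterrows():
                row = {"run_id": run_id, "replication": rep, "seed": seed}
                row.update(point)
                row["year"] = int(year_row["year"])
                for rep_name in design.reporters:
                    row[rep_name] = year_row[rep_name]
                rows.append(row)
            run_id += 1
    cols = ["run_id", "replication", "seed", *names, "year", *design.reporters]
    return pd.DataFrame(rows, columns=cols)


def _lattice(space: dict[str, tuple[float, float, float]]) -> tuple[list[str], list[np.ndarray]]:
    names = list(space)
    axes = []
    for n in names:
        lo, hi, step = space[n]
        axes.append(np.arange(lo, hi + step / 2, step))
    return names, axes


def run_search(
    spec: SearchSpec,
    evaluate: Callable[[dict[str, float]], float] | None = None,
) -> tuple[dict[str, float], float, pd.DataFrame]:
    """Search the lever lattice for the best objective value.

    ``evaluate`` defaults to running the model and averaging the objective
    reporter at the final year over paired-seed replications; tests may
    inject a stub.  Returns ``(best_point, best_value, log)`` where the log
    records every evaluated point in evaluation order.  Grid search is
    exhaustive; random search draws ``budget`` lattice points; hill climbing
    walks +-1 lattice steps from a (seeded) random start until no neighbor
    improves or the budget is spent.  Evaluations are cached per point, so
    revisits are free.
    """
    names, axes = _lattice(spec.space)
    if not names:
        raise ConfigurationError("search space must name at least one lever")

    if evaluate is None:

        def evaluate(point: dict[str, float]) -> float:
            vals = []
            for rep in range(spec.replications):
                table = _simulate_point(spec, point, spec.base_seed + rep)
                vals.append(float(table[spec.objective].iloc[-1]))
            return float(np.mean(vals))

    sign = 1.0 if spec.maximize else -1.0
    cache: dict[tuple, float] = {}
    log: list[dict] = []

    def eval_idx(idx: tuple[int, ...]) -> float:
        if idx not in cache:
            point = {n: float(axes[i][idx[i]]) for i, n in enumerate(names)}
            cache[idx] = evaluate(point)
            log.append({**point, "objective": cache[idx]})
        return cache[idx]

    shape = tuple(len(a) for a in axes)
    if spec.method == "grid":
        for idx in itertools.product(*(range(s) for s in shape)):
            eval_idx(idx)
    elif spec.method == "random":
        rng = np.random.default_rng(spec.base_seed)
        for _ in range(spec.budget):
            eval_idx(tuple(int(rng.integers(s)) for s in shape))
    else:  # hill_climb
        rng = np.random.default_rng(spec.base_seed)
        current = tuple(int(rng.integers(s)) for s in shape)
        eval_idx(current)
        while len(cache) < spec.budget:
            moves = []
            for dim in range(len(shape)):
                for delta in (-1, 1):
                    nxt = list(current)
                    nxt[dim] += delta
                    if 0 <= nxt[dim] < shape[dim]:
                        moves.append(tuple(nxt))
            improved = False
            best_move, best_val = current, sign * eval_idx(current)
            for mv in moves:
                if len(cache) >= spec.budget and mv not in cache:
                    continue
                val = sign * eval_idx(mv)
                if val > best_val + 1e-12:
                    best_move, best_val = mv, val
                    improved = True
            if not improved:
                break
            current = best_move

    best_idx = max(cache, key=lambda i: (sign * cache[i], tuple(-j for j in i)))
    best_point = {n: float(axes[i][best_idx[i]]) for i, n in enumerate(names)}
    return best_point, cache[best_idx], pd.DataFrame(log)


def oat_sensitivity(
    param_names: list[str],
    delta: float = 0.1,
    replications: int = 1,
    n_years: int = 10,
    reporters: list[str] | None = None,
    params: ModelParams | None = None,
    settings: InterfaceSettings | None = None,
    lever_overrides: dict[str, Any] | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """One-at-a-time normalized elasticities of reporters w.r.t. parameters.

    Each named pre-set parameter (or numeric governance lever) is perturbed
    to ``(1 - delta)`` and ``(1 + delta)`` times its baseline value;
    paired-seed batches are run at both values and the central elasticity
    ``(dR / R_center) / (2 * delta)`` is reported per reporter (final-year
    value, averaged over replications).  Integer-typed parameters are rounded
    after scaling.
    """
    if delta <= 0:
        raise InputError("delta must be positive")
    params = params or ModelParams()
    settings = settings or InterfaceSettings()
    lever_overrides = dict(lever_overrides or {})
    reporters = reporters or ["total_milk_t"]
    bad = set(reporters) - set(REPORTER_COLUMNS)
    if bad:
        raise ConfigurationError(f"unknown reporters: {sorted(bad)}")
    numeric_levers = set(LEVER_NAMES) - {"conversion_ban"}
    for name in param_names:
        if name not in PRESET_PARAM_NAMES and name not in numeric_levers:
            raise ConfigurationError(f"{name!r} is not a numeric parameter or lever")

    design = SweepDesign(
        replications=replications,
        n_years=n_years,
        base_seed=base_seed,
        reporters=reporters,
        params=params,
        settings=settings,
        lever_overrides=lever_overrides,
    )

    def batch_means(point: dict[str, Any]) -> dict[str, float]:
        acc = {r: [] for r in reporters}
        for rep in range(replications):
            table = _simulate_point(design, point, base_seed + rep)
            for r in reporters:
                acc[r].append(float(table[r].iloc[-1]))
        return {r: float(np.mean(v)) for r, v in acc.items()}

    rows = []
    for name in param_names:
        default = (
            params[name]
            if name in PRESET_PARAM_NAMES
            else float(lever_overrides.get(name, 0.0))
        )
        lo_val, hi_val = default * (1 - delta), default * (1 + delta)
        lo = batch_means({name: lo_val})
        hi = batch_means({name: hi_val})
        for r in reporters:
            center = (hi[r] + lo[r]) / 2
            if center == 0:
                elasticity = 0.0 if hi[r] == lo[r] else float("nan")
            else:
                elasticity = ((hi[r] - lo[r]) / center) / (2 * delta)
            rows.append(
                {
                    "parameter": name,
                    "reporter": r,
                    "value_minus": lo[r],
                    "value_plus": hi[r],
                    "elasticity": elasticity,
                }
            )
    return pd.DataFrame(
        rows, columns=["parameter", "reporter", "value_minus", "value_plus", "elasticity"]
    )


def compare_settings(table: pd.DataFrame, group_key: str, reporter: str) -> dict:
    """Per-group mean/sd and the Welch two-sample t statistic between two groups."""
    groups = sorted(table[group_key].unique(), key=str)
    if len(groups) != 2:
        raise InputError(f"expected exactly 2 groups in {group_key!r}, got {len(groups)}")
    a = table.loc[table[group_key] == groups[0], reporter].to_numpy(dtype=float)
    b = table.loc[table[group_key] == groups[1], reporter].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # identical zero-variance groups
        t, p = 0.0, 1.0
    return {
        "groups": list(groups),
        "mean": [float(a.mean()), float(b.mean())],
        "sd": [float(a.std(ddof=1)), float(b.std(ddof=1))],
        "t": float(t),
        "p": float(p),
    }
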