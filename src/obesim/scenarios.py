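"""Counterfactual intervention scenarios and natural-course contrasts.

An intervention overrides an exposure during simulation, either after the
equation draw (``set`` — deterministic override to a value, e.g. nobody
consumes sugary drinks), after the link inversion (``shift`` — add to the
Bernoulli probability, clipped to [0, 1]), or before simulation by editing
the equation itself (``scale_coefficient``).  Overrides can target a
subpopulation via a filter on agent or neighborhood attributes.  Contrasts
against the natural course use common random numbers: paired seeds make a
null intervention produce exactly zero contrast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import run_simulation
from .measures import DEFAULT_WINDOWS, measure_table, prevalence
from .params import (
    ENVIRONMENT_VARS,
    ParameterSet,
    Term,
    applicable_stages,
    engine_variables,
)

__all__ = ["InterventionSpec", "Scenario", "apply_intervention", "contrast", "run_contrast"]

_TIME_INVARIANT = ("sex", "race", "race_nonwhite", "ses_group")
_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "ge": lambda a, b: a >= b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "lt": lambda a, b: a < b,
}


@dataclass(frozen=True)
class InterventionSpec:
    """One exposure override.

    ``where`` is an optional subpopulation filter ``(column, op, value)``
    with op in eq/ne/ge/le/gt/lt, evaluated against agent socio-demographics
    or (joined) neighborhood attributes.
    """

    variable: str
    stages: tuple[int, ...]
    rule: str  # "set" | "shift" | "scale_coefficient"
    value: float
    predictor: tuple[str, int] | None = None  # for scale_coefficient
    where: tuple[str, str, object] | None = None

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(int(s) for s in self.stages))
        if self.rule not in ("set", "shift", "scale_coefficient"):
            raise ValueError(f"unknown intervention rule {self.rule!r}")
        if self.rule == "scale_coefficient" and self.predictor is None:
            raise ValueError("scale_coefficient requires a (predictor, lag) pair")
        if self.where is not None and self.where[1] not in _OPS:
            raise ValueError(f"unknown filter operator {self.where[1]!r}")


def matching_mask(spec: InterventionSpec, predictors, state) -> np.ndarray:
    """Boolean agent mask for a spec's subpopulation filter."""
    n = np.asarray(state["agent_id"]).shape[0]
    if spec.where is None:
        return np.ones(n, dtype=bool)
    column, op, value = spec.where
    if column in predictors:
        data = np.asarray(predictors[column])
    elif column in state:
        data = np.asarray(state[column])
    else:
        raise KeyError(f"intervention filter column {column!r} not found")
    return np.asarray(_OPS[op](data, value))


@dataclass
class Scenario:
    """A simulation configuration realizing one or more interventions."""

    params: ParameterSet
    runtime_overrides: tuple[InterventionSpec, ...] = ()

    def run(self, seed: int | None = None, replicate: int = 0):
        return run_simulation(
            self.params, seed=seed, interventions=self.runtime_overrides,
            replicate=replicate,
        )


def apply_intervention(
    ps: ParameterSet, specs: InterventionSpec | Sequence[InterventionSpec]
) -> Scenario:
    """Turn a parameter set plus intervention specs into a runnable scenario.

    ``scale_coefficient`` rules rewrite the equations up front; ``set`` and
    ``shift`` rules are applied at run time after each affected draw.
    Overriding a time-invariant socio-demographic is rejected.
    """
    if isinstance(specs, InterventionSpec):
        specs = [specs]
    ps = ps.copy()
    runtime = []
    for spec in specs:
        if spec.variable in _TIME_INVARIANT:
            raise ValueError(
                f"cannot intervene on time-invariant socio-demographic {spec.variable!r}"
            )
        if spec.variable in ENVIRONMENT_VARS:
            runtime.append(spec)
            continue
        if spec.variable not in engine_variables():
            raise ValueError(f"unknown intervention target {spec.variable!r}")
        valid = set(applicable_stages(spec.variable, ps.schedule))
        bad = set(spec.stages) - valid
        if bad:
            raise ValueError(
                f"intervention on {spec.variable!r} at inapplicable stages {sorted(bad)}"
            )
        if spec.rule == "scale_coefficient":
            for stage in spec.stages:
                eq = ps.equations[(spec.variable, stage)]
                term = eq.term_for(*spec.predictor)
                if term is None:
                    raise ValueError(
                        f"equation {spec.variable!r} stage {stage} has no term "
                        f"{spec.predictor}"
                    )
                eq.terms = tuple(
                    Term(t.predictor, t.lag, t.coefficient * spec.value)
                    if (t.predictor, t.lag) == spec.predictor
                    else t
                    for t in eq.terms
                )
        else:
            runtime.append(spec)
    return Scenario(params=ps, runtime_overrides=tuple(runtime))


def apply_neighborhood_overrides(
    neighborhoods: pd.DataFrame, interventions: Sequence[InterventionSpec]
) -> pd.DataFrame:
    """Apply set/shift rules targeting neighborhood environment attributes."""
    out = neighborhoods.copy()
    for spec in interventions:
        if spec.variable not in ENVIRONMENT_VARS:
            continue
        if spec.where is None:
            mask = np.ones(len(out), dtype=bool)
        else:
            column, op, value = spec.where
            mask = np.asarray(_OPS[op](out[column].to_numpy(), value))
        if spec.rule == "set":
            out.loc[mask, spec.variable] = spec.value
        elif spec.rule == "shift":
            out.loc[mask, spec.variable] = out.loc[mask, spec.variable] + spec.value
        if spec.variable.endswith("_density"):
            out[spec.variable] = out[spec.variable].clip(lower=0.0)
    return out


def contrast(
    natural_panel: pd.DataFrame,
    intervention_panel: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    schedule=None,
) -> pd.DataFrame:
    """Differences (intervention − natural) in cohort measures.

    Rows cover each window's cumulative incidence (percentage points) and
    incidence rate (per 1,000 py), plus per-stage obesity and T2DM
    prevalence (proportion scale).  Panels must describe cohorts of equal
    size; identical panels give exactly zero everywhere.
    """
    if natural_panel["agent_id"].nunique() != intervention_panel["agent_id"].nunique():
        raise ValueError("panels describe cohorts of different sizes")
    if schedule is None:
        from .params import DEFAULT_SCHEDULE as schedule  # noqa: N813

    nat = measure_table(natural_panel, windows, strata=("all",), schedule=schedule)
    inter = measure_table(intervention_panel, windows, strata=("all",), schedule=schedule)
    rows = []
    for (_, a), (_, b) in zip(nat.iterrows(), inter.iterrows()):
        rows.append(
            dict(
                measure="cumulative_incidence_pct", window=a["window"], stage=None,
                natural=a["cum_incidence_pct"], intervention=b["cum_incidence_pct"],
                difference=b["cum_incidence_pct"] - a["cum_incidence_pct"],
            )
        )
        rows.append(
            dict(
                measure="rate_per_1000py", window=a["window"], stage=None,
                natural=a["rate_per_1000py"], intervention=b["rate_per_1000py"],
                difference=b["rate_per_1000py"] - a["rate_per_1000py"],
            )
        )
    stages = sorted(natural_panel["stage"].unique())
    for condition in ("obesity", "t2dm"):
        for s in stages:
            a = prevalence(natural_panel, s, condition)
            b = prevalence(intervention_panel, s, condition)
            rows.append(
                dict(
                    measure=f"{condition}_prevalence", window=None, stage=s,
                    natural=a, intervention=b, difference=b - a,
                )
            )
    return pd.DataFrame(rows)


def run_contrast(
    ps: ParameterSet,
    specs,
    windows=DEFAULT_WINDOWS,
    seeds: Sequence[int] = tuple(range(20)),
) -> pd.DataFrame:
    """Replicate paired runs over seeds; mean difference with Monte-Carlo SD.

    Natural and intervention runs share each seed (common random numbers).
    """
    scenario = apply_intervention(ps, specs)
    reps = []
    for seed in seeds:
        nat_panel, _ = run_simulation(ps, seed=seed)
        int_panel, _ = scenario.run(seed=seed)
        c = contrast(nat_panel, int_panel, windows, ps.schedule)
        c["seed"] = seed
        reps.append(c)
    stacked = pd.concat(reps, ignore_index=True)
    grouped = stacked.groupby(["measure", "window", "stage"], dropna=False)
    out = grouped.agg(
        natural=("natural", "mean"),
        intervention=("intervention", "mean"),
        difference=("difference", "mean"),
        difference_sd=("difference", "std"),
        n_seeds=("difference", "size"),
    ).reset_index()
    return out
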