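"""Synthesis of neighborhoods and the initial (stage 0) birth cohort.

Initialization order: neighborhoods first (socio-demographic proportions
drawn from truncated normals, then the food/activity environment predicted
from those socio-demographics), then agents nested within neighborhoods
(race and income group inherited from the neighborhood's composition, age
uniform within the birth stage, stage-0 behaviors and BMI drawn from the
lag-free stage-0 equations).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .engine import classify_state, evaluate_equation, state_to_frame
from .params import ENVIRONMENT_VARS, NEIGHBORHOOD_SOCIODEM, ParameterSet, stage_update_order

__all__ = ["build_neighborhoods", "predict_environment", "build_agents", "draw_age"]

NEIGHBORHOOD_COLUMNS = ("id",) + NEIGHBORHOOD_SOCIODEM + ENVIRONMENT_VARS


def predict_environment(
    sociodem: pd.DataFrame, ps: ParameterSet, rng: np.random.Generator
) -> pd.DataFrame:
    """Predict food/activity environment attributes from neighborhood
    socio-demographics via the identity-link environment equations.
    Densities are clipped at zero."""
    for c in NEIGHBORHOOD_SOCIODEM:
        vals = np.asarray(sociodem[c], dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"neighborhood proportion {c!r} outside [0, 1]")
    n = len(sociodem)
    data = {c: sociodem[c].to_numpy(dtype=float) for c in NEIGHBORHOOD_SOCIODEM}
    out = {}
    for name in ENVIRONMENT_VARS:
        values = evaluate_equation(ps.environment[name], data, rng, size=n)
        if name.endswith("_density"):
            values = np.clip(values, 0.0, None)
        out[name] = values
    return pd.DataFrame(out, index=sociodem.index)


def build_neighborhoods(ps: ParameterSet, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the full set of neighborhoods (one row each)."""
    n = ps.n_neighborhoods
    sociodem = {}
    for name in NEIGHBORHOOD_SOCIODEM:
        mean, sd = ps.neighborhood_distributions[name]
        sociodem[name] = np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)
    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64), **sociodem})
    env = predict_environment(df, ps, rng)
    return pd.concat([df, env], axis=1)[list(NEIGHBORHOOD_COLUMNS)]


def draw_age(stage: int, schedule, rng: np.random.Generator, size: int | None = None):
    """Age uniform within the stage's band."""
    if not 0 <= stage < len(schedule):
        raise ValueError(f"stage {stage} out of range 0..{len(schedule) - 1}")
    band = schedule[stage]
    out = rng.uniform(band.age_low, band.age_high, size=size)
    return float(out) if size is None else out


def build_agents(
    neighborhoods: pd.DataFrame,
    ps: ParameterSet,
    rng: np.random.Generator,
    interventions: Iterable | None = None,
    as_state: bool = False,
):
    """Initialize the stage-0 cohort nested in the given neighborhoods.

    Per agent: sex ~ Bernoulli(0.5), age ~ Uniform(0, 1), race ~
    Bernoulli(neighborhood %-non-White), income group ~ Bernoulli(% below
    FPL); breastfeeding, stage-0 behaviors and stage-0 BMI from the lag-free
    stage-0 equations; smoking, alcohol, T2DM and marital status zero.

    Returns a stage-0 panel DataFrame, or the internal dict-of-arrays state
    if ``as_state`` is true.
    """
    apn = ps.agents_per_neighborhood
    n = ps.n_neighborhoods * apn
    nbhd_index = np.repeat(np.arange(ps.n_neighborhoods), apn)
    nb = neighborhoods.sort_values("id").reset_index(drop=True)

    state: dict[str, np.ndarray] = {
        "agent_id": np.arange(n, dtype=np.int64),
        "neighborhood_id": nb["id"].to_numpy()[nbhd_index],
        "stage": np.zeros(n, dtype=np.int64),
        "marital": np.zeros(n, dtype=np.int64),
        "smoking": np.zeros(n, dtype=np.int64),
        "alcohol": np.zeros(n, dtype=np.int64),
        "t2dm": np.zeros(n, dtype=np.int64),
    }
    state["sex"] = (rng.random(n) < 0.5).astype(np.int64)
    state["age"] = draw_age(0, ps.schedule, rng, size=n)
    pct_nonwhite = nb["pct_nonwhite"].to_numpy(dtype=float)[nbhd_index]
    pct_fpl = nb["pct_below_fpl"].to_numpy(dtype=float)[nbhd_index]
    state["race_nonwhite"] = (rng.random(n) < pct_nonwhite).astype(np.int64)
    state["ses_group"] = (rng.random(n) < pct_fpl).astype(np.int64)

    predictors = {
        k: nb[k].to_numpy(dtype=float)[nbhd_index]
        for k in NEIGHBORHOOD_SOCIODEM + ENVIRONMENT_VARS
    }
    for k in ("sex", "race_nonwhite", "ses_group", "marital", "age"):
        predictors[k] = state[k]

    from .engine import _apply_post_draw, draw_variable  # shared draw/override hooks

    for variable in stage_update_order(0, ps.schedule):
        values = draw_variable(
            ps.equations[(variable, 0)], predictors, None, rng, n, interventions, state
        )
        if variable == "bmi":
            values = np.clip(values, *ps.bmi_clip)
        state[variable] = values
        _apply_post_draw(state, variable, 0, interventions, predictors)
        predictors[variable] = state[variable]

    classify_state(state, ps)
    if as_state:
        return state
    return state_to_frame(state)
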