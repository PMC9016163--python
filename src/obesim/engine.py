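"""Simulation engine: lagged equation evaluation and cohort advancement.

Each life stage is advanced by evaluating, in a fixed order, the behavior
equations (diet, activity, and at adult stages smoking and alcohol) from the
previous stage's state, then the BMI equation (which sees the current-stage
behaviors and lagged BMI), then the T2DM equation (current BMI and behaviors,
with diagnosis absorbing), and finally the anthropometric classification.
Behaviors never depend on other same-stage behaviors — only on lag-1 state —
so their evaluation order is immaterial.

Randomness is organized as independent per-(seed, replicate, stage) streams:
the neighborhood draw, the stage-0 agent draw, and each stage advancement
consume their own streams, so a single stage can be re-simulated from a
frozen panel with exactly the stream a full run would use (common random
numbers for calibration scoring and paired intervention contrasts), and
results are independent of agent iteration order.
"""

from __future__ import annotations

import logging
import time
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit as _scipy_expit

from . import anthropometry
from .params import (
    ADULT_BEHAVIORS,
    BEHAVIORS,
    EquationSpec,
    ParameterSet,
    applicable_stages,
    stage_update_order,
)

__all__ = [
    "expit", "evaluate_equation", "linear_predictor", "draw_variable",
    "advance_state", "step", "run_simulation", "stream", "stage_means",
]

logger = logging.getLogger("obesim")

#: Columns of the long-format agent panel, one row per agent per stage.
PANEL_COLUMNS = (
    "agent_id", "neighborhood_id", "stage", "age", "sex", "race", "ses_group",
    "marital", "breastfed", "ssb", "fastfood", "ffv", "activity", "smoking",
    "alcohol", "bmi", "bmi_z", "weight_status", "t2dm",
)

_STATE_INT = ("agent_id", "neighborhood_id", "stage", "sex", "race_nonwhite",
              "ses_group", "marital", "breastfed", "ssb", "fastfood", "ffv",
              "activity", "smoking", "alcohol", "t2dm")


def expit(x):
    """Inverse logit, 1/(1+exp(-x))."""
    return _scipy_expit(x)


def stream(seed: int, replicate: int, key: int) -> np.random.Generator:
    """The dedicated RNG stream for one (seed, replicate, stage-key) triple.

    Keys: 0 = neighborhoods, 1 = stage-0 agents, 100+t = stage-t advancement.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(replicate), int(key)])
    )


def _resolve(
    spec: EquationSpec,
    term_predictor: str,
    lag: int,
    current: Mapping[str, np.ndarray],
    previous: Mapping[str, np.ndarray] | None,
):
    source = current if lag == 0 else previous
    if source is None or term_predictor not in source:
        raise KeyError(
            f"equation {spec.target!r} stage {spec.stage}: missing predictor "
            f"{term_predictor!r} (lag {lag})"
        )
    return np.asarray(source[term_predictor], dtype=float)


def linear_predictor(
    spec: EquationSpec,
    current: Mapping[str, np.ndarray],
    previous: Mapping[str, np.ndarray] | None = None,
):
    """Intercept plus the sum of coefficient-weighted (lagged) predictors."""
    lp = spec.intercept
    for t in spec.terms:
        lp = lp + t.coefficient * _resolve(spec, t.predictor, t.lag, current, previous)
    return lp


def evaluate_equation(
    spec: EquationSpec,
    current: Mapping[str, np.ndarray],
    rng: np.random.Generator,
    previous: Mapping[str, np.ndarray] | None = None,
    size: int | None = None,
):
    """Draw a realization of one equation.

    identity link: linear predictor plus Normal(0, noise_sd) noise;
    logit link: Bernoulli with probability expit(linear predictor).

    ``current``/``previous`` map predictor names to values (scalars or
    arrays) for lag 0 / lag 1.  A missing predictor raises ``KeyError``
    naming the equation and predictor.  The random stream is consumed
    identically regardless of coefficient values, so paired runs stay
    aligned.
    """
    lp = np.asarray(linear_predictor(spec, current, previous), dtype=float)
    if size is None:
        size = lp.shape[0] if lp.ndim else 1
    lp = np.broadcast_to(lp, (size,))
    if spec.link == "identity":
        return lp + spec.noise_sd * rng.standard_normal(size)
    p = expit(lp)
    return (rng.random(size) < p).astype(np.int64)


# --------------------------------------------------------------------------
# State <-> panel conversion
# --------------------------------------------------------------------------


def state_to_frame(state: dict[str, np.ndarray]) -> pd.DataFrame:
    """Convert an internal dict-of-arrays stage state to a panel DataFrame."""
    df = pd.DataFrame({
        c: state[c if c != "race" else "race_nonwhite"]
        for c in PANEL_COLUMNS if c != "race"
    })
    df.insert(
        list(PANEL_COLUMNS).index("race"),
        "race",
        np.where(np.asarray(state["race_nonwhite"]) == 1, "non-White", "White"),
    )
    return df[list(PANEL_COLUMNS)]


def frame_to_state(df: pd.DataFrame) -> dict[str, np.ndarray]:
    state = {}
    for c in PANEL_COLUMNS:
        if c == "race":
            state["race_nonwhite"] = (df["race"].to_numpy() == "non-White").astype(np.int64)
        elif c == "weight_status":
            state["weight_status"] = df["weight_status"].to_numpy(dtype=object)
        elif c in _STATE_INT:
            state[c] = df[c].to_numpy(dtype=np.int64)
        else:
            state[c] = df[c].to_numpy(dtype=float)
    return state


def _nbhd_attrs(state, neighborhoods: pd.DataFrame) -> dict[str, np.ndarray]:
    idx = neighborhoods.set_index("id")
    cols = ("pct_nonwhite", "pct_below_fpl", "pct_bachelor",
            "walkability", "park_access", "supermarket_density", "fastfood_density")
    nid = np.asarray(state["neighborhood_id"])
    return {c: idx[c].to_numpy(dtype=float)[idx.index.get_indexer(nid)] for c in cols}


def classify_state(state: dict[str, np.ndarray], ps: ParameterSet) -> None:
    """Fill bmi_z and weight_status from age and BMI (child z where age < 18)."""
    age = np.asarray(state["age"], dtype=float)
    bmi = np.asarray(state["bmi"], dtype=float)
    child = age < anthropometry.ADULT_AGE
    z = np.full(age.shape, np.nan)
    if child.any():
        z[child] = anthropometry.zscore_for_age(
            bmi[child], age[child], np.asarray(state["sex"])[child], ps.growth_reference
        )
    state["bmi_z"] = z
    state["weight_status"] = anthropometry.classify(age, bmi, z)


# --------------------------------------------------------------------------
# Stage advancement
# --------------------------------------------------------------------------


def _apply_post_draw(state, variable, stage, interventions, predictors):
    """Apply set-to-value overrides for one variable after its draw."""
    if not interventions:
        return
    from .scenarios import matching_mask  # local import to avoid a cycle

    for spec in interventions:
        if spec.rule == "set" and spec.variable == variable and stage in spec.stages:
            mask = matching_mask(spec, predictors, state)
            values = np.asarray(state[variable])
            values[mask] = spec.value
            state[variable] = values


def draw_variable(
    spec: EquationSpec,
    current: Mapping[str, np.ndarray],
    previous: Mapping[str, np.ndarray] | None,
    rng: np.random.Generator,
    n: int,
    interventions: Iterable | None = None,
    state: Mapping[str, np.ndarray] | None = None,
):
    """Draw one variable for all agents, honouring shift-probability rules.

    Shift rules add to the Bernoulli probability after link inversion and
    before the uniform comparison, clipped to [0, 1]; the random stream is
    consumed identically with or without interventions.
    """
    lp = np.broadcast_to(
        np.asarray(linear_predictor(spec, current, previous), dtype=float), (n,)
    )
    if spec.link == "identity":
        return lp + spec.noise_sd * rng.standard_normal(n)
    p = expit(lp)
    if interventions:
        from .scenarios import matching_mask

        for ispec in interventions:
            if (
                ispec.rule == "shift"
                and ispec.variable == spec.target
                and spec.stage in ispec.stages
            ):
                mask = matching_mask(ispec, current, state if state is not None else current)
                p = np.array(p)
                p[mask] = np.clip(p[mask] + ispec.value, 0.0, 1.0)
    return (rng.random(n) < p).astype(np.int64)


def advance_state(
    prev_state: dict[str, np.ndarray],
    neighborhoods: pd.DataFrame,
    ps: ParameterSet,
    t: int,
    rng: np.random.Generator,
    interventions: Iterable | None = None,
) -> dict[str, np.ndarray]:
    """Advance the internal stage state from t-1 to t (dict-of-arrays path)."""
    if not 1 <= t <= len(ps.schedule) - 1:
        raise ValueError(f"stage must be 1..{len(ps.schedule) - 1}, got {t}")
    order = np.argsort(prev_state["agent_id"], kind="stable")
    prev = {k: np.asarray(v)[order] for k, v in prev_state.items()}
    n = prev["agent_id"].shape[0]
    stage = ps.schedule[t]

    nbhd = _nbhd_attrs(prev, neighborhoods)
    prev_pred = dict(prev)
    prev_pred.update(nbhd)

    state = {
        "agent_id": prev["agent_id"],
        "neighborhood_id": prev["neighborhood_id"],
        "stage": np.full(n, t, dtype=np.int64),
        "sex": prev["sex"],
        "race_nonwhite": prev["race_nonwhite"],
        "ses_group": prev["ses_group"],
        "breastfed": np.zeros(n, dtype=np.int64),
        "smoking": np.zeros(n, dtype=np.int64),
        "alcohol": np.zeros(n, dtype=np.int64),
        "t2dm": np.zeros(n, dtype=np.int64),
    }
    state["age"] = rng.uniform(stage.age_low, stage.age_high, size=n)
    if stage.adult:
        state["marital"] = (rng.random(n) < ps.marital_prob[t]).astype(np.int64)
    else:
        state["marital"] = np.zeros(n, dtype=np.int64)

    current_pred = dict(nbhd)
    for k in ("sex", "race_nonwhite", "ses_group", "marital", "age"):
        current_pred[k] = state[k]

    for variable in stage_update_order(t, ps.schedule):
        spec = ps.equations[(variable, t)]
        values = draw_variable(
            spec, current_pred, prev_pred, rng, n, interventions, state
        )
        if variable == "bmi":
            values = np.clip(values, *ps.bmi_clip)
        if variable == "t2dm":
            values = np.maximum(values, prev["t2dm"])  # diagnosis is absorbing
        state[variable] = values
        _apply_post_draw(state, variable, t, interventions, current_pred)
        current_pred[variable] = state[variable]

    classify_state(state, ps)
    return state


def step(
    panel_prev: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    ps: ParameterSet,
    t: int,
    rng: np.random.Generator,
    interventions: Iterable | None = None,
) -> pd.DataFrame:
    """Advance a stage t-1 panel to stage t, returning the stage-t rows."""
    state = advance_state(frame_to_state(panel_prev), neighborhoods, ps, t, rng, interventions)
    return state_to_frame(state)


def run_simulation(
    ps: ParameterSet,
    seed: int | None = None,
    interventions: Iterable | None = None,
    replicate: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full closed cohort: returns (agent panel, neighborhoods).

    The panel has one row per agent per stage (population x 10 rows),
    ordered stage-major then agent-major.  The run is bit-reproducible for a
    fixed (seed, replicate) pair.
    """
    from .population import build_agents, build_neighborhoods  # avoid import cycle
    from .scenarios import apply_neighborhood_overrides

    if seed is None:
        seed = ps.seed
    t0 = time.perf_counter()
    logger.info("run start: seed=%s replicate=%s population=%s", seed, replicate, ps.population_size)

    neighborhoods = build_neighborhoods(ps, stream(seed, replicate, 0))
    if interventions:
        neighborhoods = apply_neighborhood_overrides(neighborhoods, interventions)
    state = build_agents(
        neighborhoods, ps, stream(seed, replicate, 1),
        interventions=interventions, as_state=True,
    )
    states = [state]
    for t in range(1, len(ps.schedule)):
        ts = time.perf_counter()
        state = advance_state(state, neighborhoods, ps, t, stream(seed, replicate, 100 + t),
                              interventions)
        logger.info(
            "stage %d done in %.2fs: %s", t, time.perf_counter() - ts,
            ", ".join(f"{v}={np.mean(state[v]):.3f}" for v in BEHAVIORS + ("bmi", "t2dm")),
        )
        states.append(state)

    panel = pd.concat([state_to_frame(s) for s in states], ignore_index=True)
    logger.info("run complete in %.2fs: %d panel rows", time.perf_counter() - t0, len(panel))
    return panel, neighborhoods


def stage_means(
    state_or_frame, variables: Iterable[str]
) -> dict[str, float]:
    """Mean (proportion for binaries) of each variable in one stage's rows."""
    return {
        v: float(np.mean(np.asarray(state_or_frame[v], dtype=float))) for v in variables
    }
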