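"""Calibration-in-the-large: sequential per-stage grid search plus R².

Intercepts (and, on request, feedback coefficients) are tuned so that mean
simulated behavior/outcome values match observed means or proportions per
life stage, minimizing a mean-absolute-error objective.  Tuning proceeds
sequentially from birth to the last stage; stages already tuned are frozen.
Within a stage, equations are tuned in the engine's evaluation order
(behaviors, then BMI, then T2DM) so that downstream equations see already
tuned inputs; each tunable is searched on a 1-D grid with one refinement
round, scoring each grid point on the mean of R replicate re-simulations of
the stage with common random numbers across grid points.

A single mean target per (variable, stage) cannot separately identify an
intercept and a feedback slope, so feedback coefficients are only tuned
when listed explicitly via ``feedback=...``; intercept-only is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import advance_state, stage_means, stream
from .params import (
    CalibrationTargetTable,
    ParameterSet,
    SchemaError,
    applicable_stages,
    engine_variables,
    stage_update_order,
)
from .population import build_agents, build_neighborhoods

__all__ = [
    "GridSpec",
    "CalibrationResult",
    "mae",
    "r_squared",
    "calibrate_stage",
    "calibrate",
    "simulated_targets",
]


@dataclass(frozen=True)
class GridSpec:
    """A 1-D search grid with optional refinement rounds."""

    lower: float
    upper: float
    points: int = 41
    refine_rounds: int = 1
    refine_factor: int = 5

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("grid lower bound must be below upper bound")
        if self.points < 3:
            raise ValueError("grid needs at least 3 points")

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / (self.points - 1)

    def values(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.points)

    @property
    def refined_spacing(self) -> float:
        """Cell width of the grid after all refinement rounds."""
        return self.spacing / (self.refine_factor ** self.refine_rounds)


def default_intercept_grid(incumbent: float, noise_sd: float = 0.0) -> GridSpec:
    """Default intercept grid: centred on the incumbent value.

    Centring on the incumbent (rather than on the observed mean) keeps the
    matching intercept inside the grid even for equations whose lagged and
    covariate terms offset the intercept far from the link-scale mean.
    """
    half = max(2.0, 2.0 * noise_sd)
    return GridSpec(incumbent - half, incumbent + half, points=41)


def mae(sim: Mapping[str, float], obs: Mapping[str, float] | pd.DataFrame) -> float:
    """Mean absolute error between simulated and observed variable means."""
    if isinstance(obs, pd.DataFrame):
        obs = dict(zip(obs["variable"], obs["observed_value"]))
    if set(sim) != set(obs):
        raise ValueError(
            f"variable mismatch: sim has {sorted(sim)}, obs has {sorted(obs)}"
        )
    if not sim:
        raise ValueError("no variables to compare")
    return float(np.mean([abs(sim[v] - obs[v]) for v in sim]))


def r_squared(sim: Sequence[float], obs: Sequence[float]) -> float | None:
    """Variance explained, 1 − SS_res/SS_tot, of observed vs simulated pairs.

    Returns ``None`` (undefined) with fewer than 3 paired points, mirroring
    the convention that R² is not computable on too few data points.
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("sim and obs series must have equal length")
    if sim.size < 3:
        return None
    ss_res = float(np.sum((obs - sim) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else None
    return 1.0 - ss_res / ss_tot


@dataclass
class CalibrationResult:
    """Outcome of a full sequential calibration."""

    params: ParameterSet
    mae_trace: pd.DataFrame  # stage, initial_mae, final_mae
    gaps: pd.DataFrame  # variable, stage, simulated, observed, gap
    r2: dict[str, float | None]
    replicates: int
    seed: int
    tuned: dict = field(default_factory=dict)  # (variable, stage[, predictor]) -> value


# --------------------------------------------------------------------------
# Internal scoring machinery
# --------------------------------------------------------------------------


def _calibrated_variables(stage: int, ps: ParameterSet) -> list[str]:
    """All behaviors and outcomes applicable at a stage, in update order."""
    return [v for v in stage_update_order(stage, ps.schedule)]


def _simulate_stage_once(ps, stage, prev_state, neighborhoods, seed, rep):
    if stage == 0:
        return build_agents(neighborhoods, ps, stream(seed, rep, 1), as_state=True)
    return advance_state(prev_state, neighborhoods, ps, stage, stream(seed, rep, 100 + stage))


def _score_stage(ps, stage, prev_states, nbhds, seed, replicates, variables):
    """Mean stage means over replicate re-simulations (CRN across calls)."""
    acc = {v: 0.0 for v in variables}
    for rep in range(replicates):
        prev = prev_states[rep] if prev_states is not None else None
        state = _simulate_stage_once(ps, stage, prev, nbhds[rep], seed, rep)
        for v, m in stage_means(state, variables).items():
            acc[v] += m
    return {v: acc[v] / replicates for v in variables}


def _tunables_for(variable, stage, feedback):
    """Tunable coefficients of one equation: intercept first, then feedback."""
    tunables = [("intercept", None)]
    for fb in feedback:
        if fb[0] == variable and (len(fb) < 4 or fb[3] == stage):
            tunables.append(("coefficient", (fb[1], fb[2])))
    return tunables


def _get_value(spec, kind, which):
    if kind == "intercept":
        return spec.intercept
    term = spec.term_for(*which)
    if term is None:
        raise KeyError(f"equation {spec.target!r} stage {spec.stage} has no term {which}")
    return term.coefficient


def _set_value(ps, variable, stage, kind, which, value):
    spec = ps.equations[(variable, stage)]
    if kind == "intercept":
        spec.intercept = float(value)
    else:
        from .params import Term

        spec.terms = tuple(
            Term(t.predictor, t.lag, float(value))
            if (t.predictor, t.lag) == which
            else t
            for t in spec.terms
        )


def calibrate_stage(
    ps: ParameterSet,
    targets: CalibrationTargetTable,
    stage: int,
    grids: Mapping | None = None,
    replicates: int = 3,
    seed: int = 0,
    prev_states=None,
    neighborhoods=None,
    feedback: Sequence = (),
) -> tuple[ParameterSet, dict]:
    """Tune the intercepts (and requested feedback coefficients) of one stage.

    Earlier stages must already be tuned and frozen: ``prev_states`` holds
    one frozen stage-(t−1) state per replicate (None at stage 0).  Returns
    a tuned copy of ``ps`` and an info dict with the MAE before/after and
    the selected values.  Candidate sets always include the incumbent value,
    so the stage MAE cannot increase; exact ties break toward the smallest
    absolute coefficient.
    """
    ps = ps.copy()
    grids = dict(grids or {})
    if neighborhoods is None:
        neighborhoods = [
            build_neighborhoods(ps, stream(seed, rep, 0)) for rep in range(replicates)
        ]
    stage_targets = targets.for_stage(stage)
    target_map = dict(zip(stage_targets["variable"], stage_targets["observed_value"]))
    variables = [v for v in _calibrated_variables(stage, ps) if v in target_map]
    if not variables:
        raise SchemaError(f"no calibration targets for stage {stage}")

    def score(pset):
        sim = _score_stage(pset, stage, prev_states, neighborhoods, seed, replicates, variables)
        return mae(sim, {v: target_map[v] for v in variables}), sim

    initial_mae, _ = score(ps)
    selected = {}
    for variable in variables:
        for kind, which in _tunables_for(variable, stage, feedback):
            spec = ps.equations[(variable, stage)]
            incumbent = _get_value(spec, kind, which)
            if kind == "intercept":
                grid = grids.get((variable, stage)) or default_intercept_grid(
                    incumbent, spec.noise_sd
                )
            else:
                grid = grids.get((variable, stage, which)) or (
                    GridSpec(min(0.0, 2 * incumbent), max(0.0, 2 * incumbent), 21)
                    if incumbent != 0
                    else GridSpec(-1.0, 1.0, 21)
                )
            candidates = list(grid.values()) + [incumbent]
            spacing = grid.spacing
            best_value, best_score = None, None
            for _ in range(grid.refine_rounds + 1):
                scored = []
                for value in candidates:
                    _set_value(ps, variable, stage, kind, which, value)
                    s, _ = score(ps)
                    scored.append((s, abs(value), value))
                scored.sort(key=lambda r: (r[0], r[1]))
                best_score, _, best_value = scored[0]
                spacing = spacing / grid.refine_factor
                candidates = list(
                    np.linspace(
                        best_value - grid.refine_factor * spacing,
                        best_value + grid.refine_factor * spacing,
                        2 * grid.refine_factor + 1,
                    )
                )
            _set_value(ps, variable, stage, kind, which, best_value)
            key = (variable, stage) if kind == "intercept" else (variable, stage, which)
            selected[key] = best_value

    final_mae, final_sim = score(ps)
    info = dict(
        stage=stage,
        initial_mae=initial_mae,
        final_mae=final_mae,
        selected=selected,
        simulated=final_sim,
        targets={v: target_map[v] for v in variables},
    )
    return ps, info


def calibrate(
    ps: ParameterSet,
    targets: CalibrationTargetTable,
    grids: Mapping | None = None,
    replicates: int = 3,
    seed: int = 0,
    feedback: Sequence = (),
) -> CalibrationResult:
    """Sequentially calibrate every stage from birth onward.

    Requires a target for every calibrated (variable, stage); missing
    targets raise a :class:`SchemaError` naming the gaps.  Deterministic for
    a fixed seed.  The per-variable R² compares the observed and simulated
    series across stages (undefined, ``None``, below 3 points).
    """
    missing = [
        (v, t)
        for v in engine_variables()
        for t in applicable_stages(v, ps.schedule)
        if targets.lookup(v, t) is None
    ]
    if missing:
        raise SchemaError(
            "missing calibration targets for: "
            + ", ".join(f"({v!r}, stage {t})" for v, t in missing)
        )

    ps = ps.copy()
    neighborhoods = [
        build_neighborhoods(ps, stream(seed, rep, 0)) for rep in range(replicates)
    ]
    prev_states = None
    trace_rows, tuned, gap_rows = [], {}, []
    sim_by_var: dict[str, dict[int, float]] = {}
    for stage in range(len(ps.schedule)):
        ps, info = calibrate_stage(
            ps, targets, stage,
            grids=grids, replicates=replicates, seed=seed,
            prev_states=prev_states, neighborhoods=neighborhoods, feedback=feedback,
        )
        tuned.update(info["selected"])
        trace_rows.append(
            dict(stage=stage, initial_mae=info["initial_mae"], final_mae=info["final_mae"])
        )
        for v, sim_value in info["simulated"].items():
            sim_by_var.setdefault(v, {})[stage] = sim_value
            gap_rows.append(
                dict(
                    variable=v, stage=stage, simulated=sim_value,
                    observed=info["targets"][v],
                    gap=abs(sim_value - info["targets"][v]),
                )
            )
        # Freeze this stage: advance each replicate's panel with the tuned
        # parameters, reusing the same streams the scoring consumed.
        prev_states = [
            _simulate_stage_once(
                ps, stage, prev_states[rep] if prev_states else None,
                neighborhoods[rep], seed, rep,
            )
            for rep in range(replicates)
        ]

    r2 = {}
    for v, by_stage in sim_by_var.items():
        stages = sorted(by_stage)
        obs = [targets.lookup(v, s) for s in stages]
        r2[v] = r_squared([by_stage[s] for s in stages], obs)

    return CalibrationResult(
        params=ps,
        mae_trace=pd.DataFrame(trace_rows),
        gaps=pd.DataFrame(gap_rows),
        r2=r2,
        replicates=replicates,
        seed=seed,
        tuned=tuned,
    )


def simulated_targets(
    ps: ParameterSet, replicates: int = 3, seed: int = 0
) -> CalibrationTargetTable:
    """Stage means simulated under ``ps`` packaged as a target table.

    Uses the same (seed, replicate, stage) stream convention as
    :func:`calibrate`, so calibrating against these targets with the same
    seed is a common-random-numbers parameter-recovery setting.
    """
    neighborhoods = [
        build_neighborhoods(ps, stream(seed, rep, 0)) for rep in range(replicates)
    ]
    acc: dict[tuple[str, int], float] = {}
    for rep in range(replicates):
        state = None
        for stage in range(len(ps.schedule)):
            state = _simulate_stage_once(ps, stage, state, neighborhoods[rep], seed, rep)
            for v in _calibrated_variables(stage, ps):
                acc[(v, stage)] = acc.get((v, stage), 0.0) + float(np.mean(state[v]))
    rows = [
        dict(
            variable=v, stage=s, observed_value=total / replicates,
            scale="continuous" if v == "bmi" else "proportion",
        )
        for (v, s), total in sorted(acc.items())
    ]
    return CalibrationTargetTable(pd.DataFrame(rows))
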