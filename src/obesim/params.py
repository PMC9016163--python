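"""Parameter configuration: life-stage schedule, equation specs, IO, defaults.

A :class:`ParameterSet` holds everything one simulation run needs: the
10-stage life-course schedule, the population structure (neighborhoods x
agents per neighborhood), the neighborhood socio-demographic distributions,
the environment-prediction equations, one behavior/outcome equation per
applicable (variable, stage), stage-specific marriage probabilities, and an
LMS growth reference.  :func:`default_parameter_set` synthesizes a complete,
internally consistent configuration whose coefficient signs follow the
causal structure of the model (sugary-drink and fast-food consumption raise
BMI, physical activity lowers it, BMI raises diabetes risk, and higher prior
BMI suppresses current activity — the feedback loop).

On disk a parameter set is a directory of plain-text files:

* ``params.yaml`` — structure (schedule, counts, distributions, marriage
  probabilities, BMI clip range, seed);
* ``equations.csv`` — one row per equation: variable, stage, link,
  intercept, noise_sd, evidence_level (stage ``-1`` = environment equation);
* ``coefficients.csv`` — one row per term: variable, stage, predictor, lag,
  coefficient, evidence_level;
* ``growth_reference.csv`` — sex, age_months, L, M, S.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from .anthropometry import synthetic_growth_reference, validate_growth_reference

__all__ = [
    "LifeStage",
    "LifeStageSchedule",
    "DEFAULT_SCHEDULE",
    "Term",
    "EquationSpec",
    "ParameterSet",
    "CalibrationTargetTable",
    "SchemaError",
    "BEHAVIORS",
    "ADULT_BEHAVIORS",
    "ENVIRONMENT_VARS",
    "NEIGHBORHOOD_SOCIODEM",
    "applicable_stages",
    "engine_variables",
    "stage_update_order",
    "validate_parameter_set",
    "load_parameter_set",
    "save_parameter_set",
    "default_parameter_set",
    "default_targets",
    "load_targets",
    "save_targets",
    "validate_targets",
]

# --------------------------------------------------------------------------
# Variable taxonomy
# --------------------------------------------------------------------------

#: Diet and activity behaviors, modeled at every life stage.
BEHAVIORS = ("ssb", "fastfood", "ffv", "activity")
#: Behaviors permitted only after the 18th birthday.
ADULT_BEHAVIORS = ("smoking", "alcohol")
#: Neighborhood activity/food environment attributes.
ENVIRONMENT_VARS = ("walkability", "park_access", "supermarket_density", "fastfood_density")
#: Neighborhood socio-demographic attributes (proportions).
NEIGHBORHOOD_SOCIODEM = ("pct_nonwhite", "pct_below_fpl", "pct_bachelor")
#: Agent-level socio-demographic predictors available to equations.
AGENT_SOCIODEM = ("sex", "race_nonwhite", "ses_group", "marital")


class SchemaError(ValueError):
    """A parameter configuration violates its schema invariants."""


# --------------------------------------------------------------------------
# Life-stage schedule
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeStage:
    index: int
    age_low: float
    age_high: float

    @property
    def adult(self) -> bool:
        return self.age_low >= 18.0

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_low + self.age_high)

    @property
    def label(self) -> str:
        return f"{self.age_low:g}-{self.age_high:g}"


@dataclass(frozen=True)
class LifeStageSchedule:
    """The ordered discrete life stages an agent is advanced through."""

    stages: tuple[LifeStage, ...]

    def __post_init__(self):
        problems = self.validate()
        if problems:
            raise SchemaError("; ".join(problems))

    def validate(self) -> list[str]:
        problems = []
        if len(self.stages) != 10:
            problems.append(f"schedule must have exactly 10 stages, got {len(self.stages)}")
            return problems
        if [s.index for s in self.stages] != list(range(10)):
            problems.append("stage indices must be 0..9 in order")
        if (self.stages[0].age_low, self.stages[0].age_high) != (0.0, 1.0):
            problems.append("stage 0 must span ages 0-1")
        if (self.stages[9].age_low, self.stages[9].age_high) != (60.0, 65.0):
            problems.append("stage 9 must span ages 60-65")
        for a, b in zip(self.stages, self.stages[1:]):
            if not (a.age_low < a.age_high <= b.age_low < b.age_high):
                problems.append(
                    f"stage bands must be increasing and non-overlapping "
                    f"(stages {a.index} and {b.index})"
                )
        return problems

    def __getitem__(self, index: int) -> LifeStage:
        return self.stages[index]

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def adult_stages(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.stages if s.adult)

    def stage_for_age(self, age: float) -> int:
        for s in self.stages:
            if s.age_low <= age <= s.age_high:
                return s.index
        raise ValueError(f"age {age} outside all stage bands")


def _make_schedule(bands) -> LifeStageSchedule:
    return LifeStageSchedule(
        tuple(LifeStage(i, float(lo), float(hi)) for i, (lo, hi) in enumerate(bands))
    )


#: Default age bands: birth through middle adulthood in 10 stages.
DEFAULT_SCHEDULE = _make_schedule(
    [(0, 1), (2, 5), (6, 12), (13, 17), (18, 24), (25, 29), (30, 39), (40, 49), (50, 59), (60, 65)]
)


def applicable_stages(variable: str, schedule: LifeStageSchedule) -> tuple[int, ...]:
    """Stages at which the engine updates ``variable``."""
    if variable == "breastfed":
        return (0,)
    if variable in BEHAVIORS or variable == "bmi":
        return tuple(range(len(schedule)))
    if variable in ADULT_BEHAVIORS or variable == "t2dm":
        return schedule.adult_stages
    raise KeyError(f"unknown engine variable {variable!r}")


def engine_variables() -> tuple[str, ...]:
    """All variables the engine updates through equations."""
    return ("breastfed",) + BEHAVIORS + ADULT_BEHAVIORS + ("bmi", "t2dm")


def stage_update_order(stage: int, schedule: LifeStageSchedule) -> tuple[str, ...]:
    """Within-stage evaluation order: behaviors, then BMI, then T2DM."""
    order = []
    if stage == 0:
        order.append("breastfed")
    order.extend(BEHAVIORS)
    if schedule[stage].adult:
        order.extend(ADULT_BEHAVIORS)
    order.append("bmi")
    if schedule[stage].adult:
        order.append("t2dm")
    return tuple(order)


# --------------------------------------------------------------------------
# Equations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One linear-predictor term: coefficient on a (possibly lagged) predictor."""

    predictor: str
    lag: int
    coefficient: float


@dataclass
class EquationSpec:
    """One regression equation used as a stochastic update rule.

    identity link: value = intercept + sum(coef * x) + Normal(0, noise_sd)
    logit link:    value ~ Bernoulli(expit(intercept + sum(coef * x)))
    """

    target: str
    stage: int  # -1 for neighborhood-environment equations
    link: str  # "identity" | "logit"
    intercept: float
    terms: tuple[Term, ...] = ()
    noise_sd: float = 0.0
    evidence_level: str = "synthetic"

    def __post_init__(self):
        self.terms = tuple(
            t if isinstance(t, Term) else Term(*t) for t in self.terms
        )

    def validate(self) -> list[str]:
        problems = []
        where = f"equation {self.target!r} stage {self.stage}"
        if self.link not in ("identity", "logit"):
            problems.append(f"{where}: unknown link {self.link!r}")
        if self.noise_sd < 0:
            problems.append(f"{where}: noise_sd must be >= 0, got {self.noise_sd}")
        if self.link == "logit" and self.noise_sd != 0:
            problems.append(f"{where}: logit-link equations must have noise_sd = 0")
        if str(self.evidence_level) not in ("1", "2", "3", "synthetic"):
            problems.append(f"{where}: evidence_level must be 1, 2, 3 or 'synthetic'")
        for t in self.terms:
            if t.lag not in (0, 1):
                problems.append(f"{where}: lag must be 0 or 1 on predictor {t.predictor!r}")
        return problems

    def term_for(self, predictor: str, lag: int) -> Term | None:
        for t in self.terms:
            if t.predictor == predictor and t.lag == lag:
                return t
        return None


# --------------------------------------------------------------------------
# Calibration targets
# --------------------------------------------------------------------------


@dataclass
class CalibrationTargetTable:
    """Observed mean/proportion per (variable, life stage) used for calibration."""

    rows: pd.DataFrame  # columns: variable, stage, observed_value, scale

    COLUMNS = ("variable", "stage", "observed_value", "scale")

    def __post_init__(self):
        self.rows = pd.DataFrame(self.rows)[list(self.COLUMNS)].reset_index(drop=True)
        self.rows["stage"] = self.rows["stage"].astype(int)
        self.rows["observed_value"] = self.rows["observed_value"].astype(float)

    def validate(self) -> list[str]:
        problems = []
        bad_scale = set(self.rows["scale"]) - {"proportion", "continuous"}
        if bad_scale:
            problems.append(f"target table: unknown scales {sorted(bad_scale)}")
        props = self.rows[self.rows["scale"] == "proportion"]
        bad = props[(props["observed_value"] < 0) | (props["observed_value"] > 1)]
        for _, r in bad.iterrows():
            problems.append(
                f"target table: proportion target {r['observed_value']} for "
                f"{r['variable']!r} stage {int(r['stage'])} outside [0, 1]"
            )
        dup = self.rows.duplicated(subset=["variable", "stage"])
        if dup.any():
            pairs = self.rows.loc[dup, ["variable", "stage"]].itertuples(index=False)
            problems.append(
                "target table: duplicate (variable, stage) rows: "
                + ", ".join(f"({v!r}, {s})" for v, s in pairs)
            )
        return problems

    def lookup(self, variable: str, stage: int) -> float | None:
        m = self.rows[(self.rows["variable"] == variable) & (self.rows["stage"] == stage)]
        if m.empty:
            return None
        return float(m["observed_value"].iloc[0])

    def for_stage(self, stage: int) -> pd.DataFrame:
        return self.rows[self.rows["stage"] == stage]

    def __eq__(self, other):
        return isinstance(other, CalibrationTargetTable) and self.rows.equals(other.rows)


def validate_targets(targets: CalibrationTargetTable) -> list[str]:
    return targets.validate()


def load_targets(path) -> CalibrationTargetTable:
    table = CalibrationTargetTable(pd.read_csv(path, float_precision="round_trip"))
    problems = table.validate()
    if problems:
        raise SchemaError("; ".join(problems))
    return table


def save_targets(targets: CalibrationTargetTable, path) -> None:
    targets.rows.to_csv(path, index=False)


# --------------------------------------------------------------------------
# ParameterSet
# --------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Full configuration for one simulation."""

    schedule: LifeStageSchedule
    n_neighborhoods: int
    agents_per_neighborhood: int
    population_size: int
    #: name -> (mean, sd) of the truncated-normal neighborhood proportion draw
    neighborhood_distributions: dict[str, tuple[float, float]]
    #: environment attribute -> EquationSpec (stage -1, identity link)
    environment: dict[str, EquationSpec]
    #: (variable, stage) -> EquationSpec
    equations: dict[tuple[str, int], EquationSpec]
    #: adult stage index -> probability of being married at that stage
    marital_prob: dict[int, float]
    growth_reference: pd.DataFrame = field(repr=False)
    bmi_clip: tuple[float, float] = (10.0, 80.0)
    seed: int = 0

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            schedule=self.schedule,
            n_neighborhoods=self.n_neighborhoods,
            agents_per_neighborhood=self.agents_per_neighborhood,
            population_size=self.population_size,
            neighborhood_distributions={
                k: tuple(v) for k, v in self.neighborhood_distributions.items()
            },
            environment={k: dataclasses.replace(v) for k, v in self.environment.items()},
            equations={k: dataclasses.replace(v) for k, v in self.equations.items()},
            marital_prob=dict(self.marital_prob),
            growth_reference=self.growth_reference.copy(),
            bmi_clip=tuple(self.bmi_clip),
            seed=self.seed,
        )

    def __eq__(self, other):
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (
            self.schedule == other.schedule
            and self.n_neighborhoods == other.n_neighborhoods
            and self.agents_per_neighborhood == other.agents_per_neighborhood
            and self.population_size == other.population_size
            and self.neighborhood_distributions == other.neighborhood_distributions
            and self.environment == other.environment
            and self.equations == other.equations
            and self.marital_prob == other.marital_prob
            and self.bmi_clip == other.bmi_clip
            and self.seed == other.seed
            and self.growth_reference.reset_index(drop=True).equals(
                other.growth_reference.reset_index(drop=True)
            )
        )


def _known_predictors(stage: int, schedule: LifeStageSchedule) -> set[str]:
    """Predictors resolvable at lag 0 for a stage-``stage`` equation."""
    known = set(AGENT_SOCIODEM) | set(ENVIRONMENT_VARS) | set(NEIGHBORHOOD_SOCIODEM)
    for v in engine_variables():
        if stage in applicable_stages(v, schedule):
            known.add(v)
    return known


def validate_parameter_set(ps: ParameterSet) -> list[str]:
    """All invariant violations of a parameter set (empty list = valid).

    Violations are data, not exceptions; each names the variable, stage and
    rule breached.
    """
    problems = list(ps.schedule.validate())
    sched = ps.schedule

    if ps.n_neighborhoods <= 0 or ps.agents_per_neighborhood <= 0:
        problems.append("population structure: counts must be positive")
    if ps.n_neighborhoods * ps.agents_per_neighborhood != ps.population_size:
        problems.append(
            f"population structure: {ps.n_neighborhoods} x {ps.agents_per_neighborhood} "
            f"!= declared population size {ps.population_size}"
        )

    for name in NEIGHBORHOOD_SOCIODEM:
        if name not in ps.neighborhood_distributions:
            problems.append(f"neighborhood distribution missing for {name!r}")
            continue
        mean, sd = ps.neighborhood_distributions[name]
        if not (0.0 <= mean <= 1.0):
            problems.append(f"neighborhood {name!r}: mean proportion {mean} outside [0, 1]")
        if sd < 0:
            problems.append(f"neighborhood {name!r}: sd must be >= 0")

    for name in ENVIRONMENT_VARS:
        spec = ps.environment.get(name)
        if spec is None:
            problems.append(f"environment equation missing for {name!r}")
            continue
        problems.extend(spec.validate())
        if spec.link != "identity":
            problems.append(f"environment equation {name!r}: link must be identity")
        for t in spec.terms:
            if t.lag != 0 or t.predictor not in NEIGHBORHOOD_SOCIODEM:
                problems.append(
                    f"environment equation {name!r}: predictor {t.predictor!r} (lag {t.lag}) "
                    "must be an unlagged neighborhood socio-demographic"
                )

    # Coverage: exactly one equation per applicable (variable, stage), none elsewhere.
    expected = {
        (v, t) for v in engine_variables() for t in applicable_stages(v, sched)
    }
    present = set(ps.equations)
    for v, t in sorted(expected - present):
        problems.append(f"missing equation for {v!r} at stage {t}")
    for v, t in sorted(present - expected):
        if v in engine_variables():
            problems.append(
                f"equation for {v!r} at stage {t} is not applicable "
                "(adult-only variables exist only at stages with age_low >= 18)"
            )
        else:
            problems.append(f"equation for unknown variable {v!r} at stage {t}")

    for (v, t), spec in sorted(ps.equations.items()):
        problems.extend(spec.validate())
        if spec.target != v or spec.stage != t:
            problems.append(
                f"equation keyed ({v!r}, {t}) declares target {spec.target!r} stage {spec.stage}"
            )
        expected_link = "identity" if v == "bmi" else "logit"
        if spec.link != expected_link:
            problems.append(f"equation {v!r} stage {t}: link must be {expected_link}")
        lag0_known = _known_predictors(t, sched)
        lag1_known = _known_predictors(t - 1, sched) if t > 0 else set()
        for term in spec.terms:
            if term.lag == 1 and t == 0:
                problems.append(f"equation {v!r} stage 0: lagged predictor {term.predictor!r}")
            elif term.lag == 1 and term.predictor not in lag1_known:
                problems.append(
                    f"equation {v!r} stage {t}: lag-1 predictor {term.predictor!r} "
                    f"does not exist at stage {t - 1}"
                )
            elif term.lag == 0 and term.predictor not in lag0_known:
                problems.append(
                    f"equation {v!r} stage {t}: unknown predictor {term.predictor!r}"
                )

    for t in sched.adult_stages:
        p = ps.marital_prob.get(t)
        if p is None:
            problems.append(f"marital probability missing for adult stage {t}")
        elif not (0.0 <= p <= 1.0):
            problems.append(f"marital probability {p} at stage {t} outside [0, 1]")
    for t in ps.marital_prob:
        if t not in sched.adult_stages:
            problems.append(f"marital probability given for non-adult stage {t}")

    if not ps.bmi_clip[0] < ps.bmi_clip[1]:
        problems.append("bmi_clip: lower bound must be below upper bound")
    problems.extend(validate_growth_reference(ps.growth_reference))
    return problems


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

PARAMS_YAML = "params.yaml"
EQUATIONS_CSV = "equations.csv"
COEFFICIENTS_CSV = "coefficients.csv"
GROWTH_CSV = "growth_reference.csv"


def save_parameter_set(ps: ParameterSet, path) -> None:
    """Write a parameter set to a directory of plain-text files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    structure = {
        "schedule": [[s.index, s.age_low, s.age_high] for s in ps.schedule.stages],
        "n_neighborhoods": ps.n_neighborhoods,
        "agents_per_neighborhood": ps.agents_per_neighborhood,
        "population_size": ps.population_size,
        "neighborhood_distributions": {
            k: [float(v[0]), float(v[1])] for k, v in ps.neighborhood_distributions.items()
        },
        "marital_prob": {int(k): float(v) for k, v in ps.marital_prob.items()},
        "bmi_clip": [float(ps.bmi_clip[0]), float(ps.bmi_clip[1])],
        "seed": int(ps.seed),
    }
    (path / PARAMS_YAML).write_text(yaml.safe_dump(structure, sort_keys=False))

    all_specs = list(ps.environment.values()) + [
        ps.equations[k] for k in sorted(ps.equations)
    ]
    eq_rows, coef_rows = [], []
    for spec in all_specs:
        eq_rows.append(
            dict(
                variable=spec.target,
                stage=spec.stage,
                link=spec.link,
                intercept=spec.intercept,
                noise_sd=spec.noise_sd,
                evidence_level=spec.evidence_level,
            )
        )
        for t in spec.terms:
            coef_rows.append(
                dict(
                    variable=spec.target,
                    stage=spec.stage,
                    predictor=t.predictor,
                    lag=t.lag,
                    coefficient=t.coefficient,
                    evidence_level=spec.evidence_level,
                )
            )
    pd.DataFrame(eq_rows).to_csv(path / EQUATIONS_CSV, index=False)
    pd.DataFrame(
        coef_rows,
        columns=["variable", "stage", "predictor", "lag", "coefficient", "evidence_level"],
    ).to_csv(path / COEFFICIENTS_CSV, index=False)
    ps.growth_reference.to_csv(path / GROWTH_CSV, index=False)


def load_parameter_set(path) -> ParameterSet:
    """Read and validate a parameter set directory; fail atomically if invalid."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"parameter set directory not found: {path}")
    structure = yaml.safe_load((path / PARAMS_YAML).read_text())
    schedule = _make_schedule([(lo, hi) for _, lo, hi in structure["schedule"]])

    eq_df = pd.read_csv(path / EQUATIONS_CSV, float_precision="round_trip")
    coef_df = pd.read_csv(path / COEFFICIENTS_CSV, float_precision="round_trip")
    terms_by_key: dict[tuple[str, int], list[Term]] = {}
    for r in coef_df.itertuples(index=False):
        terms_by_key.setdefault((r.variable, int(r.stage)), []).append(
            Term(r.predictor, int(r.lag), float(r.coefficient))
        )
    environment, equations = {}, {}
    for r in eq_df.itertuples(index=False):
        spec = EquationSpec(
            target=r.variable,
            stage=int(r.stage),
            link=r.link,
            intercept=float(r.intercept),
            terms=tuple(terms_by_key.get((r.variable, int(r.stage)), ())),
            noise_sd=float(r.noise_sd),
            evidence_level=str(r.evidence_level),
        )
        if spec.stage == -1:
            environment[spec.target] = spec
        else:
            equations[(spec.target, spec.stage)] = spec

    ps = ParameterSet(
        schedule=schedule,
        n_neighborhoods=int(structure["n_neighborhoods"]),
        agents_per_neighborhood=int(structure["agents_per_neighborhood"]),
        population_size=int(structure["population_size"]),
        neighborhood_distributions={
            k: (float(v[0]), float(v[1]))
            for k, v in structure["neighborhood_distributions"].items()
        },
        environment=environment,
        equations=equations,
        marital_prob={int(k): float(v) for k, v in structure["marital_prob"].items()},
        growth_reference=pd.read_csv(path / GROWTH_CSV, float_precision="round_trip"),
        bmi_clip=tuple(float(x) for x in structure["bmi_clip"]),
        seed=int(structure["seed"]),
    )
    problems = validate_parameter_set(ps)
    if problems:
        raise SchemaError("invalid parameter set:\n  " + "\n  ".join(problems))
    return ps


# --------------------------------------------------------------------------
# Synthetic default parameter set
# --------------------------------------------------------------------------

# Designed stage trajectories for the default configuration: proportions for
# binary behaviors/outcomes, means and cross-sectional SDs for BMI.  These are
# the study conditions the default model emulates (high and falling fast-food
# and sugary-drink consumption, low and falling activity with an adolescent
# trough, roughly constant fruit/vegetable intake, rising adult BMI, and a
# T2DM incidence profile that is <2% at ages 18-24 and peaks near age 40-49).
_TRAJECTORIES = {
    "breastfed": {0: 0.20},
    "fastfood": [0.30, 0.78, 0.85, 0.82, 0.75, 0.72, 0.70, 0.66, 0.62, 0.58],
    "ssb": [0.25, 0.62, 0.70, 0.68, 0.62, 0.58, 0.55, 0.52, 0.48, 0.45],
    "activity": [0.55, 0.50, 0.40, 0.20, 0.35, 0.33, 0.30, 0.27, 0.24, 0.20],
    "ffv": [0.55, 0.50, 0.45, 0.42, 0.45, 0.46, 0.47, 0.48, 0.50, 0.52],
    "smoking": {4: 0.12, 5: 0.15, 6: 0.16, 7: 0.15, 8: 0.13, 9: 0.10},
    "alcohol": {4: 0.45, 5: 0.55, 6: 0.55, 7: 0.52, 8: 0.48, 9: 0.42},
    # per-stage T2DM incidence among the not-yet-diagnosed
    "t2dm": {4: 0.012, 5: 0.05, 6: 0.12, 7: 0.25, 8: 0.20, 9: 0.16},
}
_BMI_MEANS = [16.5, 16.2, 18.0, 21.5, 25.5, 26.5, 27.5, 28.1, 28.6, 29.0]
_BMI_SDS = [1.5, 1.8, 3.0, 3.2, 4.5, 4.8, 5.0, 5.2, 5.3, 5.4]
_BMI_LAG = [0.0, 0.6, 0.6, 0.6, 0.6, 0.75, 0.75, 0.75, 0.75, 0.75]

_NBHD_DISTS = {
    "pct_nonwhite": (0.635, 0.20),
    "pct_below_fpl": (0.22, 0.12),
    "pct_bachelor": (0.30, 0.15),
}

_MARITAL = {4: 0.20, 5: 0.45, 6: 0.60, 7: 0.65, 8: 0.65, 9: 0.62}


def _environment_specs() -> dict[str, EquationSpec]:
    def env(target, intercept, terms, noise_sd):
        return EquationSpec(
            target=target,
            stage=-1,
            link="identity",
            intercept=intercept,
            terms=tuple(Term(p, 0, c) for p, c in terms),
            noise_sd=noise_sd,
        )

    return {
        "walkability": env(
            "walkability", 45.0,
            [("pct_bachelor", 20.0), ("pct_below_fpl", -5.0), ("pct_nonwhite", 5.0)], 8.0
        ),
        "park_access": env(
            "park_access", 6.0, [("pct_bachelor", 3.0), ("pct_below_fpl", -2.0)], 1.5
        ),
        "supermarket_density": env(
            "supermarket_density", 1.2, [("pct_bachelor", 1.0), ("pct_below_fpl", -0.8)], 0.3
        ),
        "fastfood_density": env(
            "fastfood_density", 1.0, [("pct_below_fpl", 2.0), ("pct_nonwhite", 0.5)], 0.3
        ),
    }


# (predictor, coefficient) blocks shared across stages; neighborhood terms
# enter diet/activity equations only.
_SOCIODEM_COEFS = {
    "breastfed": [("sex", 0.0), ("race_nonwhite", -0.2), ("ses_group", -0.3)],
    "ssb": [("sex", 0.10), ("race_nonwhite", 0.20), ("ses_group", 0.20)],
    "fastfood": [("sex", 0.05), ("race_nonwhite", -0.15), ("ses_group", 0.20)],
    "ffv": [("sex", -0.05), ("race_nonwhite", 0.10), ("ses_group", -0.20)],
    "activity": [("sex", 0.15), ("race_nonwhite", -0.25), ("ses_group", -0.15)],
    "smoking": [("sex", 0.10), ("race_nonwhite", 0.10), ("ses_group", 0.30)],
    "alcohol": [("sex", 0.15), ("race_nonwhite", -0.10), ("ses_group", -0.10)],
    "bmi": [("sex", 0.20), ("race_nonwhite", 0.30), ("ses_group", 0.20)],
    "t2dm": [("sex", 0.10), ("race_nonwhite", 0.50), ("ses_group", 0.30)],
}
_NBHD_COEFS = {
    "ssb": [("fastfood_density", 0.05)],
    "fastfood": [("fastfood_density", 0.10), ("supermarket_density", -0.05)],
    "ffv": [("supermarket_density", 0.10)],
    "activity": [("walkability", 0.010), ("park_access", 0.010)],
}
_BEHAVIOR_LAG_COEF = 0.8
#: Feedback: higher previous BMI suppresses current physical activity.
ACTIVITY_BMI_FEEDBACK = -0.04
_BMI_BEHAVIOR_COEFS = [
    ("ssb", 0.5), ("fastfood", 0.5), ("ffv", -0.3), ("activity", -0.8)
]
_BMI_ADULT_BEHAVIOR_COEFS = [("smoking", -0.3), ("alcohol", 0.2)]
_T2DM_COEFS = [
    ("bmi", 0.10), ("activity", -0.30), ("ssb", 0.20), ("fastfood", 0.15),
    ("ffv", -0.10), ("smoking", 0.20), ("alcohol", 0.10),
]


def _target(variable: str, stage: int) -> float:
    traj = _TRAJECTORIES[variable]
    return traj[stage] if isinstance(traj, dict) else traj[stage]


def _mean_predictor_value(name: str, stage: int, env_means: dict[str, float]) -> float:
    """Approximate population mean of a predictor at a stage (for intercept centring)."""
    sociodem = {
        "sex": 0.5,
        "race_nonwhite": _NBHD_DISTS["pct_nonwhite"][0],
        "ses_group": _NBHD_DISTS["pct_below_fpl"][0],
    }
    if name in sociodem:
        return sociodem[name]
    if name == "marital":
        return _MARITAL.get(stage, 0.0)
    if name in env_means:
        return env_means[name]
    if name == "bmi":
        return _BMI_MEANS[stage]
    if name == "breastfed":
        return _TRAJECTORIES["breastfed"][0] if stage == 0 else 0.0
    traj = _TRAJECTORIES.get(name)
    if traj is not None:
        if isinstance(traj, dict):
            return traj.get(stage, 0.0)
        return traj[stage]
    raise KeyError(name)


def default_parameter_set(
    seed: int,
    n_neighborhoods: int = 235,
    agents_per_neighborhood: int = 418,
) -> ParameterSet:
    """Synthesize the complete default configuration.

    The coefficient values are invented but sign-consistent with the model's
    causal structure, and every intercept is centred analytically so that the
    simulated stage means track the designed trajectories (the centring uses
    mean covariate values, so realized means differ slightly — calibration
    closes the gap when needed).  ``seed`` is stored as the default run seed;
    synthesis itself is deterministic given the arguments.
    """
    sched = DEFAULT_SCHEDULE
    environment = _environment_specs()
    env_means = {
        name: spec.intercept
        + sum(t.coefficient * _NBHD_DISTS[t.predictor][0] for t in spec.terms)
        for name, spec in environment.items()
    }

    equations: dict[tuple[str, int], EquationSpec] = {}

    def terms_for(variable: str, stage: int) -> list[Term]:
        terms = [Term(p, 0, c) for p, c in _SOCIODEM_COEFS[variable]]
        if variable in _NBHD_COEFS:
            terms += [Term(p, 0, c) for p, c in _NBHD_COEFS[variable]]
        if stage > 0 and variable in BEHAVIORS + ADULT_BEHAVIORS + ("breastfed",):
            if stage - 1 in applicable_stages(variable, sched):
                terms.append(Term(variable, 1, _BEHAVIOR_LAG_COEF))
        if variable == "activity" and stage > 0:
            terms.append(Term("bmi", 1, ACTIVITY_BMI_FEEDBACK))
        if variable == "bmi":
            terms += [Term(p, 0, c) for p, c in _BMI_BEHAVIOR_COEFS]
            if sched[stage].adult:
                terms += [Term(p, 0, c) for p, c in _BMI_ADULT_BEHAVIOR_COEFS]
            if stage > 0:
                terms.append(Term("bmi", 1, _BMI_LAG[stage]))
        if variable == "t2dm":
            terms += [Term(p, 0, c) for p, c in _T2DM_COEFS]
        return terms

    for variable in engine_variables():
        for stage in applicable_stages(variable, sched):
            terms = terms_for(variable, stage)
            contribution = 0.0
            for t in terms:
                ref_stage = stage - t.lag
                contribution += t.coefficient * _mean_predictor_value(
                    t.predictor, ref_stage, env_means
                )
            if variable == "bmi":
                m = _BMI_MEANS[stage]
                intercept = m - contribution
                if stage == 0:
                    noise = _BMI_SDS[0]
                else:
                    rho = _BMI_LAG[stage]
                    var = _BMI_SDS[stage] ** 2 - (rho * _BMI_SDS[stage - 1]) ** 2
                    noise = float(np.sqrt(max(var, 0.25)))
                spec = EquationSpec(variable, stage, "identity", intercept, tuple(terms), noise)
            else:
                p = _target(variable, stage)
                intercept = float(logit(p)) - contribution
                spec = EquationSpec(variable, stage, "logit", intercept, tuple(terms), 0.0)
            equations[(variable, stage)] = spec

    ps = ParameterSet(
        schedule=sched,
        n_neighborhoods=n_neighborhoods,
        agents_per_neighborhood=agents_per_neighborhood,
        population_size=n_neighborhoods * agents_per_neighborhood,
        neighborhood_distributions=dict(_NBHD_DISTS),
        environment=environment,
        equations=equations,
        marital_prob=dict(_MARITAL),
        growth_reference=synthetic_growth_reference(),
        seed=int(seed),
    )
    problems = validate_parameter_set(ps)
    if problems:  # pragma: no cover - construction bug guard
        raise SchemaError("default parameter set invalid:\n  " + "\n  ".join(problems))
    return ps


def default_targets(ps: ParameterSet | None = None) -> CalibrationTargetTable:
    """The designed stage trajectories as a calibration-target table.

    T2DM is expressed as stage prevalence (the quantity a simulated panel
    mean measures under the absorbing-diagnosis rule), accumulated from the
    designed per-stage incidences.
    """
    rows = []
    t2dm_prev, at_risk = {}, 1.0
    for stage in sorted(_TRAJECTORIES["t2dm"]):
        at_risk *= 1.0 - _TRAJECTORIES["t2dm"][stage]
        t2dm_prev[stage] = 1.0 - at_risk
    for variable in engine_variables():
        stages = applicable_stages(variable, DEFAULT_SCHEDULE)
        for stage in stages:
            if variable == "bmi":
                rows.append(("bmi", stage, _BMI_MEANS[stage], "continuous"))
            elif variable == "t2dm":
                rows.append(("t2dm", stage, t2dm_prev[stage], "proportion"))
            else:
                rows.append((variable, stage, _target(variable, stage), "proportion"))
    return CalibrationTargetTable(
        pd.DataFrame(rows, columns=list(CalibrationTargetTable.COLUMNS))
    )
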