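"""Cohort epidemiologic measures from an agent panel.

For each risk window (e.g. obesity ages 2-65, T2DM ages 18-65) the module
identifies first events among at-risk agents (those without the condition
at window entry), accrues person-time (events contribute time to the event
stage's midpoint age, censored agents the full window width), and reports
average incidence rates per 1,000 person-years with Poisson-approximate
Wald intervals and cumulative incidences with binomial Wald intervals —
the layout of a classic cohort-incidence table stratified by race.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import LifeStageSchedule, applicable_stages

__all__ = [
    "RiskWindow",
    "DEFAULT_WINDOWS",
    "first_events",
    "person_time",
    "cumulative_incidence",
    "incidence_rate",
    "age_specific_incidence",
    "prevalence",
    "measure_table",
]

Z95 = 1.96

_STATUS_COLUMNS = {"obesity": None, "t2dm": "t2dm"}


@dataclass(frozen=True)
class RiskWindow:
    """One outcome followed over an age window, with at-risk entry rule."""

    outcome: str  # "obesity" | "t2dm"
    age_low: float
    age_high: float
    label: str = ""

    def __post_init__(self):
        if self.outcome not in _STATUS_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be below age_high")
        if self.outcome == "t2dm" and self.age_low < 18:
            raise ValueError("t2dm risk windows must start at age >= 18")

    @property
    def width(self) -> float:
        return self.age_high - self.age_low

    def stages(self, schedule: LifeStageSchedule) -> list[int]:
        """Stage indices whose age band lies within the window."""
        return [
            s.index
            for s in schedule.stages
            if s.age_low >= self.age_low and s.age_high <= self.age_high
        ]

    def name(self) -> str:
        return self.label or f"{self.outcome} ({self.age_low:g}-{self.age_high:g})"


DEFAULT_WINDOWS = (
    RiskWindow("obesity", 2, 65, "Obesity (2-65)"),
    RiskWindow("obesity", 2, 17, "Obesity childhood (2-17)"),
    RiskWindow("obesity", 18, 65, "Obesity adulthood (18-65)"),
    RiskWindow("t2dm", 18, 65, "Type 2 diabetes adulthood (18-65)"),
)


def _status_matrix(panel: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """agents x stages boolean status (obese / diagnosed) pivot."""
    if outcome == "obesity":
        status = (panel["weight_status"] == "obese").astype(int)
    else:
        status = panel["t2dm"].astype(int)
    wide = (
        pd.DataFrame(
            {"agent_id": panel["agent_id"], "stage": panel["stage"], "status": status}
        )
        .pivot(index="agent_id", columns="stage", values="status")
    )
    if wide.isna().any().any():
        raise ValueError("panel is incomplete: every agent needs one row per stage")
    return wide.astype(bool)


def first_events(
    panel: pd.DataFrame, window: RiskWindow, schedule: LifeStageSchedule
) -> pd.DataFrame:
    """Per-agent at-risk flag, first-event flag and event/censor timing.

    An agent is at risk if not positive at the stage preceding window entry
    (agents positive before the window are excluded).  The event stage is
    the first in-window stage with positive status; the event age is that
    stage's midpoint.  Agents without an event are censored at window end.
    """
    stages = window.stages(schedule)
    if not stages:
        raise ValueError(f"window {window.name()} covers no complete life stage")
    wide = _status_matrix(panel, window.outcome)
    entry_stage = stages[0]
    at_risk = (
        ~wide[entry_stage - 1].to_numpy()
        if entry_stage > 0
        else np.ones(len(wide), dtype=bool)
    )
    in_window = wide[stages].to_numpy()
    any_event = in_window.any(axis=1)
    first_idx = in_window.argmax(axis=1)  # first True column, 0 if none
    event = at_risk & any_event
    event_stage = np.where(event, np.asarray(stages)[first_idx], -1)
    midpoints = {s: schedule[s].midpoint for s in stages}
    event_age = np.where(
        event, np.vectorize(lambda s: midpoints.get(s, np.nan))(event_stage), np.nan
    )
    return pd.DataFrame(
        {
            "agent_id": wide.index.to_numpy(),
            "at_risk": at_risk,
            "event": event,
            "event_stage": event_stage,
            "event_age": event_age,
            "exit_age": np.where(event, event_age, window.age_high),
        }
    )


def person_time(events: pd.DataFrame, window: RiskWindow) -> float:
    """Total person-years among at-risk agents.

    Events accrue time from window entry to the event stage's midpoint;
    censored agents accrue the full window width.
    """
    at_risk = events[events["at_risk"]]
    time = np.where(
        at_risk["event"].to_numpy(),
        at_risk["event_age"].to_numpy() - window.age_low,
        window.width,
    )
    return float(time.sum())


def cumulative_incidence(events: int, n: int) -> tuple[float, float, float]:
    """Proportion with a binomial Wald 95% CI (all on the proportion scale)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    p = events / n
    half = Z95 * np.sqrt(p * (1 - p) / n)
    return p, max(p - half, 0.0), min(p + half, 1.0)


def incidence_rate(events: int, person_years: float) -> tuple[float, float, float]:
    """Rate per 1,000 person-years with a Poisson-approximate Wald 95% CI."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    r = 1000.0 * events / person_years
    half = Z95 * 1000.0 * np.sqrt(events) / person_years
    return r, max(r - half, 0.0), r + half


def age_specific_incidence(
    panel: pd.DataFrame, stage: int, outcome: str, schedule: LifeStageSchedule
) -> float:
    """First events at a stage over the at-risk count entering the stage.

    At risk = never positive at any earlier stage.  Returns NaN (with a
    warning) when nobody is at risk.
    """
    outcome_var = "t2dm" if outcome == "t2dm" else "obesity"
    if outcome_var == "t2dm" and stage not in applicable_stages("t2dm", schedule):
        return 0.0
    wide = _status_matrix(panel, outcome)
    prior = [s for s in wide.columns if s < stage]
    at_risk = ~wide[prior].any(axis=1) if prior else pd.Series(True, index=wide.index)
    n_risk = int(at_risk.sum())
    if n_risk == 0:
        warnings.warn(
            f"age-specific incidence undefined: no at-risk agents entering stage {stage}",
            stacklevel=2,
        )
        return float("nan")
    return float(wide.loc[at_risk, stage].mean())


def prevalence(panel: pd.DataFrame, stage: int, condition: str) -> float:
    """Positive-status proportion among the cohort at one stage."""
    rows = panel[panel["stage"] == stage]
    if condition == "obesity":
        return float((rows["weight_status"] == "obese").mean())
    return float(rows[condition].astype(float).mean())


def _stratum_mask(panel: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=panel.index)
    return panel["race"] == stratum


def measure_table(
    panel: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    strata=("all", "White", "non-White"),
    schedule: LifeStageSchedule | None = None,
) -> pd.DataFrame:
    """Assemble the incidence/cumulative-incidence table over windows x strata.

    Cumulative incidences are reported in percent, rates per 1,000
    person-years, both with 95% CIs.  Race-stratum agent totals are checked
    to sum to the overall total; empty strata are omitted with a warning.
    """
    if schedule is None:
        from .params import DEFAULT_SCHEDULE as schedule  # noqa: N813

    rows = []
    totals: dict[str, dict[str, int]] = {}
    for window in windows:
        for stratum in strata:
            sub = panel[_stratum_mask(panel, stratum)]
            n_agents = sub["agent_id"].nunique()
            if n_agents == 0:
                warnings.warn(f"stratum {stratum!r} is empty; omitted", stacklevel=2)
                continue
            ev = first_events(sub, window, schedule)
            at_risk = ev[ev["at_risk"]]
            n_events = int(at_risk["event"].sum())
            py = person_time(ev, window)
            rate, rate_lo, rate_hi = incidence_rate(n_events, py)
            # Denominator convention: the full stratum cohort, so that
            # cumulative incidence = events / total_n cell by cell.
            ci, ci_lo, ci_hi = cumulative_incidence(n_events, n_agents)
            totals.setdefault(window.name(), {})[stratum] = n_agents
            rows.append(
                dict(
                    window=window.name(),
                    outcome=window.outcome,
                    stratum=stratum,
                    total_n=n_agents,
                    at_risk_n=len(at_risk),
                    events=n_events,
                    person_years=py,
                    rate_per_1000py=rate,
                    rate_lo=rate_lo,
                    rate_hi=rate_hi,
                    cum_incidence_pct=100 * ci,
                    cum_lo_pct=100 * ci_lo,
                    cum_hi_pct=100 * ci_hi,
                )
            )
    for window_name, by_stratum in totals.items():
        if "all" in by_stratum and {"White", "non-White"} <= set(by_stratum):
            if by_stratum["White"] + by_stratum["non-White"] != by_stratum["all"]:
                raise AssertionError(
                    f"{window_name}: race stratum totals do not sum to the overall total"
                )
    return pd.DataFrame(rows)
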