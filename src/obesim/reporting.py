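"""Descriptive outputs: stage trend series and calibration comparison tables.

Tables are the canonical artifact; figures are optional and headless-safe.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import r_squared
from .params import (
    CalibrationTargetTable,
    DEFAULT_SCHEDULE,
    LifeStageSchedule,
    applicable_stages,
    engine_variables,
)

__all__ = ["trend_series", "calibration_report", "plot_trends"]

#: Derived status variables that can be trended alongside engine variables.
_DERIVED = ("obesity", "overweight")


def _variable_values(panel: pd.DataFrame, variable: str) -> pd.Series:
    if variable == "obesity":
        return (panel["weight_status"] == "obese").astype(float)
    if variable == "overweight":
        return (panel["weight_status"] == "overweight").astype(float)
    if variable not in panel.columns:
        raise KeyError(f"unknown trend variable {variable!r}")
    return panel[variable].astype(float)


def trend_series(
    panel: pd.DataFrame,
    variable: str,
    strata=("all", "White", "non-White"),
    schedule: LifeStageSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Per-stage means/proportions of one variable, overall and by race.

    Variables restricted to certain stages (breastfeeding at birth only;
    smoking, alcohol, T2DM at adult stages) report only their applicable
    stages.
    """
    if variable == "breastfed":
        stages = applicable_stages(variable, schedule)  # recorded at birth only
    elif variable in engine_variables() or variable in _DERIVED:
        # Adult-only variables are reported at every stage: they are
        # structurally zero during childhood, which is itself informative.
        stages = tuple(range(len(schedule)))
    else:
        raise KeyError(f"unknown trend variable {variable!r}")
    values = _variable_values(panel, variable)
    rows = []
    for stratum in strata:
        mask = (
            pd.Series(True, index=panel.index)
            if stratum == "all"
            else panel["race"] == stratum
        )
        for stage in stages:
            sel = mask & (panel["stage"] == stage)
            rows.append(
                dict(
                    variable=variable,
                    stratum=stratum,
                    stage=stage,
                    age_band=schedule[stage].label,
                    value=float(values[sel].mean()),
                    n=int(sel.sum()),
                )
            )
    return pd.DataFrame(rows)


def calibration_report(
    sim_series: pd.DataFrame, targets: CalibrationTargetTable
) -> pd.DataFrame:
    """Side-by-side simulated vs observed values with gaps and per-variable R².

    ``sim_series`` needs columns variable, stage, value (e.g. concatenated
    overall :func:`trend_series` output).  R² is reported on the rows of
    each variable with at least 3 paired points and flagged undefined
    otherwise.
    """
    rows = []
    for variable, grp in sim_series.groupby("variable", sort=True):
        grp = grp.sort_values("stage")
        sim_vals, obs_vals = [], []
        for r in grp.itertuples(index=False):
            obs = targets.lookup(variable, int(r.stage))
            if obs is None:
                continue
            sim_vals.append(float(r.value))
            obs_vals.append(obs)
            rows.append(
                dict(
                    variable=variable,
                    stage=int(r.stage),
                    simulated=float(r.value),
                    observed=obs,
                    gap=abs(float(r.value) - obs),
                )
            )
        r2 = r_squared(sim_vals, obs_vals)
        for row in rows:
            if row["variable"] == variable and "r_squared" not in row:
                row["r_squared"] = np.nan if r2 is None else r2
                row["r_squared_defined"] = r2 is not None
    return pd.DataFrame(rows)


def plot_trends(trends: pd.DataFrame, path) -> Path:
    """Line plot of trend series by stratum (optional; writes a file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    for (variable, stratum), grp in trends.groupby(["variable", "stratum"]):
        grp = grp.sort_values("stage")
        ax.plot(grp["stage"], grp["value"], marker="o", label=f"{variable} ({stratum})")
    ax.set_xlabel("life stage")
    ax.set_ylabel("mean / proportion")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
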