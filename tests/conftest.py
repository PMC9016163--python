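"""Shared fixtures: small synthetic configurations and runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import obesim


@pytest.fixture(scope="session")
def small_ps():
    """A scaled-down default configuration (10 neighborhoods x 50 agents)."""
    return obesim.default_parameter_set(7, n_neighborhoods=10, agents_per_neighborhood=50)


@pytest.fixture(scope="session")
def small_run(small_ps):
    """One full run of the scaled-down configuration."""
    panel, neighborhoods = obesim.run_simulation(small_ps, seed=3)
    return panel, neighborhoods


def make_status_panel(status_by_agent: dict[int, list[int]]) -> pd.DataFrame:
    """Hand-built 10-stage panel with prescribed obesity/T2DM status per agent.

    ``status_by_agent`` maps agent id to a list of 10 ints (1 = obese and
    diabetic at that stage).  Ages sit at stage midpoints; all other columns
    are filled with neutral values.
    """
    schedule = obesim.DEFAULT_SCHEDULE
    rows = []
    for agent_id, statuses in status_by_agent.items():
        assert len(statuses) == 10
        for stage, positive in enumerate(statuses):
            rows.append(
                dict(
                    agent_id=agent_id,
                    neighborhood_id=0,
                    stage=stage,
                    age=schedule[stage].midpoint,
                    sex=0,
                    race="White" if agent_id % 2 == 0 else "non-White",
                    ses_group=0,
                    marital=0,
                    breastfed=0,
                    ssb=0,
                    fastfood=0,
                    ffv=0,
                    activity=0,
                    smoking=0,
                    alcohol=0,
                    bmi=35.0 if positive else 22.0,
                    bmi_z=np.nan,
                    weight_status="obese" if positive else "normal",
                    t2dm=int(positive) if schedule[stage].adult else 0,
                )
            )
    return pd.DataFrame(rows)
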