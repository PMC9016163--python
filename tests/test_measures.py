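"""Incidence, person-time, cumulative incidence, and the cohort table."""

import numpy as np
import pandas as pd
import pytest

import obesim
from obesim.measures import (
    DEFAULT_WINDOWS,
    RiskWindow,
    age_specific_incidence,
    cumulative_incidence,
    first_events,
    incidence_rate,
    measure_table,
    person_time,
    prevalence,
)

from conftest import make_status_panel

SCHEDULE = obesim.DEFAULT_SCHEDULE
OBESITY_2_65 = DEFAULT_WINDOWS[0]
OBESITY_CHILD = DEFAULT_WINDOWS[1]



class TestFirstEvents:
    def test_always_obese_agent_events_at_window_entry(self):
        panel = make_status_panel({0: [0] + [1] * 9})
        ev = first_events(panel, OBESITY_2_65, SCHEDULE)
        row = ev.iloc[0]
        assert row["at_risk"] and row["event"] and row["event_stage"] == 1
        assert row["event_age"] == SCHEDULE[1].midpoint

    def test_never_obese_agent_censored(self):
        panel = make_status_panel({0: [0] * 10})
        ev = first_events(panel, OBESITY_2_65, SCHEDULE)
        row = ev.iloc[0]
        assert row["at_risk"] and not row["event"] and row["exit_age"] == 65

    def test_prevalent_at_entry_excluded_from_risk_set(self):
        panel = make_status_panel({0: [1] * 10})
        ev = first_events(panel, OBESITY_2_65, SCHEDULE)
        assert not ev.iloc[0]["at_risk"]

    def test_adult_window_reenters_reverted_childhood_cases(self):
        # obese during childhood, reverted by adolescence -> at risk as adult
        panel = make_status_panel({0: [0, 1, 1, 0, 0, 1, 1, 1, 1, 1]})
        ev = first_events(panel, DEFAULT_WINDOWS[2], SCHEDULE)
        row = ev.iloc[0]
        assert row["at_risk"] and row["event"] and row["event_stage"] == 5


class TestPersonTime:
    def test_no_events_full_width(self):
        panel = make_status_panel({i: [0] * 10 for i in range(5)})
        ev = first_events(panel, OBESITY_2_65, SCHEDULE)
        assert person_time(ev, OBESITY_2_65) == pytest.approx(5 * 63.0)

    def test_early_events_accrue_less_than_full_width(self):
        panel = make_status_panel({i: [0] + [1] * 9 for i in range(5)})
        ev = first_events(panel, OBESITY_2_65, SCHEDULE)
        py = person_time(ev, OBESITY_2_65)
        assert py == pytest.approx(5 * (3.5 - 2.0))
        assert py < 5 * 63.0

    def test_additive_in_cohort_size(self):
        histories = {0: [0] * 10, 1: [0, 1, 1, 1, 1, 1, 1, 1, 1, 1]}
        single = first_events(make_status_panel(histories), OBESITY_2_65, SCHEDULE)
        doubled = first_events(
            make_status_panel({**histories, 10: histories[0], 11: histories[1]}),
            OBESITY_2_65,
            SCHEDULE,
        )
        assert person_time(doubled, OBESITY_2_65) == pytest.approx(
            2 * person_time(single, OBESITY_2_65)
        )


class TestIntervalFormulas:
    def test_zero_events(self):
        p, lo, hi = cumulative_incidence(0, 100)
        assert (p, lo, hi) == (0.0, 0.0, 0.0)
        r, rlo, rhi = incidence_rate(0, 1000.0)
        assert (r, rlo, rhi) == (0.0, 0.0, 0.0)

    def test_degenerate_denominators_rejected(self):
        with pytest.raises(ValueError):
            cumulative_incidence(1, 0)
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)

    def test_t2dm_window_must_be_adult(self):
        with pytest.raises(ValueError, match="18"):
            RiskWindow("t2dm", 10, 65)


class TestAgeSpecificIncidence:
    def test_all_at_risk_convert(self):
        panel = make_status_panel({i: [0, 1, 1, 1, 1, 1, 1, 1, 1, 1] for i in range(4)})
        assert age_specific_incidence(panel, 1, "obesity", SCHEDULE) == 1.0

    def test_no_at_risk_agents_flagged_undefined(self):
        panel = make_status_panel({0: [1] * 10})
        with pytest.warns(UserWarning, match="no at-risk"):
            out = age_specific_incidence(panel, 3, "obesity", SCHEDULE)
        assert np.isnan(out)

    def test_t2dm_zero_at_child_stages(self, small_run):
        panel, _ = small_run
        for stage in (0, 1, 2, 3):
            assert age_specific_incidence(panel, stage, "t2dm", SCHEDULE) == 0.0


class TestPrevalence:
    def test_extremes(self):
        all_obese = make_status_panel({0: [1] * 10, 1: [1] * 10})
        none_obese = make_status_panel({0: [0] * 10})
        assert prevalence(all_obese, 5, "obesity") == 1.0
        assert prevalence(none_obese, 5, "obesity") == 0.0


class TestMeasureTable:
    def test_stratum_totals_and_cell_identity(self, small_run):
        panel, _ = small_run
        table = measure_table(panel)
        for window, grp in table.groupby("window"):
            by = grp.set_index("stratum")
            assert (
                by.loc["White", "total_n"] + by.loc["non-White", "total_n"]
                == by.loc["all", "total_n"]
            )
        # cumulative incidence = events / total_n in every cell
        assert np.allclose(
            table["cum_incidence_pct"], 100 * table["events"] / table["total_n"]
        )

    def test_person_years_bounded_by_cohort_time(self, small_run):
        panel, _ = small_run
        table = measure_table(panel)
        widths = {w.name(): w.width for w in DEFAULT_WINDOWS}
        for _, row in table.iterrows():
            assert row["person_years"] <= row["total_n"] * widths[row["window"]] + 1e-9
            assert row["events"] <= row["total_n"]

    def test_empty_stratum_omitted_with_warning(self):
        panel = make_status_panel({0: [0] * 10, 2: [0] * 10})  # Whites only
        with pytest.warns(UserWarning, match="empty"):
            table = measure_table(panel, windows=(OBESITY_2_65,))
        assert set(table["stratum"]) == {"all", "White"}
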