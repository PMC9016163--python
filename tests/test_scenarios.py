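"""Counterfactual interventions and natural-course contrasts."""

import numpy as np
import pandas as pd
import pytest

import obesim
from obesim.measures import DEFAULT_WINDOWS, first_events
from obesim.scenarios import InterventionSpec, apply_intervention, contrast

ALL_STAGES = tuple(range(10))


class TestApplyIntervention:
    def test_empty_intervention_is_identity(self, small_ps):
        scenario = apply_intervention(small_ps, [])
        nat, _ = obesim.run_simulation(small_ps, seed=5)
        alt, _ = scenario.run(seed=5)
        pd.testing.assert_frame_equal(nat, alt, check_exact=True)

    def test_set_override_dominates(self, small_ps):
        scenario = apply_intervention(
            small_ps, InterventionSpec("ssb", ALL_STAGES, "set", 0.0)
        )
        panel, _ = scenario.run(seed=5)
        assert (panel["ssb"] == 0).all()

    def test_shift_saturates_probability(self, small_ps):
        up = apply_intervention(
            small_ps, InterventionSpec("ssb", ALL_STAGES, "shift", 1.0)
        )
        panel, _ = up.run(seed=5)
        assert (panel["ssb"] == 1).all()

    def test_time_invariant_target_rejected(self, small_ps):
        with pytest.raises(ValueError, match="time-invariant"):
            apply_intervention(small_ps, InterventionSpec("ses_group", (0,), "set", 0.0))

    def test_inapplicable_stage_rejected(self, small_ps):
        with pytest.raises(ValueError, match="inapplicable"):
            apply_intervention(small_ps, InterventionSpec("t2dm", (0,), "set", 0.0))

    def test_scale_coefficient_rewrites_equation(self, small_ps):
        scenario = apply_intervention(
            small_ps,
            InterventionSpec("bmi", (4,), "scale_coefficient", 0.0, predictor=("ssb", 0)),
        )
        assert scenario.params.equations[("bmi", 4)].term_for("ssb", 0).coefficient == 0.0
        # original untouched
        assert small_ps.equations[("bmi", 4)].term_for("ssb", 0).coefficient != 0.0

    def test_neighborhood_environment_override(self, small_ps):
        scenario = apply_intervention(
            small_ps,
            InterventionSpec(
                "park_access", (), "set", 10.0, where=("pct_below_fpl", "ge", 0.3)
            ),
        )
        _, nb = scenario.run(seed=5)
        assert (nb.loc[nb["pct_below_fpl"] >= 0.3, "park_access"] == 10.0).all()


class TestContrast:
    def test_identical_panels_zero_contrast(self, small_run):
        panel, _ = small_run
        c = contrast(panel, panel.copy())
        assert (c["difference"] == 0).all()

    def test_null_intervention_paired_seed_exactly_zero(self, small_ps):
        scenario = apply_intervention(
            small_ps, InterventionSpec("ssb", ALL_STAGES, "shift", 0.0)
        )
        nat, _ = obesim.run_simulation(small_ps, seed=8)
        alt, _ = scenario.run(seed=8)
        c = contrast(nat, alt)
        assert (c["difference"] == 0).all()

    def test_antisymmetric_in_arguments(self, small_ps):
        nat, _ = obesim.run_simulation(small_ps, seed=1)
        alt, _ = apply_intervention(
            small_ps, InterventionSpec("ssb", ALL_STAGES, "set", 0.0)
        ).run(seed=1)
        fwd = contrast(nat, alt)
        rev = contrast(alt, nat)
        assert np.allclose(fwd["difference"], -rev["difference"])

    def test_mismatched_cohorts_rejected(self, small_ps, small_run):
        panel, _ = small_run
        with pytest.raises(ValueError, match="different sizes"):
            contrast(panel, panel[panel["agent_id"] < 100])

    def test_removing_ssb_cannot_raise_obesity(self, small_ps):
        """With positive sugary-drink effects on BMI, eliminating consumption
        weakly lowers mean adult BMI and obesity cumulative incidence
        (paired seeds, monotone coupling)."""
        scenario = apply_intervention(
            small_ps, InterventionSpec("ssb", ALL_STAGES, "set", 0.0)
        )
        for seed in (1, 2, 3):
            nat, _ = obesim.run_simulation(small_ps, seed=seed)
            alt, _ = scenario.run(seed=seed)
            assert (
                alt.loc[alt["age"] >= 18, "bmi"].mean()
                <= nat.loc[nat["age"] >= 18, "bmi"].mean()
            )
            c = contrast(nat, alt)
            obesity_ci = c[
                (c["measure"] == "cumulative_incidence_pct")
                & (c["window"] == "Obesity (2-65)")
            ]
            assert (obesity_ci["difference"] <= 0).all()


def test_subpopulation_effects_partition(small_ps):
    """Under a shared seed, the event-count effect of intervening on a
    subgroup plus that of intervening on its complement equals the effect of
    the whole-population intervention (additive count measure)."""
    window = DEFAULT_WINDOWS[0]

    def events(specs):
        scenario = apply_intervention(small_ps, specs)
        panel, _ = scenario.run(seed=4)
        ev = first_events(panel, window, small_ps.schedule)
        return int(ev["event"].sum())

    base = events([])
    low = events([InterventionSpec("ssb", ALL_STAGES, "set", 0.0, where=("ses_group", "eq", 1))])
    high = events([InterventionSpec("ssb", ALL_STAGES, "set", 0.0, where=("ses_group", "eq", 0))])
    both = events([InterventionSpec("ssb", ALL_STAGES, "set", 0.0)])
    assert (low - base) + (high - base) == both - base
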