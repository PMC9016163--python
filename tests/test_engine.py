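"""Equation evaluation and cohort advancement dynamics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import obesim
from obesim.engine import (
    advance_state,
    evaluate_equation,
    expit,
    frame_to_state,
    linear_predictor,
    step,
)
from obesim.params import EquationSpec, Term


class TestExpit:
    def test_symmetry_point(self):
        assert expit(0.0) == pytest.approx(0.5)

    def test_inverse_of_logit(self):
        assert expit(logit(0.25)) == pytest.approx(0.25)

    def test_monotone_saturation(self):
        xs = np.array([0.0, 5.0, 20.0, 50.0])
        ps = expit(xs)
        assert np.all(np.diff(ps) > 0) and ps[-1] == pytest.approx(1.0, abs=1e-12)


class TestEvaluateEquation:
    def test_identity_arithmetic_noise_free(self):
        spec = EquationSpec("bmi", 1, "identity", 22.0, (Term("x", 0, 1.0),), 0.0)
        out = evaluate_equation(spec, {"x": np.array([3.0])}, np.random.default_rng(0))
        assert out[0] == pytest.approx(25.0)

    def test_zero_coefficients_logit_is_fair_coin(self):
        spec = EquationSpec("ssb", 1, "logit", 0.0, ())
        draws = evaluate_equation(spec, {}, np.random.default_rng(0), size=10_000)
        assert abs(draws.mean() - 0.5) < 0.02

    def test_saturated_logit_never_fires(self):
        spec = EquationSpec("t2dm", 4, "logit", -50.0, ())
        draws = evaluate_equation(spec, {}, np.random.default_rng(0), size=1000)
        assert draws.sum() == 0

    def test_missing_predictor_named_error(self):
        spec = EquationSpec("bmi", 3, "identity", 0.0, (Term("walkability", 1, 1.0),))
        with pytest.raises(KeyError, match="bmi.*walkability.*lag 1"):
            evaluate_equation(spec, {}, np.random.default_rng(0), previous={})


class TestStep:
    def test_children_never_smoke_drink_or_have_diabetes(self, small_run):
        panel, _ = small_run
        child = panel[panel["age"] < 18]
        assert (child[["smoking", "alcohol", "t2dm"]] == 0).all().all()

    def test_t2dm_is_absorbing(self, small_run):
        panel, _ = small_run
        diffs = panel.sort_values(["agent_id", "stage"]).groupby("agent_id")["t2dm"].diff()
        assert (diffs.dropna() >= 0).all()

    def test_first_t2dm_event_is_adult(self, small_run):
        panel, _ = small_run
        cases = panel[panel["t2dm"] == 1]
        assert (cases["age"] >= 18).all()

    def test_identity_lag_dynamics_preserve_bmi(self, small_ps):
        ps = small_ps.copy()
        ps.equations[("bmi", 1)] = EquationSpec(
            "bmi", 1, "identity", 0.0, (Term("bmi", 1, 1.0),), 0.0
        )
        nb = obesim.build_neighborhoods(ps, np.random.default_rng(0))
        panel0 = obesim.build_agents(nb, ps, np.random.default_rng(1))
        panel1 = step(panel0, nb, ps, 1, np.random.default_rng(2))
        merged = panel0.merge(panel1, on="agent_id", suffixes=("_0", "_1"))
        assert np.allclose(merged["bmi_0"], merged["bmi_1"])

    def test_agent_iteration_order_is_immaterial(self, small_ps, small_run):
        panel, nb = small_run
        stage0 = panel[panel["stage"] == 0]
        shuffled = stage0.sample(frac=1.0, random_state=9)
        a = step(stage0, nb, small_ps, 1, np.random.default_rng(5))
        b = step(shuffled, nb, small_ps, 1, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_stage_out_of_range_rejected(self, small_ps, small_run):
        panel, nb = small_run
        with pytest.raises(ValueError, match="stage"):
            step(panel[panel["stage"] == 0], nb, small_ps, 11, np.random.default_rng(0))


class TestRunSimulation:
    def test_closed_cohort_complete_panel(self, small_ps, small_run):
        panel, _ = small_run
        assert len(panel) == small_ps.population_size * 10
        per_agent = panel.groupby("agent_id")["stage"].agg(["count", "nunique"])
        assert (per_agent["count"] == 10).all() and (per_agent["nunique"] == 10).all()

    def test_bit_identical_under_same_seed(self, small_ps):
        a, na = obesim.run_simulation(small_ps, seed=11)
        b, nb = obesim.run_simulation(small_ps, seed=11)
        pd.testing.assert_frame_equal(a, b, check_exact=True)
        pd.testing.assert_frame_equal(na, nb, check_exact=True)

    def test_bmi_within_clip_range(self, small_ps, small_run):
        panel, _ = small_run
        lo, hi = small_ps.bmi_clip
        assert panel["bmi"].between(lo, hi).all()

    def test_ages_respect_stage_bands(self, small_ps, small_run):
        panel, _ = small_run
        for s in small_ps.schedule.stages:
            ages = panel.loc[panel["stage"] == s.index, "age"]
            assert ages.between(s.age_low, s.age_high).all()

    def test_ssb_coefficient_raises_adult_bmi(self, small_ps):
        """Removing the sugary-drink effect from every BMI equation lowers
        mean adult BMI in paired runs (common random numbers, 3 seeds)."""
        ps_null = small_ps.copy()
        for t in range(10):
            eq = ps_null.equations[("bmi", t)]
            eq.terms = tuple(
                Term(term.predictor, term.lag, 0.0)
                if term.predictor == "ssb"
                else term
                for term in eq.terms
            )
        for seed in (1, 2, 3):
            with_effect, _ = obesim.run_simulation(small_ps, seed=seed)
            without, _ = obesim.run_simulation(ps_null, seed=seed)
            adult = with_effect["age"] >= 18
            assert (
                with_effect.loc[adult, "bmi"].mean()
                > without.loc[without["age"] >= 18, "bmi"].mean()
            )


def test_bmi_feedback_suppresses_next_stage_activity(small_ps, small_run):
    """Raising an agent's BMI lowers the model's probability of
    moderate-to-vigorous activity at the next stage (negative feedback),
    computed exactly on the linear-predictor scale."""
    panel, nb = small_run
    state = frame_to_state(panel[panel["stage"] == 4])
    from obesim.engine import _nbhd_attrs

    spec = small_ps.equations[("activity", 5)]
    predictors = dict(state)
    predictors.update(_nbhd_attrs(state, nb))
    p_base = expit(linear_predictor(spec, predictors, predictors))
    bumped = dict(predictors)
    bumped["bmi"] = np.asarray(predictors["bmi"]) + 5.0
    p_bumped = expit(linear_predictor(spec, bumped, bumped))
    assert np.all(p_bumped < p_base)
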