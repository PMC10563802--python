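"""Baseline hazard, absolute risk, Kaplan-Meier, and two-group Cox."""

import math

import numpy as np
import pytest

from iboxkit import (
    BaselineHazard,
    Outcome,
    Score,
    breslow_baseline,
    cox_two_group_loghr,
    km_curve,
    predict_event_probability,
    simulate_cohort,
)
from conftest import homogeneous_config


def brute_force_breslow_loglik(beta, times, events, x):
    """Breslow-ties two-group partial log-likelihood, written directly.

    ``beta`` may be an array (evaluated on a grid)."""
    beta = np.asarray(beta, dtype=float)
    ll = np.zeros_like(beta)
    for tk in np.unique(times[events]):
        dead = events & (times == tk)
        risk = times >= tk
        n1, n0 = x[risk].sum(), (1 - x[risk]).sum()
        ll += beta * x[dead].sum() - dead.sum() * np.log(n0 + n1 * np.exp(beta))
    return ll


class TestBreslowBaseline:
    def test_all_zero_scores_reduce_to_nelson_aalen(self):
        outcomes = [Outcome("a", 1.0, True), Outcome("b", 2.0, True)]
        bh = breslow_baseline([0.0, 0.0], outcomes)
        np.testing.assert_allclose(bh.times, [1.0, 2.0])
        np.testing.assert_allclose(bh.cumhaz, [0.5, 1.5])  # increments 1/2 then 1/1

    def test_risk_weights_are_exponentiated_scores(self):
        outcomes = [Outcome("a", 1.0, True), Outcome("b", 2.0, False), Outcome("c", 2.0, False)]
        bh = breslow_baseline([math.log(2), 0.0, 0.0], outcomes)
        assert bh.cumhaz[0] == pytest.approx(1 / (2 + 1 + 1))

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="no events"):
            breslow_baseline([0.0], [Outcome("a", 1.0, False)])

    def test_cumulative_hazard_is_step_and_clamped(self):
        bh = BaselineHazard(np.array([1.0, 3.0]), np.array([0.1, 0.25]), support_end=5.0)
        assert bh.cumulative_hazard(0.5) == 0.0
        assert bh.cumulative_hazard(1.0) == 0.1
        assert bh.cumulative_hazard(2.9) == 0.1
        with pytest.warns(UserWarning, match="clamping"):
            assert bh.cumulative_hazard(10.0) == 0.25


class TestPredictEventProbability:
    def test_zero_score_identity(self):
        bh = BaselineHazard(np.array([5.0]), np.array([0.3]), support_end=7.0)
        assert predict_event_probability(0.0, bh, 5.0) == pytest.approx(1 - math.exp(-0.3))

    def test_zero_hazard_gives_zero_probability(self):
        bh = BaselineHazard(np.array([5.0]), np.array([0.1]), support_end=7.0)
        assert predict_event_probability(0.0, bh, 0.5) == 0.0

    def test_worked_value(self):
        bh = BaselineHazard(np.array([5.0]), np.array([0.10]), support_end=7.0)
        s = Score("s", "full", math.log(2))
        assert predict_event_probability(s, bh, 5.0) == pytest.approx(1 - math.exp(-0.2))

    def test_monotone_in_score_and_horizon(self):
        bh = BaselineHazard(np.array([1.0, 2.0, 5.0]), np.array([0.05, 0.1, 0.3]), support_end=7.0)
        probs = [predict_event_probability(s, bh, 5.0) for s in (-1.0, 0.0, 1.0)]
        assert probs == sorted(probs)
        horizons = [predict_event_probability(0.0, bh, h) for h in (0.0, 1.0, 2.0, 5.0)]
        assert horizons == sorted(horizons)
        assert horizons[0] == 0.0


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        outcomes = [Outcome(f"s{i}", float(i), True) for i in range(1, 5)]
        km = km_curve(outcomes)
        assert km.survival_at(2.5) == pytest.approx(0.5)
        times = np.array([o.followup_years for o in outcomes])
        for t in np.arange(0.5, 5.0, 0.5):
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_hand_product_limit_with_censoring(self):
        outcomes = [
            Outcome("a", 1.0, True), Outcome("b", 2.0, False),
            Outcome("c", 3.0, True), Outcome("d", 4.0, False),
        ]
        km = km_curve(outcomes)
        assert km.survival_at(3.0) == pytest.approx(0.75 * 0.5)

    def test_all_censored_is_flat_at_one(self):
        km = km_curve([Outcome("a", 1.0, False), Outcome("b", 2.0, False)])
        assert km.survival_at(5.0) == 1.0

    def test_greenwood_se_hand_value(self):
        # single event among 4 at t=1: Var = S^2 * d/(n(n-d)) = 0.75^2 * 1/12
        outcomes = [Outcome("a", 1.0, True)] + [Outcome(f"c{i}", 2.0, False) for i in range(3)]
        km = km_curve(outcomes)
        assert km.se_at(1.0) == pytest.approx(math.sqrt(0.75**2 / 12))

    def test_death_with_function_is_censoring_unless_all_cause(self):
        outcomes = [Outcome("a", 1.0, False, died_with_function=True), Outcome("b", 2.0, True)]
        assert km_curve(outcomes).survival_at(1.5) == 1.0
        assert km_curve(outcomes, all_cause=True).survival_at(1.5) == pytest.approx(0.5)


class TestCoxTwoGroup:
    def test_identical_arms_give_null_effect(self):
        outcomes = [Outcome(f"s{i}", t, e) for i, (t, e) in enumerate(
            [(1.0, True), (2.0, False), (3.0, True)] * 2)]
        arm = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        eff = cox_two_group_loghr(outcomes, arm)
        assert eff.log_hr == pytest.approx(0.0, abs=1e-8)
        assert eff.p == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_grid_on_toy_data(self):
        # interleaved events so the partial likelihood has an interior maximum
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([True, True, True, True, True, False])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        outcomes = [Outcome(f"s{i}", float(t), bool(e)) for i, (t, e) in enumerate(zip(times, events))]
        eff = cox_two_group_loghr(outcomes, x)
        grid = np.linspace(-5, 5, 200001)
        lls = brute_force_breslow_loglik(grid, times, events, x)
        assert eff.log_hr == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_matches_brute_force_grid_on_random_small_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(4, 13))
            times = np.round(rng.exponential(2.0, n), 1) + 0.1
            events = rng.random(n) < 0.7
            x = (rng.random(n) < 0.5).astype(float)
            if not events.any() or x.all() or not x.any():
                continue
            grid = np.linspace(-6, 6, 120001)
            lls = brute_force_breslow_loglik(grid, times, events, x)
            argmax = grid[int(np.argmax(lls))]
            if abs(argmax) > 5.5:
                continue  # monotone likelihood: no interior maximizer
            outcomes = [Outcome(f"s{i}", float(t), bool(e)) for i, (t, e) in enumerate(zip(times, events))]
            eff = cox_two_group_loghr(outcomes, x)
            assert eff.converged
            assert eff.log_hr == pytest.approx(argmax, abs=1e-4)

    def test_agrees_with_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 400
        x = (rng.random(n) < 0.5)
        t = rng.exponential(1 / (0.2 * np.exp(-0.5 * x)))
        c = rng.exponential(6.0, n)
        outcomes = [
            Outcome(f"s{i}", float(max(min(t[i], c[i]), 1e-6)), bool(t[i] <= c[i]))
            for i in range(n)
        ]
        eff = cox_two_group_loghr(outcomes, x.astype(float))
        df = pd.DataFrame({
            "t": [o.followup_years for o in outcomes],
            "e": [o.graft_loss for o in outcomes],
            "x": x.astype(float),
        })
        cph = CoxPHFitter().fit(df, "t", "e")
        assert eff.log_hr == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert eff.se == pytest.approx(float(cph.standard_errors_.iloc[0]), rel=1e-4)

    def test_monotone_likelihood_flagged_nonconvergent(self):
        outcomes = [Outcome("a", 1.0, True), Outcome("b", 2.0, True),
                    Outcome("c", 3.0, False), Outcome("d", 4.0, False)]
        arm = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="monotone"):
            eff = cox_two_group_loghr(outcomes, arm)
        assert not eff.converged
        assert eff.se is None and eff.p is None
        assert abs(eff.log_hr) <= 20

    def test_parameter_recovery_on_simulated_trial(self):
        """Simulated arm hazard ratio e^-0.7 is recovered within 2 SE."""
        from iboxkit import simulate_trial

        ctrl = homogeneous_config(n=1000)
        trt = ctrl.with_overrides(baseline_rate=ctrl.baseline_rate * math.exp(-0.7))
        sim = simulate_trial(ctrl, trt, seed=11)
        eff = cox_two_group_loghr(sim.cohort.outcomes, sim.cohort.arms == "B")
        assert abs(eff.log_hr - (-0.7)) < 2 * eff.se

    def test_calibration_in_the_large_self_consistency(self):
        """Breslow baseline + summed predictions reproduce the event count."""
        cfg = homogeneous_config(n=400, censoring_rate=0.0, death_rate=0.0,
                                 egfr_sd=15.0, baseline_rate=0.5)
        sim = simulate_cohort(cfg, seed=5)
        cohort = sim.cohort.assessed()
        from iboxkit import score_assessment

        scores = [score_assessment(s.assessment, "full") for s in cohort]
        bh = breslow_baseline(scores, cohort.outcomes)
        horizon = max(o.followup_years for o in cohort.outcomes)
        expected = sum(predict_event_probability(s, bh, horizon) for s in scores)
        observed = sum(o.graft_loss for o in cohort.outcomes)
        assert expected == pytest.approx(observed, rel=0.05)
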