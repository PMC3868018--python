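import math

import numpy as np
import pytest

from advicerl.choice_model import ParameterVector, policy_trace
from advicerl.learners import BAYES_TAG, RW_TAG, BeliefTrajectory
from advicerl.schedules import GREEN, ScheduleConfig, generate_schedule
from advicerl.simulate import AgentSpec, ChoiceRecord, simulate_agent
from advicerl.inference import (FitGrid, _information_criteria, compare_models,
                                fit_posterior, fit_subject, log_likelihood,
                                predictive_accuracy)


def _beliefs(estimates):
    est = np.asarray(estimates, dtype=float)
    return BeliefTrajectory(estimates=est, spreads=np.zeros_like(est),
                            learner_tag=BAYES_TAG)


def _flat_schedule(n, mag=(1, 100), seed=0):
    return generate_schedule(ScheduleConfig(
        n_trials=n, reward_prob_blocks=((n, 0.7),),
        advice_fidelity_blocks=((n, 0.7),),
        magnitude_low=mag[0], magnitude_high=mag[1], seed=seed))


def test_single_indifferent_trial_gives_log_half():
    sched = _flat_schedule(1, mag=(50, 50), seed=1)
    record = ChoiceRecord(choices=np.array(["G"]), schedule=sched)
    params = ParameterVector(1.0, 1.0, 1.0)
    ll = log_likelihood(params, record, _beliefs([0.5]), _beliefs([0.5]))
    assert ll == pytest.approx(math.log(0.5), abs=1e-12)


def test_log_likelihood_additivity():
    sched = _flat_schedule(30, seed=2)
    rng = np.random.default_rng(3)
    est_r, est_s = rng.uniform(0.2, 0.8, 30), rng.uniform(0.2, 0.8, 30)
    choices = np.where(rng.random(30) < 0.5, "G", "B")
    params = ParameterVector(1.5, 0.7, 0.2)

    def sub(lo, hi):
        sub_sched = generate_schedule(ScheduleConfig(
            n_trials=hi - lo, reward_prob_blocks=((hi - lo, 0.7),),
            advice_fidelity_blocks=((hi - lo, 0.7),), seed=0))
        for field in ("r_green", "r_blue", "correct", "advice"):
            object.__setattr__(sub_sched, field, getattr(sched, field)[lo:hi])
        rec = ChoiceRecord(choices=choices[lo:hi], schedule=sub_sched)
        return log_likelihood(params, rec, _beliefs(est_r[lo:hi]),
                              _beliefs(est_s[lo:hi]))

    total = sub(0, 30)
    assert total == pytest.approx(sub(0, 12) + sub(12, 30), abs=1e-10)


def straight_line_ll(params, record, est_r, est_s):
    """Oracle: trial-by-trial recomputation with plain Python floats."""
    sched = record.schedule
    total = 0.0
    for i in range(len(record)):
        ps = 1 / (1 + math.exp(-params.gamma_social * (est_s[i] - 0.5)))
        pg = 1 / (1 + math.exp(-params.gamma_reward_history * (est_r[i] - 0.5)))
        if sched.advice[i] == "G":
            q = ps * pg / (ps * pg + (1 - ps) * (1 - pg))
        else:
            q = (1 - ps) * pg / ((1 - ps) * pg + ps * (1 - pg))
        dv = q * sched.r_green[i] - (1 - q) * sched.r_blue[i]
        x = (1.0 if record.choices[i] == "G" else -1.0) * params.beta * dv
        p = 1 / (1 + math.exp(-x)) if abs(x) < 700 else float(x > 0)
        total += math.log(min(max(p, 1e-9), 1 - 1e-9))
    return total


def test_log_likelihood_matches_straight_line_oracle():
    sched = _flat_schedule(100, seed=4)
    rng = np.random.default_rng(5)
    est_r, est_s = rng.uniform(0.1, 0.9, 100), rng.uniform(0.1, 0.9, 100)
    record = ChoiceRecord(choices=np.where(rng.random(100) < 0.5, "G", "B"),
                          schedule=sched)
    for params in (ParameterVector(0.5, 2.0, 0.1), ParameterVector(3.0, 0.2, 1.0)):
        ll = log_likelihood(params, record, _beliefs(est_r), _beliefs(est_s))
        assert ll == pytest.approx(straight_line_ll(params, record, est_r, est_s),
                                   abs=1e-10)


def test_posterior_marginals_normalised_and_bounded(fast_fit_grid,
                                                    small_learner_grid):
    sched = _flat_schedule(80, seed=6)
    spec = AgentSpec(params=ParameterVector(2.0, 1.0, 0.3), seed=7)
    record = simulate_agent(spec, sched, small_learner_grid)
    post = fit_subject(record, fast_fit_grid, small_learner_grid)
    for marg in post.marginals.values():
        assert marg.sum() == pytest.approx(1.0, abs=1e-10)
        assert (marg >= 0).all()
    for name in ("gamma_social", "gamma_reward_history", "beta"):
        val = getattr(post.point_estimates, name)
        assert fast_fit_grid.lower <= val <= fast_fit_grid.upper
    assert np.isfinite(post.log_evidence)
    assert post.max_log_likelihood >= post.total_log_likelihood_at_estimate - 1e-6


def test_coin_flip_record_pushes_beta_to_lower_edge(fast_fit_grid,
                                                    small_learner_grid):
    """Pure random choices with equalised magnitudes are best explained by
    maximal choice stochasticity (beta at the bottom of the grid)."""
    sched = _flat_schedule(200, mag=(50, 50), seed=8)
    rng = np.random.default_rng(9)
    record = ChoiceRecord(choices=np.where(rng.random(200) < 0.5, "G", "B"),
                          schedule=sched)
    post = fit_subject(record, fast_fit_grid, small_learner_grid)
    beta_marg = post.marginals["beta"]
    assert np.argmax(beta_marg) <= 2
    assert post.point_estimates.beta < 0.1


def test_predictive_accuracy_behaviour(small_learner_grid):
    sched = _flat_schedule(290, seed=10)
    sharp = AgentSpec(params=ParameterVector(3.0, 3.0, 10.0), seed=11)
    record = simulate_agent(sharp, sched, small_learner_grid)
    post = fit_subject(record, FitGrid(points_per_dim=30), small_learner_grid)
    from advicerl.simulate import agent_beliefs
    beliefs = agent_beliefs(AgentSpec(params=post.point_estimates), sched,
                            small_learner_grid)
    trace = policy_trace(post.point_estimates, sched, *beliefs)
    acc_sharp = predictive_accuracy(record, trace)
    assert acc_sharp > 0.95

    rng = np.random.default_rng(12)
    coin = ChoiceRecord(choices=np.where(rng.random(290) < 0.5, "G", "B"),
                        schedule=sched)
    acc_coin = predictive_accuracy(coin, trace)
    assert 0.4 <= acc_coin <= 0.6
    assert 0.0 <= acc_coin <= 1.0


def test_tied_probabilities_score_half():
    sched = _flat_schedule(2, mag=(50, 50), seed=13)
    record = ChoiceRecord(choices=np.array(["G", "B"]), schedule=sched)

    class Trace:
        p_choose_green = np.array([0.5, 0.5])

    assert predictive_accuracy(record, Trace()) == 0.5


def test_information_criterion_formulas():
    bic3, aic3 = _information_criteria(-100.0, 3, 290)
    bic5, aic5 = _information_criteria(-100.0, 5, 290)
    assert bic5 - bic3 == pytest.approx(2 * math.log(290))
    assert aic5 - aic3 == pytest.approx(4.0)
    assert bic3 == pytest.approx(3 * math.log(290) + 200.0)


def test_model_comparison_on_bayes_generated_agent(small_learner_grid):
    sched = _flat_schedule(290, seed=14)
    spec = AgentSpec(params=ParameterVector(2.0, 1.2, 0.4), seed=15)
    record = simulate_agent(spec, sched, small_learner_grid)
    comp = compare_models(record, FitGrid(points_per_dim=30), small_learner_grid,
                          rw_grid=FitGrid(points_per_dim=15), rw_alpha_points=6)
    assert set(comp.fits) == {BAYES_TAG, RW_TAG}
    assert comp.fits[BAYES_TAG].n_params == 3
    assert comp.fits[RW_TAG].n_params == 5
    for fit in comp.fits.values():
        assert fit.bic == pytest.approx(
            fit.n_params * math.log(290) - 2 * fit.max_log_likelihood)
    assert comp.preferred_by_bic == BAYES_TAG


def test_grid_refinement_stability(small_learner_grid):
    """Point estimates move by < 5% when the grid resolution doubles."""
    sched = _flat_schedule(290, seed=16)
    spec = AgentSpec(params=ParameterVector(1.5, 0.8, 0.5), seed=17)
    record = simulate_agent(spec, sched, small_learner_grid)
    coarse = fit_subject(record, FitGrid(points_per_dim=25), small_learner_grid)
    fine = fit_subject(record, FitGrid(points_per_dim=50), small_learner_grid)
    for name in ("gamma_social", "gamma_reward_history", "beta"):
        a = getattr(coarse.point_estimates, name)
        b = getattr(fine.point_estimates, name)
        assert abs(a - b) / b < 0.05


def test_posterior_contraction_with_trial_count(small_learner_grid):
    """Average posterior SD shrinks as the record grows 50 -> 290 -> 1000."""
    spec_params = ParameterVector(2.0, 1.0, 0.3)
    sds = []
    for n, seed in ((50, 18), (290, 19), (1000, 20)):
        sched = _flat_schedule(n, seed=seed)
        record = simulate_agent(AgentSpec(params=spec_params, seed=seed + 1),
                                sched, small_learner_grid)
        post = fit_subject(record, FitGrid(points_per_dim=30), small_learner_grid)
        sds.append(np.mean([post.posterior_sds["gamma_social"],
                            post.posterior_sds["gamma_reward_history"]]))
    assert sds[0] > sds[1] > sds[2]
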