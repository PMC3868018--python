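import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from advicerl.choice_model import (ChoiceModelError, ParameterVector,
                                   choice_probability, combine,
                                   expected_values, policy_trace,
                                   subjective_probability)
from advicerl.learners import BeliefTrajectory, BAYES_TAG
from advicerl.schedules import ScheduleConfig, generate_schedule

probs = st.floats(0.001, 0.999)
gammas = st.floats(0.0, 10.0)


def test_subjective_probability_examples():
    assert subjective_probability(0.5, 3.7) == pytest.approx(0.5)
    assert subjective_probability(0.7, 0.0) == pytest.approx(0.5)
    assert subjective_probability(0.7, 1e-8) == pytest.approx(0.5, abs=1e-8)
    assert subjective_probability(0.7, 10.0) == pytest.approx(1 / (1 + math.exp(-2)),
                                                              abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(p=probs, gamma=gammas)
def test_subjective_probability_symmetry(p, gamma):
    left = subjective_probability(1 - p, gamma)
    right = 1 - subjective_probability(p, gamma)
    assert left == pytest.approx(right, abs=1e-12)


def test_uninformative_advice_passes_reward_belief_through():
    for pg in (0.1, 0.5, 0.9):
        for advice_green in (True, False):
            assert combine(0.5, pg, advice_green) == pytest.approx(pg, abs=1e-9)


def test_conflicting_equally_weighted_information_cancels():
    """Reward history 0.3 for green vs advice green at fidelity 0.7 cancel."""
    for gamma in (0.5, 1.0, 2.0, 10.0):
        ps = subjective_probability(0.7, gamma)
        pg = subjective_probability(0.3, gamma)
        assert combine(ps, pg, True) == pytest.approx(0.5, abs=1e-12)


def brute_force_combine(p_social, p_green, advice_green):
    """Oracle: enumerate the four (advice truthful) x (green correct) worlds."""
    post = {True: 0.0, False: 0.0}
    for truthful in (True, False):
        for green_correct in (True, False):
            w = (p_social if truthful else 1 - p_social) \
                * (p_green if green_correct else 1 - p_green)
            advised_green = green_correct if truthful else not green_correct
            if advised_green == advice_green:
                post[green_correct] += w
    return post[True] / (post[True] + post[False])


@settings(max_examples=200, derandomize=True)
@given(ps=probs, pg=probs, advice_green=st.booleans())
def test_combine_matches_enumeration_oracle(ps, pg, advice_green):
    assert combine(ps, pg, advice_green) == pytest.approx(
        brute_force_combine(ps, pg, advice_green), abs=1e-12)


def test_combine_monotonicity():
    pg = np.linspace(0.05, 0.95, 40)
    for advice_green in (True, False):
        q = combine(0.7, pg, advice_green)
        assert (np.diff(q) > 0).all()
    ps = np.linspace(0.05, 0.95, 40)
    assert (np.diff(combine(ps, 0.4, True)) > 0).all()
    assert (np.diff(combine(ps, 0.4, False)) < 0).all()


def test_as_printed_variant_differs_only_for_blue_advice():
    assert combine(0.7, 0.3, True, as_printed=True) == combine(0.7, 0.3, True)
    printed = combine(0.7, 0.3, False, as_printed=True)
    consistent = combine(0.7, 0.3, False)
    assert printed != pytest.approx(consistent, abs=1e-6)
    # the printed numerator does not normalise against its denominator
    assert consistent == pytest.approx(brute_force_combine(0.7, 0.3, False), abs=1e-12)


def test_expected_values_arithmetic():
    assert expected_values(1.0 - 1e-12, 40, 25) == pytest.approx((40, 0), abs=1e-9)
    assert expected_values(0.5, 60, 30) == (30.0, 15.0)
    vg, vb = expected_values(0.4, 90, 10)
    assert (vg, vb) == (36.0, 6.0) and vg > vb  # less likely colour, higher value
    with pytest.raises(ChoiceModelError):
        expected_values(0.5, -1, 10)


def test_choice_probability_examples():
    assert choice_probability(17.0, 17.0, 2.0) == 0.5
    assert choice_probability(90.0, 3.0, 0.0) == 0.5
    assert choice_probability(1.0, 0.0, 1.0) == pytest.approx(1 / (1 + math.exp(-1)),
                                                              abs=1e-12)
    # overflow-safe at extreme value gaps
    assert choice_probability(1e6, 0.0, 10.0) == pytest.approx(1.0)
    assert choice_probability(0.0, 1e6, 10.0) == pytest.approx(0.0)


@settings(max_examples=100, derandomize=True)
@given(vg=st.floats(0, 1000), vb=st.floats(0, 1000), beta=st.floats(0, 10))
def test_softmax_normalisation(vg, vb, beta):
    p_green = choice_probability(vg, vb, beta)
    p_blue = choice_probability(vb, vg, beta)
    assert p_green + p_blue == pytest.approx(1.0, abs=1e-12)


def _toy_beliefs(estimates):
    est = np.asarray(estimates, dtype=float)
    return BeliefTrajectory(estimates=est, spreads=np.zeros_like(est),
                            learner_tag=BAYES_TAG)


def straight_line_trace(params, schedule, est_reward, est_social):
    """Oracle: recompute the policy trial-by-trial with no shared code."""
    out = []
    for i in range(schedule.n_trials):
        ps = 1 / (1 + math.exp(-params.gamma_social * (est_social[i] - 0.5)))
        pg = 1 / (1 + math.exp(-params.gamma_reward_history * (est_reward[i] - 0.5)))
        if schedule.advice[i] == "G":
            q = ps * pg / (ps * pg + (1 - ps) * (1 - pg))
        else:
            q = (1 - ps) * pg / ((1 - ps) * pg + ps * (1 - pg))
        vg = q * schedule.r_green[i]
        vb = (1 - q) * schedule.r_blue[i]
        out.append(1 / (1 + math.exp(-params.beta * (vg - vb))))
    return np.array(out)


def test_policy_trace_matches_straight_line_oracle(schedule):
    rng = np.random.default_rng(5)
    est_r = rng.uniform(0.05, 0.95, schedule.n_trials)
    est_s = rng.uniform(0.05, 0.95, schedule.n_trials)
    params = ParameterVector(gamma_social=2.3, gamma_reward_history=0.8, beta=0.07)
    trace = policy_trace(params, schedule, _toy_beliefs(est_r), _toy_beliefs(est_s))
    expected = straight_line_trace(params, schedule, est_r, est_s)
    np.testing.assert_allclose(trace.p_choose_green, expected, atol=1e-12)
    np.testing.assert_allclose(trace.v_green, trace.q_hat * schedule.r_green, atol=1e-12)
    np.testing.assert_allclose(trace.v_blue, (1 - trace.q_hat) * schedule.r_blue,
                               atol=1e-12)


def _conflict_schedule():
    """Single trial: reward history favours blue, advice says green, equal points."""
    cfg = ScheduleConfig(n_trials=1, reward_prob_blocks=((1, 0.5),),
                         advice_fidelity_blocks=((1, 0.5),),
                         magnitude_low=50, magnitude_high=50, seed=0)
    sched = generate_schedule(cfg)
    object.__setattr__(sched, "advice", np.array(["G"]))
    return sched


def test_conflict_trial_weight_asymmetry():
    """Equal weights cancel; the larger weight's channel wins the conflict trial."""
    sched = _conflict_schedule()
    br, bs = _toy_beliefs([0.3]), _toy_beliefs([0.7])
    equal = policy_trace(ParameterVector(2.0, 2.0, 1.0), sched, br, bs)
    assert equal.p_choose_green[0] == pytest.approx(0.5, abs=1e-12)
    social = policy_trace(ParameterVector(4.0, 1.0, 1.0), sched, br, bs)
    assert social.p_choose_green[0] > 0.5
    reward = policy_trace(ParameterVector(1.0, 4.0, 1.0), sched, br, bs)
    assert reward.p_choose_green[0] < 0.5


def test_vanishing_weights_leave_only_magnitudes(schedule):
    """gamma -> 0 reduces the policy to a pure magnitude comparison."""
    rng = np.random.default_rng(6)
    br = _toy_beliefs(rng.uniform(0.1, 0.9, schedule.n_trials))
    bs = _toy_beliefs(rng.uniform(0.1, 0.9, schedule.n_trials))
    trace = policy_trace(ParameterVector(0.0, 0.0, 0.5), schedule, br, bs)
    expected = 1 / (1 + np.exp(-0.5 * 0.5 * (schedule.r_green - schedule.r_blue)))
    np.testing.assert_allclose(trace.p_choose_green, expected, atol=1e-12)


def test_parameter_validation():
    with pytest.raises(ChoiceModelError):
        ParameterVector(-0.1, 1.0, 1.0)
    with pytest.raises(ChoiceModelError):
        subjective_probability(1.2, 1.0)
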