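"""Hybrid model-based/model-free learner: updates, values, likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualcontrol.hybrid import (
    AgentParams,
    PARAM_NAMES,
    ValueState,
    choice_probs,
    from_transformed,
    hybrid_values,
    mb_values,
    mf_update,
    session_nll,
    simulate_agent,
    split_betas,
    to_transformed,
)
from dualcontrol.stats import stay_probability_table
from dualcontrol.twostep import Session, TwoStepConfig, TwoStepTrial, trials_to_frame


def params_strategy():
    unit = st.floats(0.01, 0.99)
    return st.builds(
        AgentParams,
        alpha1=unit, alpha2=unit, lam=unit, omega=unit,
        beta1=st.floats(0.01, 20.0), beta2=st.floats(0.01, 20.0),
        rho=st.floats(-2.0, 2.0),
    )


def make_trial(t=0, a1=0, state2=0, a2=0, r=0, valid=True):
    return TwoStepTrial(
        t=t, a1=a1, state2=state2,
        transition="common" if state2 == a1 else "rare",
        a2=a2, r=r, valid=valid,
    )


class TestMFUpdate:
    def test_zero_values_no_reward_is_fixed_point(self, anchor_params):
        state = ValueState.zeros()
        _, d1, d2 = mf_update(state, make_trial(r=0), anchor_params)
        assert d1 == 0 and d2 == 0
        assert np.all(state.q_mf_stage1 == 0) and np.all(state.q_mf_stage2 == 0)

    def test_stage2_delta_and_increment(self):
        p = AgentParams(0.5, 0.5, 0.5, 0.5, 1, 1, 0)
        state = ValueState.zeros()
        _, _, d2 = mf_update(state, make_trial(r=1), p)
        assert d2 == 1.0
        assert state.q_mf_stage2[0, 0] == 0.5

    def test_hand_trace_of_lambda_backup(self):
        # all values 0, r=1, alpha1=0.5, lam=0.5:
        # delta1 = 0, delta2 = 1; stage-1 value = 0 + 0 + 0.5*0.5*1 = 0.25
        p = AgentParams(0.5, 0.5, 0.5, 0.5, 1, 1, 0)
        state = ValueState.zeros()
        mf_update(state, make_trial(r=1), p)
        assert state.q_mf_stage1[0] == pytest.approx(0.25, abs=1e-15)

    def test_invalid_trial_leaves_state_untouched(self, anchor_params):
        state = ValueState.zeros()
        state.q_mf_stage1[:] = [0.3, 0.4]
        _, d1, d2 = mf_update(state, make_trial(r=1, valid=False), anchor_params)
        assert d1 == 0 and d2 == 0
        assert list(state.q_mf_stage1) == [0.3, 0.4] and state.last_a1 is None

    def test_unchosen_values_untouched(self, anchor_params):
        state = ValueState.zeros()
        mf_update(state, make_trial(a1=0, state2=0, a2=1, r=1), anchor_params)
        assert state.q_mf_stage1[1] == 0
        assert state.q_mf_stage2[0, 0] == 0 and np.all(state.q_mf_stage2[1] == 0)


class TestMBValues:
    def test_equal_best_values_give_equal_mb(self, config):
        state = ValueState.zeros()
        state.q_mf_stage2[0, 1] = 0.6
        state.q_mf_stage2[1, 0] = 0.6
        np.testing.assert_allclose(mb_values(state, config), [0.6, 0.6])

    def test_direct_substitution(self, config):
        state = ValueState.zeros()
        state.q_mf_stage2[0, 0] = 1.0  # max Q(B) = 1, max Q(C) = 0
        np.testing.assert_allclose(mb_values(state, config), [0.7, 0.3])

    def test_hand_computation(self, config):
        # p_common=0.7, max Q(B)=0.4, max Q(C)=0.9 -> (0.55, 0.75)
        state = ValueState.zeros()
        state.q_mf_stage2[0, 1] = 0.4
        state.q_mf_stage2[1, 0] = 0.9
        np.testing.assert_allclose(mb_values(state, config), [0.55, 0.75], atol=1e-15)


class TestHybridValues:
    @pytest.mark.parametrize("omega", [0.0, 1.0])
    def test_boundary_omegas(self, config, omega):
        p = AgentParams(0.5, 0.5, 0.5, omega, 1, 1, 0)
        state = ValueState.zeros()
        state.q_mf_stage1[:] = [0.2, 0.6]
        state.q_mf_stage2[0, 0] = 0.9
        expected = mb_values(state, config) if omega == 1 else state.q_mf_stage1
        np.testing.assert_allclose(hybrid_values(state, p, config), expected)

    def test_convex_combination(self, config):
        # omega=0.68, Q_MB=0.7, Q_MF=0.2 -> 0.54
        p = AgentParams(0.5, 0.5, 0.5, 0.68, 1, 1, 0)
        state = ValueState.zeros()
        state.q_mf_stage1[:] = [0.2, 0.2]
        state.q_mf_stage2[:, :] = 0.7  # both MB values 0.7
        np.testing.assert_allclose(
            hybrid_values(state, p, config), [0.54, 0.54], atol=1e-15
        )


class TestChoiceProbs:
    def test_equal_values_symmetric(self):
        np.testing.assert_allclose(choice_probs(np.array([0.4, 0.4]), beta=3.0), [0.5, 0.5])

    def test_zero_beta_uniform(self):
        np.testing.assert_allclose(
            choice_probs(np.array([5.0, -3.0]), beta=0.0), [0.5, 0.5]
        )

    def test_perseveration_closed_form(self):
        # equal values, beta=7.67, rho=0.13, last action 0:
        # p(0) = logistic(7.67*0.13)
        p = choice_probs(np.array([0.3, 0.3]), beta=7.67, rho=0.13, last_action=0)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-7.67 * 0.13)), abs=1e-12)
        assert p[0] == pytest.approx(0.7305, abs=5e-4)

    def test_no_perseveration_at_stage2(self):
        p = choice_probs(np.array([0.3, 0.3]), beta=7.67, rho=0.13,
                         last_action=0, stage=2)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_large_beta_does_not_overflow(self):
        p = choice_probs(np.array([1000.0, -1000.0]), beta=50.0)
        assert p[0] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        q0=st.floats(-5, 5), q1=st.floats(-5, 5),
        beta=st.floats(0, 30), rho=st.floats(-2, 2),
        last=st.sampled_from([None, 0, 1]),
    )
    def test_probabilities_sum_to_one(self, q0, q1, beta, rho, last):
        p = choice_probs(np.array([q0, q1]), beta=beta, rho=rho, last_action=last)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


class TestSplitBetas:
    def test_symmetric_split(self):
        assert split_betas(0.5, 4.0) == (2.0, 2.0)

    def test_anchor_product(self):
        bmb, bmf = split_betas(0.68, 7.0)
        assert bmb == pytest.approx(4.76) and bmf == pytest.approx(2.24)

    @pytest.mark.parametrize("omega,beta", [(0.5, 4.0), (0.68, 7.67), (0.25, 16.0), (0.0, 3.0), (1.0, 3.0)])
    def test_sum_identity_exact_on_model_scale(self, omega, beta):
        bmb, bmf = split_betas(omega, beta)
        assert bmb + bmf == beta

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(omega=st.floats(0, 1), beta=st.floats(0, 50))
    def test_sum_identity_within_one_ulp(self, omega, beta):
        # exact in real arithmetic; float rounding can cost at most one ulp
        bmb, bmf = split_betas(omega, beta)
        assert abs((bmb + bmf) - beta) <= np.spacing(max(beta, 1e-300))


class TestTransforms:
    def test_logistic_midpoint_and_unit_beta(self):
        x = np.zeros(7)
        p = from_transformed(x)
        assert p.omega == 0.5 and p.alpha1 == 0.5 and p.beta1 == 1.0 and p.rho == 0.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(params=params_strategy())
    def test_round_trip_identity(self, params):
        back = from_transformed(to_transformed(params))
        np.testing.assert_allclose(back.to_vector(), params.to_vector(), atol=1e-12)

    @pytest.mark.parametrize("field,value", [("omega", 0.0), ("omega", 1.0), ("beta1", 0.0)])
    def test_boundary_values_raise(self, anchor_params, field, value):
        import dataclasses
        p = dataclasses.replace(anchor_params, **{field: value})
        with pytest.raises(ValueError):
            to_transformed(p)

    def test_json_round_trip_both_scales(self, anchor_params):
        for scale in ("natural", "transformed"):
            back = AgentParams.from_json(anchor_params.to_json(scale))
            np.testing.assert_allclose(
                back.to_vector(), anchor_params.to_vector(), atol=1e-12
            )


def oracle_nll(trials, params: AgentParams, p_common: float) -> float:
    """Independent step-by-step trace of the hybrid likelihood.

    Deliberately written with per-trial scalar arithmetic and explicit
    softmax, sharing no code with the vectorized implementation.
    """
    q1 = {0: 0.0, 1: 0.0}
    q2 = {(s, a): 0.0 for s in (0, 1) for a in (0, 1)}
    last = None
    nll = 0.0
    for tr in trials:
        if not tr.valid:
            continue
        qmb = {}
        for a in (0, 1):
            common_state, rare_state = a, 1 - a
            qmb[a] = p_common * max(q2[(common_state, 0)], q2[(common_state, 1)]) + (
                1 - p_common
            ) * max(q2[(rare_state, 0)], q2[(rare_state, 1)])
        vals = {}
        for a in (0, 1):
            rep = 1.0 if (last is not None and a == last) else 0.0
            q = params.omega * qmb[a] + (1 - params.omega) * q1[a]
            vals[a] = params.beta1 * (q + params.rho * rep)
        denom = math.exp(vals[0]) + math.exp(vals[1])
        nll -= vals[tr.a1] - math.log(denom)
        v2 = {a: params.beta2 * q2[(tr.state2, a)] for a in (0, 1)}
        denom2 = math.exp(v2[0]) + math.exp(v2[1])
        nll -= v2[tr.a2] - math.log(denom2)
        d1 = q2[(tr.state2, tr.a2)] - q1[tr.a1]
        d2 = tr.r - q2[(tr.state2, tr.a2)]
        q1[tr.a1] += params.alpha1 * d1
        q2[(tr.state2, tr.a2)] += params.alpha2 * d2
        q1[tr.a1] += params.alpha1 * params.lam * d2
        last = tr.a1
    return nll


class TestSessionNLL:
    def test_uniform_policy_closed_form(self, config, anchor_params):
        import dataclasses
        trials = simulate_agent(anchor_params, config, seed=5)
        p0 = dataclasses.replace(anchor_params, beta1=0.0, beta2=0.0)
        assert session_nll(trials, p0, config) == pytest.approx(
            2 * 201 * math.log(2), abs=1e-9
        )

    def test_empty_session_scores_zero(self, config, anchor_params):
        assert session_nll([], anchor_params, config) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_trace_on_fixtures(self, config, seed):
        rng = np.random.default_rng(seed)
        cfg10 = TwoStepConfig(n_trials=10)
        gen = AgentParams(0.4, 0.6, 0.5, 0.7, 4.0, 3.0, 0.2)
        trials = simulate_agent(gen, cfg10, seed=seed)
        probe = AgentParams(
            alpha1=float(rng.uniform(0.2, 0.8)), alpha2=float(rng.uniform(0.2, 0.8)),
            lam=float(rng.uniform(0.2, 0.8)), omega=float(rng.uniform(0.1, 0.9)),
            beta1=float(rng.uniform(0.5, 8)), beta2=float(rng.uniform(0.5, 8)),
            rho=float(rng.uniform(-0.5, 0.5)),
        )
        assert session_nll(trials, probe, cfg10) == pytest.approx(
            oracle_nll(trials, probe, cfg10.p_common), abs=1e-10
        )

    def test_invalid_trials_contribute_nothing(self, config, anchor_params):
        trials = simulate_agent(anchor_params, TwoStepConfig(n_trials=20), seed=8)
        import dataclasses
        dropped = [dataclasses.replace(t, valid=False) if t.t >= 10 else t for t in trials]
        assert session_nll(dropped, anchor_params, config) == pytest.approx(
            session_nll(trials[:10], anchor_params, config), abs=1e-10
        )

    def test_likelihood_lower_at_generating_params(self, config, anchor_params):
        """At 201 trials the generating parameters beat +/-50% perturbations
        of omega and beta1 on average across seeds."""
        import dataclasses
        diffs = []
        for seed in range(20):
            trials = simulate_agent(anchor_params, config, seed=seed)
            s = Session.from_trials(trials)
            base = session_nll(s, anchor_params, config)
            for factor in (0.5, 1.5):
                pert = dataclasses.replace(
                    anchor_params,
                    omega=min(anchor_params.omega * factor, 0.99),
                    beta1=anchor_params.beta1 * factor,
                )
                diffs.append(session_nll(s, pert, config) - base)
        assert np.mean(diffs) > 0


class TestSimulateAgent:
    def test_fixed_seed_reproducible(self, config, anchor_params):
        a = trials_to_frame(simulate_agent(anchor_params, config, seed=6)).to_csv()
        b = trials_to_frame(simulate_agent(anchor_params, config, seed=6)).to_csv()
        assert a == b

    def test_mf_agent_is_transition_blind(self):
        p = AgentParams(0.5, 0.5, 0.6, 0.0, 5.0, 5.0, 0.0)
        trials = simulate_agent(p, TwoStepConfig(n_trials=10_000), seed=7)
        a = stay_probability_table(trials).as_array()
        assert abs(a[0, 0] - a[0, 1]) < 0.04  # rewarded rows
        assert abs(a[1, 0] - a[1, 1]) < 0.04  # unrewarded rows
        assert a[0].mean() - a[1].mean() > 0.1  # reward main effect present

    def test_mb_agent_shows_crossover(self):
        p = AgentParams(0.5, 0.5, 0.6, 1.0, 5.0, 5.0, 0.0)
        trials = simulate_agent(p, TwoStepConfig(n_trials=10_000), seed=7)
        a = stay_probability_table(trials).as_array()
        assert a[0, 0] > a[0, 1] + 0.05  # rewarded: common > rare
        assert a[1, 1] > a[1, 0] + 0.05  # unrewarded: rare > common

    def test_stage2_values_bounded_by_rewards(self, config, anchor_params):
        """With 0/1 rewards and zero initialization stage-2 MF values stay
        in [0, 1] throughout a session."""
        state = ValueState.zeros()
        trials = simulate_agent(anchor_params, config, seed=9)
        for tr in trials:
            mf_update(state, tr, anchor_params)
            assert np.all(state.q_mf_stage2 >= 0) and np.all(state.q_mf_stage2 <= 1)
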