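"""Learner dynamics: update arithmetic, policies, reductions, dual-path NLL."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import socialrl as s
from socialrl.agents import LearnerAgent, softmax_pair


def make_agent(name, **params):
    spec = s.get_model(name)
    return LearnerAgent(spec, s.ParameterSet(**params), n_contexts=2)


class TestInitialization:
    @pytest.mark.parametrize("name", ["RW2", "DB6", "MB1", "VS2", "metaVS"])
    def test_initial_state(self, name):
        agent = make_agent(name)
        assert agent.Q == [[0.0, 0.0], [0.0, 0.0]]
        assert agent.pi_D == [[0.5, 0.5], [0.5, 0.5]]
        assert agent.Q_D == [[0.0, 0.0], [0.0, 0.0]]
        assert agent.alpha_i_state == [0.0, 0.0]
        assert agent.last_action == [None, None]
        assert agent.trace == [None, None]


class TestPolicy:
    def test_flat_when_beta_zero(self):
        assert softmax_pair(0.7, -0.2, 0.0, 1.0, 0) == (0.5, 0.5)

    def test_symmetric_values(self):
        assert softmax_pair(0.4, 0.4, 5.0, 0.0, None) == (0.5, 0.5)

    def test_closed_form_unit_gap(self):
        # V = (1, 0), beta = 1, kappa = 0, no previous action
        p0, p1 = softmax_pair(1.0, 0.0, 1.0, 0.0, None)
        assert p0 == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)
        assert p0 == pytest.approx(0.7310585786300049, abs=1e-9)
        assert p0 + p1 == pytest.approx(1.0, abs=1e-15)

    def test_autocorrelation_favors_last_action(self):
        stay0, _ = softmax_pair(0.0, 0.0, 2.0, 0.5, 0)
        stay1, _ = softmax_pair(0.0, 0.0, 2.0, 0.5, 1)
        assert stay0 > 0.5 > stay1
        # manual evaluation: exponent beta * (dV - lambda*kappa) = -2*0.5*... wait
        assert stay0 == pytest.approx(1.0 / (1.0 + math.exp(-2.0 * 0.5)), abs=1e-12)


class TestPrivateUpdate:
    def test_delta_rule_arithmetic(self):
        agent = make_agent("RW1", alpha_p=0.5)
        agent.learn(0, 0, +1)
        assert agent.Q[0] == [0.5, 0.0]
        agent2 = make_agent("RW2", alpha_p=0.5)
        agent2.learn(0, 0, +1)
        assert agent2.Q[0] == [0.5, -0.5]  # symmetric update

    def test_zero_learning_rate_freezes_values(self):
        agent = make_agent("RW2", alpha_p=0.0)
        for r in (1, -1, 1):
            agent.learn(0, 0, r)
        assert agent.Q[0] == [0.0, 0.0]

    def test_converges_to_outcome_mean(self):
        # running-average oracle: with iid outcomes the value tracks the mean
        rng = np.random.default_rng(0)
        agent = make_agent("RW1", alpha_p=0.05)
        p_win = 0.8
        outcomes = np.where(rng.random(4000) < p_win, 1.0, -1.0)
        for r in outcomes:
            agent.learn(0, 0, r)
        assert agent.Q[0][0] == pytest.approx(2 * p_win - 1, abs=0.15)

    def test_invalid_outcome_rejected(self):
        with pytest.raises(ValueError):
            make_agent("RW1").learn(0, 0, 0.5)


class TestDemonstrationUpdates:
    def test_db1_policy_bias(self):
        agent = make_agent("DB1", alpha_i=0.2, beta=1.0, kappa=0.0)
        agent.observe(0, 0)  # pi derived from Q=(0,0) is (0.5, 0.5)
        assert agent.trace[0] == pytest.approx([0.6, 0.4])

    def test_vs2_symmetric_update(self):
        agent = make_agent("VS2", alpha_i=0.3)
        agent.observe(0, 0)
        assert agent.Q[0] == pytest.approx([0.3, -0.3])

    def test_vs1_leaves_other_option(self):
        agent = make_agent("VS1", alpha_i=0.3)
        agent.observe(0, 0)
        assert agent.Q[0] == pytest.approx([0.3, 0.0])

    def test_metavs_agreement_sequence(self):
        # hand evaluation: Q = (0.4, 0.1), demonstrated option is the better
        # one -> tau = 1, alpha_i(s): 0 -> 0.5, then Q(d) = 0.4 + 0.5*0.6 = 0.7
        agent = make_agent("metaVS", alpha_m=0.5)
        agent.Q[0] = [0.4, 0.1]
        agent.observe(0, 0)
        assert agent.alpha_i_state[0] == pytest.approx(0.5)
        assert agent.Q[0][0] == pytest.approx(0.7)

    def test_metavs_tie_counts_as_agreement(self):
        agent = make_agent("metaVS", alpha_m=0.5)
        agent.observe(0, 1)  # Q(d) = Q(dbar) = 0 satisfies the max condition
        assert agent.tau == 1
        assert agent.alpha_i_state[0] == pytest.approx(0.5)

    def test_db6_accumulates_two_demonstrations(self):
        # two applications of the value update from Q'(d) = 0 with rate 0.2:
        # 0.2 then 0.2 + 0.2*0.8 = 0.36
        agent = make_agent("DB6", alpha_i=0.2)
        agent.observe(0, 0)
        agent.observe(0, 0)
        assert agent.trace[0][0] == pytest.approx(0.36)

    def test_mb9_bias_step(self):
        # demonstrator values (0.8, -0.8): preferred option biases a copy of
        # Q = (0, 0) by the symmetric value update with alpha_i = 0.4
        agent = make_agent("MB9", alpha_i=0.4, beta=1.0, kappa=0.0)
        agent.Q_D[0] = [0.8, -0.8]
        p0, p1 = agent.action_policy(0)
        expect = softmax_pair(0.4, -0.4, 1.0, 0.0, None)
        assert (p0, p1) == pytest.approx(expect)

    def test_mb_build_rates(self):
        agent = make_agent("MB1")  # alpha_d fixed at 0.1
        agent.observe(0, 0)
        assert agent.pi_D[0] == pytest.approx([0.55, 0.45])
        assert agent.Q[0] == [0.0, 0.0]  # demonstrations never touch Q in MB

    def test_mb_tie_gives_no_bias(self):
        agent = make_agent("MB9", alpha_i=0.4)
        assert agent.action_policy(0) == agent.value_policy(0)


class TestAccumulationMechanism:
    """DB1-3 re-derive their trace from Q, so repeated identical
    demonstrations bias no more than one; DB4-6 and VS strictly accumulate."""

    @pytest.mark.parametrize("name", ["DB1", "DB2", "DB3"])
    def test_rederiving_variants_do_not_accumulate(self, name):
        one = make_agent(name, alpha_i=0.3)
        one.observe(0, 0)
        two = make_agent(name, alpha_i=0.3)
        two.observe(0, 0)
        two.observe(0, 0)
        assert two.action_policy(0)[0] == pytest.approx(one.action_policy(0)[0])

    @pytest.mark.parametrize("name", ["DB4", "DB5", "DB6", "VS1", "VS2"])
    def test_accumulating_variants_grow(self, name):
        one = make_agent(name, alpha_i=0.3)
        one.observe(0, 0)
        two = make_agent(name, alpha_i=0.3)
        two.observe(0, 0)
        two.observe(0, 0)
        assert two.action_policy(0)[0] > one.action_policy(0)[0]


class TestPropagationMechanism:
    """DB traces die with the next private choice; VS effects persist."""

    @pytest.mark.parametrize("name", ["DB1", "DB4", "DB6"])
    def test_db_trace_reverts_after_private_choice(self, name):
        agent = make_agent(name, alpha_p=0.3, alpha_i=0.4)
        agent.observe(0, 0)
        assert agent.action_policy(0) != agent.value_policy(0)
        agent.learn(0, 1, -1)
        assert agent.trace[0] is None
        assert agent.action_policy(0) == agent.value_policy(0)

    def test_vs_effect_survives_private_choice(self):
        shaped = make_agent("VS2", alpha_p=0.3, alpha_i=0.4)
        blank = make_agent("VS2", alpha_p=0.3, alpha_i=0.4)
        shaped.observe(0, 0)
        shaped.learn(0, 1, -1)
        blank.learn(0, 1, -1)
        assert shaped.action_policy(0)[0] > blank.action_policy(0)[0]

    def test_block_boundary_clears_trace(self):
        agent = make_agent("DB6", alpha_i=0.4)
        agent.observe(0, 0)
        agent.start_block(0)
        assert agent.trace[0] is None


class TestReductions:
    @pytest.mark.parametrize("name", ["DB1", "DB3", "DB6", "MB1", "MB5", "MB9", "VS1", "VS2"])
    def test_zero_imitation_collapses_to_rw(self, name, vs2_dataset):
        spec = s.get_model(name)
        rw = s.get_model("RW2").replace(symmetric_private=spec.symmetric_private)
        params = s.ParameterSet(alpha_p=0.37, alpha_i=0.0, beta=4.2, kappa=0.4)
        assert s.dataset_nll(spec, params, vs2_dataset) == pytest.approx(
            s.dataset_nll(rw, params, vs2_dataset), abs=1e-12
        )

    def test_zero_meta_rate_collapses_to_rw(self, vs2_dataset):
        params = s.ParameterSet(alpha_p=0.37, alpha_m=0.0, beta=4.2, kappa=0.4)
        assert s.dataset_nll(s.get_model("metaVS"), params, vs2_dataset) == pytest.approx(
            s.dataset_nll(s.get_model("RW2"), params, vs2_dataset), abs=1e-12
        )

    def test_simulation_reduction_same_choices(self, exp2_schedule):
        params = s.ParameterSet(alpha_p=0.4, alpha_i=0.0, beta=5.0)
        a = s.simulate_agent(s.get_model("VS2"), params, exp2_schedule, 3)
        b = s.simulate_agent(s.get_model("RW2"), params, exp2_schedule, 3)
        assert a["choice"].tolist() == b["choice"].tolist()


class TestKernelAgreement:
    """The compiled likelihood must agree exactly with the reference agent."""

    @pytest.mark.parametrize("name", s.list_models())
    def test_nll_paths_agree(self, name, vs2_dataset):
        spec = s.get_model(name)
        rng = np.random.default_rng(sum(ord(c) for c in name))
        for _ in range(3):
            params = s.sample_parameters(spec, rng)
            k = s.dataset_nll(spec, params, vs2_dataset)
            r = s.dataset_nll_reference(spec, params, vs2_dataset)
            assert k == pytest.approx(r, abs=1e-9)

    @pytest.mark.parametrize("flag", ["use_kappa", "symmetric_private",
                                      "match_updates_last_action"])
    def test_flags_respected_by_both_paths(self, flag, vs2_dataset):
        spec = s.get_model("DB6").replace(**{flag: False})
        params = s.ParameterSet(alpha_p=0.3, alpha_i=0.2, beta=3.0, kappa=0.8)
        k = s.dataset_nll(spec, params, vs2_dataset)
        r = s.dataset_nll_reference(spec, params, vs2_dataset)
        assert k == pytest.approx(r, abs=1e-9)
        on = s.dataset_nll(s.get_model("DB6"), params, vs2_dataset)
        assert k != pytest.approx(on, abs=1e-9)  # the flag changes the fit

    def test_mb_blend_variant_agrees(self, vs2_dataset):
        spec = s.get_model("MB2", mb_bias="blend")
        params = s.ParameterSet(alpha_p=0.3, alpha_i=0.25, beta=3.0, kappa=0.1)
        assert s.dataset_nll(spec, params, vs2_dataset) == pytest.approx(
            s.dataset_nll_reference(spec, params, vs2_dataset), abs=1e-9
        )


@st.composite
def event_sequences(draw):
    n = draw(st.integers(5, 40))
    return [
        (draw(st.sampled_from(["obs", "priv"])),
         draw(st.integers(0, 1)),
         draw(st.sampled_from([1.0, -1.0])))
        for _ in range(n)
    ]


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        name=st.sampled_from(["RW1", "RW2", "DB1", "DB4", "DB6", "MB3", "MB9",
                              "VS2", "metaVS"]),
        events=event_sequences(),
        alpha_p=st.floats(0.01, 0.99),
        alpha_i=st.floats(0.01, 0.99),
        beta=st.floats(0.0, 20.0),
        kappa=st.floats(-3.0, 3.0),
    )
    def test_values_bounded_and_policy_normalised(self, name, events,
                                                  alpha_p, alpha_i, beta, kappa):
        """Q, Q', Q_D stay in [-1, 1] and every policy sums to one, for any
        admissible parameters and any event sequence."""
        spec = s.get_model(name)
        params = s.ParameterSet(alpha_p=alpha_p, alpha_i=alpha_i,
                                alpha_m=alpha_i, beta=beta, kappa=kappa)
        agent = LearnerAgent(spec, params, n_contexts=1)
        for kind, option, outcome in events:
            if kind == "obs":
                agent.observe(0, option)
            else:
                agent.learn(0, option, outcome)
            p0, p1 = agent.action_policy(0)
            assert p0 + p1 == pytest.approx(1.0, abs=1e-9)
            assert -1e-9 <= p0 <= 1 + 1e-9
            assert all(abs(v) <= 1 + 1e-9 for v in agent.Q[0])
            assert all(abs(v) <= 1 + 1e-9 for v in agent.Q_D[0])
            if agent.trace[0] is not None and spec.variant not in (1, 4):
                assert all(abs(v) <= 1 + 1e-9 for v in agent.trace[0])
            assert 0.0 <= agent.alpha_i_state[0] <= 1.0


class TestSimulation:
    def test_greedy_agent_exploits_deterministic_reward(self):
        sched = s.make_schedule(s.TaskConfig.exp2(p_correct=1.0), 0)
        params = s.ParameterSet(alpha_p=0.9, beta=50.0, kappa=0.0)
        sim = s.simulate_agent(s.get_model("RW1"), params, sched, 1)
        # within each block, once the better option pays off the agent stays
        rate = s.correct_choice_rate(sim)
        assert rate > 0.9

    def test_simulation_reproducible(self, exp2_schedule):
        params = s.ParameterSet(alpha_p=0.4, alpha_i=0.2, beta=4.0)
        a = s.simulate_agent(s.get_model("VS2"), params, exp2_schedule, 11)
        b = s.simulate_agent(s.get_model("VS2"), params, exp2_schedule, 11)
        assert a.equals(b)
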