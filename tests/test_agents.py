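"""Cognitive hierarchy: level -1 reactive models, level-0 planning,
level collapses, and the de-duplicated estimation grid."""

import numpy as np
import pytest

import oracles
from trustpomcp.agents import (
    AgentSpec,
    effective_level,
    investor_grid,
    level0_investor_policy,
    level0_investor_values,
    level0_trustee_policy,
    level_minus1_expected_utilities,
    level_minus1_policy,
    nesting_depth,
    trustee_grid,
)
from trustpomcp.game import GUILT_TYPES, UTIL_I
from trustpomcp.tables import TRUSTEE_RESPONSE, pair_id


class TestEffectiveLevel:
    @pytest.mark.parametrize(
        "role,k,expected",
        [
            ("investor", 0, 0), ("investor", 1, 0), ("investor", 2, 2),
            ("investor", 3, 2),
            ("trustee", 0, 0), ("trustee", 1, 1), ("trustee", 2, 1),
        ],
    )
    def test_collapse(self, role, k, expected):
        assert effective_level(role, k) == expected

    def test_estimation_grids_are_deduplicated(self):
        inv, tru = investor_grid(), trustee_grid()
        assert len(inv) == 15 and len(tru) == 9
        assert len(inv) * len(tru) == 135
        assert all(s.P == 0 for s in tru if s.k == 0)


class TestLevelMinus1:
    def test_policies_normalize(self):
        for role in ("investor", "trustee"):
            for alpha in GUILT_TYPES:
                p = level_minus1_policy(role, alpha, investment=3)
                assert np.isclose(p.sum(), 1.0)
                assert np.all(p >= 0)

    def test_guilty_trustee_modal_action_restores_equality(self):
        # full investment: returning 1/2 equalizes payoffs at 30/30
        p = level_minus1_policy("trustee", 1.0, investment=4)
        assert p.argmax() == 3

    def test_greedy_trustee_modal_action_returns_nothing(self):
        p = level_minus1_policy("trustee", 0.0, investment=4)
        assert p.argmax() == 0

    def test_degenerate_round_is_forced(self):
        p = level_minus1_policy("trustee", 0.4, investment=0)
        assert p[0] == 1.0 and p[1:].sum() == 0.0

    def test_beta_limit_degenerates_to_argmax(self):
        eu = level_minus1_expected_utilities("investor", 0.4)
        p = level_minus1_policy("investor", 0.4, beta=1e6)
        assert p.argmax() == int(np.argmax(eu))
        assert p.max() > 0.999

    def test_nesting_terminates_in_k_plus_1_steps(self):
        assert nesting_depth(AgentSpec("investor", 2, 1.0, 7)) == 3
        assert nesting_depth(AgentSpec("trustee", 1, 0.4, 2)) == 2
        assert nesting_depth(AgentSpec("investor", 0, 0.0, 0)) == 1


class TestLevel0Trustee:
    def test_policy_identical_for_any_nominal_horizon(self):
        for alpha in GUILT_TYPES:
            for i in range(5):
                p0 = level0_trustee_policy(i, alpha, P=0)
                p7 = level0_trustee_policy(i, alpha, P=7)
                assert np.array_equal(p0, p7)

    def test_matches_reactive_response_table(self):
        for g, alpha in enumerate(GUILT_TYPES):
            for i in range(1, 5):
                assert np.allclose(
                    level0_trustee_policy(i, alpha), TRUSTEE_RESPONSE[g, i, :]
                )


class TestLevel0Investor:
    def test_horizon0_values_are_immediate_expected_utilities(self):
        for g, alpha in enumerate(GUILT_TYPES):
            q = level0_investor_values([], 5, 0, alpha)
            pred = np.ones(3) / 3
            for a in range(5):
                if a == 0:
                    expected = UTIL_I[g, 0, 0]
                else:
                    resp = pred @ TRUSTEE_RESPONSE[:, a, :]
                    expected = float(resp @ UTIL_I[g, a, :])
                assert np.isclose(q[a], expected)

    @pytest.mark.parametrize("guilt_idx", [0, 1, 2])
    @pytest.mark.parametrize("t,P", [(9, 2), (9, 7), (8, 2)])
    def test_agrees_with_brute_force_expectimax(self, guilt_idx, t, P):
        """Recombining DP equals exhaustive ordered-history softmax
        expectimax on truncated games."""
        history = [(4, 3), (2, 0)][: 10 - t - 1]
        pids = [pair_id(i, j) for i, j in history]
        dp = level0_investor_values(pids, t, P, GUILT_TYPES[guilt_idx])
        oracle = oracles.level0_investor_q(history, t, P, guilt_idx)
        assert np.allclose(dp, oracle, atol=1e-9)

    def test_values_invariant_under_exchange_permutation(self):
        exchanges = [(4, 0), (2, 3), (4, 3), (1, 2), (0, 0)]
        pids = [pair_id(i, j) for i, j in exchanges]
        ref = level0_investor_values(pids, 6, 7, 1.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(rng.permutation(pids))
            assert np.array_equal(level0_investor_values(perm, 6, 7, 1.0), ref)

    def test_policy_normalizes_and_prefers_investment_when_guilty(self):
        p = level0_investor_policy([], 1, 7, 1.0)
        assert np.isclose(p.sum(), 1.0)
        assert p[0] < 0.05  # keeping everything is strongly dispreferred


def test_spec_validation():
    with pytest.raises(ValueError):
        AgentSpec("investor", 0, 0.5, 2)
    with pytest.raises(ValueError):
        AgentSpec("banker", 0, 0.0, 2)
    with pytest.raises(ValueError):
        AgentSpec("investor", -1, 0.0, 2)
    assert AgentSpec("trustee", 0, 1.0, 7).effective_P == 0
    assert AgentSpec("investor", 2, 1.0, 7).partner_spec(0.4) == AgentSpec(
        "trustee", 1, 0.4, 7
    )
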