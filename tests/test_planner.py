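"""POMCP mechanics: backup, SoftUCT, schedule, pre-search, determinism,
and closed-form equivalences of the trivial cases."""

import random

import numpy as np
import pytest

from trustpomcp.agents import AgentSpec
from trustpomcp.beliefs import init_belief
from trustpomcp.game import UTIL_T
from trustpomcp.planner import (
    PlannerContext,
    SearchConfig,
    TreeNode,
    backup,
    search,
    simulation_schedule,
    soft_uct_select,
)
from trustpomcp.tables import softmax


class TestBackup:
    def test_first_backup_sets_the_mean(self):
        node = TreeNode(5)
        backup(node, 2, 10.0)
        assert node.q[2] == 10.0 and node.counts[2] == 1 and node.n == 1

    def test_running_mean(self):
        node = TreeNode(5)
        for r in (4.0, 8.0):
            backup(node, 1, r)
        assert node.q[1] == 6.0
        for r in (1.0, 2.0, 6.0):
            backup(node, 1, r)
        assert np.isclose(node.q[1], np.mean([4, 8, 1, 2, 6]))

    def test_backup_of_current_mean_is_fixed_point(self):
        node = TreeNode(3)
        backup(node, 0, 7.0)
        backup(node, 0, 7.0)
        assert node.q[0] == 7.0

    def test_node_count_is_sum_of_action_counts(self):
        node = TreeNode(4)
        rng = random.Random(0)
        for _ in range(50):
            backup(node, rng.randrange(4), rng.random())
        assert node.n == sum(node.counts)


class TestSoftUCT:
    def test_unvisited_actions_selected_first_in_index_order(self):
        node = TreeNode(5)
        rng = random.Random(1)
        picks = []
        for _ in range(5):
            a = soft_uct_select(node, 1 / 3, 25.0, rng)
            picks.append(a)
            backup(node, a, 0.0)
        assert picks == [0, 1, 2, 3, 4]

    def test_symmetric_node_selects_uniformly(self):
        node = TreeNode(4)
        for a in range(4):
            node.counts[a] = 10
            node.q[a] = 5.0
        node.n = 40
        rng = random.Random(2)
        draws = [soft_uct_select(node, 1 / 3, 25.0, rng) for _ in range(4000)]
        freqs = np.bincount(draws, minlength=4) / 4000
        assert np.allclose(freqs, 0.25, atol=0.03)

    def test_zero_exploration_high_beta_is_greedy(self):
        node = TreeNode(3)
        node.counts = [10, 10, 10]
        node.q = [1.0, 5.0, 3.0]
        node.n = 30
        rng = random.Random(3)
        assert all(
            soft_uct_select(node, 1e6, 0.0, rng) == 1 for _ in range(20)
        )


def test_simulation_schedule():
    assert simulation_schedule(1000, 1) == 1000
    assert simulation_schedule(1000, 10) == 100
    counts = [simulation_schedule(1000, t) for t in range(1, 11)]
    assert counts == sorted(counts, reverse=True)
    with pytest.raises(ValueError):
        simulation_schedule(1000, 0)


def test_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(n_paths=0)
    cfg = SearchConfig(n_paths=1000)
    assert cfg.presearch == 20 and cfg.nested_paths == 50


class TestClosedForms:
    def test_horizon0_investor_distribution_is_immediate_softmax(self, shared_ctx):
        spec = AgentSpec("investor", 0, 0.4, 0)
        res = search([], 3, spec, shared_ctx, seed=0)
        from trustpomcp.agents import level0_investor_values

        q = level0_investor_values([], 3, 0, 0.4)
        assert np.allclose(res.probs, softmax(q))

    def test_level0_trustee_distribution_matches_immediate_row(self, shared_ctx):
        spec = AgentSpec("trustee", 0, 1.0, 0)
        res = search([], 4, spec, shared_ctx, seed=0, pending_investment=4)
        assert np.allclose(res.probs, softmax(UTIL_T[2, 4, :]))

    def test_degenerate_trustee_round_is_forced(self, shared_ctx):
        spec = AgentSpec("trustee", 1, 0.4, 7)
        res = search([], 4, spec, shared_ctx, seed=0, pending_investment=0)
        assert res.action == 0 and res.probs[0] == 1.0

    def test_round_validation(self, shared_ctx):
        spec = AgentSpec("investor", 0, 0.0, 0)
        with pytest.raises(ValueError):
            search([], 11, spec, shared_ctx, seed=0)
        with pytest.raises(ValueError):
            search([], 1, AgentSpec("trustee", 0, 0.0, 0), shared_ctx, seed=0)


class TestSearchDeterminism:
    def test_identical_seeds_give_identical_results(self, small_config):
        spec = AgentSpec("trustee", 1, 1.0, 2)
        hist = [(4, 3), (2, 2)]
        a = search(hist, 3, spec, PlannerContext(small_config), seed=42,
                   pending_investment=4)
        b = search(hist, 3, spec, PlannerContext(small_config), seed=42,
                   pending_investment=4)
        assert np.array_equal(a.probs, b.probs)
        assert np.array_equal(a.q, b.q)
        assert a.action == b.action

    def test_cache_state_does_not_change_results(self, small_config):
        """Nested policies are seeded from their keys, so a warm cache
        returns bit-identical search results."""
        spec = AgentSpec("investor", 2, 1.0, 2)
        ctx = PlannerContext(small_config)
        a = search([], 1, spec, ctx, seed=7)
        b = search([], 1, spec, ctx, seed=7)
        assert np.array_equal(a.probs, b.probs) and a.action == b.action


class TestPresearch:
    def test_presearch_gives_every_root_action_visits(self, small_config):
        cfg = SearchConfig(n_paths=30, presearch_per_action=4, nested_n_paths=20)
        spec = AgentSpec("trustee", 1, 0.0, 2)
        res = search([], 1, spec, PlannerContext(cfg), seed=5,
                     pending_investment=4)
        assert all(c >= 4 for c in res.counts)
        assert res.counts.sum() == 30 + 5 * 4

    def test_presearch_reduces_first_action_variance(self, small_config):
        """At equal total budget, seeding root values from constant
        strategies stabilizes the returned action probabilities."""
        spec = AgentSpec("trustee", 1, 1.0, 2)

        def spread(presearch, n_paths, seeds):
            cfg = SearchConfig(n_paths=n_paths, presearch_per_action=presearch,
                               nested_n_paths=20)
            ctx = PlannerContext(cfg)
            probs = [
                search([], 1, spec, ctx, seed=s, pending_investment=4).probs
                for s in seeds
            ]
            return np.array(probs).std(axis=0).max()

        seeds = range(12)
        with_pre = spread(20, 100, seeds)      # 100 + 5*20 = 200 paths
        without = spread(0, 200, seeds)        # 200 paths
        assert with_pre < without
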