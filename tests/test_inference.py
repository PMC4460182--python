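"""Maximum-likelihood inversion: NLL accounting, grid fits, recovery."""

import math

import numpy as np
import pytest

from trustpomcp.agents import AgentSpec
from trustpomcp.inference import (
    fit_dyad,
    history_nll,
    ks_two_sample,
    random_baseline_nll,
)
from trustpomcp.planner import PlannerContext, SearchConfig
from trustpomcp.simulate import batch_simulate

GUILT_GRID = (0.0, 0.4, 1.0)


def test_random_baseline_is_ten_log_five():
    assert np.isclose(random_baseline_nll(), 10 * math.log(5))
    assert round(random_baseline_nll(), 1) == 16.1
    assert np.isclose(random_baseline_nll(4), 4 * math.log(5))


class TestHistoryNll:
    def test_additive_over_rounds(self, small_config, shared_ctx):
        spec = AgentSpec("investor", 0, 0.4, 2)
        hist = [(2, 2), (4, 3), (1, 0)]
        total, per_round = history_nll(hist, spec, small_config, ctx=shared_ctx)
        assert np.isclose(total, sum(per_round))
        partial, _ = history_nll(hist[:2], spec, small_config, ctx=shared_ctx)
        assert np.isclose(partial, sum(per_round[:2]))

    def test_single_round_matches_closed_form_policy(self, small_config, shared_ctx):
        from trustpomcp.agents import level0_investor_values
        from trustpomcp.tables import softmax

        spec = AgentSpec("investor", 0, 1.0, 0)
        nll, _ = history_nll([(3, 2)], spec, small_config, ctx=shared_ctx)
        probs = softmax(level0_investor_values([], 1, 0, 1.0))
        assert np.isclose(nll, -math.log(probs[3]))

    def test_degenerate_rounds_contribute_zero_trustee_nll(
        self, small_config, shared_ctx
    ):
        spec = AgentSpec("trustee", 0, 0.4, 0)
        nll, per_round = history_nll(
            [(0, 0), (2, 1), (0, 0)], spec, small_config, ctx=shared_ctx
        )
        assert per_round[0] == 0.0 and per_round[2] == 0.0
        assert nll == per_round[1] > 0


class TestFitDyad:
    def test_empty_history_flagged_unidentifiable(self, small_config, shared_ctx):
        fi, ft = fit_dyad([], small_config, ctx=shared_ctx)
        assert fi.unidentifiable and ft.unidentifiable
        assert fi.best is None and ft.best is None
        assert all(v == 0.0 for _s, v in fi.nll_table)

    def test_all_zero_investments_leave_trustee_unidentifiable(
        self, small_config, shared_ctx
    ):
        hist = [(0, 0)] * 10
        _fi, ft = fit_dyad(hist, small_config, ctx=shared_ctx)
        assert ft.unidentifiable and ft.n_informative_rounds == 0

    def test_guilt_recovery_from_closed_form_agents(self, small_config, shared_ctx):
        """Games of non-planning agents are cheap and strongly typed:
        the generating guilt must win the guilt-only fit, and beat the
        random baseline."""
        for alpha in (0.0, 1.0):
            inv = AgentSpec("investor", 0, alpha, 0)
            tru = AgentSpec("trustee", 0, alpha, 0)
            records = batch_simulate([(inv, tru)], 3, small_config, seed=13,
                                     ctx=shared_ctx)
            inv_cells = [AgentSpec("investor", 0, a, 0) for a in GUILT_GRID]
            tru_cells = [AgentSpec("trustee", 0, a, 0) for a in GUILT_GRID]
            wins_i = wins_t = informative = 0
            for rec in records:
                fi, ft = fit_dyad(rec.exchanges, small_config,
                                  inv_cells, tru_cells, ctx=shared_ctx)
                best_nll_i = min(v for _s, v in fi.nll_table)
                assert best_nll_i < random_baseline_nll(fi.n_informative_rounds)
                wins_i += fi.best.alpha == alpha
                if not ft.unidentifiable:
                    informative += 1
                    wins_t += ft.best.alpha == alpha
            assert wins_i >= 2
            assert informative == 0 or wins_t >= informative / 2


class TestKsTwoSample:
    def test_identical_samples_give_zero_statistic(self):
        stat, p = ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == 0.0 and p == 1.0

    def test_disjoint_support_gives_one(self):
        stat, _p = ks_two_sample([0, 1, 2], [10, 11, 12])
        assert stat == 1.0

    def test_agrees_with_reference_implementation(self):
        import scipy.stats

        rng = np.random.default_rng(5)
        a, b = rng.normal(size=40), rng.normal(0.5, 1.2, size=30)
        stat, p = ks_two_sample(a, b)
        ref = scipy.stats.ks_2samp(a, b)
        assert stat == ref.statistic and p == ref.pvalue

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
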