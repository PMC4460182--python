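"""Dyadic game engine: full 10-round games and batch experiments.

A game alternates investor and trustee decisions, each planned by
:func:`trustpomcp.planner.search` (closed forms for the trivial levels),
with both agents' Dirichlet beliefs about the partner's guilt updated
after every observed action using the likelihoods of their respective
intentional models.  Batches over the de-duplicated (k, alpha, P) grid
reproduce the paradigmatic behaviours of the model: cooperation between
guilty long-horizon pairs, coaxing by level-1 trustees, greedy
breakdown, and the planning-horizon dependence of total earnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import AgentSpec, level_minus1_policy
from .beliefs import init_belief, predictive_probs, update_belief
from .game import (
    GAME_LENGTH,
    GUILT_TYPES,
    INVESTOR_FRACTIONS,
    TRUSTEE_FRACTIONS,
    monetary_payoffs,
)
from .planner import (
    PlannerContext,
    SearchConfig,
    search,
    simulation_schedule,
    stable_seed,
)
from .tables import TRUSTEE_RESPONSE


@dataclass
class GameRecord:
    """One simulated 10-round game with full belief trajectories."""

    investor: AgentSpec
    trustee: AgentSpec
    seed: int
    exchanges: list[tuple[int, int]] = field(default_factory=list)
    payoffs: list[tuple[float, float]] = field(default_factory=list)
    investor_posteriors: list[tuple[float, float, float]] = field(default_factory=list)
    trustee_posteriors: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def total_gains(self) -> tuple[float, float]:
        chi_i = sum(p[0] for p in self.payoffs)
        chi_t = sum(p[1] for p in self.payoffs)
        return chi_i, chi_t

    @property
    def total_money(self) -> float:
        return sum(self.total_gains)


def _investor_likelihood_of_response(history, t, i, j, spec, ctx):
    """P[observed trustee action | each trustee guilt type] under the
    investor's intentional model of the trustee."""
    if i == 0:
        return np.ones(len(GUILT_TYPES))
    if spec.effective_k >= 2 and spec.effective_P > 0:
        return np.array([
            ctx.nested_trustee_policy(tuple(history), t, i, g, spec.P)[j]
            for g in range(len(GUILT_TYPES))
        ])
    return TRUSTEE_RESPONSE[:, i, j].copy()


def _trustee_likelihood_of_investment(history, t, i, spec, ctx):
    """P[observed investment | each investor guilt type] under the
    trustee's intentional model of the investor."""
    if spec.effective_k >= 1:
        return np.array(ctx.investor_likelihood(tuple(history), t, i, spec.P))
    static = [level_minus1_policy("investor", a)[i] for a in GUILT_TYPES]
    return np.array(static)


def play_game(
    investor: AgentSpec,
    trustee: AgentSpec,
    config: SearchConfig,
    seed: int,
    ctx: PlannerContext | None = None,
) -> GameRecord:
    """Simulate one full game; bit-reproducible for a fixed seed."""
    if ctx is None:
        ctx = PlannerContext(config)
    record = GameRecord(investor, trustee, seed)
    history: list[tuple[int, int]] = []
    belief_i = init_belief()  # investor's belief over trustee guilt
    belief_t = init_belief()  # trustee's belief over investor guilt
    for t in range(1, GAME_LENGTH + 1):
        n_t = simulation_schedule(config.n_paths, t)
        res_i = search(
            history, t, investor, ctx, stable_seed(seed, "I", t),
            n_paths=n_t, belief=belief_i,
        )
        i = res_i.action
        belief_t = update_belief(
            belief_t, _trustee_likelihood_of_investment(history, t, i, trustee, ctx)
        )
        res_t = search(
            history, t, trustee, ctx, stable_seed(seed, "T", t),
            pending_investment=i, n_paths=n_t, belief=belief_t,
        )
        j = res_t.action
        belief_i = update_belief(
            belief_i, _investor_likelihood_of_response(history, t, i, j, investor, ctx)
        )
        history.append((i, j))
        record.exchanges.append((i, j))
        record.payoffs.append(monetary_payoffs(i, j))
        record.investor_posteriors.append(tuple(predictive_probs(belief_i)))
        record.trustee_posteriors.append(tuple(predictive_probs(belief_t)))
    return record


def batch_simulate(
    pairings,
    reps: int,
    config: SearchConfig,
    seed: int,
    ctx: PlannerContext | None = None,
) -> list[GameRecord]:
    """``reps`` independently seeded games for every (investor, trustee)
    pairing; planner caches are shared across the batch for speed."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if ctx is None:
        ctx = PlannerContext(config)
    records = []
    for p_idx, (inv, tru) in enumerate(pairings):
        for rep in range(reps):
            game_seed = stable_seed(seed, "game", p_idx, rep)
            records.append(play_game(inv, tru, config, game_seed, ctx))
    return records


# ---------------------------------------------------------------------
# batch summaries


def average_trajectories(records) -> pd.DataFrame:
    """Mean and standard deviation, per round, of the fraction of
    available points offered (investor) and returned (trustee).

    The trustee's available points are the trebled investment;
    degenerate rounds (zero investment) are excluded from the return
    average, since nothing was available.
    """
    rows = []
    for t in range(GAME_LENGTH):
        inv = [float(INVESTOR_FRACTIONS[r.exchanges[t][0]]) for r in records]
        ret = [
            float(TRUSTEE_FRACTIONS[r.exchanges[t][1]])
            for r in records
            if r.exchanges[t][0] > 0
        ]
        rows.append({
            "round": t + 1,
            "invest_frac_mean": np.mean(inv),
            "invest_frac_std": np.std(inv),
            "return_frac_mean": np.mean(ret) if ret else np.nan,
            "return_frac_std": np.std(ret) if ret else np.nan,
            "n_nondegenerate": len(ret),
        })
    return pd.DataFrame(rows)


def mean_posteriors(records, rounds=(0, 3, 6, 9)) -> pd.DataFrame:
    """Mean posterior over partner guilt for both roles at a few stages
    of the game (round 0 is the uniform prior)."""
    rows = []
    for t in rounds:
        for role, attr in (("investor", "investor_posteriors"),
                           ("trustee", "trustee_posteriors")):
            if t == 0:
                post = np.full((len(records), 3), 1.0 / 3.0)
            else:
                post = np.array([getattr(r, attr)[t - 1] for r in records])
            mean = post.mean(axis=0)
            rows.append({
                "round": t, "role": role,
                "p_guilt_0": mean[0], "p_guilt_0.4": mean[1], "p_guilt_1": mean[2],
            })
    return pd.DataFrame(rows)


def fair_return_fraction(i: int) -> float:
    """Return fraction (of the trebled amount) that equalizes payoffs
    for investment category ``i`` — the 'fair split' reference."""
    a_i = float(INVESTOR_FRACTIONS[i])
    if a_i == 0:
        return 0.0
    return max(0.0, (40 * a_i - 10) / (60 * a_i))


def coaxing_rate(records, rounds=(1, 2, 3)) -> float:
    """Fraction of early non-degenerate rounds in which the trustee
    returned strictly more than the fair split (coaxing)."""
    hits = 0
    total = 0
    for r in records:
        for t in rounds:
            i, j = r.exchanges[t - 1]
            if i == 0:
                continue
            total += 1
            if float(TRUSTEE_FRACTIONS[j]) > fair_return_fraction(i) + 1e-12:
                hits += 1
    return hits / total if total else float("nan")


def discrepancy_matrix(prob_vectors, reference) -> np.ndarray:
    """Between-run discrepancy of first-action probabilities.

    C_ij = 1/(K-1) sum_k |p_k(i) - ref(i)| |p_k(j) - ref(j)| over K
    repeated runs; a small sum of squared entries means the action
    probabilities are close to their converged values.
    """
    p = np.asarray(prob_vectors, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need at least 2 repeated probability vectors")
    dev = np.abs(p - ref[None, :])
    return dev.T @ dev / (p.shape[0] - 1)
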