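"""Maximum-likelihood inversion of observed games and parameter recovery.

Fitting scans the de-duplicated (k, alpha, P) grid — 15 investor cells,
9 trustee cells — and accumulates, for each cell, the negative log
likelihood of the observed actions under the policies that the planner
produces for that cell given the preceding history.  Degenerate trustee
rounds (zero investment) are forced actions and contribute zero.  The
reference point is the uniform-random policy, whose NLL over 10 rounds
of 5 actions is 10 ln 5 ~ 16.1 nats: fits should beat it for the
estimates to be trustworthy.

The confusion experiment closes the loop: simulate games from known
cells, re-fit them, and tabulate inferred-versus-true proportions of
guilt, theory-of-mind level and planning horizon per role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .agents import AgentSpec, investor_grid, trustee_grid
from .game import GAME_LENGTH, N_ACTIONS
from .planner import (
    PlannerContext,
    SearchConfig,
    search,
    simulation_schedule,
    stable_seed,
)
from .simulate import batch_simulate


def random_baseline_nll(n_rounds: int = GAME_LENGTH, n_actions: int = N_ACTIONS) -> float:
    """NLL of a uniform-random policy: n_rounds * ln(n_actions) nats
    (16.1 for a full game with no degenerate rounds)."""
    return n_rounds * math.log(n_actions)


def history_nll(
    history,
    spec: AgentSpec,
    config: SearchConfig,
    seed: int = 0,
    ctx: PlannerContext | None = None,
) -> tuple[float, list[float]]:
    """Negative log likelihood of one agent's observed actions.

    Returns the total NLL in nats and the per-round action log
    likelihood contributions (0 for degenerate trustee rounds).  Action
    probabilities are recomputed with the planner per round, seeded
    deterministically from ``seed`` so NLL tables are reproducible.
    """
    if ctx is None:
        ctx = PlannerContext(config)
    history = [tuple(p) for p in history]
    per_round = []
    nll = 0.0
    for t, (i, j) in enumerate(history, start=1):
        prefix = history[: t - 1]
        n_t = simulation_schedule(config.n_paths, t)
        if spec.role == "investor":
            res = search(prefix, t, spec, ctx, stable_seed(seed, "nll", t),
                         n_paths=n_t)
            p = float(res.probs[i])
            if p <= 0:
                raise ValueError(f"round {t}: observed action has zero probability")
            contrib = -math.log(p)
        else:
            if i == 0:
                contrib = 0.0
            else:
                res = search(prefix, t, spec, ctx, stable_seed(seed, "nll", t),
                             pending_investment=i, n_paths=n_t)
                p = float(res.probs[j])
                if p <= 0:
                    raise ValueError(f"round {t}: observed action has zero probability")
                contrib = -math.log(p)
        per_round.append(contrib)
        nll += contrib
    return nll, per_round


@dataclass
class FitResult:
    """Grid-search fit of one agent's behaviour in one game."""

    role: str
    best: AgentSpec | None
    nll_table: list[tuple[AgentSpec, float]]
    per_round: dict = field(default_factory=dict)
    n_informative_rounds: int = 0
    unidentifiable: bool = False

    @property
    def baseline(self) -> float:
        """Random-policy NLL over the informative rounds of this fit."""
        return random_baseline_nll(self.n_informative_rounds)

    def table_frame(self) -> pd.DataFrame:
        rows = [{"k": s.k, "alpha": s.alpha, "P": s.P, "nll": v}
                for s, v in self.nll_table]
        return pd.DataFrame(rows)


def _fit_role(history, cells, config, seed, ctx) -> FitResult:
    role = cells[0].role
    if role == "investor":
        informative = len(history)
    else:
        informative = sum(1 for i, _j in history if i > 0)
    table = []
    per_round = {}
    for cell in cells:
        cell_seed = stable_seed(seed, "cell", role, cell.k, cell.alpha, cell.P)
        nll, rounds = history_nll(history, cell, config, cell_seed, ctx)
        table.append((cell, nll))
        per_round[cell] = rounds
    unidentifiable = len(history) == 0 or informative == 0
    if unidentifiable:
        best = None
    else:
        # ties broken toward lower k, then lower P
        best = min(table, key=lambda cv: (cv[1], cv[0].k, cv[0].P, cv[0].guilt_idx))[0]
    return FitResult(role, best, table, per_round, informative, unidentifiable)


def fit_dyad(
    history,
    config: SearchConfig,
    investor_cells=None,
    trustee_cells=None,
    seed: int = 0,
    ctx: PlannerContext | None = None,
) -> tuple[FitResult, FitResult]:
    """Independent exhaustive grid fits of investor and trustee."""
    if ctx is None:
        ctx = PlannerContext(config)
    history = [tuple(p) for p in history]
    inv_cells = list(investor_cells) if investor_cells is not None else investor_grid()
    tru_cells = list(trustee_cells) if trustee_cells is not None else trustee_grid()
    return (
        _fit_role(history, inv_cells, config, seed, ctx),
        _fit_role(history, tru_cells, config, seed, ctx),
    )


@dataclass
class ConfusionResult:
    """Inferred-vs-true proportion matrices, one per role and factor."""

    matrices: dict
    n_games: int

    def matrix(self, role: str, factor: str) -> pd.DataFrame:
        return self.matrices[(role, factor)]


def _confusion_frame(pairs) -> pd.DataFrame:
    """Row-normalized inferred-vs-true proportions from (true, inferred)
    value pairs."""
    values = sorted({v for pair in pairs for v in pair})
    mat = pd.DataFrame(0.0, index=values, columns=values)
    for true, inferred in pairs:
        mat.loc[true, inferred] += 1.0
    sums = mat.sum(axis=1)
    mat = mat.div(sums.replace(0, np.nan), axis=0)
    mat.index.name = "true"
    mat.columns.name = "inferred"
    return mat


def confusion_experiment(
    investor_cells,
    trustee_cells,
    reps: int,
    config: SearchConfig,
    seed: int,
    ctx: PlannerContext | None = None,
) -> ConfusionResult:
    """Simulate the uniform crossing of the given cells, re-fit every
    game over the same grids, and tabulate recovery per role for guilt,
    ToM level and planning horizon (marginalizing the other factors)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if ctx is None:
        ctx = PlannerContext(config)
    pairings = [(inv, tru) for inv in investor_cells for tru in trustee_cells]
    records = batch_simulate(pairings, reps, config, seed, ctx)
    pairs = {("investor", f): [] for f in ("guilt", "tom", "planning")}
    pairs.update({("trustee", f): [] for f in ("guilt", "tom", "planning")})
    for g_idx, record in enumerate(records):
        fit_inv, fit_tru = fit_dyad(
            record.exchanges, config,
            investor_cells=investor_cells, trustee_cells=trustee_cells,
            seed=stable_seed(seed, "fit", g_idx), ctx=ctx,
        )
        for role, true_spec, fit in (
            ("investor", record.investor, fit_inv),
            ("trustee", record.trustee, fit_tru),
        ):
            if fit.best is None:
                continue
            pairs[(role, "guilt")].append((true_spec.alpha, fit.best.alpha))
            pairs[(role, "tom")].append((true_spec.k, fit.best.k))
            pairs[(role, "planning")].append((true_spec.P, fit.best.P))
    matrices = {key: _confusion_frame(val) for key, val in pairs.items() if val}
    return ConfusionResult(matrices, len(records))


def ks_two_sample(values_a, values_b):
    """Two-sample Kolmogorov-Smirnov test (statistic, p-value), used to
    compare fitted-parameter distributions between groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = scipy.stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
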