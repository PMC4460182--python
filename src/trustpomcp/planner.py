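"""Adapted POMCP tree search for the trust-game agent hierarchy.

Each decision of a level-1 trustee or level-2 investor is planned by a
Monte-Carlo tree search over future exchanges: the partner's guilt type
is sampled from the current Dirichlet belief at the root of every
simulation and held fixed along the path (root sampling), in-tree
actions follow SoftUCT (softmax over running-mean values plus a UCT
exploration bonus), leaves are evaluated by epsilon-greedy reactive
rollouts, and returns are backed up as running arithmetic means.
Before the search proper, agents with a partner model first explore the
constant strategies (always offering/returning a fixed fraction) so
every root action starts from a stable value estimate.

Partner responses inside simulations come from the intentional model
one level down: sampled level-0 investor actions are drawn from the
exact recombining-tree policy, and sampled level-1 trustee actions are
drawn from nested searches whose results are cached and seeded by a
stable hash of the public history, so that every quantity in the module
is bit-reproducible given a seed.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass
from math import exp, log, sqrt

import numpy as np

from . import level0
from .agents import AgentSpec, level_minus1_policy
from .beliefs import init_belief, predictive_probs, update_belief
from .game import (
    GAME_LENGTH,
    GUILT_TYPES,
    N_ACTIONS,
    UTIL_I,
    UTIL_T,
    horizon_rounds,
    trustee_action_space,
)
from .tables import DEFAULT_BETA, INVESTOR_EU_MINUS1, TRUSTEE_RESPONSE, pair_id


def simulation_schedule(n: int, round_index: int) -> int:
    """Per-round simulation budget (n, 9n/10, ..., n/10 for rounds 1..10).

    The budget is largest at the first round, where beliefs are still
    uniform and the planning horizon furthest away.
    """
    if not 1 <= round_index <= GAME_LENGTH:
        raise ValueError("round index must be in 1..10")
    return max(1, int(round(n * (GAME_LENGTH + 1 - round_index) / GAME_LENGTH)))


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the tree search.

    ``n_paths`` is the first-round simulation budget (later rounds are
    scaled down by :func:`simulation_schedule`); ``c`` the SoftUCT
    exploration constant; ``epsilon_rollout`` the exploration rate of
    the reactive rollout policy; ``nested_n_paths`` the budget of the
    nested partner searches inside a level-2 search.  Pre-search runs
    ``presearch_per_action`` simulations of each constant strategy.
    ``seed_salt`` enters the stable per-key seeds of nested searches.
    """

    n_paths: int = 25_000
    c: float = 25.0
    beta: float = DEFAULT_BETA
    epsilon_rollout: float = 0.1
    presearch_per_action: int | None = None
    nested_n_paths: int | None = None
    seed_salt: int = 0

    def __post_init__(self):
        if self.n_paths <= 0:
            raise ValueError("n_paths must be positive")

    @property
    def presearch(self) -> int:
        if self.presearch_per_action is not None:
            return self.presearch_per_action
        return max(1, self.n_paths // 50)

    @property
    def nested_paths(self) -> int:
        if self.nested_n_paths is not None:
            return self.nested_n_paths
        return max(50, self.n_paths // 20)

    @property
    def nested_presearch(self) -> int:
        return max(1, self.nested_paths // 50)


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary hashable parts."""
    digest = hashlib.blake2b(repr(parts).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


class TreeNode:
    """Visit counts and running-mean action values of one history node."""

    __slots__ = ("n", "counts", "q")

    def __init__(self, n_actions: int):
        self.n = 0
        self.counts = [0] * n_actions
        self.q = [0.0] * n_actions


def soft_uct_select(node: TreeNode, beta: float, c: float, rng: random.Random) -> int:
    """SoftUCT: unvisited actions first (in index order), then a sample
    from softmax over Q + c * sqrt(log N(h) / N(h, a))."""
    for idx, cnt in enumerate(node.counts):
        if cnt == 0:
            return idx
    log_n = log(node.n)
    scores = [
        node.q[idx] + c * sqrt(log_n / node.counts[idx])
        for idx in range(len(node.counts))
    ]
    return _sample_softmax(scores, beta, rng)


def backup(node: TreeNode, action_idx: int, value: float) -> None:
    """Incremental running-mean update of Q(h, a) with return ``value``."""
    node.n += 1
    node.counts[action_idx] += 1
    node.q[action_idx] += (value - node.q[action_idx]) / node.counts[action_idx]


def _sample_softmax(scores, beta: float, rng: random.Random) -> int:
    m = max(scores)
    weights = [exp(beta * (s - m)) for s in scores]
    total = sum(weights)
    u = rng.random() * total
    acc = 0.0
    for idx, w in enumerate(weights):
        acc += w
        if u <= acc:
            return idx
    return len(weights) - 1


def _sample_probs(probs, rng: random.Random) -> int:
    u = rng.random()
    acc = 0.0
    for idx, p in enumerate(probs):
        acc += p
        if u <= acc:
            return idx
    return len(probs) - 1


def _eps_greedy(values, eps: float, rng: random.Random) -> int:
    if rng.random() < eps:
        return rng.randrange(len(values))
    m = max(values)
    best = [idx for idx, v in enumerate(values) if v == m]
    return best[0] if len(best) == 1 else rng.choice(best)


def _softmax_list(values, beta: float):
    m = max(values)
    w = [exp(beta * (v - m)) for v in values]
    s = sum(w)
    return [x / s for x in w]


@dataclass
class SearchResult:
    """Root action distribution, sampled action and diagnostics."""

    probs: np.ndarray
    action: int
    q: np.ndarray
    counts: np.ndarray
    n_paths: int

    def to_dict(self) -> dict:
        return {
            "probs": [float(p) for p in self.probs],
            "action": int(self.action),
            "q": [float(v) for v in self.q],
            "counts": [int(c) for c in self.counts],
            "n_paths": int(self.n_paths),
        }


class PlannerContext:
    """Shared caches for one batch of related planning problems.

    Holds the nested level-1 policy cache and the trustee-belief prefix
    cache.  Results are independent of cache state (nested searches are
    seeded from their keys), so sharing a context across games changes
    nothing but speed.
    """

    _MAX_ENTRIES = 2_000_000

    def __init__(self, config: SearchConfig):
        self.config = config
        self._nested: dict = {}
        self._tbelief: dict = {}

    # -- trustee-side beliefs about investor guilt ---------------------

    def investor_likelihood(self, history: tuple, t: int, investment: int, P: int):
        """P[observed investment | each investor guilt type] under the
        level-0 intentional investor model at horizon ``P``."""
        pids = tuple(pair_id(i, j) for i, j in history)
        return tuple(
            level0.investor_policy(pids, t, P, g)[investment]
            for g in range(len(GUILT_TYPES))
        )

    def trustee_belief(self, history: tuple, P: int) -> np.ndarray:
        """Level-1 trustee's Dirichlet belief over investor guilt after
        all completed exchanges in ``history``."""
        key = (history, P)
        cached = self._tbelief.get(key)
        if cached is not None:
            return cached.copy()
        if not history:
            b = init_belief()
        else:
            prev = self.trustee_belief(history[:-1], P)
            i, _j = history[-1]
            lik = self.investor_likelihood(history[:-1], len(history), i, P)
            b = update_belief(prev, lik)
        if len(self._tbelief) < self._MAX_ENTRIES:
            self._tbelief[key] = b.copy()
        return b

    # -- nested level-1 trustee policies -------------------------------

    def nested_trustee_policy(
        self, history: tuple, t: int, investment: int, guilt_idx: int, P: int
    ):
        """Action distribution of a level-1 trustee with guilt
        ``guilt_idx`` facing ``investment`` at round ``t`` after
        ``history`` — the generative partner model inside a level-2
        search, cached and deterministically seeded by its key."""
        if investment == 0:
            return _FORCED_PROBS
        if horizon_rounds(t, P) == 1 or P == 0:
            return tuple(TRUSTEE_RESPONSE[guilt_idx, investment, :])
        key = (history, investment, guilt_idx, P)
        cached = self._nested.get(key)
        if cached is not None:
            return cached
        belief = update_belief(
            self.trustee_belief(history, P),
            self.investor_likelihood(history, t, investment, P),
        )
        spec = AgentSpec("trustee", 1, GUILT_TYPES[guilt_idx], P)
        rng = random.Random(stable_seed("nested", key, self.config.seed_salt))
        result = _run_trustee_search(
            history, t, investment, spec, self, rng,
            self.config.nested_paths, belief, nested=True,
        )
        probs = tuple(result.probs)
        if len(self._nested) < self._MAX_ENTRIES:
            self._nested[key] = probs
        return probs


_FORCED_PROBS = (1.0, 0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------
# beliefs implied by a history for the searching agent itself


def belief_from_history(history, spec: AgentSpec, ctx: PlannerContext) -> np.ndarray:
    """Dirichlet belief over the partner's guilt implied by ``history``
    for an agent described by ``spec`` (soft-count updates with the
    action likelihoods of the partner's intentional model)."""
    history = tuple(tuple(p) for p in history)
    k = spec.effective_k
    if spec.role == "investor":
        if k == 0 or spec.effective_P == 0:
            b = init_belief()
            for i, j in history:
                if i == 0:
                    b = update_belief(b, np.ones(3))
                else:
                    b = update_belief(b, TRUSTEE_RESPONSE[:, i, j])
            return b
        if k == 2:
            b = init_belief()
            for t, (i, j) in enumerate(history, start=1):
                if i == 0:
                    lik = np.ones(3)
                else:
                    lik = np.array([
                        ctx.nested_trustee_policy(history[: t - 1], t, i, g, spec.P)[j]
                        for g in range(len(GUILT_TYPES))
                    ])
                b = update_belief(b, lik)
            return b
        raise NotImplementedError("investor levels above 2 are out of scope")
    # trustee
    if k == 0:
        b = init_belief()
        static = [level_minus1_policy("investor", a) for a in GUILT_TYPES]
        for i, _j in history:
            b = update_belief(b, np.array([p[i] for p in static]))
        return b
    if k == 1:
        return ctx.trustee_belief(history, spec.P)
    raise NotImplementedError("trustee levels above 1 are out of scope")


# ---------------------------------------------------------------------
# level-1 trustee search


def _run_trustee_search(
    history, t, investment, spec, ctx, rng, n_paths, belief, nested=False
) -> SearchResult:
    cfg = ctx.config
    g_own = spec.guilt_idx
    P = spec.P
    beta, c, eps = cfg.beta, cfg.c, cfg.epsilon_rollout
    pids0 = tuple(pair_id(i, j) for i, j in history)
    d0 = horizon_rounds(t, P)
    actions0 = trustee_action_space(investment)
    pred = list(predictive_probs(belief))
    tree: dict = {(): TreeNode(len(actions0))}
    root = tree[()]

    def invest_next(pids, tau, g_inv):
        probs = level0.investor_policy(tuple(pids), tau, P, g_inv)
        return _sample_probs(probs, rng)

    def rollout(i, tau, d, g_inv, pids):
        total = 0.0
        while True:
            actions = trustee_action_space(i)
            if len(actions) == 1:
                j = actions[0]
            else:
                j = _eps_greedy(list(UTIL_T[g_own, i, :]), eps, rng)
            total += UTIL_T[g_own, i, j]
            d -= 1
            if d == 0:
                return total
            pids.append(pair_id(i, j))
            tau += 1
            i = invest_next(pids, tau, g_inv)

    def simulate(key, i, tau, d, g_inv, pids):
        if d == 0:
            return 0.0
        node = tree.get(key)
        if node is None:
            tree[key] = TreeNode(len(trustee_action_space(i)))
            return rollout(i, tau, d, g_inv, pids)
        actions = trustee_action_space(i)
        a_idx = 0 if len(actions) == 1 else soft_uct_select(node, beta, c, rng)
        j = actions[a_idx]
        value = UTIL_T[g_own, i, j]
        if d > 1:
            pids.append(pair_id(i, j))
            i2 = invest_next(pids, tau + 1, g_inv)
            value += simulate(key + (j, i2), i2, tau + 1, d - 1, g_inv, pids)
        backup(node, a_idx, value)
        return value

    # pre-search: constant strategies seed the root action values
    n_pre = cfg.nested_presearch if nested else cfg.presearch
    if len(actions0) > 1:
        for a_idx, j0 in enumerate(actions0):
            for _ in range(n_pre):
                g_inv = _sample_probs(pred, rng)
                pids = list(pids0)
                i, tau, d = investment, t, d0
                total = 0.0
                while True:
                    j = j0 if j0 in trustee_action_space(i) else 0
                    total += UTIL_T[g_own, i, j]
                    d -= 1
                    if d == 0:
                        break
                    pids.append(pair_id(i, j))
                    tau += 1
                    i = invest_next(pids, tau, g_inv)
                backup(root, a_idx, total)

    for _ in range(n_paths):
        g_inv = _sample_probs(pred, rng)
        simulate((), investment, t, d0, g_inv, list(pids0))

    return _finish(root, actions0, beta, rng, n_paths)


# ---------------------------------------------------------------------
# level-2 investor search


def _run_investor_search(
    history, t, spec, ctx, rng, n_paths, belief
) -> SearchResult:
    cfg = ctx.config
    g_own = spec.guilt_idx
    P = spec.P
    beta, c, eps = cfg.beta, cfg.c, cfg.epsilon_rollout
    d0 = horizon_rounds(t, P)
    pred = list(predictive_probs(belief))
    hist0 = tuple(tuple(p) for p in history)
    tree: dict = {(): TreeNode(N_ACTIONS)}
    root = tree[()]

    def trustee_response(hist, tau, i, g_tr):
        if i == 0:
            return 0
        probs = ctx.nested_trustee_policy(hist, tau, i, g_tr, P)
        return _sample_probs(probs, rng)

    def rollout(tau, d, g_tr):
        # crude leaf estimate: own actions eps-greedy on reactive
        # expected utilities, partner reduced to its reactive core
        total = 0.0
        eu = list(INVESTOR_EU_MINUS1[g_own])
        while d > 0:
            i = _eps_greedy(eu, eps, rng)
            if i == 0:
                j = 0
            else:
                j = _sample_probs(TRUSTEE_RESPONSE[g_tr, i, :], rng)
            total += UTIL_I[g_own, i, j]
            d -= 1
        return total

    def simulate(key, hist, tau, d, g_tr):
        if d == 0:
            return 0.0
        node = tree.get(key)
        if node is None:
            tree[key] = TreeNode(N_ACTIONS)
            return rollout(tau, d, g_tr)
        i = soft_uct_select(node, beta, c, rng)
        j = trustee_response(hist, tau, i, g_tr)
        value = UTIL_I[g_own, i, j]
        if d > 1:
            value += simulate(key + ((i, j),), hist + ((i, j),), tau + 1, d - 1, g_tr)
        backup(node, i, value)
        return value

    for i0 in range(N_ACTIONS):
        for _ in range(cfg.presearch):
            g_tr = _sample_probs(pred, rng)
            hist, tau, d, total = hist0, t, d0, 0.0
            while True:
                j = trustee_response(hist, tau, i0, g_tr)
                total += UTIL_I[g_own, i0, j]
                d -= 1
                if d == 0:
                    break
                hist = hist + ((i0, j),)
                tau += 1
            backup(root, i0, total)

    for _ in range(n_paths):
        g_tr = _sample_probs(pred, rng)
        simulate((), hist0, t, d0, g_tr)

    return _finish(root, tuple(range(N_ACTIONS)), beta, rng, n_paths)


def _finish(root, actions, beta, rng, n_paths) -> SearchResult:
    """Root action distribution: softmax over plain running-mean values
    (the exploration bonus is used only during tree descent)."""
    probs = np.zeros(N_ACTIONS)
    q = np.zeros(N_ACTIONS)
    counts = np.zeros(N_ACTIONS, dtype=int)
    local = _softmax_list(root.q, beta)
    for idx, a in enumerate(actions):
        probs[a] = local[idx]
        q[a] = root.q[idx]
        counts[a] = root.counts[idx]
    action = actions[_sample_probs(local, rng)]
    return SearchResult(probs, action, q, counts, n_paths)


# ---------------------------------------------------------------------
# public entry point


def search(
    history,
    t: int,
    spec: AgentSpec,
    ctx: PlannerContext | SearchConfig,
    seed: int,
    pending_investment: int | None = None,
    n_paths: int | None = None,
    belief: np.ndarray | None = None,
) -> SearchResult:
    """Plan one decision at round ``t`` given the completed ``history``.

    For a trustee decision ``pending_investment`` is the investment just
    observed.  Trivial levels (level-0 trustee, level-0 investor, any
    agent with an effective one-round horizon) are solved in closed form
    or by the exact DP; level-1 trustees and level-2 investors run the
    Monte-Carlo search.  Identical seeds and configurations give
    bit-identical results.
    """
    if not 1 <= t <= GAME_LENGTH:
        raise ValueError("decisions happen at rounds 1..10")
    if isinstance(ctx, SearchConfig):
        ctx = PlannerContext(ctx)
    history = tuple(tuple(p) for p in history)
    n = n_paths if n_paths is not None else ctx.config.n_paths
    if n <= 0:
        raise ValueError("at least one simulation is required")
    rng = random.Random(seed)
    beta = ctx.config.beta

    if spec.role == "trustee":
        if pending_investment is None:
            raise ValueError("trustee decisions require the observed investment")
        i = pending_investment
        if i == 0:
            return SearchResult(
                np.array(_FORCED_PROBS), 0, np.zeros(N_ACTIONS),
                np.zeros(N_ACTIONS, dtype=int), 0,
            )
        k = spec.effective_k
        if k == 0 or spec.effective_P == 0 or horizon_rounds(t, spec.P) == 1:
            q = UTIL_T[spec.guilt_idx, i, :].copy()
            probs = np.array(_softmax_list(list(q), beta))
            action = _sample_probs(probs, rng)
            return SearchResult(probs, action, q, np.zeros(N_ACTIONS, dtype=int), 0)
        if k == 1:
            if belief is None:
                belief = belief_from_history(history, spec, ctx)
            return _run_trustee_search(history, t, i, spec, ctx, rng, n, belief)
        raise NotImplementedError("trustee levels above 1 are out of scope")

    # investor
    k = spec.effective_k
    pids = tuple(pair_id(i, j) for i, j in history)
    if k == 0 or spec.P == 0:
        # exact recombining-tree values (a level-2 investor with P = 0
        # collapses onto level 0: its partner model is then reactive)
        q = np.array(level0.investor_q_values(pids, t, spec.P if k == 0 else 0, spec.guilt_idx))
        probs = np.array(_softmax_list(list(q), beta))
        action = _sample_probs(probs, rng)
        return SearchResult(probs, action, q, np.zeros(N_ACTIONS, dtype=int), 0)
    if k == 2:
        if belief is None:
            belief = belief_from_history(history, spec, ctx)
        if horizon_rounds(t, spec.P) == 1:
            # last round: the modelled level-1 trustee is reactive too,
            # so immediate expected utilities are available in closed form
            pred = predictive_probs(belief)
            q = np.zeros(N_ACTIONS)
            for a in range(N_ACTIONS):
                if a == 0:
                    q[a] = UTIL_I[spec.guilt_idx, 0, 0]
                else:
                    resp = pred @ TRUSTEE_RESPONSE[:, a, :]
                    q[a] = float(resp @ UTIL_I[spec.guilt_idx, a, :])
            probs = np.array(_softmax_list(list(q), beta))
            action = _sample_probs(probs, rng)
            return SearchResult(probs, action, q, np.zeros(N_ACTIONS, dtype=int), 0)
        return _run_investor_search(history, t, spec, ctx, rng, n, belief)
    raise NotImplementedError("investor levels above 2 are out of scope")
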