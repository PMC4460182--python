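"""Precomputed lookup tables shared by the agent hierarchy and planner.

Everything here is a pure function of the game rules and the fixed
inverse temperature beta = 1/3: reactive (level -1) trustee response
probabilities, the Dirichlet soft-count increment attached to each of
the 21 admissible exchanges, and level -1 investor expected utilities.
"""

from __future__ import annotations

import numpy as np

from .game import (
    DEGENERATE_ACTION,
    N_ACTIONS,
    N_GUILT,
    UTIL_I,
    UTIL_T,
    trustee_action_space,
)

#: inverse temperature of every softmax decision rule in the model
DEFAULT_BETA = 1.0 / 3.0

#: number of distinct admissible exchange outcomes (1 degenerate + 4*5)
N_PAIR_TYPES = 21


def softmax(values, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Softmax with inverse temperature ``beta`` over a 1-d array."""
    v = np.asarray(values, dtype=float)
    w = np.exp(beta * (v - v.max()))
    return w / w.sum()


def pair_id(i: int, j: int) -> int:
    """Canonical index 0..20 of the admissible exchange (i, j)."""
    if i == 0:
        return 0
    return 1 + (i - 1) * N_ACTIONS + j


def pair_from_id(pid: int) -> tuple[int, int]:
    if pid == 0:
        return 0, DEGENERATE_ACTION
    pid -= 1
    return pid // N_ACTIONS + 1, pid % N_ACTIONS


def _reactive_trustee_table() -> np.ndarray:
    """P[a_T = j | a_I = i, guilt g] for a trustee acting on immediate
    Fehr-Schmidt utilities (the level -1 / level 0 trustee policy)."""
    table = np.zeros((N_GUILT, N_ACTIONS, N_ACTIONS))
    for g in range(N_GUILT):
        for i in range(N_ACTIONS):
            actions = trustee_action_space(i)
            if len(actions) == 1:
                table[g, i, actions[0]] = 1.0
            else:
                table[g, i, list(actions)] = softmax(UTIL_T[g, i, list(actions)])
    return table


#: reactive trustee response probabilities, indexed [guilt_idx, i, j]
TRUSTEE_RESPONSE = _reactive_trustee_table()


def _increment_table() -> np.ndarray:
    """Soft-count belief increment for each exchange outcome.

    Observing trustee action j after investment i adds, to the investor's
    pseudo-count of each trustee guilt type, the probability of j under
    the reactive model of that type.  The degenerate exchange (i = 0) is
    a forced action with likelihood 1 under every type: it adds uniform
    mass and carries no information about the type.
    """
    inc = np.zeros((N_PAIR_TYPES, N_GUILT))
    inc[0] = 1.0
    for i in range(1, N_ACTIONS):
        for j in range(N_ACTIONS):
            inc[pair_id(i, j)] = TRUSTEE_RESPONSE[:, i, j]
    return inc


#: Dirichlet increment vectors, indexed [pair_id, guilt_idx]
PAIR_INCREMENTS = _increment_table()


def _level_minus1_investor_eu() -> np.ndarray:
    """Level -1 investor expected utilities, indexed [own guilt, i].

    The level -1 investor treats all partner guilt types as equally
    likely, plans zero steps ahead and marginalizes the reactive trustee
    responses of each type.
    """
    eu = np.zeros((N_GUILT, N_ACTIONS))
    for g_own in range(N_GUILT):
        for i in range(N_ACTIONS):
            resp = TRUSTEE_RESPONSE[:, i, :].mean(axis=0)
            eu[g_own, i] = float(resp @ UTIL_I[g_own, i, :])
    return eu


#: level -1 investor expected utilities, indexed [own guilt_idx, i]
INVESTOR_EU_MINUS1 = _level_minus1_investor_eu()
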