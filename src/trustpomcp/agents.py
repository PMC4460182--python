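"""The cognitive hierarchy of trust-game agents.

An agent is identified by its role, theory-of-mind level ``k``, guilt
``alpha`` and planning horizon ``P`` (inverse temperature is fixed at
beta = 1/3 throughout).  A level-k agent models its partner as the same
kind of agent at level k-1 with the *same* planning horizon; the
recursion bottoms out at the reactive level -1 model, which holds no
partner model and acts on immediate expected utilities under a uniform
guess about the partner's guilt.

Because the trustee moves second and cannot influence the investor's
physical state, a level-0 trustee gains nothing from planning and odd
investor levels (even trustee levels) collapse onto the level below;
the estimation grid therefore uses investor k in {0, 2} and trustee k
in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import level0
from .game import (
    GAME_LENGTH,
    GUILT_TYPES,
    N_ACTIONS,
    UTIL_T,
    trustee_action_space,
)
from .tables import DEFAULT_BETA, INVESTOR_EU_MINUS1, TRUSTEE_RESPONSE, softmax

ROLES = ("investor", "trustee")


def effective_level(role: str, k: int) -> int:
    """Canonical behavioural level (Theorem: odd investor levels and
    positive even trustee levels behave like the level below)."""
    if k < 0:
        raise ValueError("effective_level is defined for k >= 0")
    if role == "investor":
        return k - 1 if k % 2 == 1 else k
    if role == "trustee":
        return k - 1 if (k > 0 and k % 2 == 0) else k
    raise ValueError(f"unknown role {role!r}")


@dataclass(frozen=True)
class AgentSpec:
    """Role plus the (k, alpha, P) triplet identifying an agent."""

    role: str
    k: int
    alpha: float
    P: int
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.alpha not in GUILT_TYPES:
            raise ValueError(f"guilt must be on the grid {GUILT_TYPES}")
        if not 0 <= self.P <= GAME_LENGTH - 1:
            raise ValueError("planning horizon must be in 0..9")
        if self.k < 0:
            raise ValueError("ToM level must be >= 0 (level -1 is internal)")

    @property
    def guilt_idx(self) -> int:
        return GUILT_TYPES.index(self.alpha)

    @property
    def effective_k(self) -> int:
        return effective_level(self.role, self.k)

    @property
    def effective_P(self) -> int:
        """A level-0 trustee cannot benefit from planning: P acts as 0."""
        if self.role == "trustee" and self.effective_k == 0:
            return 0
        return self.P

    def partner_spec(self, alpha: float) -> "AgentSpec":
        """Intentional model of a partner with guilt ``alpha``: one ToM
        level down, same planning horizon and temperature."""
        if self.effective_k == 0:
            raise ValueError("level-0 agents model partners at level -1")
        other = "trustee" if self.role == "investor" else "investor"
        return AgentSpec(other, self.effective_k - 1, alpha, self.P, self.beta)

    def label(self) -> str:
        prefix = "I" if self.role == "investor" else "T"
        return f"{prefix}:({self.k},{self.alpha:g},{self.P})"


def nesting_depth(spec: AgentSpec) -> int:
    """Number of mentalization steps until the level -1 base model."""
    depth = 0
    current = spec
    while current.effective_k > 0:
        current = current.partner_spec(GUILT_TYPES[0])
        depth += 1
    return depth + 1  # the level-0 agent still holds level -1 models


def level_minus1_expected_utilities(
    role: str, alpha: float, investment: int | None = None
) -> np.ndarray:
    """Immediate expected utilities of the reactive level -1 model.

    For the trustee this is its own Fehr-Schmidt utility row for the
    observed investment; for the investor it marginalizes reactive
    trustee responses under uniform partner-type probabilities.
    """
    g = GUILT_TYPES.index(alpha)
    if role == "investor":
        return INVESTOR_EU_MINUS1[g].copy()
    if investment is None:
        raise ValueError("trustee utilities require the observed investment")
    return UTIL_T[g, investment, :].copy()


def level_minus1_policy(
    role: str,
    alpha: float,
    investment: int | None = None,
    beta: float = DEFAULT_BETA,
) -> np.ndarray:
    """Softmax policy of the reactive level -1 model (5-vector;
    inadmissible trustee actions carry probability 0)."""
    if role == "trustee":
        if investment is None:
            raise ValueError("trustee policy requires the observed investment")
        actions = trustee_action_space(investment)
        probs = np.zeros(N_ACTIONS)
        if len(actions) == 1:
            probs[actions[0]] = 1.0
        else:
            eu = UTIL_T[GUILT_TYPES.index(alpha), investment, list(actions)]
            probs[list(actions)] = softmax(eu, beta)
        return probs
    eu = level_minus1_expected_utilities("investor", alpha)
    return softmax(eu, beta)


def level0_trustee_policy(
    investment: int, alpha: float, P: int = 0, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Policy of the level-0 trustee: softmax over immediate expected
    utilities, numerically identical for any nominal planning horizon
    (planning is trivial for the second mover)."""
    del P  # planning cannot change the level-0 trustee's choices
    return level_minus1_policy("trustee", alpha, investment, beta)


def level0_investor_values(pids, t: int, P: int, alpha: float) -> np.ndarray:
    """Bellman action values of the level-0 investor (exact recombining
    DP); ``pids`` is the multiset of past exchange pair-ids."""
    g = GUILT_TYPES.index(alpha)
    return np.array(level0.investor_q_values(tuple(pids), t, P, g))


def level0_investor_policy(pids, t: int, P: int, alpha: float) -> np.ndarray:
    g = GUILT_TYPES.index(alpha)
    return np.array(level0.investor_policy(tuple(pids), t, P, g))


def investor_grid() -> list[AgentSpec]:
    """The 15 behaviourally distinct investor (k, alpha, P) cells.

    k = 2 with P = 0 duplicates k = 0 with P = 0 (a non-planning
    level-2 investor's partner model is reactive) and is omitted.
    """
    cells = []
    for k in (0, 2):
        for alpha in GUILT_TYPES:
            for P in (0, 2, 7):
                if k == 2 and P == 0:
                    continue
                cells.append(AgentSpec("investor", k, alpha, P))
    return cells


def trustee_grid() -> list[AgentSpec]:
    """The 9 behaviourally distinct trustee cells (level-0 trustees are
    forced to P = 0; a level-1 trustee with P = 0 duplicates level 0)."""
    cells = []
    for alpha in GUILT_TYPES:
        cells.append(AgentSpec("trustee", 0, alpha, 0))
    for alpha in GUILT_TYPES:
        for P in (2, 7):
            cells.append(AgentSpec("trustee", 1, alpha, P))
    return cells


def reactive_trustee_likelihood(investment: int, response: int) -> np.ndarray:
    """P[observed trustee action | each guilt type] under the reactive
    model — the belief increment used by level-0 investors."""
    if investment == 0:
        return np.ones(len(GUILT_TYPES))
    return TRUSTEE_RESPONSE[:, investment, response].copy()
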