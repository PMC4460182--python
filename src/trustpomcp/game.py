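"""Physical rules of the multi-round trust game.

One round: the investor receives an endowment of 20 monetary units and
invests a fraction of it; the experimenter trebles the investment; the
trustee returns a fraction of the trebled amount.  Both actions are
quantized onto 5-point grids.  Agents evaluate monetary outcomes through
Fehr-Schmidt inequality-aversion ("guilt") utilities, and a survival
function truncates planning at a horizon ``P`` and at the end of the
10-round game.

Actions are handled as category indices 0-4 throughout the package; the
corresponding fractions are available in :data:`INVESTOR_FRACTIONS` and
:data:`TRUSTEE_FRACTIONS`.  All monetary payoffs are exact multiples of
2.5 units and therefore bit-exact in floating point.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

ENDOWMENT = 20
MULTIPLIER = 3
GAME_LENGTH = 10
N_ACTIONS = 5

#: investor invests ENDOWMENT * fraction
INVESTOR_FRACTIONS = (Fraction(0), Fraction(1, 4), Fraction(1, 2), Fraction(3, 4), Fraction(1))
#: trustee returns (MULTIPLIER * investment) * fraction
TRUSTEE_FRACTIONS = (Fraction(0), Fraction(1, 6), Fraction(1, 3), Fraction(1, 2), Fraction(2, 3))

#: Fehr-Schmidt guilt grid; constant within a game
GUILT_TYPES = (0.0, 0.4, 1.0)
N_GUILT = 3

#: planning-horizon grid (steps ahead beyond the current round)
HORIZONS = (0, 2, 7)

#: the single admissible trustee category when the investment is zero
DEGENERATE_ACTION = 0


def investor_amount(i: int) -> float:
    """Monetary units invested for investor category ``i``."""
    return float(ENDOWMENT * INVESTOR_FRACTIONS[i])


def _return_amount(i: int, j: int) -> Fraction:
    trebled = MULTIPLIER * ENDOWMENT * INVESTOR_FRACTIONS[i]
    return trebled * TRUSTEE_FRACTIONS[j]


def is_admissible(i: int, j: int) -> bool:
    """Whether trustee category ``j`` is admissible after investment ``i``."""
    if not (0 <= i < N_ACTIONS and 0 <= j < N_ACTIONS):
        return False
    return i != 0 or j == DEGENERATE_ACTION


def trustee_action_space(i: int) -> tuple[int, ...]:
    """Admissible trustee categories given investor category ``i``.

    The trustee's choice is degenerate (forced return of 0) when the
    investor sends nothing.
    """
    if i == 0:
        return (DEGENERATE_ACTION,)
    return tuple(range(N_ACTIONS))


def monetary_payoffs(i: int, j: int) -> tuple[float, float]:
    """Monetary payoffs (investor, trustee) for one exchange.

    chi_I = 20 - 20 a_I + 60 a_I a_T and chi_T = 60 a_I - 60 a_I a_T,
    with a_I, a_T the fractional actions of categories ``i`` and ``j``.
    """
    if not is_admissible(i, j):
        raise ValueError(f"inadmissible action pair (investor={i}, trustee={j})")
    invested = ENDOWMENT * INVESTOR_FRACTIONS[i]
    trebled = MULTIPLIER * invested
    returned = _return_amount(i, j)
    chi_i = ENDOWMENT - invested + returned
    chi_t = trebled - returned
    return float(chi_i), float(chi_t)


def fehr_schmidt_utility(role: str, i: int, j: int, alpha: float) -> float:
    """Inequality-aversion utility of one exchange for ``role``.

    r = chi_self - alpha * max(chi_self - chi_other, 0); the guilt
    parameter ``alpha`` penalizes advantageous inequity only, and must
    lie on the model's 3-point grid.
    """
    if alpha not in GUILT_TYPES:
        raise ValueError(f"guilt must be one of {GUILT_TYPES}, got {alpha}")
    chi_i, chi_t = monetary_payoffs(i, j)
    if role == "investor":
        return chi_i - alpha * max(chi_i - chi_t, 0.0)
    if role == "trustee":
        return chi_t - alpha * max(chi_t - chi_i, 0.0)
    raise ValueError(f"role must be 'investor' or 'trustee', got {role!r}")


def survival(tau: int, t: int, P: int) -> int:
    """Planning-horizon survival indicator H_P(tau, t).

    1 iff round ``tau`` lies within ``P`` steps of the reference round
    ``t`` and does not address a round past the end of the game.
    """
    if tau < t:
        raise ValueError("survival is defined for tau >= t")
    return int(tau - t <= P and tau <= GAME_LENGTH)


def horizon_rounds(t: int, P: int) -> int:
    """Number of rounds covered by planning at round ``t`` (incl. ``t``)."""
    return min(P, GAME_LENGTH - t) + 1


def admissible_pairs() -> list[tuple[int, int]]:
    """All 21 admissible (investor, trustee) category pairs."""
    return [(i, j) for i in range(N_ACTIONS) for j in trustee_action_space(i)]


def _payoff_tables() -> tuple[np.ndarray, np.ndarray]:
    chi_i = np.zeros((N_ACTIONS, N_ACTIONS))
    chi_t = np.zeros((N_ACTIONS, N_ACTIONS))
    for i in range(N_ACTIONS):
        for j in trustee_action_space(i):
            chi_i[i, j], chi_t[i, j] = monetary_payoffs(i, j)
    # inadmissible cells duplicate the forced action so tables are total
    chi_i[0, :] = chi_i[0, DEGENERATE_ACTION]
    chi_t[0, :] = chi_t[0, DEGENERATE_ACTION]
    return chi_i, chi_t


#: monetary payoff lookup tables, indexed [i, j]
PAYOFF_I, PAYOFF_T = _payoff_tables()


def _utility_tables() -> tuple[np.ndarray, np.ndarray]:
    u_i = np.zeros((N_GUILT, N_ACTIONS, N_ACTIONS))
    u_t = np.zeros((N_GUILT, N_ACTIONS, N_ACTIONS))
    for g, alpha in enumerate(GUILT_TYPES):
        for i in range(N_ACTIONS):
            for j in trustee_action_space(i):
                u_i[g, i, j] = fehr_schmidt_utility("investor", i, j, alpha)
                u_t[g, i, j] = fehr_schmidt_utility("trustee", i, j, alpha)
        u_i[g, 0, :] = u_i[g, 0, DEGENERATE_ACTION]
        u_t[g, 0, :] = u_t[g, 0, DEGENERATE_ACTION]
    return u_i, u_t


#: Fehr-Schmidt utility lookup tables, indexed [guilt_idx, i, j]
UTIL_I, UTIL_T = _utility_tables()
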