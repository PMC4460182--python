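"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's planner and DP machinery: they
recurse over *ordered* histories with plain Python floats, so agreement
with the recombining DP / Monte-Carlo search is a real cross-check.
Only the static game tables (payoff/utility grids and the reactive
trustee response table) are shared, since those are themselves verified
directly against hand-computed values.
"""

import math

from trustpomcp.game import GAME_LENGTH, UTIL_I, UTIL_T, trustee_action_space
from trustpomcp.tables import DEFAULT_BETA, TRUSTEE_RESPONSE


def softmax(values, beta=DEFAULT_BETA):
    m = max(values)
    w = [math.exp(beta * (v - m)) for v in values]
    s = sum(w)
    return [x / s for x in w]


def softmax_value(values, beta=DEFAULT_BETA):
    """Softmax-policy value: sum_a pi(a) Q(a)."""
    w = softmax(values, beta)
    return sum(wi * qi for wi, qi in zip(w, values))


def predictive(history):
    """Dirichlet predictive over trustee guilt from ordered exchanges."""
    b = [1.0, 1.0, 1.0]
    for i, j in history:
        for g in range(3):
            b[g] += 1.0 if i == 0 else TRUSTEE_RESPONSE[g, i, j]
    total = sum(b)
    return [x / total for x in b]


def level0_investor_q(history, t, P, guilt_idx):
    """Exhaustive (non-recombining) softmax-expectimax action values of
    the level-0 investor; exponential in the horizon, for tiny games."""
    depth = min(P, GAME_LENGTH - t) + 1

    def q_values(hist, d):
        p = predictive(hist)
        out = []
        for a in range(5):
            if a == 0:
                v = UTIL_I[guilt_idx, 0, 0]
                if d > 1:
                    v += value(hist + [(0, 0)], d - 1)
            else:
                v = 0.0
                for j in range(5):
                    pj = sum(p[g] * TRUSTEE_RESPONSE[g, a, j] for g in range(3))
                    term = UTIL_I[guilt_idx, a, j]
                    if d > 1:
                        term += value(hist + [(a, j)], d - 1)
                    v += pj * term
            out.append(v)
        return out

    def value(hist, d):
        return softmax_value(q_values(hist, d))

    return q_values(list(history), depth)


def level1_trustee_q_2round(investment, t, P, guilt_idx, belief):
    """Exact softmax-expectimax values for a level-1 trustee decision
    with exactly two rounds in its horizon (t = 9): immediate utility
    plus the expected round-10 value, marginalizing investor guilt over
    ``belief`` and round-10 investments over the level-0 policy."""
    assert min(P, GAME_LENGTH - t) + 1 == 2
    total_b = sum(belief)
    pred = [b / total_b for b in belief]
    qs = []
    for j in trustee_action_space(investment):
        total = 0.0
        for g_inv in range(3):
            v = UTIL_T[guilt_idx, investment, j]
            pi0 = softmax(level0_investor_q([(investment, j)], t + 1, P, g_inv))
            for i2 in range(5):
                acts = trustee_action_space(i2)
                row = [UTIL_T[guilt_idx, i2, jj] for jj in acts]
                v += pi0[i2] * softmax_value(row)
            total += pred[g_inv] * v
        qs.append(total)
    return qs
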