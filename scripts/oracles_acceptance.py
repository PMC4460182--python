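"""Brute-force softmax-expectimax reference values for acceptance runs.

Mirrors tests/oracles.py: plain recursion over ordered histories using
only the static game tables, independent of the package's recombining
DP and Monte-Carlo search.
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
    w = softmax(values, beta)
    return sum(wi * qi for wi, qi in zip(w, values))


def predictive(history):
    b = [1.0, 1.0, 1.0]
    for i, j in history:
        for g in range(3):
            b[g] += 1.0 if i == 0 else TRUSTEE_RESPONSE[g, i, j]
    total = sum(b)
    return [x / total for x in b]


def level0_investor_q(history, t, P, guilt_idx):
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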