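"""Exact level-0 investor planning on the recombining exchange tree.

A level-0 investor models the trustee as a reactive (level -1) agent of
unknown guilt type.  Its Dirichlet belief after any prefix of the game
depends only on the *multiset* of past exchanges, not their order, so
its Bellman action values can be computed by dynamic programming on a
recombining tree whose states are (exchange multiset, remaining depth).
This module implements that DP exactly, memoized across all queries in
the process, with a numba-compiled core so that horizon-7 agents are
tractable.

States are packed into a single int64 key: ten 5-bit slots holding the
sorted exchange pair-ids (31 marks an empty slot), 4 bits of remaining
depth and 2 bits of own guilt index.  Values are softmax-policy values
(Convention: V = sum_a pi(a) Q(a) with pi = softmax(beta * Q)).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.core import types
from numba.typed import Dict

from .game import GAME_LENGTH, N_ACTIONS, UTIL_I, horizon_rounds
from .tables import DEFAULT_BETA, N_PAIR_TYPES, PAIR_INCREMENTS, TRUSTEE_RESPONSE, softmax

_EMPTY = 31
_SLOT_MASK = (1 << 50) - 1

# module-level constants captured by the jitted core at compile time
_INC = np.ascontiguousarray(PAIR_INCREMENTS)
_UI = np.ascontiguousarray(UTIL_I)
_RESP = np.ascontiguousarray(TRUSTEE_RESPONSE)
_BETA = DEFAULT_BETA


@njit(cache=True)
def _insert_pid(slots: np.int64, pid: np.int64) -> np.int64:
    """Insert a pair id into the sorted 5-bit slot packing."""
    ids = np.empty(10, np.int64)
    n = 0
    s = slots
    for _ in range(10):
        v = s & 31
        s >>= 5
        if v == _EMPTY:
            break
        ids[n] = v
        n += 1
    # insertion keeping ascending order
    pos = n
    for m in range(n):
        if ids[m] > pid:
            pos = m
            break
    for m in range(n, pos, -1):
        ids[m] = ids[m - 1]
    ids[pos] = pid
    n += 1
    out = np.int64(0)
    shift = 0
    for m in range(10):
        v = ids[m] if m < n else _EMPTY
        out |= np.int64(v) << shift
        shift += 5
    return out


@njit(cache=True)
def _predictive(slots: np.int64):
    b0 = 1.0
    b1 = 1.0
    b2 = 1.0
    s = slots
    for _ in range(10):
        pid = s & 31
        s >>= 5
        if pid == _EMPTY:
            break
        b0 += _INC[pid, 0]
        b1 += _INC[pid, 1]
        b2 += _INC[pid, 2]
    tot = b0 + b1 + b2
    return b0 / tot, b1 / tot, b2 / tot


@njit(cache=True)
def _immediate_q(slots: np.int64, alpha: np.int64, q: np.ndarray) -> None:
    """One-round (depth-1) action values: expected immediate utilities
    under the belief implied by ``slots``."""
    p0, p1, p2 = _predictive(slots)
    for a in range(N_ACTIONS):
        if a == 0:
            q[a] = _UI[alpha, 0, 0]
        else:
            acc = 0.0
            for j in range(N_ACTIONS):
                pj = (
                    p0 * _RESP[0, a, j]
                    + p1 * _RESP[1, a, j]
                    + p2 * _RESP[2, a, j]
                )
                acc += pj * _UI[alpha, a, j]
            q[a] = acc


@njit(cache=True)
def _softmax_value(q: np.ndarray) -> float:
    qmax = q[0]
    for a in range(1, N_ACTIONS):
        if q[a] > qmax:
            qmax = q[a]
    wsum = 0.0
    vsum = 0.0
    for a in range(N_ACTIONS):
        w = np.exp(_BETA * (q[a] - qmax))
        wsum += w
        vsum += w * q[a]
    return vsum / wsum


@njit(cache=True)
def _leaf_value(slots: np.int64, alpha: np.int64) -> float:
    """Depth-1 state value, computed on the fly rather than memoized:
    the deepest layer holds ~70% of the reachable states and its value
    is a cheap closed form."""
    q = np.empty(N_ACTIONS)
    _immediate_q(slots, alpha, q)
    return _softmax_value(q)


@njit(cache=True)
def _q_from_children(key: np.int64, vmemo, q: np.ndarray) -> None:
    """Fill q[0..4] for a state whose deeper children are memoized
    (depth-2 children use the closed-form leaf value)."""
    d = (key >> 50) & 15
    alpha = (key >> 54) & 3
    slots = key & _SLOT_MASK
    if d == 1:
        _immediate_q(slots, alpha, q)
        return
    p0, p1, p2 = _predictive(slots)
    for a in range(N_ACTIONS):
        if a == 0:
            child_slots = _insert_pid(slots, 0)
            if d == 2:
                cont = _leaf_value(child_slots, alpha)
            else:
                cont = vmemo[child_slots | ((d - 1) << 50) | (alpha << 54)]
            q[a] = _UI[alpha, 0, 0] + cont
        else:
            acc = 0.0
            for j in range(N_ACTIONS):
                pj = (
                    p0 * _RESP[0, a, j]
                    + p1 * _RESP[1, a, j]
                    + p2 * _RESP[2, a, j]
                )
                pid = 1 + (a - 1) * N_ACTIONS + j
                child_slots = _insert_pid(slots, pid)
                if d == 2:
                    cont = _leaf_value(child_slots, alpha)
                else:
                    cont = vmemo[child_slots | ((d - 1) << 50) | (alpha << 54)]
                acc += pj * (_UI[alpha, a, j] + cont)
            q[a] = acc


@njit(cache=True)
def _compute(root_key: np.int64, vmemo) -> None:
    """Iterative post-order evaluation of V over the recombining tree."""
    stack = np.empty(8192, np.int64)
    top = 0
    stack[top] = root_key
    top += 1
    q = np.empty(N_ACTIONS)
    while top > 0:
        key = stack[top - 1]
        if key in vmemo:
            top -= 1
            continue
        d = (key >> 50) & 15
        alpha = (key >> 54) & 3
        slots = key & _SLOT_MASK
        missing = False
        if d > 2:
            for pid in range(N_PAIR_TYPES):
                child = _insert_pid(slots, pid) | ((d - 1) << 50) | (alpha << 54)
                if child not in vmemo:
                    stack[top] = child
                    top += 1
                    missing = True
        if missing:
            continue
        _q_from_children(key, vmemo, q)
        vmemo[key] = _softmax_value(q)
        top -= 1


@njit(cache=True)
def _root_q(root_key: np.int64, vmemo) -> np.ndarray:
    q = np.empty(N_ACTIONS)
    _q_from_children(root_key, vmemo, q)
    return q


# process-wide value memo; shared by every game, search and fit
_VMEMO = Dict.empty(key_type=types.int64, value_type=types.float64)
# python-side cache of root action values / policies (size-capped)
_QCACHE: dict[int, tuple[tuple[float, ...], tuple[float, ...]]] = {}
_QCACHE_MAX = 1_500_000


def _encode(pids, depth: int, guilt_idx: int) -> int:
    if len(pids) > 10:
        raise ValueError("at most 10 exchanges fit in a game")
    slots = 0
    shift = 0
    for pid in sorted(pids):
        slots |= int(pid) << shift
        shift += 5
    for _ in range(10 - len(pids)):
        slots |= _EMPTY << shift
        shift += 5
    return slots | (depth << 50) | (guilt_idx << 54)


def clear_cache() -> None:
    """Drop all memoized level-0 values (mainly for memory control)."""
    _VMEMO.clear()
    _QCACHE.clear()


def investor_q_values(pids, t: int, P: int, guilt_idx: int) -> tuple[float, ...]:
    """Level-0 investor action values at round ``t``.

    ``pids`` is the multiset (any order) of pair ids of the exchanges
    observed so far; ``P`` the planning horizon; ``guilt_idx`` the
    investor's own guilt index.  Values cover min(P, 10 - t) + 1 rounds,
    never extending past round 10.
    """
    if not 1 <= t <= GAME_LENGTH:
        raise ValueError(f"round index must be in 1..{GAME_LENGTH}, got {t}")
    depth = horizon_rounds(t, P)
    key = _encode(pids, depth, guilt_idx)
    hit = _QCACHE.get(key)
    if hit is not None:
        return hit[0]
    if depth >= 2:
        _compute(np.int64(key), _VMEMO)
    q = tuple(_root_q(np.int64(key), _VMEMO))
    probs = tuple(softmax(q))
    if len(_QCACHE) >= _QCACHE_MAX:
        _QCACHE.clear()
    _QCACHE[key] = (q, probs)
    return q


def investor_policy(pids, t: int, P: int, guilt_idx: int) -> tuple[float, ...]:
    """Softmax (beta = 1/3) policy of the level-0 investor."""
    if not 1 <= t <= GAME_LENGTH:
        raise ValueError(f"round index must be in 1..{GAME_LENGTH}, got {t}")
    depth = horizon_rounds(t, P)
    key = _encode(pids, depth, guilt_idx)
    hit = _QCACHE.get(key)
    if hit is not None:
        return hit[1]
    investor_q_values(pids, t, P, guilt_idx)
    return _QCACHE[key][1]
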