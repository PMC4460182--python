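"""Dirichlet-multinomial belief over the partner's guilt type.

The only latent quantity inferred online during a game is the partner's
Fehr-Schmidt guilt parameter, one of three types.  Beliefs are carried
as three Dirichlet pseudo-counts starting from the uniform (1, 1, 1)
prior.  After each observed partner action the pseudo-count of each
guilt type grows by the probability of that action under the
corresponding intentional model (a soft-count increment, added raw and
unnormalized).  Because increments add, the posterior depends only on
the multiset of observed exchanges, not their order — the property that
licenses the recombining planning tree for level-0 agents.
"""

from __future__ import annotations

import numpy as np

from .game import N_GUILT


def init_belief() -> np.ndarray:
    """Uniform prior pseudo-counts (1, 1, 1) over the guilt grid."""
    return np.ones(N_GUILT)


def predictive_probs(b: np.ndarray) -> np.ndarray:
    """Predictive probability of each guilt type, a_i / sum(a)."""
    b = np.asarray(b, dtype=float)
    total = b.sum()
    if total <= 0:
        raise ValueError("belief pseudo-counts must have positive mass")
    return b / total

def update_belief(b: np.ndarray, likelihoods) -> np.ndarray:
    """Soft-count update: a'_i = a_i + P[observed action | guilt_i].

    ``likelihoods`` are the probabilities of the observed partner action
    under each guilt-typed intentional model; they are added raw,
    without normalization across types.
    """
    lik = np.asarray(likelihoods, dtype=float)
    if lik.shape != (N_GUILT,):
        raise ValueError(f"expected {N_GUILT} likelihoods, got shape {lik.shape}")
    if np.any(lik < 0) or np.any(lik > 1):
        raise ValueError("likelihoods must lie in [0, 1]")
    return np.asarray(b, dtype=float) + lik
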