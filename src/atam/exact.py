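"""Brute-force enumeration of the latent posterior on tiny instances.

Useful only for corpora with a handful of tokens: the configuration
space is A^D x (Z+2)^T for ATAM and (Z+1)^T for the LDA baseline.
These utilities exist to validate the Gibbs samplers: the empirical
distribution of a long chain must match the enumerated posterior.
"""

from __future__ import annotations

import itertools

import numpy as np

from .corpus import EncodedCorpus
from .lda_bg import LDABGHypers, LDABGState, LDABGStats, lda_joint_log_likelihood
from .model import ATAMHypers, LatentState, SufficientStats, joint_log_likelihood

__all__ = [
    "atam_config_id",
    "lda_config_id",
    "enumerate_atam_posterior",
    "enumerate_lda_posterior",
]

_MAX_CONFIGS = 2_000_000


def atam_config_id(doc_ailment: np.ndarray, token_state: np.ndarray,
                   num_ailments: int, num_states: int) -> int:
    """Mixed-radix integer encoding of a full ATAM latent configuration."""
    cid = 0
    for a in doc_ailment:
        cid = cid * num_ailments + int(a)
    for ts in token_state:
        cid = cid * num_states + int(ts)
    return cid


def lda_config_id(token_state: np.ndarray, num_states: int) -> int:
    cid = 0
    for ts in token_state:
        cid = cid * num_states + int(ts)
    return cid


def enumerate_atam_posterior(corpus: EncodedCorpus,
                             hypers: ATAMHypers) -> np.ndarray:
    """Exact posterior over all configurations, indexed by atam_config_id."""
    D, T = corpus.num_docs, corpus.num_tokens
    A, S = hypers.num_ailments, hypers.num_topics + 2
    n_configs = A ** D * S ** T
    if n_configs > _MAX_CONFIGS:
        raise ValueError(f"{n_configs} configurations is too many to enumerate")
    log_probs = np.empty(n_configs)
    idx = 0
    for ails in itertools.product(range(A), repeat=D):
        doc_ailment = np.array(ails, dtype=np.int32)
        for states in itertools.product(range(S), repeat=T):
            token_state = np.array(states, dtype=np.int32)
            st = LatentState(doc_ailment=doc_ailment, token_state=token_state,
                             num_active=D)
            stats = SufficientStats.from_state(corpus, st, A,
                                               hypers.num_topics)
            log_probs[idx] = joint_log_likelihood(corpus, st, stats, hypers)
            idx += 1
    log_probs -= log_probs.max()
    p = np.exp(log_probs)
    return p / p.sum()


def enumerate_lda_posterior(corpus: EncodedCorpus,
                            hypers: LDABGHypers) -> np.ndarray:
    T = corpus.num_tokens
    S = hypers.num_topics + 1
    n_configs = S ** T
    if n_configs > _MAX_CONFIGS:
        raise ValueError(f"{n_configs} configurations is too many to enumerate")
    log_probs = np.empty(n_configs)
    for idx, states in enumerate(itertools.product(range(S), repeat=T)):
        token_state = np.array(states, dtype=np.int32)
        st = LDABGState(token_state=token_state, num_active=corpus.num_docs)
        stats = LDABGStats.from_state(corpus, st, hypers.num_topics)
        log_probs[idx] = lda_joint_log_likelihood(corpus, st, stats, hypers)
    log_probs -= log_probs.max()
    p = np.exp(log_probs)
    return p / p.sum()
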