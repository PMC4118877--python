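"""Dirichlet-multinomial hyperparameter optimization.

Fixed-point (digamma-ratio) updates for Dirichlet hyperparameters of
grouped count data: free per-component updates for the topic priors
alpha_i, and precision-only updates (the mean m_i stays fixed) for the
informative ailment word priors beta_i = s_i * m_i.  Each pass is
guaranteed not to decrease the marginal likelihood of the counts.
Interleaved with sampling: every `interval` Gibbs sweeps, `passes`
fixed-point passes are applied to every alpha_i and s_i.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln, psi

from .model import ATAMHypers, LatentState, SufficientStats

__all__ = [
    "dirmult_log_likelihood",
    "fixed_mean_log_likelihood",
    "update_alpha",
    "update_precision",
    "HyperoptSchedule",
    "optimize_atam_hypers",
    "optimize_lda_alpha",
]

FLOOR = 1e-6


def dirmult_log_likelihood(counts: np.ndarray, alpha: np.ndarray) -> float:
    """log P(counts | alpha) for a group of Dirichlet-multinomial vectors.

    counts: (G, K) nonnegative integer rows; alpha: (K,) positive.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.float64))
    asum = alpha.sum()
    tot = counts.sum(axis=1)
    ll = np.sum(gammaln(asum) - gammaln(asum + tot))
    ll += np.where(counts > 0, gammaln(counts + alpha) - gammaln(alpha), 0.0).sum()
    return float(ll)


def fixed_mean_log_likelihood(counts: np.ndarray, m: np.ndarray,
                              s: float) -> float:
    return dirmult_log_likelihood(counts, s * np.asarray(m))


def update_alpha(counts: np.ndarray, alpha: np.ndarray,
                 floor: float = FLOOR) -> np.ndarray:
    """One fixed-point pass of the free Dirichlet update.

    alpha_k <- alpha_k * sum_g [psi(n_gk + alpha_k) - psi(alpha_k)]
                       / sum_g [psi(n_g. + alpha.) - psi(alpha.)],
    clamped to a positive floor.  All-zero counts leave alpha unchanged.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.float64))
    alpha = np.asarray(alpha, dtype=np.float64)
    if counts.size == 0 or counts.sum() == 0:
        return alpha.copy()
    asum = alpha.sum()
    tot = counts.sum(axis=1)
    denom = np.sum(psi(tot + asum) - psi(asum))
    if denom <= 0:
        return alpha.copy()
    num = np.where(counts > 0, psi(counts + alpha) - psi(alpha), 0.0).sum(axis=0)
    return np.maximum(alpha * num / denom, floor)


def update_precision(counts: np.ndarray, m: np.ndarray, s: float,
                     floor: float = FLOOR) -> float:
    """One fixed-point precision update for a fixed-mean Dirichlet prior.

    s <- s * sum_{g,v} m_v [psi(n_gv + s m_v) - psi(s m_v)]
           / sum_g [psi(n_g. + s) - psi(s)].
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.float64))
    m = np.asarray(m, dtype=np.float64)
    if counts.size == 0 or counts.sum() == 0:
        return float(s)
    tot = counts.sum(axis=1)
    denom = np.sum(psi(tot + s) - psi(s))
    if denom <= 0:
        return float(s)
    sm = s * m
    num = float(np.where(counts > 0, m * (psi(counts + sm) - psi(sm)), 0.0).sum())
    return max(s * num / denom, floor)


@dataclasses.dataclass
class HyperoptSchedule:
    """When and how hard to optimize during training."""

    interval: int = 10   # Gibbs sweeps between optimization events
    passes: int = 5      # fixed-point passes per event
    min_group: int = 5   # alpha_i groups smaller than this are left alone
    enabled: bool = True

    def due(self, sweep_index: int) -> bool:
        return (self.enabled and self.interval > 0
                and (sweep_index + 1) % self.interval == 0)


def optimize_atam_hypers(state: LatentState, stats: SufficientStats,
                         hypers: ATAMHypers,
                         schedule: HyperoptSchedule) -> None:
    """One optimization event: update every alpha_i and s_i in place.

    The alpha_i group is the per-document topic-count rows of documents
    currently assigned ailment i; the s_i group is ailment i's three
    per-aspect word-count rows.
    """
    D = state.num_active
    a = state.doc_ailment[:D]
    for _ in range(schedule.passes):
        for i in range(hypers.num_ailments):
            rows = stats.n_doc_topic[:D][a == i]
            if rows.shape[0] >= schedule.min_group:
                hypers.alpha[i] = update_alpha(rows, hypers.alpha[i])
            hypers.s[i] = update_precision(stats.n_aaw[i], hypers.m[i],
                                           hypers.s[i])


def optimize_lda_alpha(stats, hypers, schedule: HyperoptSchedule,
                       num_active: int) -> None:
    """Optimize the LDA baseline's single alpha vector with the same updates."""
    rows = stats.n_doc_topic[:num_active]
    for _ in range(schedule.passes):
        hypers.alpha = update_alpha(rows, hypers.alpha)
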