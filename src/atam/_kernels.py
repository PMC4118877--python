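"""Numba kernels for the collapsed Gibbs samplers.

Token composite-state encoding (ATAM): -1 unassigned, 0 background (l=0),
1 ailment word (l=1, x=1), 2+k topic word k (l=1, x=0, z=k).
LDA-with-background encoding: -1 unassigned, 0 background, 1+k topic k.

All conditional weights are accumulated in log space and normalized by
log-sum-exp; a zero weight (e.g. lam = 0) becomes -inf.  Categorical
draws use pre-generated uniforms via inverse-CDF, so a run is fully
determined by its seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -math.inf

BG = 0
AIL = 1
TOP0 = 2  # TOP(k) = TOP0 + k


@njit(cache=True)
def _draw(logp, u):
    """Inverse-CDF draw from unnormalized log-weights using uniform u."""
    n = logp.shape[0]
    mx = NEG_INF
    for i in range(n):
        if logp[i] > mx:
            mx = logp[i]
    total = 0.0
    for i in range(n):
        if logp[i] > NEG_INF:
            total += math.exp(logp[i] - mx)
    target = u * total
    acc = 0.0
    for i in range(n):
        if logp[i] > NEG_INF:
            acc += math.exp(logp[i] - mx)
            if acc >= target:
                return i
    return n - 1


@njit(cache=True)
def _argmax(logp):
    best = 0
    bestv = logp[0]
    for i in range(1, logp.shape[0]):
        if logp[i] > bestv:
            bestv = logp[i]
            best = i
    return best


# ---------------------------------------------------------------------------
# ATAM
# ---------------------------------------------------------------------------

@njit(cache=True)
def atam_remove_token(d, t, code, i, words, aspects,
                      n_doc_topic, n_topic_word, n_topic_sum,
                      n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top):
    if code < 0:
        return
    v = words[t]
    j = aspects[t]
    if code == BG:
        n_bgw[j, v] -= 1
        n_bgs[j] -= 1
    elif code == AIL:
        n_aaw[i, j, v] -= 1
        n_aas[i, j] -= 1
        n_doc_ail[d] -= 1
    else:
        k = code - TOP0
        n_doc_topic[d, k] -= 1
        n_topic_word[k, v] -= 1
        n_topic_sum[k] -= 1
        n_doc_top[d] -= 1


@njit(cache=True)
def atam_add_token(d, t, code, i, words, aspects,
                   n_doc_topic, n_topic_word, n_topic_sum,
                   n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top):
    v = words[t]
    j = aspects[t]
    if code == BG:
        n_bgw[j, v] += 1
        n_bgs[j] += 1
    elif code == AIL:
        n_aaw[i, j, v] += 1
        n_aas[i, j] += 1
        n_doc_ail[d] += 1
    else:
        k = code - TOP0
        n_doc_topic[d, k] += 1
        n_topic_word[k, v] += 1
        n_topic_sum[k] += 1
        n_doc_top[d] += 1


@njit(cache=True)
def atam_token_logprobs(d, t, i, words, aspects,
                        n_doc_topic, n_topic_word, n_topic_sum,
                        n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top,
                        alpha, alpha_sum, s, m,
                        gamma_ail, gamma_top, lam, beta_flat, num_words,
                        mask_ail, out):
    """Collapsed conditional over the Z+2 composite states of token (d, t).

    The token's own contribution must already be removed from the counts.
    With mask_ail the ailment branch is forbidden and the ailment-vs-topic
    switch factor is dropped (x pinned to 0), which reduces the model to
    LDA-with-background.
    """
    v = words[t]
    j = aspects[t]
    Z = n_topic_word.shape[0]

    w_bg = (1.0 - lam) * (n_bgw[j, v] + beta_flat) / (n_bgs[j] + num_words * beta_flat)
    out[0] = math.log(w_bg) if w_bg > 0.0 else NEG_INF

    if mask_ail:
        out[1] = NEG_INF
        pi_top = 1.0
    else:
        denom = n_doc_ail[d] + n_doc_top[d] + gamma_ail + gamma_top
        pi_ail = (n_doc_ail[d] + gamma_ail) / denom
        pi_top = (n_doc_top[d] + gamma_top) / denom
        w_ail = lam * pi_ail * (n_aaw[i, j, v] + s[i] * m[i, v]) / (n_aas[i, j] + s[i])
        out[1] = math.log(w_ail) if w_ail > 0.0 else NEG_INF

    asum = alpha_sum[i]
    theta_denom = n_doc_top[d] + asum
    for k in range(Z):
        w_top = (lam * pi_top
                 * (n_doc_topic[d, k] + alpha[i, k]) / theta_denom
                 * (n_topic_word[k, v] + beta_flat)
                 / (n_topic_sum[k] + num_words * beta_flat))
        out[TOP0 + k] = math.log(w_top) if w_top > 0.0 else NEG_INF


@njit(cache=True)
def atam_ailment_logprobs(d, doc_ptr, words, aspects, token_state,
                          n_ail, n_doc_topic, n_aaw, n_aas,
                          alpha, alpha_sum, s, m, sigma, out):
    """Collapsed conditional over candidate ailments for document d.

    Document d's own contributions (its a assignment and its AIL-token
    counts) must already be removed.  Three factors per candidate i:
    prevalence, the grouped Dirichlet-multinomial predictive of d's
    ailment-word counts under s_i * m_i, and the Dirichlet-multinomial
    predictive of d's topic-assignment counts under alpha_i.
    """
    A = n_ail.shape[0]
    Z = alpha.shape[1]
    start = doc_ptr[d]
    end = doc_ptr[d + 1]

    t_top = 0
    for k in range(Z):
        t_top += n_doc_topic[d, k]

    for i in range(A):
        lp = math.log(n_ail[i] + sigma)
        if t_top > 0:
            lp += math.lgamma(alpha_sum[i]) - math.lgamma(alpha_sum[i] + t_top)
            for k in range(Z):
                ndk = n_doc_topic[d, k]
                if ndk > 0:
                    lp += math.lgamma(alpha[i, k] + ndk) - math.lgamma(alpha[i, k])
        # sequential predictive over the document's AIL tokens; the doc is
        # short, so the O(n_d^2) duplicate scan is cheap
        added0 = 0
        added1 = 0
        added2 = 0
        for t in range(start, end):
            if token_state[t] == AIL:
                v = words[t]
                j = aspects[t]
                prev_same = 0
                for t2 in range(start, t):
                    if token_state[t2] == AIL and aspects[t2] == j and words[t2] == v:
                        prev_same += 1
                if j == 0:
                    added = added0
                    added0 += 1
                elif j == 1:
                    added = added1
                    added1 += 1
                else:
                    added = added2
                    added2 += 1
                lp += math.log(n_aaw[i, j, v] + s[i] * m[i, v] + prev_same)
                lp -= math.log(n_aas[i, j] + s[i] + added)
        out[i] = lp


@njit(cache=True)
def atam_remove_doc_ailment(d, doc_ptr, words, aspects, token_state, a,
                            n_ail, n_aaw, n_aas):
    n_ail[a] -= 1
    for t in range(doc_ptr[d], doc_ptr[d + 1]):
        if token_state[t] == AIL:
            n_aaw[a, aspects[t], words[t]] -= 1
            n_aas[a, aspects[t]] -= 1


@njit(cache=True)
def atam_add_doc_ailment(d, doc_ptr, words, aspects, token_state, a,
                         n_ail, n_aaw, n_aas):
    n_ail[a] += 1
    for t in range(doc_ptr[d], doc_ptr[d + 1]):
        if token_state[t] == AIL:
            n_aaw[a, aspects[t], words[t]] += 1
            n_aas[a, aspects[t]] += 1


@njit(cache=True)
def atam_sweep(docs, doc_ptr, words, aspects, doc_ail, token_state,
               n_ail, n_doc_topic, n_topic_word, n_topic_sum,
               n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top,
               alpha, alpha_sum, s, m, sigma,
               gamma_ail, gamma_top, lam, beta_flat, num_words,
               uniforms, sample_docs):
    """One full Gibbs sweep over the given documents (in order).

    For each document: resample a_d, then resample every token's composite
    state.  Consumes one uniform per draw from `uniforms` in a fixed order.
    """
    A = n_ail.shape[0]
    Z = n_topic_word.shape[0]
    lp_a = np.empty(A)
    lp_t = np.empty(Z + 2)
    u_idx = 0
    for di in range(docs.shape[0]):
        d = docs[di]
        if sample_docs:
            a_old = doc_ail[d]
            atam_remove_doc_ailment(d, doc_ptr, words, aspects, token_state,
                                    a_old, n_ail, n_aaw, n_aas)
            atam_ailment_logprobs(d, doc_ptr, words, aspects, token_state,
                                  n_ail, n_doc_topic, n_aaw, n_aas,
                                  alpha, alpha_sum, s, m, sigma, lp_a)
            a_new = _draw(lp_a, uniforms[u_idx])
            u_idx += 1
            atam_add_doc_ailment(d, doc_ptr, words, aspects, token_state,
                                 a_new, n_ail, n_aaw, n_aas)
            doc_ail[d] = a_new
        i = doc_ail[d]
        for t in range(doc_ptr[d], doc_ptr[d + 1]):
            code = token_state[t]
            atam_remove_token(d, t, code, i, words, aspects,
                              n_doc_topic, n_topic_word, n_topic_sum,
                              n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top)
            atam_token_logprobs(d, t, i, words, aspects,
                                n_doc_topic, n_topic_word, n_topic_sum,
                                n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top,
                                alpha, alpha_sum, s, m,
                                gamma_ail, gamma_top, lam, beta_flat, num_words,
                                False, lp_t)
            new_code = _draw(lp_t, uniforms[u_idx])
            u_idx += 1
            atam_add_token(d, t, new_code, i, words, aspects,
                           n_doc_topic, n_topic_word, n_topic_sum,
                           n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top)
            token_state[t] = new_code
    return u_idx


@njit(cache=True)
def atam_greedy_assign(docs, doc_ptr, words, aspects, doc_ail, token_state,
                       n_ail, n_doc_topic, n_topic_word, n_topic_sum,
                       n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top,
                       alpha, alpha_sum, s, m, sigma,
                       gamma_ail, gamma_top, lam, beta_flat, num_words):
    """Initialize fresh documents to the argmax of the current conditionals.

    Documents are processed in order: the ailment is set first (with the
    document's tokens still unassigned), then each token greedily, with
    counts updated as they are placed.
    """
    A = n_ail.shape[0]
    Z = n_topic_word.shape[0]
    lp_a = np.empty(A)
    lp_t = np.empty(Z + 2)
    for di in range(docs.shape[0]):
        d = docs[di]
        atam_ailment_logprobs(d, doc_ptr, words, aspects, token_state,
                              n_ail, n_doc_topic, n_aaw, n_aas,
                              alpha, alpha_sum, s, m, sigma, lp_a)
        a = _argmax(lp_a)
        doc_ail[d] = a
        n_ail[a] += 1
        for t in range(doc_ptr[d], doc_ptr[d + 1]):
            atam_token_logprobs(d, t, a, words, aspects,
                                n_doc_topic, n_topic_word, n_topic_sum,
                                n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top,
                                alpha, alpha_sum, s, m,
                                gamma_ail, gamma_top, lam, beta_flat, num_words,
                                False, lp_t)
            code = _argmax(lp_t)
            atam_add_token(d, t, code, a, words, aspects,
                           n_doc_topic, n_topic_word, n_topic_sum,
                           n_aaw, n_aas, n_bgw, n_bgs, n_doc_ail, n_doc_top)
            token_state[t] = code


# ---------------------------------------------------------------------------
# LDA with background
# ---------------------------------------------------------------------------

@njit(cache=True)
def lda_token_logprobs(d, t, words,
                       n_doc_topic, n_topic_word, n_topic_sum,
                       n_bg_word, n_bg_sum, n_doc_top,
                       alpha, alpha_sum, lam, beta_flat, num_words, out):
    """Collapsed conditional over {BG} + Z topics for token (d, t)."""
    v = words[t]
    Z = n_topic_word.shape[0]
    w_bg = (1.0 - lam) * (n_bg_word[v] + beta_flat) / (n_bg_sum[0] + num_words * beta_flat)
    out[0] = math.log(w_bg) if w_bg > 0.0 else NEG_INF
    theta_denom = n_doc_top[d] + alpha_sum
    for k in range(Z):
        w = (lam * (n_doc_topic[d, k] + alpha[k]) / theta_denom
             * (n_topic_word[k, v] + beta_flat)
             / (n_topic_sum[k] + num_words * beta_flat))
        out[1 + k] = math.log(w) if w > 0.0 else NEG_INF


@njit(cache=True)
def lda_sweep(docs, doc_ptr, words, token_state,
              n_doc_topic, n_topic_word, n_topic_sum,
              n_bg_word, n_bg_sum, n_doc_top,
              alpha, alpha_sum, lam, beta_flat, num_words, uniforms):
    Z = n_topic_word.shape[0]
    lp = np.empty(Z + 1)
    u_idx = 0
    for di in range(docs.shape[0]):
        d = docs[di]
        for t in range(doc_ptr[d], doc_ptr[d + 1]):
            code = token_state[t]
            v = words[t]
            if code == 0:
                n_bg_word[v] -= 1
                n_bg_sum[0] -= 1
            elif code > 0:
                k = code - 1
                n_doc_topic[d, k] -= 1
                n_topic_word[k, v] -= 1
                n_topic_sum[k] -= 1
                n_doc_top[d] -= 1
            lda_token_logprobs(d, t, words, n_doc_topic, n_topic_word,
                               n_topic_sum, n_bg_word, n_bg_sum, n_doc_top,
                               alpha, alpha_sum, lam, beta_flat, num_words, lp)
            new_code = _draw(lp, uniforms[u_idx])
            u_idx += 1
            if new_code == 0:
                n_bg_word[v] += 1
                n_bg_sum[0] += 1
            else:
                k = new_code - 1
                n_doc_topic[d, k] += 1
                n_topic_word[k, v] += 1
                n_topic_sum[k] += 1
                n_doc_top[d] += 1
            token_state[t] = new_code
    return u_idx
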