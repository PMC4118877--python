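"""Independent oracles used to validate the samplers and likelihoods.

Everything here is written from first principles with plain Python
containers and math.lgamma — deliberately sharing no code with the
package implementation — so agreement between the two is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

BG, AIL = 0, 1  # composite token codes; TOP(k) = 2 + k


def _dm_group(counter: Counter, prior_of, prior_total: float) -> float:
    """log Dirichlet-multinomial normalizer ratio for one count vector.

    counter maps category -> count; prior_of(category) gives that
    category's prior pseudo-count; prior_total is the summed prior.
    """
    total = sum(counter.values())
    ll = math.lgamma(prior_total) - math.lgamma(prior_total + total)
    for cat, cnt in counter.items():
        ll += math.lgamma(prior_of(cat) + cnt) - math.lgamma(prior_of(cat))
    return ll


def atam_log_joint(doc_words, doc_aspects, doc_ailment, token_states,
                   *, num_ailments, num_topics, num_words, m, s, alpha,
                   sigma, gamma_ail, gamma_top, lam, beta_flat) -> float:
    """Collapsed log P(w, a, z, x, l) for one full latent configuration.

    doc_words / doc_aspects / token_states are lists of per-document lists;
    m is per-ailment prior mean rows, s per-ailment precisions, alpha the
    per-ailment topic prior rows.
    """
    D = len(doc_words)
    ll = 0.0

    # ailment prevalence
    a_counts = Counter(doc_ailment)
    ll += _dm_group(a_counts, lambda i: sigma, num_ailments * sigma)

    topic_word = Counter()   # (k, v)
    topic_tot = Counter()    # k
    ail_word = Counter()     # (i, j, v)
    ail_tot = Counter()      # (i, j)
    bg_word = Counter()      # (j, v)
    bg_tot = Counter()       # j

    for d in range(D):
        a = doc_ailment[d]
        n_bg = n_ail = n_top = 0
        doc_topics = Counter()
        for w, y, st in zip(doc_words[d], doc_aspects[d], token_states[d]):
            if st == BG:
                n_bg += 1
                bg_word[(y, w)] += 1
                bg_tot[y] += 1
            elif st == AIL:
                n_ail += 1
                ail_word[(a, y, w)] += 1
                ail_tot[(a, y)] += 1
            else:
                k = st - 2
                n_top += 1
                doc_topics[k] += 1
                topic_word[(k, w)] += 1
                topic_tot[k] += 1
        # background switch l
        if n_bg + n_ail + n_top:
            if lam in (0.0, 1.0):
                if (lam == 0.0 and (n_ail + n_top)) or (lam == 1.0 and n_bg):
                    return -math.inf
            if n_ail + n_top and lam > 0:
                ll += (n_ail + n_top) * math.log(lam)
            if n_bg and lam < 1:
                ll += n_bg * math.log(1.0 - lam)
        # ailment-vs-topic switch x (Beta-Bernoulli)
        ll += (math.lgamma(gamma_ail + gamma_top)
               - math.lgamma(gamma_ail) - math.lgamma(gamma_top)
               + math.lgamma(gamma_ail + n_ail) + math.lgamma(gamma_top + n_top)
               - math.lgamma(gamma_ail + gamma_top + n_ail + n_top))
        # topic assignments under alpha_{a_d}
        ll += _dm_group(doc_topics, lambda k, a=a: alpha[a][k],
                        sum(alpha[a]))

    # word tables
    for k in range(num_topics):
        cnt = Counter({v: c for (kk, v), c in topic_word.items() if kk == k})
        ll += _dm_group(cnt, lambda v: beta_flat, num_words * beta_flat)
    for j in range(3):
        cnt = Counter({v: c for (jj, v), c in bg_word.items() if jj == j})
        ll += _dm_group(cnt, lambda v: beta_flat, num_words * beta_flat)
    for i in range(num_ailments):
        for j in range(3):
            cnt = Counter({v: c for (ii, jj, v), c in ail_word.items()
                           if ii == i and jj == j})
            ll += _dm_group(cnt, lambda v, i=i: s[i] * m[i][v], s[i])
    return ll


def lda_log_joint(doc_words, token_states, *, num_topics, num_words,
                  alpha, lam, beta_flat) -> float:
    """Collapsed log P(w, z, l) for the LDA-with-background baseline.

    Token codes: 0 background, 1 + k topic k.
    """
    ll = 0.0
    topic_word = Counter()
    bg_word = Counter()
    for d in range(len(doc_words)):
        doc_topics = Counter()
        n_bg = n_top = 0
        for w, st in zip(doc_words[d], token_states[d]):
            if st == 0:
                n_bg += 1
                bg_word[w] += 1
            else:
                k = st - 1
                n_top += 1
                doc_topics[k] += 1
                topic_word[(k, w)] += 1
        if lam in (0.0, 1.0):
            if (lam == 0.0 and n_top) or (lam == 1.0 and n_bg):
                return -math.inf
        if n_top and lam > 0:
            ll += n_top * math.log(lam)
        if n_bg and lam < 1:
            ll += n_bg * math.log(1.0 - lam)
        ll += _dm_group(doc_topics, lambda k: alpha[k], sum(alpha))
    for k in range(num_topics):
        cnt = Counter({v: c for (kk, v), c in topic_word.items() if kk == k})
        ll += _dm_group(cnt, lambda v: beta_flat, num_words * beta_flat)
    ll += _dm_group(bg_word, lambda v: beta_flat, num_words * beta_flat)
    return ll


def enumerate_atam_posterior_oracle(doc_words, doc_aspects, **kw):
    """Exact posterior over all (a, token-state) configurations.

    Returns a dict mapping (tuple(a), tuple(flattened token states)) ->
    probability.
    """
    D = len(doc_words)
    T = sum(len(w) for w in doc_words)
    A = kw["num_ailments"]
    S = kw["num_topics"] + 2
    logps = {}
    for ails in itertools.product(range(A), repeat=D):
        for flat in itertools.product(range(S), repeat=T):
            states, pos = [], 0
            for d in range(D):
                states.append(list(flat[pos:pos + len(doc_words[d])]))
                pos += len(doc_words[d])
            logps[(ails, flat)] = atam_log_joint(doc_words, doc_aspects,
                                                 list(ails), states, **kw)
    mx = max(logps.values())
    tot = sum(math.exp(v - mx) for v in logps.values())
    return {k: math.exp(v - mx) / tot for k, v in logps.items()}


def enumerate_lda_posterior_oracle(doc_words, **kw):
    T = sum(len(w) for w in doc_words)
    S = kw["num_topics"] + 1
    logps = {}
    for flat in itertools.product(range(S), repeat=T):
        states, pos = [], 0
        for d in range(len(doc_words)):
            states.append(list(flat[pos:pos + len(doc_words[d])]))
            pos += len(doc_words[d])
        logps[flat] = lda_log_joint(doc_words, states, **kw)
    mx = max(logps.values())
    tot = sum(math.exp(v - mx) for v in logps.values())
    return {k: math.exp(v - mx) / tot for k, v in logps.items()}


def pearson_textbook(x, y) -> float:
    """Sample Pearson correlation from the definitional formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def dirmult_loglik_plain(count_rows, alpha) -> float:
    """Dirichlet-multinomial log-likelihood of grouped counts, plainly."""
    ll = 0.0
    a_tot = sum(alpha)
    for row in count_rows:
        n = sum(row)
        ll += math.lgamma(a_tot) - math.lgamma(a_tot + n)
        for c, a in zip(row, alpha):
            ll += math.lgamma(a + c) - math.lgamma(a)
    return ll
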