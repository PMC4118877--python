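# atam — Ailment Topic Aspect Model

Topic modelling for syndromic surveillance from short informal text
(tweets and similar), for computational epidemiologists and
computational social scientists who want to track ailments — influenza,
allergies, insomnia, … — from what people say about their health online.

## The model

Standard LDA applied to health-related social text mixes genuine ailment
vocabulary with conversational noise and with topics that are merely
*associated* with being ill ("home watching tv"). ATAM separates the
three explicitly. Each document *d* gets one latent **ailment**
*a_d ~ Categorical(η)*. Each token *n* carries an observed **aspect**
label *y_dn ∈ {general, symptom, treatment}*, assigned before inference
by greedy keyphrase matching against a symptom/treatment lexicon. The
token is then generated as:

- with probability *1 − λ*: **background noise**, word *w_dn ~ φ_B,y*
  (one shared background distribution per aspect);
- otherwise, with probability *π_d ~ Beta(γ, γ)*: an **ailment word**,
  *w_dn ~ φ_A,a_d,y* — each ailment owns three aspect-conditioned word
  distributions, so "red eye" (symptom) and "eye drops" (treatment) are
  kept apart even within one ailment;
- otherwise: a **topic word** under standard LDA, *z_dn ~ θ_d*,
  *w_dn ~ φ_T,z*, where *θ_d ~ Dirichlet(α_{a_d})* — the topic prior
  depends on the document's ailment, linking ailments to the
  conversational topics that co-occur with them.

Ailment word distributions get informative priors
*β_i = s_i · m_i*, where *m_i* is the empirical unigram distribution of
reference health articles about ailment *i* and the precision *s_i* is
learned. Inference is collapsed Gibbs sampling over *(a, z, x, ℓ)* with
interleaved Minka fixed-point optimization of every *α_i* and *s_i*
(every 10 sweeps), an incremental data schedule (10% increments, sweeps
∝ 1/fraction), and optional shard-pooled sweeps. Defaults: *A = Z = 20*,
*λ = 0.2*, *γ = σ = 1*, *β = 0.01* for non-ailment distributions, 8000
iterations.

The trend layer turns assignments plus metadata into surveillance-style
series: *P(a = i | week)* or *P(a = i | region)* as the fraction of
documents assigned to ailment *i*, keyword-count baselines, z-scoring,
and Pearson correlation against external series (e.g. CDC ILINet).

## Worked example

```python
import numpy as np
from atam.synthetic import TrueParams, generate_corpus, recovery_report
from atam.model import ATAMHypers, init_state, gibbs_sweep, estimate_parameters
from atam.hyperopt import HyperoptSchedule, optimize_atam_hypers
from atam.priors import build_prior_means

# a well-separated synthetic world: 3 ailments, 3 topics, 200 words
params = TrueParams.well_separated(3, 3, 200, seed=1, lam=0.5)
gen = generate_corpus(params, num_docs=2000, doc_length=15, seed=2)
enc = gen.corpus.encode()

# informative priors from (synthetic) per-ailment reference texts
rng = np.random.default_rng(3)
refs = []
for i in range(3):
    mix = (params.aspect_probs[i][:, None] * params.phi_ailment[i]).sum(0)
    words = rng.choice(200, p=mix, size=3000)
    refs.append([" ".join(gen.corpus.vocab.word(int(v)) for v in words)])
priors = build_prior_means(refs, gen.corpus.vocab, smoothing=0.01, s_init=200.0)

hypers = ATAMHypers(alpha=np.full((3, 3), 1.0), s=priors.precisions,
                    m=priors.means, sigma=1.0, gamma_ail=1.0, gamma_top=1.0,
                    lam=0.5, beta_flat=0.01)
state, stats = init_state(enc, hypers, seed=4)
g = np.random.default_rng(5)
sched = HyperoptSchedule(interval=10, passes=2)   # Minka updates every 10 sweeps
for sweep in range(2000):
    gibbs_sweep(enc, state, stats, hypers, g)
    if sched.due(sweep):
        optimize_atam_hypers(state, stats, hypers, sched)

est = estimate_parameters(enc, state, stats, hypers)
print(recovery_report(gen, params, est, state.doc_ailment))
```

prints (up to Monte-Carlo variation in the sampler)

```
{'doc_ailment_accuracy': 0.914, 'phi_ailment_mean_l1': 0.1530,
 'phi_topic_mean_l1': 0.2378, 'eta_max_abs_error': 0.0099,
 'ailment_permutation': [0, 1, 2], 'topic_permutation': [2, 1, 0]}
```

i.e. 91% of documents are assigned their true ailment after optimal
component matching, and the estimated aspect-conditioned ailment word
distributions are within mean L1 distance 0.16 of the generating ones
(0 is perfect, 2 is disjoint support). The permutations report how
estimated components were matched to true ones — topic components are
only identified up to relabelling, while the informative priors anchor
ailment identity.

A command-line interface covers the same pipeline on real data:
`atam train --corpus tweets.jsonl --lexicon keyphrases.tsv --priors refs/
--config config.yaml --out run/`, plus `atam lda`, `atam resume`,
`atam estimate`, and `atam simulate`.

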