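# Methods

## Model

ATAM is a generative model of short documents with observed per-token
aspect labels. Notation: *A* ailments, *Z* topics, *Y* = 3 aspects
(general, symptom, treatment), *W* vocabulary words, *D* documents,
*N_d* tokens in document *d*.

For each document *d*:

1. ailment *a_d ~ Categorical(η)*, with *η ~ Dirichlet(σ)*;
2. topic distribution *θ_d ~ Dirichlet(α_{a_d})* — one free α vector
   per ailment, so ailments can prefer particular non-ailment topics;
3. ailment-word propensity *π_d ~ Beta(γ_ail, γ_top)* (symmetric
   *γ = 1* by default).

For each token *n* with observed word *w_dn* and observed aspect
*y_dn = j*:

1. background switch *ℓ_dn ~ Bernoulli(λ)* (ℓ = 0 means background);
   background words come from *φ_B,j*, one shared distribution per
   aspect;
2. if non-background, ailment-vs-topic switch *x_dn ~ Bernoulli(π_d)*;
   ailment words come from *φ_A,a_d,j* (aspect-conditioned per ailment),
   topic words from *φ_T,z* with *z_dn ~ θ_d*.

Aspect labels are input, produced by greedy longest-match keyphrase
labelling (lower-cased, left-to-right, matched tokens not re-matched);
the model never samples *y*.

Priors: *φ_A,ij ~ Dirichlet(β_i)* with the mean/precision decomposition
*β_i = s_i · m_i*, where *m_i* is the smoothed empirical unigram
distribution of ailment *i*'s reference articles and *s_i > 0* a learned
confidence. All other word distributions get a symmetric
Dirichlet(*β* = 0.01). Defaults (`atam.priors.default_config`):
*A = Z = 20*, *λ = 0.2* (i.e. background probability 0.8 — short social
text is mostly conversational noise), *γ = σ = 1*, 8000 Gibbs
iterations, hyperparameter optimization every 10 sweeps.

## Collapsed Gibbs sampler

All multinomial/Bernoulli parameters are integrated out; the sampler
moves only *(a, z, x, ℓ)*. Per token, *(ℓ, x, z)* is drawn as a single
block over the *Z + 2* composite states {background, ailment-word,
topic 0, …, topic Z−1}; the separate per-variable distributions and the
block draw target the same conditional, and the block avoids any
within-token ordering ambiguity. The token conditional is the product
of the usual collapsed ratios: background predictive for the BG state;
switch-fraction × ailment-word predictive for the AIL state;
switch-fraction × topic-assignment predictive × topic-word predictive
per topic state.

Per document, *a_d* is resampled from the product of three factors:
prevalence (*n_i + σ*), the grouped Dirichlet-multinomial predictive of
all of the document's ailment-word counts under *s_i·m_i* (all the
document's ailment tokens move jointly, so this is accumulated with
log-gamma ratios, not per-token approximations), and the
Dirichlet-multinomial predictive of the document's topic-assignment
counts under *α_i*. The last factor exists because *θ_d*'s prior
depends on *a_d*; omitting it would break detailed balance, which the
enumeration tests would catch.

The correctness authority for all of this is brute-force enumeration:
on tiny corpora every latent configuration is enumerated, the collapsed
joint evaluated, and (a) each conditional compared entrywise (≤ 1e-10)
to the renormalized exact joints, and (b) the long-run configuration
frequencies of the full chain compared to the exact posterior in total
variation. The test-suite oracle (`tests/oracles.py`) is an independent
plain-Python implementation of the collapsed joint sharing no code with
the package.

Numerical policy: the document-level conditional is accumulated in log
space with `lgamma`; token-level weights are short products of
probability-scale ratios computed in linear space and logged once (a
structurally zero weight, e.g. λ = 0, becomes −inf); normalization by
max-subtracted exponentiation. Categorical draws use inverse-CDF on
pre-generated uniforms, so a run is a pure function of its seed; the
training driver derives one RNG per sweep from (seed, sweep index),
which makes checkpoint/resume bit-exact without serializing generator
state. Hot loops are numba-compiled over flat int64 count tables; the
pure-numpy recount (`SufficientStats.from_state`) doubles as the audit
that every table matches an independent recount of the latent state.

The Beta prior on *π_d* is held as an asymmetric (γ_ail, γ_top) pair
(default symmetric 1.0). This is what makes the model's limit structure
explicit and testable: γ → (0, ∞) — or equivalently the `mask_ail`
flag, which pins *x* = 0 and drops the switch factor — reduces the
token conditional exactly to the LDA-with-background baseline, and
λ ∈ {0, 1} degenerate cases produce exact point masses rather than
numerical near-zeros.

## Hyperparameter optimization

Minka's fixed-point digamma-ratio updates, interleaved every 10 sweeps
(5 passes per event by default; the recovery experiments use 2):

- each *α_i* updated freely, component-wise, on the group of
  per-document topic-count rows of documents currently assigned
  ailment *i*; groups smaller than 5 documents keep their previous
  values to avoid degenerate fits;
- each *s_i* updated precision-only (mean fixed) on ailment *i*'s three
  per-aspect word-count rows.

Both updates are clamped at a floor of 1e-6 and provably do not
decrease the group's Dirichlet-multinomial likelihood; since the
collapsed joint decomposes over exactly these groups, an optimization
event never decreases the joint likelihood (asserted at 1e-8). The
fixed points are validated against dense grid searches of the exact
likelihood; on simulated counts (10,000 groups × 100 tokens) the
precision update lands within a fraction of a percent of both the grid
maximizer and the generating value. Convergence of these fixed-point
iterations is slow near flat directions (identical count vectors push
*s* → ∞ at a logarithmic rate); this is a property of the update, not
a defect, and per-event pass counts are kept small accordingly.

## Training schedule and large corpora

Data is fed in increments: fraction *t* = 0.1, 0.2, …, 1.0 of the
(caller-ordered) documents, with sweep counts proportional to 1/*t* —
more sweeps on less data — normalized to the configured total, each
level getting at least one sweep. The rounding remainder is absorbed by
the *smallest* fraction rather than the largest: putting it at the
final level can violate the non-increasing-sweeps property the
allocation is supposed to have (e.g. 11 sweeps over 10 levels).
Newly activated documents are initialized greedily: the document's
ailment to the argmax of its conditional (evaluated before any of its
tokens are placed), then each token to the argmax of its conditional,
counts updating as they are placed; a sampling-based initializer is
available behind a flag.

Shard-pooled sweeps implement the approximate-distributed scheme on one
machine: each shard sweeps its own documents against a private copy of
the global tables (stale within the sweep with respect to other
shards), and afterwards the global tables are rebuilt by exact recount.
With one shard this is bit-identical to a plain sweep. Point estimates
are posterior means from the final sample's counts; averaging over
post-burn-in samples is available but final-state estimates are the
default, matching single-assignment trend usage.

## Synthetic data

The generator samples the generative story exactly as written, with
known η, α_i, π capability (γ), φ_A, φ_T, φ_B, λ, and per-ailment
aspect probabilities (default 0.7/0.2/0.1 general/symptom/treatment).
`TrueParams.well_separated` builds block-structured worlds: each
ailment and each topic owns a disjoint vocabulary block carrying 95% of
its mass (aspects concentrating on different thirds of the ailment
block), the background spreading over the remainder. Optional planted
per-ailment temporal or regional intensities modulate *P(a | bin)* and
stamp metadata, giving ground truth for the trend layer.

What the generator deliberately does not emulate: real orthography,
hashtags, phrase-level (multi-token) keyphrase matches, document-length
variation, vocabulary burstiness, or label noise in aspects. Passing
recovery tests therefore demonstrate the *inference machinery* is
correct and consistent, not that real tweets are this separable.

Evaluation resolves label switching by optimal assignment
(`scipy.optimize.linear_sum_assignment`) on pairwise L1 distances,
verified against exhaustive permutation search.

### Experiment sizes and conditions

The reference experiments (`atam.experiments`, also driven by
`scripts/acceptance.py`) use these problem sizes, chosen so the battery
runs in minutes on one core while each check retains statistical power:

- **Exact-posterior agreement**: A = Z = 2, W = 4, three single-token
  documents with fixed mixed aspects and informative prior means
  (s = 8); 512 ATAM configurations (81 for LDA-bg), 2,000 burn-in +
  200,000 retained sweeps. The instance is deliberately small and
  concentrated: the Monte-Carlo noise floor of total variation over K
  configurations scales like Σ_k √(p_k/n), which for a diffuse
  2,048-configuration posterior already approaches the 0.02 acceptance
  threshold at n = 200,000 even for a perfect sampler.
- **Recovery**: A = Z = 3, W = 200, D = 2,000, N = 15, priors built
  from 3,000-token synthetic reference texts at s = 200, 2,000 sweeps
  with interleaved optimization. The generating noise level is λ = 0.5:
  at the inference default λ = 0.2 with N = 15, roughly a third of
  documents contain no ailment token at all, which caps document-level
  accuracy below 0.8 regardless of sampler quality; 50% background
  keeps the task hard but identifiable.
- **Trend recovery**: 20 weekly bins × 5,000 documents of 10 tokens,
  A = 3, Z = 2, W = 150, a sinusoidal intensity (amplitude 0.8) planted
  on one ailment, 100 sweeps.
- **Hyperparameter recovery**: 10,000 groups × 100 tokens at
  s_true = 50, W = 20; α on 4,000 two-dimensional count vectors.

## Trend layer

Rates are tweet-level: *P(a = i | bin)* = fraction of the bin's
documents whose final-sample ailment is *i*; documents lacking the
needed metadata are excluded from numerator and denominator and the
exclusion logged. Weeks start on Sunday (surveillance-week convention;
configurable); months are calendar months; regions are the documents'
region codes. Keyword baselines count document *presence* of the
keyword, tokenized with the corpus tokenizer. Correlation is sample
Pearson over the bins common to both series (scipy), standardization is
z-scoring with sample (n − 1) standard deviation; both are checked
against textbook-formula reimplementations at 1e-12. LDA documents are
assigned the topic with the plurality of non-background tokens, ties to
the lowest index, all-background documents unassigned and excluded.

## Known limitations

- The sampler is single-threaded; shard pooling approximates
  parallelism but runs shards sequentially in-process.
- Informative priors assume the reference-corpus vocabulary reasonably
  overlaps the target corpus; the 0.01 pseudo-count smoothing only
  prevents hard zeros, it cannot make an unrelated reference corpus
  informative.
- Hyperparameter optimization of *s_i* can drift far from its
  initialization when the prior mean is misspecified — by design (the
  data should win), but it means *s_i* is not interpretable as a fixed
  confidence.
- Trend correlation significance tests for dependent correlations are
  not implemented; only the correlation machinery itself is.
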