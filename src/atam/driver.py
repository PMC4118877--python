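"""Training orchestration: incremental schedule, shard pooling, checkpoints.

Training feeds data to the sampler in increments (10% steps by default):
a fraction t of the documents is sampled for a share of the iterations
proportional to 1/t, so more iterations are spent on less data.  When an
increment activates new documents, their latent variables are
initialized greedily to the argmax of the current conditionals.
Per-sweep randomness is derived from (seed, sweep index), so a run can
be checkpointed and resumed bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import _kernels as K
from .corpus import EncodedCorpus
from .hyperopt import HyperoptSchedule, optimize_atam_hypers
from .model import (ATAMHypers, LatentState, SufficientStats, gibbs_sweep,
                    init_state, joint_log_likelihood)
from .priors import AilmentPriorSet, ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSchedule",
    "make_schedule",
    "extend_data",
    "pooled_sweep",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "Checkpoint",
]


@dataclasses.dataclass
class TrainingSchedule:
    fractions: list[float]   # non-decreasing, ends at 1.0
    sweeps: list[int]        # positive, non-increasing, sums to total
    total: int

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.sweeps):
            raise ValueError("fractions and sweeps must align")
        if self.fractions != sorted(self.fractions) or self.fractions[-1] != 1.0:
            raise ValueError("fractions must be non-decreasing and end at 1.0")
        if any(s <= 0 for s in self.sweeps):
            raise ValueError("sweep counts must be positive")
        if sum(self.sweeps) != self.total:
            raise ValueError("sweep counts must sum to the total")


def make_schedule(total_iters: int, num_increments: int = 10) -> TrainingSchedule:
    """Allocate sweeps across data fractions t = 1/L, 2/L, ..., 1.

    Sweeps at fraction t are proportional to 1/t (at least one each),
    so smaller fractions receive more sweeps; any rounding surplus or
    deficit is absorbed by the smallest fraction, which keeps the
    allocation non-increasing in t.
    """
    if num_increments < 1 or total_iters < num_increments:
        raise ValueError("need total_iters >= num_increments >= 1")
    fractions = [(k + 1) / num_increments for k in range(num_increments)]
    weights = np.array([1.0 / t for t in fractions])
    ideal = total_iters * weights / weights.sum()
    sweeps = np.maximum(np.floor(ideal).astype(int), 1)
    sweeps[0] += total_iters - int(sweeps.sum())
    if num_increments > 1 and sweeps[0] < sweeps[1]:
        # only possible for tiny totals; flatten to an even split
        base = total_iters // num_increments
        sweeps = np.full(num_increments, base, dtype=int)
        sweeps[0] += total_iters - base * num_increments
    return TrainingSchedule(fractions=fractions,
                            sweeps=[int(s) for s in sweeps],
                            total=total_iters)


def extend_data(corpus: EncodedCorpus, state: LatentState,
                stats: SufficientStats, hypers: ATAMHypers,
                new_active: int, greedy: bool = True,
                rng=None) -> None:
    """Activate documents [num_active, new_active), in place.

    Each new document's ailment and token states are set to the argmax of
    the current conditionals (documents processed in order, counts updated
    as they are placed).  With greedy=False the same conditionals are
    sampled instead.
    """
    if new_active < state.num_active:
        raise ValueError("cannot deactivate documents")
    if new_active > corpus.num_docs:
        raise ValueError("new_active exceeds the corpus")
    if new_active == state.num_active:
        return
    docs = np.arange(state.num_active, new_active, dtype=np.int64)
    if greedy:
        K.atam_greedy_assign(docs, corpus.doc_ptr, corpus.words, corpus.aspects,
                             state.doc_ailment, state.token_state,
                             stats.n_ail, stats.n_doc_topic, stats.n_topic_word,
                             stats.n_topic_sum, stats.n_aaw, stats.n_aas,
                             stats.n_bgw, stats.n_bgs, stats.n_doc_ail,
                             stats.n_doc_top, hypers.alpha, hypers.alpha_sum,
                             hypers.s, hypers.m, hypers.sigma,
                             hypers.gamma_ail, hypers.gamma_top, hypers.lam,
                             hypers.beta_flat, corpus.num_words)
        state.num_active = new_active
    else:
        rng = np.random.default_rng(rng)
        # uniform placement followed by one constrained sweep over new docs
        state.doc_ailment[docs] = rng.integers(0, hypers.num_ailments,
                                               size=len(docs))
        t0 = int(corpus.doc_ptr[state.num_active])
        t1 = int(corpus.doc_ptr[new_active])
        state.token_state[t0:t1] = rng.integers(0, hypers.num_topics + 2,
                                                size=t1 - t0)
        state.num_active = new_active
        fresh = SufficientStats.from_state(corpus, state, hypers.num_ailments,
                                           hypers.num_topics)
        for f in dataclasses.fields(stats):
            getattr(stats, f.name)[...] = getattr(fresh, f.name)
        gibbs_sweep(corpus, state, stats, hypers, rng, docs=docs)
        return
    # n_doc_* tables for the new docs were updated by the kernel already


def pooled_sweep(corpus: EncodedCorpus, state: LatentState,
                 stats: SufficientStats, hypers: ATAMHypers,
                 shards: list[np.ndarray], seed) -> None:
    """Approximate-distributed sweep: shards sample against stale globals.

    Documents are partitioned into shards.  Each shard sweeps its own
    documents against a private copy of the global count tables (stale
    with respect to the other shards within the sweep); afterwards the
    global tables are rebuilt by pooling (an exact recount over all
    shards).  Per-document tables are owned by their shard and are not
    altered by pooling.  With a single shard this is bit-identical to
    :func:`atam.model.gibbs_sweep` with the same seed.
    """
    flat = np.concatenate([np.asarray(s, dtype=np.int64) for s in shards]) \
        if shards else np.empty(0, np.int64)
    if len(np.unique(flat)) != len(flat):
        raise ValueError("shards overlap")
    if len(shards) == 1:
        gibbs_sweep(corpus, state, stats, hypers, np.random.default_rng(seed),
                    docs=np.asarray(shards[0], dtype=np.int64))
        return
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(len(shards))]
    for shard, rng in zip(shards, rngs):
        shard = np.asarray(shard, dtype=np.int64)
        if shard.size == 0:
            continue
        local = stats.copy()
        gibbs_sweep(corpus, state, local, hypers, rng, docs=shard)
    pooled = SufficientStats.from_state(corpus, state, hypers.num_ailments,
                                        hypers.num_topics)
    for f in dataclasses.fields(stats):
        getattr(stats, f.name)[...] = getattr(pooled, f.name)


@dataclasses.dataclass
class Checkpoint:
    config: ModelConfig
    hypers: ATAMHypers
    state: LatentState
    stats: SufficientStats
    iteration: int
    log: list[dict]


def _sweep_rng(seed: int, sweep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(sweep,)))


def train(corpus: EncodedCorpus, config: ModelConfig,
          prior_set: AilmentPriorSet | None = None,
          seed: int | None = None,
          checkpoint: Checkpoint | None = None,
          log_hook=None, stop_at: int | None = None) -> Checkpoint:
    """Full training run (or resume) on an encoded corpus.

    Builds the incremental schedule, initializes on the first increment,
    interleaves Gibbs sweeps with hyperparameter optimization, activates
    more documents at each increment boundary, and returns the final
    checkpoint.  Fully determined by (corpus, config, seed).
    """
    if seed is None:
        seed = config.seed
    if prior_set is None:
        prior_set = AilmentPriorSet.symmetric(config.num_ailments,
                                              corpus.num_words,
                                              precision=config.s_init)
    schedule = make_schedule(config.iterations, config.num_increments)
    boundaries = []
    start_sweeps = 0
    for frac, n_sweeps in zip(schedule.fractions, schedule.sweeps):
        n_active = max(1, int(round(frac * corpus.num_docs)))
        boundaries.append((start_sweeps, n_active))
        start_sweeps += n_sweeps

    if checkpoint is None:
        hypers = ATAMHypers.build(config.fixed_hypers(), config.alpha_set(),
                                  prior_set)
        # spawn key `iterations` never collides with a sweep index
        state, stats = init_state(corpus, hypers,
                                  _sweep_rng(seed, config.iterations),
                                  num_active=boundaries[0][1])
        iteration = 0
        log: list[dict] = []
    else:
        hypers, state, stats = checkpoint.hypers, checkpoint.state, checkpoint.stats
        iteration = checkpoint.iteration
        log = list(checkpoint.log)

    opt_schedule = HyperoptSchedule(interval=config.hyperopt_interval,
                                    passes=config.hyperopt_passes,
                                    min_group=config.hyperopt_min_group,
                                    enabled=config.optimize_hypers)

    last = config.iterations if stop_at is None else min(stop_at,
                                                         config.iterations)
    for sweep in range(iteration, last):
        for at_sweep, n_active in boundaries:
            if sweep == at_sweep and n_active > state.num_active:
                extend_data(corpus, state, stats, hypers, n_active)
                logger.info("sweep %d: extended to %d documents", sweep, n_active)
        gibbs_sweep(corpus, state, stats, hypers, _sweep_rng(seed, sweep))
        if opt_schedule.due(sweep):
            optimize_atam_hypers(state, stats, hypers, opt_schedule)
        if (config.log_likelihood_every
                and (sweep + 1) % config.log_likelihood_every == 0):
            ll = joint_log_likelihood(corpus, state, stats, hypers)
            entry = {"iteration": sweep + 1, "joint_log_likelihood": ll,
                     "num_active": state.num_active,
                     "mean_s": float(hypers.s.mean()),
                     "mean_alpha": float(hypers.alpha.mean())}
            log.append(entry)
            if log_hook is not None:
                log_hook(entry)
    return Checkpoint(config=config, hypers=hypers, state=state, stats=stats,
                      iteration=last, log=log)


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    """Single-archive checkpoint (npz) sufficient for bit-exact resume."""
    arrays = {
        "doc_ailment": ckpt.state.doc_ailment,
        "token_state": ckpt.state.token_state,
        "alpha": ckpt.hypers.alpha,
        "s": ckpt.hypers.s,
        "m": ckpt.hypers.m,
    }
    for f in dataclasses.fields(ckpt.stats):
        arrays["stats_" + f.name] = getattr(ckpt.stats, f.name)
    scalars = {
        "config": ckpt.config.to_dict(),
        "num_active": ckpt.state.num_active,
        "iteration": ckpt.iteration,
        "sigma": ckpt.hypers.sigma,
        "gamma_ail": ckpt.hypers.gamma_ail,
        "gamma_top": ckpt.hypers.gamma_top,
        "lam": ckpt.hypers.lam,
        "beta_flat": ckpt.hypers.beta_flat,
        "log": ckpt.log,
    }
    np.savez_compressed(path, meta=json.dumps(scalars), **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = ModelConfig.from_dict(meta["config"])
        hypers = ATAMHypers(alpha=data["alpha"], s=data["s"], m=data["m"],
                            sigma=meta["sigma"], gamma_ail=meta["gamma_ail"],
                            gamma_top=meta["gamma_top"], lam=meta["lam"],
                            beta_flat=meta["beta_flat"])
        state = LatentState(doc_ailment=data["doc_ailment"].copy(),
                            token_state=data["token_state"].copy(),
                            num_active=int(meta["num_active"]))
        stats = SufficientStats(**{f.name: data["stats_" + f.name].copy()
                                   for f in dataclasses.fields(SufficientStats)})
    return Checkpoint(config=config, hypers=hypers, state=state, stats=stats,
                      iteration=int(meta["iteration"]), log=meta["log"])
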