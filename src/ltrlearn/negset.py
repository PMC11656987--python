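"""LTR-negative training-set construction.

A useful negative set mixes three classes of non-LTR sequence:

* uniform-random DNA (trivially separable composition),
* genomic-like windows sampled from non-LTR regions of real or simulated
  contigs (realistic base composition and patchiness),
* order-2 Markov resamples of the LTR set itself -- sequences that share
  LTR 3-mer composition but lack the spatial organization (edges, TATA,
  positioned motifs) that defines an LTR.  Markov models are trained per
  similarity cluster of the LTR set so that compositional diversity is
  preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ALPHABET, LabeledSequence

_BASES = np.array(list(ALPHABET))


@dataclass
class MarkovModel:
    """Fixed-order Markov chain over A,C,G,T.

    ``transition`` maps an order-length context string to 4 next-base
    probabilities (A,C,G,T); ``initial`` is the distribution of sequence
    prefixes of length ``order``.  Unseen contexts fall back to the
    pseudocount-smoothed uniform distribution.
    """

    order: int = 2
    transition: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        for ctx, probs in self.transition.items():
            if not np.isclose(np.sum(probs), 1.0, atol=1e-9):
                raise ValueError(f"transition probabilities for context {ctx!r} do not sum to 1")
        if self.initial and not np.isclose(sum(self.initial.values()), 1.0, atol=1e-9):
            raise ValueError("initial distribution does not sum to 1")

    def transition_probs(self, context: str) -> np.ndarray:
        probs = self.transition.get(context)
        if probs is None:
            return np.full(4, 0.25)
        return np.asarray(probs)


def train_markov(seqs, order: int = 2, pseudocount: float = 0.5) -> MarkovModel:
    """Estimate a Markov chain from sequences.

    transition(c -> b) = (count(cb) + pseudocount) / (count(c.) + 4*pseudocount);
    the initial distribution is the empirical distribution of each
    sequence's first ``order`` bases.  N-containing windows are skipped.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    usable = [s.sequence if isinstance(s, LabeledSequence) else str(s) for s in seqs]
    usable = [s for s in usable if len(s) > order]
    if not usable:
        raise ValueError(f"no sequence longer than order={order}")
    context_counts: dict[str, np.ndarray] = {}
    initial_counts: dict[str, int] = {}
    for s in usable:
        prefix = s[:order]
        if "N" not in prefix:
            initial_counts[prefix] = initial_counts.get(prefix, 0) + 1
        for i in range(len(s) - order):
            window = s[i : i + order + 1]
            if "N" in window:
                continue
            ctx, nxt = window[:order], window[order]
            if ctx not in context_counts:
                context_counts[ctx] = np.zeros(4)
            context_counts[ctx][ALPHABET.index(nxt)] += 1
    transition = {}
    for ctx, counts in context_counts.items():
        smoothed = counts + pseudocount
        transition[ctx] = smoothed / smoothed.sum()
    total = sum(initial_counts.values())
    initial = {ctx: c / total for ctx, c in initial_counts.items()}
    return MarkovModel(order=order, transition=transition, initial=initial, pseudocount=pseudocount)


def generate_markov(model: MarkovModel, length: int, seed: int | np.random.Generator = 0) -> str:
    """Sample one sequence from the chain; deterministic under seed."""
    if length <= model.order:
        raise ValueError(f"length must exceed the model order ({model.order})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model.initial:
        contexts = sorted(model.initial)
        probs = np.array([model.initial[c] for c in contexts])
        start = contexts[rng.choice(len(contexts), p=probs / probs.sum())]
    else:
        start = "".join(rng.choice(_BASES, size=model.order))
    out = list(start)
    # cumulative transition rows cached per context; inverse-CDF sampling
    cum_cache: dict[str, np.ndarray] = {}
    draws = rng.random(length - model.order)
    for step in range(length - model.order):
        ctx = "".join(out[-model.order :])
        cum = cum_cache.get(ctx)
        if cum is None:
            cum = np.cumsum(model.transition_probs(ctx))
            cum_cache[ctx] = cum
        out.append(ALPHABET[int(np.searchsorted(cum, draws[step] * cum[-1]))])
    return "".join(out)


def sample_genomic_windows(
    genome_seqs,
    exclude: list[tuple[str, int, int]] | None = None,
    n: int = 10,
    length_sampler=None,
    seed: int | np.random.Generator = 0,
    max_attempts_per_window: int = 200,
) -> list[LabeledSequence]:
    """Sample n windows from contigs, avoiding excluded intervals.

    ``exclude`` holds (contig id, start, end) in 0-based half-open
    coordinates (e.g. annotated LTR regions).  Window lengths come from
    ``length_sampler(rng)`` (default: uniform 100-1000).  Rejection
    sampling; raises RuntimeError when the exclusions leave no room.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length_sampler is None:
        length_sampler = lambda r: int(r.integers(100, 1001))
    contigs = [
        (s.id, s.sequence) if isinstance(s, LabeledSequence) else (f"contig_{i}", str(s))
        for i, s in enumerate(genome_seqs)
    ]
    excluded: dict[str, list[tuple[int, int]]] = {}
    for cid, start, end in exclude or []:
        excluded.setdefault(cid, []).append((start, end))
    out = []
    for w in range(n):
        for _ in range(max_attempts_per_window):
            cid, seq = contigs[rng.integers(len(contigs))]
            length = int(length_sampler(rng))
            if length > len(seq):
                continue
            start = int(rng.integers(0, len(seq) - length + 1))
            end = start + length
            if any(start < e and s < end for (s, e) in excluded.get(cid, [])):
                continue
            out.append(
                LabeledSequence(id=f"{cid}:{start}-{end}", sequence=seq[start:end], is_ltr=False)
            )
            break
        else:
            raise RuntimeError(
                f"could not place window {w + 1}/{n}: exclusions leave no admissible position"
            )
    return out


def random_uniform_sequences(
    n: int, length_sampler=None, seed: int | np.random.Generator = 0, prefix: str = "random"
) -> list[LabeledSequence]:
    """i.i.d. uniform ACGT sequences."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length_sampler is None:
        length_sampler = lambda r: int(r.integers(100, 1001))
    out = []
    for i in range(n):
        length = int(length_sampler(rng))
        out.append(
            LabeledSequence(
                id=f"{prefix}_{i}",
                sequence="".join(rng.choice(_BASES, size=length)),
                is_ltr=False,
            )
        )
    return out


def compose_negative_set(
    ltrs,
    genome_seqs=None,
    proportions: dict | None = None,
    cluster_threshold: float = 0.70,
    n_total: int = 300,
    markov_order: int = 2,
    pseudocount: float = 0.5,
    seed: int = 0,
    exclude=None,
) -> tuple[list[LabeledSequence], dict]:
    """Build the mixed negative set; returns (negatives, per-class counts).

    The Markov share clusters the LTR set at ``cluster_threshold`` (low,
    to create large clusters of loosely similar sequences), trains an
    order-``markov_order`` chain per cluster, and samples sequences whose
    lengths follow the cluster's own length distribution.
    """
    proportions = proportions or {"genomic": 1 / 3, "random": 1 / 3, "markov": 1 / 3}
    unknown = set(proportions) - {"genomic", "random", "markov"}
    if unknown:
        raise ValueError(f"unknown negative classes: {sorted(unknown)}")
    if not np.isclose(sum(proportions.values()), 1.0, atol=1e-9):
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    n_by_class = {k: int(round(v * n_total)) for k, v in proportions.items()}
    # rounding drift goes to the largest share
    drift = n_total - sum(n_by_class.values())
    if drift and n_by_class:
        n_by_class[max(n_by_class, key=n_by_class.get)] += drift

    negatives: list[LabeledSequence] = []
    counts: dict[str, int] = {}

    n_random = n_by_class.get("random", 0)
    if n_random:
        negatives.extend(random_uniform_sequences(n_random, seed=rng, prefix="neg_random"))
        counts["random"] = n_random

    n_genomic = n_by_class.get("genomic", 0)
    if n_genomic:
        if not genome_seqs:
            raise ValueError("genomic share requested but no genome sequences supplied")
        windows = sample_genomic_windows(genome_seqs, exclude=exclude, n=n_genomic, seed=rng)
        for i, w in enumerate(windows):
            w.id = f"neg_genomic_{i}|{w.id}"
        negatives.extend(windows)
        counts["genomic"] = n_genomic

    n_markov = n_by_class.get("markov", 0)
    if n_markov:
        from .curation import greedy_identity_cluster

        assignment = greedy_identity_cluster(list(ltrs), threshold=cluster_threshold)
        clusters = assignment.clusters
        by_id = {s.id: s for s in ltrs}
        models = []
        for rep, members in clusters:
            member_seqs = [by_id[m] for m in members]
            lengths = [len(s) for s in member_seqs]
            models.append(
                (train_markov(member_seqs, order=markov_order, pseudocount=pseudocount), lengths, len(members))
            )
        weights = np.array([m[2] for m in models], dtype=float)
        weights /= weights.sum()
        for i in range(n_markov):
            model, lengths, _ = models[rng.choice(len(models), p=weights)]
            length = int(lengths[rng.integers(len(lengths))])
            length = max(length, markov_order + 1)
            negatives.append(
                LabeledSequence(
                    id=f"neg_markov_{i}", sequence=generate_markov(model, length, rng), is_ltr=False
                )
            )
        counts["markov"] = n_markov

    return negatives, counts
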