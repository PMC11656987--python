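"""Dataset curation: redundancy reduction, solo-LTR screening, splits.

Training on near-duplicate LTRs inflates apparent accuracy, so the LTR
set is reduced with CD-HIT-style greedy incremental clustering: sequences
are sorted by length (descending) and each either joins the first cluster
whose representative it matches at the identity threshold, or founds a new
cluster.  Identity is matches / alignment columns of a banded global
alignment (edlib).  The negative set is additionally screened against the
LTR database so that orphaned solo-LTRs cannot leak into the negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import LabeledSequence


@dataclass
class ClusterAssignment:
    """Greedy identity clustering result.

    ``clusters`` is a list of (representative id, member ids); every input
    id appears in exactly one cluster and each member matches its
    representative at >= ``threshold`` identity.
    """

    threshold: float
    clusters: list[tuple[str, list[str]]]
    sequences: dict[str, LabeledSequence] = field(default_factory=dict, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> list[str]:
        return [m for _, members in self.clusters for m in members]


@dataclass
class SplitSpec:
    """Stratified train/validation/test split specification."""

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    stratify_by: str = "is_ltr"

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions) or not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")


def _cigar_identity(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended cigar."""
    matches = alen = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            alen += n
            if ch == "=":
                matches += n
    return matches, alen


def pairwise_identity(a: str, b: str, min_identity: float | None = None) -> float:
    """Global-alignment identity = matches / alignment length.

    With ``min_identity`` the alignment is banded via an edit-distance
    bound: identity >= t implies edit distance <= (1-t)(|a|+|b|), so
    pairs beyond the band report identity 0.0 without a full alignment.
    """
    k = -1
    if min_identity is not None:
        k = int((1.0 - min_identity) * (len(a) + len(b))) + 1
    res = edlib.align(a, b, mode="NW", task="path", k=k)
    if res["editDistance"] < 0:
        return 0.0
    matches, alen = _cigar_identity(res["cigar"])
    return matches / alen if alen else 0.0


def _kmer_profile(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def greedy_identity_cluster(
    seqs: list[LabeledSequence], threshold: float, word_size: int = 6
) -> ClusterAssignment:
    """CD-HIT-style greedy incremental clustering at an identity threshold.

    Candidate pairs sharing no ``word_size``-mer are rejected before
    alignment (the word screen).  The representative of each cluster is
    its longest member (ties broken by lexicographic id), which under the
    length-descending processing order is always the founder.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0.5, 1.0], got {threshold}")
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.id))
    reps: list[LabeledSequence] = []
    rep_words: list[set[str]] = []
    clusters: list[list[str]] = []
    for seq in ordered:
        words = _kmer_profile(seq.sequence, word_size)
        placed = False
        for j, rep in enumerate(reps):
            if words and rep_words[j] and not (words & rep_words[j]):
                continue
            if pairwise_identity(seq.sequence, rep.sequence, min_identity=threshold) >= threshold:
                clusters[j].append(seq.id)
                placed = True
                break
        if not placed:
            reps.append(seq)
            rep_words.append(words)
            clusters.append([seq.id])
    return ClusterAssignment(
        threshold=threshold,
        clusters=[(rep.id, members) for rep, members in zip(reps, clusters)],
        sequences={s.id: s for s in seqs},
    )


def select_representatives(assignment: ClusterAssignment) -> list[LabeledSequence]:
    """One sequence per cluster: the longest member, ties by id order."""
    out = []
    for _, members in assignment.clusters:
        chosen = sorted(members, key=lambda m: (-len(assignment.sequences[m].sequence), m))[0]
        out.append(assignment.sequences[chosen])
    return out


def solo_ltr_screen(
    negatives: list[LabeledSequence],
    ltr_db: list[LabeledSequence],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    word_size: int = 11,
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Remove negatives that align to a database LTR (solo-LTR candidates).

    A negative is removed when an infix alignment of some LTR reaches
    ``min_identity`` matches over ``min_coverage`` of the LTR length.
    The 0.8/0.8 default echoes the 80/80 family-definition convention.
    A shared-``word_size``-mer screen skips hopeless pairs before any
    alignment is computed.
    """
    if not ltr_db:
        return list(negatives), []
    ltr_words = [(ltr, _kmer_profile(ltr.sequence, word_size)) for ltr in ltr_db]
    kept, removed = [], []
    for neg in negatives:
        neg_words = _kmer_profile(neg.sequence, word_size)
        hit = False
        for ltr, words in ltr_words:
            if words and not (neg_words & words):
                continue
            L = len(ltr.sequence)
            needed = min_identity * min_coverage * L
            k = L - int(np.ceil(needed)) + 1
            res = edlib.align(ltr.sequence, neg.sequence, mode="HW", task="path", k=k)
            if res["editDistance"] < 0:
                continue
            matches, _ = _cigar_identity(res["cigar"])
            if matches >= needed:
                hit = True
                break
        (removed if hit else kept).append(neg)
    return kept, removed


def split_dataset(
    seqs: list[LabeledSequence], spec: SplitSpec
) -> tuple[list[LabeledSequence], list[LabeledSequence], list[LabeledSequence]]:
    """Stratified, reproducible train/validation/test split.

    Per-stratum counts follow the target fractions by largest-remainder
    apportionment, so each split size deviates from its target by less
    than one sequence per stratum.  Strata smaller than 3 go wholly to
    the training split (with a warning).
    """
    def label_of(s: LabeledSequence):
        value = getattr(s, spec.stratify_by, None)
        if value is None:
            raise ValueError(f"sequence {s.id!r} lacks stratification label {spec.stratify_by!r}")
        return value

    strata: dict = {}
    for s in seqs:
        strata.setdefault(label_of(s), []).append(s)
    rng = np.random.default_rng(spec.seed)
    splits: tuple[list, list, list] = ([], [], [])
    for label in sorted(strata, key=str):
        group = strata[label]
        if len(group) < 3:
            warnings.warn(f"stratum {label!r} has {len(group)} < 3 members; assigned to train")
            splits[0].extend(group)
            continue
        order = rng.permutation(len(group))
        targets = [f * len(group) for f in spec.fractions]
        counts = [int(t) for t in targets]
        remainders = sorted(range(3), key=lambda i: targets[i] - counts[i], reverse=True)
        for i in remainders[: len(group) - sum(counts)]:
            counts[i] += 1
        offset = 0
        for split_idx, c in enumerate(counts):
            splits[split_idx].extend(group[i] for i in order[offset : offset + c])
            offset += c
    return splits


def cluster_report(assignment: ClusterAssignment) -> "object":
    """TSV-ready table: one row per member with its cluster representative."""
    import pandas as pd

    rows = [
        {"cluster": ci, "representative": rep, "member": m, "length": len(assignment.sequences[m])}
        for ci, (rep, members) in enumerate(assignment.clusters)
        for m in members
    ]
    return pd.DataFrame(rows)
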