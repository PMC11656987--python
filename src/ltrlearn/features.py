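"""Featurization of LTR sequences.

Three parallel tracks feed the three model families:

* PWM scanning of a motif panel (e.g. JASPAR plant TFBS) into per-sequence
  occurrence counts, optionally TF-IDF weighted -- the input of the
  gradient-boosted track.  Column *i* of the resulting matrix is the
  feature vector F_i referred to throughout the explainability layer.
* One-hot encoding with zero-padding and masking -- the input of the
  CNN-LSTM track.
* Overlapping k-mer tokenization -- the input of the embedding track.

Plus the classical k-mer Jaccard similarity used for composition-level
set comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import TfidfTransformer

from .seqio import LabeledSequence, PWMotif

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _as_str(seq) -> str:
    return seq.sequence if isinstance(seq, LabeledSequence) else str(seq)


def _seq_ids(seqs) -> list[str]:
    return [s.id if isinstance(s, LabeledSequence) else f"seq_{i}" for i, s in enumerate(seqs)]


@dataclass
class FeatureMatrix:
    """Sequences x motifs table of occurrence counts or TF-IDF weights."""

    data: pd.DataFrame
    kind: str = "counts"  # "counts" | "tfidf"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "tfidf"):
            raise ValueError(f"unknown FeatureMatrix kind {self.kind!r}")
        if self.kind == "tfidf" and len(self.data):
            norms = np.linalg.norm(self.data.to_numpy(), axis=1)
            nonzero = norms > 0
            if not np.allclose(norms[nonzero], 1.0, atol=1e-9):
                raise ValueError("tfidf rows must be L2-normalized")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sequence_id")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "counts") -> "FeatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="sequence_id"), kind=kind)


@dataclass
class OneHotBatch:
    """Fixed-length one-hot batch with a real-vs-padded position mask."""

    array: np.ndarray  # (n, L_max, 4) float32
    mask: np.ndarray  # (n, L_max) bool
    ids: list[str]

    @property
    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)


@dataclass
class TokenSequence:
    """Overlapping k-mer tokens of one sequence, 5'->3'."""

    k: int
    tokens: list[str]


# ---------------------------------------------------------------------------
# PWM scanning


def pwm_score_positions(seq, motif: PWMotif, background=None, pseudocount: float = 0.8) -> np.ndarray:
    """Forward-strand log-odds score at every window start (empty if L < width).

    N bases contribute the per-column minimum so that ambiguity never
    creates a hit.
    """
    s = _as_str(seq)
    lo = motif.log_odds(background=background, pseudocount=pseudocount)
    w = motif.width
    if len(s) < w:
        return np.zeros(0)
    lo5 = np.vstack([lo, lo.min(axis=0)])  # row 4 scores N
    idx = np.fromiter((_BASE_INDEX[b] for b in s), dtype=np.int8, count=len(s))
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return lo5[windows, np.arange(w)].sum(axis=1)


def _score_threshold(motif: PWMotif, rel_threshold: float, background, pseudocount: float) -> float:
    lo = motif.log_odds(background=background, pseudocount=pseudocount)
    lo_min, lo_max = lo.min(axis=0).sum(), lo.max(axis=0).sum()
    return lo_min + rel_threshold * (lo_max - lo_min)


def pwm_hit_positions(
    seq,
    motif: PWMotif,
    rel_threshold: float = 0.8,
    background=None,
    pseudocount: float = 0.8,
) -> np.ndarray:
    """0-based window starts whose score reaches the relative threshold."""
    scores = pwm_score_positions(seq, motif, background=background, pseudocount=pseudocount)
    if scores.size == 0:
        return np.zeros(0, dtype=int)
    thr = _score_threshold(motif, rel_threshold, background, pseudocount)
    return np.flatnonzero(scores >= thr)


class PwmMotifCounter(BaseEstimator, TransformerMixin):
    """sklearn transformer: DNA sequences -> motif occurrence count matrix.

    A window counts as an occurrence of a motif when its log-odds score
    reaches ``rel_threshold`` of the motif's attainable score range
    (min + rel_threshold * (max - min)).  Forward strand only by default;
    LTRs are orientation-defined.
    """

    def __init__(
        self,
        motifs: Sequence[PWMotif] | None = None,
        rel_threshold: float = 0.8,
        background: tuple = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 0.8,
        both_strands: bool = False,
    ):
        self.motifs = motifs
        self.rel_threshold = rel_threshold
        self.background = background
        self.pseudocount = pseudocount
        self.both_strands = both_strands

    def fit(self, X, y=None):
        if not self.motifs:
            self.motif_names_ = []
        else:
            self.motif_names_ = [m.name for m in self.motifs]
        if not 0 < self.rel_threshold <= 1:
            raise ValueError("rel_threshold must be in (0, 1]")
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "motif_names_"):
            self.fit(X)
        motifs = list(self.motifs or [])
        counts = np.zeros((len(X), len(motifs)), dtype=float)
        # precompute per-motif scoring tables once; scoring itself is a
        # vectorized gather over sliding windows
        scan_plan = []
        for j, m in enumerate(motifs):
            variants = [m] + ([m.reverse_complement()] if self.both_strands else [])
            for v in variants:
                lo = v.log_odds(background=self.background, pseudocount=self.pseudocount)
                lo5 = np.vstack([lo, lo.min(axis=0)])
                thr = _score_threshold(v, self.rel_threshold, self.background, self.pseudocount)
                scan_plan.append((j, lo5, v.width, thr))
        for i, seq in enumerate(X):
            s = _as_str(seq)
            idx = np.fromiter((_BASE_INDEX[b] for b in s), dtype=np.int8, count=len(s))
            for j, lo5, w, thr in scan_plan:
                if len(s) < w:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(idx, w)
                scores = lo5[windows, np.arange(w)].sum(axis=1)
                counts[i, j] += int(np.count_nonzero(scores >= thr))
        return counts


def scan_pwm_counts(
    seqs,
    motifs: Sequence[PWMotif],
    rel_threshold: float = 0.8,
    background=(0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.8,
    both_strands: bool = False,
) -> FeatureMatrix:
    """Occurrence counts of every motif in every sequence (counts-kind)."""
    counter = PwmMotifCounter(
        motifs=list(motifs),
        rel_threshold=rel_threshold,
        background=background,
        pseudocount=pseudocount,
        both_strands=both_strands,
    ).fit(seqs)
    values = counter.transform(seqs)
    df = pd.DataFrame(values, index=_seq_ids(seqs), columns=[m.name for m in motifs])
    return FeatureMatrix(df, kind="counts")


def tfidf_transform(counts: FeatureMatrix) -> FeatureMatrix:
    """TF-IDF weighting of motif counts.

    idf(t) = ln((1+N)/(1+df(t))) + 1 with smooth document frequencies,
    followed by L2 row normalization; downweights ubiquitous, unspecific
    TFBS.  All-zero rows stay zero.
    """
    if counts.kind != "counts":
        raise ValueError("tfidf_transform expects a counts-kind FeatureMatrix")
    transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    values = transformer.fit_transform(counts.values).toarray()
    return FeatureMatrix(
        pd.DataFrame(values, index=counts.data.index, columns=counts.data.columns),
        kind="tfidf",
    )


# ---------------------------------------------------------------------------
# One-hot encoding


def one_hot_encode(seqs, L_max: int = 4000) -> OneHotBatch:
    """One-hot encode to a fixed length.

    N bases are deleted before encoding; sequences are truncated at the
    3' end (the 5'-most ``L_max`` bases are kept) and padded with all-zero
    rows at the 3' end.  The mask marks real positions.
    """
    if L_max <= 0:
        raise ValueError("L_max must be positive")
    n = len(seqs)
    array = np.zeros((n, L_max, 4), dtype=np.float32)
    mask = np.zeros((n, L_max), dtype=bool)
    ids = _seq_ids(seqs)
    for i, seq in enumerate(seqs):
        s = _as_str(seq).replace("N", "")
        if not s:
            warnings.warn(f"sequence {ids[i]!r} is all-N; encoded as an all-pad row")
            continue
        s = s[:L_max]
        idx = np.fromiter((_BASE_INDEX[b] for b in s), dtype=np.int8, count=len(s))
        array[i, np.arange(len(s)), idx] = 1.0
        mask[i, : len(s)] = True
    return OneHotBatch(array=array, mask=mask, ids=ids)


# ---------------------------------------------------------------------------
# k-mers


def kmer_tokenize(seq, k: int) -> TokenSequence:
    """Overlapping k-mers, stride 1, 5'->3'; empty when L < k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    s = _as_str(seq)
    return TokenSequence(k=k, tokens=[s[i : i + k] for i in range(len(s) - k + 1)])


def kmer_set(seqs: Iterable, k: int) -> set[str]:
    """Distinct ACGT-only k-mers pooled over a set of sequences."""
    out: set[str] = set()
    for seq in seqs:
        s = _as_str(seq)
        for i in range(len(s) - k + 1):
            token = s[i : i + k]
            if "N" not in token:
                out.add(token)
    return out


def jaccard_kmer(setA: Iterable, setB: Iterable, k: int = 6) -> float:
    """Jaccard index |A∩B| / |A∪B| of pooled distinct k-mer sets.

    Returns 0.0 when both sides are empty (convention).
    """
    a, b = kmer_set(setA, k), kmer_set(setB, k)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
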