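"""CNN filter-to-motif mapping and LTR edge tetramer analysis.

First-layer convolutional filters of a trained sequence network act as
soft motif detectors.  They are extracted as width x 4 weight matrices,
normalized with the exponential transform  S_hat = exp(lambda * S / max(S))
(lambda = 3), column-normalized into position probability matrices, and
matched against a reference motif set (export to MEME for an external
matcher, or the built-in correlation matcher).

The edge analysis tallies the terminal tetramers of LTR sequences.  LTRs
canonically start with TG and end with CA; apparent 1-bp annotation
shifts are corrected by assigning each observed (5', 3') tetramer pair to
a canonical pair when a single-base shift improves 5'/3' reverse-
complement complementarity and restores the TG..CA signature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import LabeledSequence, PWMotif

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# filters


@dataclass
class FilterMatrix:
    """A first-layer convolutional filter and its normalized form.

    ``raw`` is (width, 4) with channel order A,C,G,T; ``normalized`` is
    exp(lambda * raw / max(raw)), entries in (0, e^lambda].
    """

    name: str
    raw: np.ndarray
    normalized: np.ndarray | None = None
    lam: float = 3.0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != 4:
            raise ValueError("filter must have shape (width, 4)")

    @property
    def width(self) -> int:
        return int(self.raw.shape[0])

    def to_pwm(self) -> PWMotif:
        """Position probability matrix: per-position normalized S_hat."""
        if self.normalized is None:
            raise ValueError("normalize the filter first (normalize_filter)")
        probs = self.normalized / self.normalized.sum(axis=1, keepdims=True)
        return PWMotif(self.name, probs.T, kind="probabilities")


def extract_filters(handle) -> list[FilterMatrix]:
    """Raw first-layer filters of a fitted CNN-LSTM track."""
    clf = getattr(handle, "model", handle)
    net = getattr(clf, "net_", None)
    if net is None:
        raise TypeError("model is not a fitted CNN-LSTM track")
    return [FilterMatrix(f"filter_{i}", W) for i, W in enumerate(net.filter_matrices())]


def normalize_filter(filt, lam: float = 3.0) -> FilterMatrix:
    """Exponential filter normalization S_hat = exp(lambda * S / max(S)).

    ``max(S)`` is the global matrix maximum.  Filters whose maximum is
    not positive carry no preferred base and are rejected; shift such a
    filter by its maximum beforehand if a PWM is still wanted.
    """
    S = filt.raw if isinstance(filt, FilterMatrix) else np.asarray(filt, dtype=float)
    name = filt.name if isinstance(filt, FilterMatrix) else "filter"
    m = S.max()
    if m <= 0:
        raise ValueError("filter maximum must be positive (shift by max(S) first)")
    normalized = np.exp(lam * S / m)
    return FilterMatrix(name, S, normalized=normalized, lam=lam)


def match_motifs(queries, targets, min_overlap: int = 5) -> pd.DataFrame:
    """Correlation matcher: best-offset per-column Pearson r, both strands.

    For every query/target pair the score is the maximum over offsets and
    orientations of the mean per-column Pearson correlation across the
    overlapping columns (overlap >= ``min_overlap``).  Columns with zero
    variance on either side contribute 0.  Scores are raw correlations,
    not E-values; E-value calibration belongs to an external matcher.
    """
    rows = []
    for q in queries:
        qm = q.to_probabilities().matrix if q.kind == "counts" else q.matrix
        for t in targets:
            tm = t.to_probabilities().matrix if t.kind == "counts" else t.matrix
            best = None
            for orientation, tmat in (("+", tm), ("-", tm[::-1, ::-1])):
                wq, wt = qm.shape[1], tmat.shape[1]
                for offset in range(-(wq - min_overlap), wt - min_overlap + 1):
                    lo_q = max(0, -offset)
                    lo_t = max(0, offset)
                    ov = min(wq - lo_q, wt - lo_t)
                    if ov < min_overlap:
                        continue
                    cols = []
                    for i in range(ov):
                        a = qm[:, lo_q + i]
                        b = tmat[:, lo_t + i]
                        if a.std() == 0 or b.std() == 0:
                            cols.append(0.0)
                        else:
                            cols.append(float(np.corrcoef(a, b)[0, 1]))
                    score = float(np.mean(cols))
                    if best is None or score > best[0]:
                        best = (score, offset, orientation)
            if best is not None:
                rows.append({"query": q.name, "target": t.name, "offset": best[1],
                             "orientation": best[2], "score": best[0]})
    df = pd.DataFrame(rows, columns=["query", "target", "offset", "orientation", "score"])
    return df.sort_values(["query", "score"], ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# edge tetramers


def edge_tetramers(seqs) -> tuple[Counter, int]:
    """Tally of (first 4 bases, last 4 bases) pairs; returns (tally, skipped).

    Sequences shorter than 8 bases cannot contribute both tetramers and
    are skipped; their count is the second return value.
    """
    tally: Counter = Counter()
    skipped = 0
    for seq in seqs:
        s = seq.sequence if isinstance(seq, LabeledSequence) else str(seq)
        if len(s) < 8:
            skipped += 1
            continue
        tally[(s[:4], s[-4:])] += 1
    return tally, skipped


def complementarity(t5: str, t3: str) -> int:
    """Positions (0..4) at which t3 equals the reverse complement of t5."""
    for t in (t5, t3):
        if len(t) != 4 or set(t) - set("ACGT"):
            raise ValueError(f"tetramer must be 4 bases over ACGT, got {t!r}")
    rc = revcomp(t5)
    return sum(a == b for a, b in zip(rc, t3))


def _is_canonical(t5: str, t3: str) -> bool:
    return t5.startswith("TG") and t3.endswith("CA")


def assign_canonical(pair: tuple[str, str]) -> tuple[tuple[str, str], bool]:
    """Assign an edge pair to its canonical form via 1-bp shift correction.

    A 5' tetramer shifted 1 bp into the element lost the leading T of the
    canonical TG start (candidate: prepend T, drop the last base); a 3'
    tetramer shifted 1 bp lost the trailing A of the CA end (candidate:
    drop the first base, append A).  Among the identity and the three
    shift candidates, the one restoring the TG..CA signature with the
    highest complementarity wins; a shift is only accepted when it does
    not decrease complementarity, and the identity is preferred on ties.
    """
    t5, t3 = pair
    ident_comp = complementarity(t5, t3)
    candidates = [
        (t5, t3),
        ("T" + t5[:3], t3),
        (t5, t3[1:] + "A"),
        ("T" + t5[:3], t3[1:] + "A"),
    ]
    best, best_key = (t5, t3), (_is_canonical(t5, t3), ident_comp)
    for cand in candidates[1:]:
        comp = complementarity(*cand)
        if comp < ident_comp:
            continue
        key = (_is_canonical(*cand), comp)
        if key > best_key:
            best, best_key = cand, key
    return best, best != (t5, t3)


@dataclass
class EdgeSummary:
    """Canonical assignment of the most frequent edge tetramer pairs."""

    pairs: pd.DataFrame  # observed pair, count, canonical pair, shifted
    totals: dict  # canonical pair -> summed count
    percentages: dict  # canonical pair -> rounded percent of summarized counts

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def summarize_edges(tally, top_n: int = 5) -> EdgeSummary:
    """Assign the ``top_n`` most frequent pairs to canonical pairs.

    Totals conserve the summarized counts; percentages are over the
    summarized (top_n) counts, rounded to the nearest integer.
    """
    if isinstance(tally, tuple):
        tally = tally[0]
    if not tally:
        raise ValueError("empty tally")
    top = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    rows = []
    totals: dict = {}
    for (t5, t3), count in top:
        (c5, c3), shifted = assign_canonical((t5, t3))
        rows.append({"t5": t5, "t3": t3, "count": count,
                     "canonical_t5": c5, "canonical_t3": c3, "shifted": shifted})
        totals[(c5, c3)] = totals.get((c5, c3), 0) + count
    grand = sum(totals.values())
    percentages = {pair: int(round(100.0 * c / grand)) for pair, c in totals.items()}
    return EdgeSummary(pairs=pd.DataFrame(rows), totals=totals, percentages=percentages)
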