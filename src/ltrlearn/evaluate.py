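"""Metrics and model-comparison statistics.

Precision/recall/F1 reports (binary, or per-class one-vs-rest with
support-weighted averaging for the family task), stratified k-fold
assignment, the Wilcoxon signed-rank test used to compare fold scores
against a reported test score, and the Friedman test with Nemenyi
post-hoc analysis for comparing three model tracks over repeated folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold


class DegenerateInputError(ValueError):
    pass


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    averaging: str  # binary | weighted
    per_class: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.per_class.to_csv(path, sep="\t", index_label="class")


def compute_metrics(y_true, y_pred, averaging: str = "binary") -> MetricsReport:
    """Standard precision/recall/F1.

    Multiclass uses per-class one-vs-rest scores averaged with class
    support as weights (``averaging="weighted"``); macro averaging is a
    caller choice away via the per-class table.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if averaging == "binary":
        if len(classes) > 2:
            raise ValueError("binary averaging with more than 2 classes")
        pos = classes.max()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="binary", pos_label=pos, zero_division=0
            )
    elif averaging == "weighted":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="weighted", zero_division=0
            )
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pc, rc, fc, sup = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
    per_class = pd.DataFrame(
        {"precision": pc, "recall": rc, "f1": fc, "support": sup}, index=classes
    )
    return MetricsReport(float(p), float(r), float(f), averaging, per_class)


def stratified_kfold(labels, k: int, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per item; folds preserve class proportions."""
    y = np.asarray(list(labels))
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold
    return folds


def _exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum under random signs.

    Enumerates the distribution of W+ by dynamic programming over the
    (possibly tied, hence half-integer) ranks; the distribution is
    symmetric about n(n+1)/4, so the two-sided p doubles the lower tail
    of min(W+, W-).
    """
    scaled = np.round(ranks * 2).astype(int)  # tied ranks are half-integers
    total = scaled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w_min_scaled = int(round(2 * min(w_plus, ranks.sum() - w_plus)))
    return float(min(1.0, 2.0 * dist[: w_min_scaled + 1].sum()))


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped (Wilcoxon convention).  The statistic is
    min(W+, W-).  For n <= 25 the p-value comes from the exact sign-flip
    distribution (computed here so that tied ranks are handled exactly);
    above that, from the normal approximation with tie correction.
    Warns below 5 non-zero differences, where the minimal attainable
    two-sided p exceeds conventional levels.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    if nz.size < 5:
        warnings.warn(f"only {nz.size} non-zero differences; the test has little power")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    statistic = min(w_plus, w_minus)
    if nz.size <= 25:
        pvalue = _exact_signed_rank_pvalue(ranks, w_plus)
    else:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="approx")
        pvalue = float(res.pvalue)
    return statistic, pvalue


@dataclass
class FriedmanNemenyiResult:
    statistic: float
    pvalue: float
    mean_ranks: pd.Series
    nemenyi: pd.DataFrame | None  # pairwise p matrix; None when Friedman fails to reject
    alpha: float


def friedman_nemenyi(score_matrix, model_names=None, alpha: float = 0.05,
                     force_posthoc: bool = False) -> FriedmanNemenyiResult:
    """Friedman rank test over k datasets x m models, with Nemenyi post hoc.

    Ranks are computed within rows (average ranks on ties).  The Nemenyi
    pairwise p-values come from the studentized range distribution of the
    mean-rank differences, and are computed when the Friedman test
    rejects at ``alpha`` (or when forced).
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2:
        raise ValueError("score_matrix must be 2-D (datasets x models)")
    k, m = S.shape
    if m < 3 or k < 2:
        raise ValueError("need at least 3 models and 2 datasets")
    if np.all(S == S.flat[0]):
        raise DegenerateInputError("score matrix is constant; ranks are undefined")
    names = list(model_names) if model_names is not None else [f"model_{j}" for j in range(m)]
    ranks = np.apply_along_axis(stats.rankdata, 1, S)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=names)
    if np.allclose(S, S[:, [0]]):
        statistic, pvalue = 0.0, 1.0
    else:
        statistic, pvalue = stats.friedmanchisquare(*(S[:, j] for j in range(m)))
    nemenyi = None
    if force_posthoc or pvalue < alpha:
        scale = np.sqrt(m * (m + 1) / (12.0 * k))
        P = np.ones((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                q = abs(mean_ranks.iloc[i] - mean_ranks.iloc[j]) / scale
                p = float(stats.studentized_range.sf(q, m, np.inf))
                P[i, j] = P[j, i] = min(1.0, p)
        nemenyi = pd.DataFrame(P, index=names, columns=names)
    return FriedmanNemenyiResult(float(statistic), float(pvalue), mean_ranks, nemenyi, alpha)


def confusion_table(y_true, y_pred) -> pd.DataFrame:
    """Contingency table, rows = truth, columns = prediction."""
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    classes = np.unique(np.concatenate([y_true, y_pred]))
    table = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y_true, y_pred):
        table.loc[t, p] += 1
    return table
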