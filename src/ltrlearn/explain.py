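"""Explainability layer: Shapley attributions and their aggregations.

Three attribution routes cover the model tracks:

* :func:`tree_shap` -- exact interventional Shapley values for the
  gradient-boosted tree ensemble.  For a single tree leaf, the path
  conditions split features into those that must be present (satisfied by
  the explained instance x but not the background row z) and those that
  must be absent (satisfied by z but not x); the Shapley value of such a
  conjunction game has a closed form, so the per-leaf contributions sum
  to the exact attribution in polynomial time.  Additivity holds exactly:
  base value + attributions = the model margin.
* :func:`model_agnostic_shap` -- permutation-sampling Shapley estimate
  for any predict function (used for k-mer/token models).
* :func:`gradient_shap` -- expected-gradients attribution for the
  network track (gradient of the margin along interpolations between a
  background reference and the instance, times input difference).

Aggregations turn per-instance attributions into per-position importance
tracks (sum of squares over one-hot channels; mean over covering k-mers),
per-k-mer global importances (min-max scaled separately for the positive
and negative groups), anchor-centered matrices (start / TATA / TSS / end),
and assembled consensus motifs from overlapping high-importance k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .features import FeatureMatrix, OneHotBatch, one_hot_encode
from .seqio import PWMotif


@dataclass
class AttributionSet:
    """Per-instance attribution values aligned to a model's input."""

    kind: str  # "features" | "onehot" | "tokens"
    values: list
    base_value: float
    ids: list
    feature_names: list | None = None
    masks: list | None = None
    tokens: list | None = None

    def mean_abs_by_feature(self) -> pd.Series:
        if self.kind != "features":
            raise ValueError("mean_abs_by_feature applies to feature-kind attributions")
        arr = np.abs(np.stack(self.values)).mean(axis=0)
        return pd.Series(arr, index=self.feature_names).sort_values(ascending=False)


@dataclass
class ImportanceTrack:
    """Per-position importance for one sequence plus named anchors."""

    sequence_id: str
    values: np.ndarray
    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = len(self.values)
        self.anchors.setdefault("start", 0 if L else None)
        self.anchors.setdefault("end", L - 1 if L else None)


@dataclass
class KmerImportance:
    """Globally aggregated, group-wise min-max scaled k-mer scores.

    Positive-mean k-mers scale to [0, 1], negative-mean to [-1, 0]; the
    sign of every scaled score matches the sign of its raw mean.
    """

    scores: dict
    raw_means: dict

    def top(self, n: int = 20) -> list:
        return sorted(self.scores.items(), key=lambda kv: -abs(kv[1]))[:n]


# ---------------------------------------------------------------------------
# exact tree SHAP (interventional)


def _tree_leaves(tree) -> list:
    """DFS leaf enumeration: (leaf value, per-feature admissible interval)."""
    t = tree.tree_
    leaves = []

    def walk(node, bounds):
        if t.children_left[node] == -1:
            leaves.append((float(t.value[node].ravel()[0]), dict(bounds)))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        if lo <= thr:  # left: x[f] <= thr
            bounds[f] = (lo, min(hi, thr))
            walk(t.children_left[node], bounds)
            bounds[f] = (lo, hi)
        if hi > thr:  # right: x[f] > thr
            bounds[f] = (max(lo, thr), hi)
            walk(t.children_right[node], bounds)
            bounds[f] = (lo, hi)

    walk(0, {})
    return leaves


def _shapley_weight_tables(max_players: int):
    Wpos = np.zeros((max_players + 1, max_players + 1))
    Wneg = np.zeros((max_players + 1, max_players + 1))
    for a in range(max_players + 1):
        for b in range(max_players + 1 - a):
            if a > 0:
                Wpos[a, b] = factorial(a - 1) * factorial(b) / factorial(a + b)
            if b > 0:
                Wneg[a, b] = factorial(a) * factorial(b - 1) / factorial(a + b)
    return Wpos, Wneg


def tree_shap(handle, features, background=None, max_background: int = 64) -> AttributionSet:
    """Exact interventional Shapley attributions of the GBC margin.

    The value of a coalition S is the expectation of the margin with
    features in S taken from the instance and the rest from a background
    row; the expectation runs over ``background`` (default: the explained
    matrix itself, subsampled to ``max_background`` rows).  Exact per
    background row, averaged over rows, so additivity holds to machine
    precision: sum(attributions) = margin(x) - mean margin(background).
    """
    model = getattr(handle, "model", handle)
    if not isinstance(model, GradientBoostingClassifier):
        raise TypeError("tree_shap requires a fitted gradient-boosted tree ensemble")
    if isinstance(features, FeatureMatrix):
        X = features.values
        names = features.column_ids
        ids = features.row_ids
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
        ids = [f"row_{i}" for i in range(X.shape[0])]
    if model.n_classes_ != 2:
        raise NotImplementedError("tree attribution is implemented for binary tasks")
    Z = X if background is None else (
        background.values if isinstance(background, FeatureMatrix) else np.asarray(background, dtype=float)
    )
    if len(Z) > max_background:
        step = len(Z) / max_background
        Z = Z[np.floor(np.arange(max_background) * step).astype(int)]
    n, M = X.shape
    phi = np.zeros((n, M))
    lr = model.learning_rate
    max_depth = max(est[0].get_depth() for est in model.estimators_)
    Wpos, Wneg = _shapley_weight_tables(max_depth + 1)
    for (est,) in model.estimators_:
        for value, bounds in _tree_leaves(est):
            feats = sorted(bounds)
            if not feats:
                continue  # constant leaf: identical under x and z, no attribution
            sat_x = {f: (X[:, f] > bounds[f][0]) & (X[:, f] <= bounds[f][1]) for f in feats}
            for z in Z:
                sat_z = {f: bool(bounds[f][0] < z[f] <= bounds[f][1]) for f in feats}
                reach = np.ones(n, dtype=bool)
                a = np.zeros(n, dtype=int)
                b = np.zeros(n, dtype=int)
                for f in feats:
                    if sat_z[f]:
                        b += ~sat_x[f]  # f must stay out of the coalition
                    else:
                        # f must be in the coalition; if x fails too, the
                        # leaf is unreachable under any coalition
                        reach &= sat_x[f]
                        a += sat_x[f]
                if not reach.any():
                    continue
                va = value * lr / len(Z)
                for f in feats:
                    if sat_z[f]:
                        in_B = reach & ~sat_x[f]
                        if in_B.any():
                            phi[in_B, f] -= va * Wneg[a[in_B], b[in_B]]
                    else:
                        in_A = reach  # reachable implies sat_x[f] when z fails
                        phi[in_A, f] += va * Wpos[a[in_A], b[in_A]]
    base = float(np.mean(model.decision_function(Z)))
    return AttributionSet(kind="features", values=list(phi), base_value=base,
                          ids=list(ids), feature_names=list(names))


def brute_force_shapley(predict_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exponential-time interventional Shapley values (oracle for few features)."""
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    M = x.size
    if M > 12:
        raise ValueError("brute force is exponential; use few features")

    def v(mask_bits: int) -> float:
        hybrid = Z.copy()
        for j in range(M):
            if mask_bits >> j & 1:
                hybrid[:, j] = x[j]
        return float(np.mean(predict_fn(hybrid)))

    vals = {S: v(S) for S in range(1 << M)}
    phi = np.zeros(M)
    for j in range(M):
        for S in range(1 << M):
            if S >> j & 1:
                continue
            s = bin(S).count("1")
            w = factorial(s) * factorial(M - s - 1) / factorial(M)
            phi[j] += w * (vals[S | (1 << j)] - vals[S])
    return phi


# ---------------------------------------------------------------------------
# sampling-based SHAP


def model_agnostic_shap(predict_fn, instances, background, n_samples: int = 128,
                        seed: int = 0, feature_names=None, ids=None) -> AttributionSet:
    """Permutation-sampling Shapley estimate for any predict function.

    For each sampled feature permutation and background row, features are
    flipped from the background value to the instance value in permutation
    order and each feature is credited with the change in model output it
    causes.  The estimator is unbiased for the interventional Shapley
    value; variance shrinks as 1/n_samples.  Deterministic under seed.
    """
    X = np.atleast_2d(np.asarray(instances, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    if Z.size == 0:
        raise ValueError("background must be non-empty")
    rng = np.random.default_rng(seed)
    n, M = X.shape
    phi = np.zeros((n, M))
    for s in range(n_samples):
        perm = rng.permutation(M)
        z = Z[rng.integers(len(Z))]
        hybrid = np.tile(z, (n, 1))
        prev = np.asarray(predict_fn(hybrid), dtype=float).ravel()
        # flip features to the instance values in permutation order,
        # evaluating all instances at each step in one batched call
        batch = np.empty((n * M, M))
        for step, j in enumerate(perm):
            hybrid[:, j] = X[:, j]
            batch[step * n : (step + 1) * n] = hybrid
        outs = np.asarray(predict_fn(batch), dtype=float).ravel().reshape(M, n)
        for step, j in enumerate(perm):
            phi[:, j] += outs[step] - prev
            prev = outs[step]
    phi /= n_samples
    base = float(np.mean(np.asarray(predict_fn(Z), dtype=float)))
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(M)]
    ids = list(ids) if ids is not None else [f"row_{i}" for i in range(n)]
    return AttributionSet(kind="features", values=list(phi), base_value=base,
                          ids=ids, feature_names=names)


def gradient_shap(classifier, X, background=None, n_samples: int = 16, seed: int = 0,
                  output_index: int = 0, batch_size: int = 64) -> AttributionSet:
    """Expected-gradients attribution of the network margin over one-hot input.

    attribution = E over background rows z and interpolation factors
    a ~ U(0,1) of  grad margin(z + a(x-z)) * (x - z).  With the default
    all-zero (padding) reference this reduces to integrated gradients.
    Completeness (sum of attributions ~ margin(x) - margin(reference))
    holds up to Monte-Carlo error.
    """
    batch = X if isinstance(X, OneHotBatch) else one_hot_encode(X, L_max=classifier.L_max)
    net = classifier.net_
    rng = np.random.default_rng(seed)
    A = batch.array.astype(float)
    n = len(A)
    if background is None:
        Zarr = np.zeros((1,) + A.shape[1:])
    else:
        zb = background if isinstance(background, OneHotBatch) else one_hot_encode(
            background, L_max=classifier.L_max)
        Zarr = zb.array.astype(float)
    phi = np.zeros_like(A)
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        Xb, Mb = A[sl], batch.mask[sl]
        acc = np.zeros_like(Xb)
        for _ in range(n_samples):
            z = Zarr[rng.integers(len(Zarr), size=len(Xb))]
            alpha = rng.uniform(size=(len(Xb), 1, 1))
            interp = z + alpha * (Xb - z)
            grad = net.input_gradient(interp, Mb, output_index=output_index)
            acc += grad * (Xb - z)
        phi[sl] = acc / n_samples
    # reference margin under the explained instances' own masks
    ref = Zarr.mean(axis=0, keepdims=True)
    margins, _ = net.forward(np.repeat(ref, n, axis=0), batch.mask)
    base = float(np.mean(margins[:, output_index]))
    return AttributionSet(kind="onehot", values=[phi[i] for i in range(n)], base_value=base,
                          ids=list(batch.ids), masks=[batch.mask[i] for i in range(n)])


# ---------------------------------------------------------------------------
# perturbation analysis


def perturbation_importance(model, features: FeatureMatrix, y_true, feature_names,
                            n_iter: int = 5, seed: int = 0) -> pd.Series:
    """Mean F1 drop when a feature column is randomized on [0, max(F_i)].

    Each listed feature column is replaced by i.i.d. uniform draws on
    [0, max of that column], the model is rescored, and the mean F1
    change over ``n_iter`` iterations is reported.  An all-zero column
    perturbs to itself and reports a drop of 0.
    """
    from .evaluate import compute_metrics

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mdl = getattr(model, "model", model)
    X = features.values.copy()
    y_true = np.asarray(list(y_true))
    averaging = "binary" if len(np.unique(y_true)) == 2 else "weighted"
    baseline = compute_metrics(y_true, mdl.predict(X), averaging=averaging).f1
    rng = np.random.default_rng(seed)
    cols = {name: j for j, name in enumerate(features.column_ids)}
    drops = {}
    for name in feature_names:
        if name not in cols:
            raise KeyError(f"unknown feature {name!r}")
        j = cols[name]
        fmax = X[:, j].max()
        scores = []
        for _ in range(n_iter):
            Xp = X.copy()
            Xp[:, j] = rng.uniform(0.0, fmax, size=len(X)) if fmax > 0 else 0.0
            scores.append(compute_metrics(y_true, mdl.predict(Xp), averaging=averaging).f1)
        drops[name] = baseline - float(np.mean(scores))
    return pd.Series(drops, name="f1_drop")


# ---------------------------------------------------------------------------
# positional aggregation


def positional_track_onehot(attribs: AttributionSet) -> list[ImportanceTrack]:
    """Per-position track: sum of squared attributions over the 4 channels.

    Padded positions are excluded, so the track length equals the
    un-padded sequence length.
    """
    if attribs.kind != "onehot":
        raise ValueError("expected one-hot attributions")
    tracks = []
    for i, vals in enumerate(attribs.values):
        mask = attribs.masks[i] if attribs.masks is not None else np.ones(len(vals), dtype=bool)
        real = np.asarray(vals)[mask]
        tracks.append(ImportanceTrack(attribs.ids[i], (real**2).sum(axis=1)))
    return tracks


def positional_track_kmer(token_attribs: np.ndarray, k: int, sequence_id: str = "seq") -> ImportanceTrack:
    """Per-position track: mean attribution of the k-mers covering a position."""
    t = np.asarray(token_attribs, dtype=float)
    T = len(t)
    L = T + k - 1
    values = np.zeros(L)
    csum = np.concatenate([[0.0], np.cumsum(t)])
    for p in range(L):
        lo = max(0, p - k + 1)
        hi = min(T - 1, p)
        values[p] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return ImportanceTrack(sequence_id, values)


def aggregate_kmer_importance(token_attribs: list, tokens: list) -> KmerImportance:
    """Mean attribution per distinct k-mer, min-max scaled per sign group.

    The mean over occurrences (rather than the sum) keeps frequent k-mers
    from dominating by count alone.  Positive means scale to [0, 1] and
    negative means to [-1, 0]; each group's extreme maps to +-1.
    """
    if not token_attribs:
        raise ValueError("no instances")
    sums: dict = {}
    counts: dict = {}
    for attr, toks in zip(token_attribs, tokens):
        toks = toks.tokens if hasattr(toks, "tokens") else toks
        for a, tok in zip(np.asarray(attr, dtype=float), toks):
            sums[tok] = sums.get(tok, 0.0) + float(a)
            counts[tok] = counts.get(tok, 0) + 1
    means = {tok: sums[tok] / counts[tok] for tok in sums}
    pos = {t: m for t, m in means.items() if m > 0}
    neg = {t: m for t, m in means.items() if m < 0}
    scores = {t: 0.0 for t, m in means.items() if m == 0}
    if pos:
        lo, hi = min(pos.values()), max(pos.values())
        scores.update({t: 1.0 if hi == lo else (m - lo) / (hi - lo) for t, m in pos.items()})
    if neg:
        lo, hi = min(neg.values()), max(neg.values())
        scores.update({t: -1.0 if hi == lo else (m - hi) / (hi - lo) for t, m in neg.items()})
    return KmerImportance(scores=scores, raw_means=means)


# ---------------------------------------------------------------------------
# anchors


TATA_PWM = PWMotif(
    "TATAWA",
    # consensus TATAWA; W splits evenly between A and T
    np.array([
        [0.03, 0.91, 0.03, 0.91, 0.47, 0.91],
        [0.03, 0.03, 0.03, 0.03, 0.03, 0.03],
        [0.03, 0.03, 0.03, 0.03, 0.03, 0.03],
        [0.91, 0.03, 0.91, 0.03, 0.47, 0.03],
    ]),
    kind="probabilities",
)


def find_tata(seq, search_window: tuple = (0.2, 0.8), rel_threshold: float = 0.85) -> int | None:
    """Best TATAWA-box hit inside a central window, or None.

    A PWM-style stand-in for an external promoter predictor: the TATAWA
    consensus is scored at every window start within the central
    ``search_window`` fraction of the sequence; the best position is
    returned when it clears ``rel_threshold`` of the attainable score
    range.  Anchor files override this heuristic when provided.
    """
    from .features import pwm_score_positions, _score_threshold

    s = seq.sequence if hasattr(seq, "sequence") else str(seq)
    L = len(s)
    w = TATA_PWM.width
    lo = int(search_window[0] * L)
    hi = max(lo, int(search_window[1] * L) - w + 1)
    if L < w or lo >= hi:
        return None
    # light smoothing keeps the consensus sharp: a single non-W mismatch
    # already falls below the default threshold
    scores = pwm_score_positions(s, TATA_PWM, pseudocount=0.05)
    window_scores = scores[lo:hi]
    if window_scores.size == 0:
        return None
    thr = _score_threshold(TATA_PWM, rel_threshold, None, 0.05)
    best = int(np.argmax(window_scores))
    if window_scores[best] < thr:
        return None
    return lo + best


def predict_anchors(seq, tata_tss_spacing: int = 30, **tata_kwargs) -> dict:
    """start/TATA/TSS/end anchor positions (0-based) for one sequence.

    The TSS defaults to TATA + ``tata_tss_spacing`` (canonical spacing)
    when no external prediction is supplied.
    """
    s = seq.sequence if hasattr(seq, "sequence") else str(seq)
    tata = find_tata(s, **tata_kwargs)
    tss = None
    if tata is not None and tata + tata_tss_spacing < len(s):
        tss = tata + tata_tss_spacing
    return {"start": 0, "TATA": tata, "TSS": tss, "end": len(s) - 1}


def load_anchor_file(path) -> dict:
    """TSV (sequence id, tata_pos, tss_pos), 0-based, into an anchor map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "tata", "tss"])
    out = {}
    for _, row in df.iterrows():
        out[str(row["id"])] = {
            "TATA": None if pd.isna(row["tata"]) else int(row["tata"]),
            "TSS": None if pd.isna(row["tss"]) else int(row["tss"]),
        }
    return out


def center_tracks(tracks: list, anchor: str, flank: int) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Anchor-centered importance matrix and its median profile.

    Rows are tracks windowed to anchor +- flank (out-of-range cells NaN);
    the median profile is taken over non-NaN cells per column.  Tracks
    lacking the anchor are skipped; their count is returned.
    """
    rows, ids, skipped = [], [], 0
    width = 2 * flank + 1
    for tr in tracks:
        pos = tr.anchors.get(anchor)
        if pos is None:
            skipped += 1
            continue
        row = np.full(width, np.nan)
        L = len(tr.values)
        lo = max(0, pos - flank)
        hi = min(L, pos + flank + 1)
        row[lo - (pos - flank) : hi - (pos - flank)] = tr.values[lo:hi]
        rows.append(row)
        ids.append(tr.sequence_id)
    if not rows:
        raise ValueError(f"no track carries anchor {anchor!r}")
    matrix = pd.DataFrame(rows, index=ids, columns=np.arange(-flank, flank + 1))
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            median = np.nanmedian(matrix.to_numpy(), axis=0)
    return matrix, median, skipped


# ---------------------------------------------------------------------------
# consensus assembly


def _overlap_connection(u: str, v: str, min_overlap: int):
    """Smallest-shift admissible overlap between equal-length k-mers.

    Returns the offset of v relative to u, or None.  Zero shift admits
    mismatches (stacked variants) as long as >= min_overlap positions
    agree; non-zero shifts require an exact suffix-prefix match of
    length >= min_overlap.
    """
    k = len(u)
    for s in sorted(range(-(k - min_overlap), k - min_overlap + 1), key=abs):
        if s >= 0:
            a, b = u[s:], v[: k - s]
        else:
            a, b = u[: k + s], v[-s:]
        matches = sum(x == y for x, y in zip(a, b))
        if s == 0:
            if matches >= min_overlap:
                return 0
        elif matches == len(a) and len(a) >= min_overlap:
            return s
    return None


def assemble_consensus(kmers: list, min_overlap: int | None = None) -> list[str]:
    """Chain overlapping k-mers into degenerate consensus motifs.

    k-mers (all the same length, ordered by importance) are connected
    when they overlap per :func:`_overlap_connection`; each connected
    component is laid out by relative offset and per-column letter sets
    become bracket classes, e.g. {TATAAA, TATATA} -> "TATA[AT]A".
    """
    kmers = [str(k).upper() for k in kmers]
    if not kmers:
        return []
    k = len(kmers[0])
    if any(len(x) != k for x in kmers):
        raise ValueError("all k-mers must have equal length")
    if min_overlap is None:
        min_overlap = k - 2
    if not 0 < min_overlap < k:
        raise ValueError("min_overlap must be in (0, k)")
    seen = []
    for x in kmers:
        if x not in seen:
            seen.append(x)
    offsets: dict = {}
    components: list[list[str]] = []
    for x in seen:
        placed = False
        for comp in components:
            for member in comp:
                s = _overlap_connection(member, x, min_overlap)
                if s is not None:
                    offsets[x] = offsets[member] + s
                    comp.append(x)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            offsets[x] = 0
            components.append([x])
    out = []
    for comp in components:
        base = min(offsets[x] for x in comp)
        width = max(offsets[x] for x in comp) - base + k
        columns = [set() for _ in range(width)]
        for x in comp:
            off = offsets[x] - base
            for i, ch in enumerate(x):
                columns[off + i].add(ch)
        motif = "".join(
            next(iter(c)) if len(c) == 1 else "[" + "".join(sorted(c)) + "]" for c in columns
        )
        out.append(motif)
    return out
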