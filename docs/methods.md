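# Methods

This note documents the models and procedures implemented in
`ltrlearn`, the parameters that matter, the synthetic data the test
suite runs on, and the numerical and design choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Tasks and data model

Three supervised tasks operate on DNA sequences of ~100–4000 bp in
element orientation (no reverse-complement handling unless requested;
LTRs are orientation-defined): LTR detection (binary), superfamily
classification (Ty1/Copia vs Ty3/Gypsy, binary), and family
classification (15 classes; the default family list of 9 Copia and 6
Gypsy lineages is a configuration default, not a biological claim).
Coordinates are 0-based, half-open throughout. Lower-case and U bases
normalize to the upper-case T alphabet; `N` is retained in sequences,
deleted before one-hot encoding, and scored as the per-column minimum in
PWM scanning so ambiguity never creates a motif hit.

## Curation

Redundancy reduction uses CD-HIT-style greedy incremental clustering:
sequences sorted by length (descending, ties by id) either join the
first cluster whose representative they match at the identity threshold
or found a new cluster. Identity is `matches / alignment columns` of a
global alignment computed with edlib; a pair is pre-screened by shared
words (default word size 6) and the alignment is banded through the
implied edit-distance bound `(1 − t)(|a| + |b|) + 1`, which is exact:
any pair beyond the band is provably below the threshold. The
representative of a cluster is its longest member, which under the
processing order is always the founder, so results are order-invariant.

Solo-LTR screening removes a negative when an infix alignment of any
database LTR reaches `min_identity` matches over `min_coverage` of the
LTR length (defaults 0.8/0.8, echoing the 80/80 convention used to
delimit TE families); an 11-mer shared-word screen precedes alignment.

Splits are stratified 70/10/20 by largest-remainder apportionment per
stratum, so each split size deviates from its target by less than one
sequence per stratum; strata smaller than 3 go wholly to training with
a warning.

## Negative sets

Three classes, default equal thirds: uniform-random sequences;
genomic-like windows rejected against excluded (annotated-LTR)
intervals; and order-2 Markov resamples. For the Markov share the LTR
set is clustered at 70% identity (low, to produce large clusters of
loosely similar sequences), one chain is trained per cluster with
transition `(count(cb) + q) / (count(c·) + 4q)` (pseudocount q = 0.5,
which avoids zero-probability dead ends on small clusters), and sampled
lengths follow the source cluster's own length distribution. Generated
sequences reproduce the training 3-mer composition but not the spatial
organization of LTRs — which is exactly their role as hard negatives.
The round-trip check (re-estimated transitions vs model transitions)
is asserted at 0.02 max absolute deviation for 10^5 generated bases;
binomial sampling error alone is ~0.006 SD per cell at that length, so
a tighter bound is not attainable.

## Featurization

**TFBS occurrence vectors.** Each motif of a JASPAR-format panel is
scanned along the forward strand as a log-odds PWM (pseudocount 0.8
added before normalization, uniform background). A window counts as an
occurrence when its score reaches `min + 0.8·(max − min)` of the
motif's attainable score range; the 0.8 relative threshold is standard
practice for JASPAR scanning and configurable. Counts are TF-IDF
weighted with the smoothed-idf + L2 convention
(`idf(t) = ln((1+N)/(1+df(t))) + 1`, rows normalized), which
down-weights ubiquitous, unspecific TFBS; all-zero rows stay zero.

**One-hot encoding.** N bases deleted, 3′ truncation to `L_max`
(default 4000), 3′ zero-padding, and a boolean mask of real positions.
Padded positions are masked out of pooling and recurrence, so the
network output is provably independent of pad contents.

**k-mers.** Overlapping tokens, stride 1, 5′→3′; k ∈ {4, 5, 6}
supported, 6 the default. Set-level similarity uses the Jaccard index
of pooled distinct k-mers.

## Models

**TFBS track.** A TF-IDF transformer feeding a gradient-boosted
decision-tree ensemble (sklearn; defaults 200 trees, depth 3, learning
rate 0.1), with an exhaustive stratified k-fold grid search (gbdt /
random-forest / MLP arms) selecting by mean F1.

**CNN-LSTM track.** Input `L_max`, one valid-mode 1-D convolution
(default 64 filters of width 12 — wide enough to span typical JASPAR
motifs so filter→motif mapping stays meaningful), max pooling, a
unidirectional LSTM whose state carries unchanged through masked steps
(so the final hidden state is the state at the last real position), and
one sigmoid unit (binary) or a 15-way softmax (family). Training uses
Adam (default lr 1e-3), batches of 64, 15 epochs with early stopping at
patience 3 and best-weight restoration; the family loss is weighted by
inverse class frequency `w_c = N/(K·n_c)` (frequency-weighted mean 1).
The engine is a compact numpy implementation with exact
backpropagation (finite-difference-verified in the test suite) and
seeded, reproducible initialization and shuffling.

A practical finding that shaped the desk-scale defaults: with a few
thousand training sequences this optimizer does not recover planted
signals through more than roughly eight recurrent steps — the
convolution learns, but gradient through a long LSTM plateau does not.
All shipped training configurations therefore choose `pool_size` so
that `L_max / pool_size ≤ 8` (e.g. pool 128 at `L_max` 512–1024), and a
`forget_bias` knob (default 1.0) is exposed for longer memory horizons.
This is a statement about optimization at small sample sizes, not about
the topology's capacity.

**Windowed-embedding track.** Any embedder satisfying "sequence of ≤
`window` bases → fixed-length vector" is slid along the sequence
(window 510, stride 170, a final end-anchored window when needed) and
average-pooled; a convolutional head (32 filters of width 3, global max
pool, dense 32) classifies the pooled vector. The default offline
embedder is a deterministic keyed-hash k-mer projector; a pre-trained
transformer embedder plugs into the same contract but is deliberately
not bundled (it requires a weight download).

## Evaluation and model comparison

Precision/recall/F1 with binary or support-weighted averaging (the
family-task summary uses support weighting; macro is available from the
per-class table). The Wilcoxon signed-rank test drops zero differences,
reports `min(W+, W−)`, and computes the two-sided p exactly for n ≤ 25
by dynamic programming over the (possibly tied, half-integer) ranks —
tied ranks are therefore handled exactly, which scipy's exact mode
declines — and by normal approximation above. The Friedman test uses
within-row average ranks; when it rejects at α = 0.05 (conventional
default), Nemenyi pairwise p-values follow from the studentized range
distribution of mean-rank differences,
`q = |R̄_i − R̄_j| / sqrt(m(m+1)/(12k))` vs `Q(m, ∞)`. A fully constant
score matrix is rejected as degenerate; identical model columns return
the trivial (0, p = 1) result.

## Explainability

**Trees.** `tree_shap` computes exact interventional Shapley values of
the boosted-ensemble margin. For one leaf, one explained instance x and
one background row z, the path conditions partition the path's features
into A (x satisfies, z does not — must be in the coalition), B (z
satisfies, x does not — must be out), null (both satisfy), and
unreachable (neither); the Shapley value of the induced conjunction
game is closed-form (`φ_i = v·(a−1)!·b!/(a+b)!` for i ∈ A, the negative
analogue for B). Summing over leaves, trees and background rows gives
the exact attribution in polynomial time; additivity
(`base + Σφ = margin`) holds to machine precision and equality with
brute-force coalition enumeration is asserted for small feature counts.
The default background is a 64-row even subsample of the explained set.

**Model-agnostic.** Permutation sampling: per sampled permutation and
background row, features flip from background to instance values in
order and each is credited with the output change; unbiased for the
interventional Shapley value, deterministic under seed, variance
shrinking as 1/n_samples.

**Network.** Expected gradients: `E[∇f(z + α(x − z))·(x − z)]` over
background rows z and α ~ U(0,1), using the engine's exact input
gradients; with the zero (padding) reference this is integrated
gradients. This gradient-based estimator fills the role a
deep-network SHAP explainer plays for framework models; completeness
holds to Monte-Carlo error only, and no exact-additivity claim is made
on this path.

**Aggregations.** One-hot attributions aggregate per position as the
sum of squared channel values (padded positions excluded); token
attributions as the mean over tokens covering a position. Global k-mer
importance is the mean attribution over occurrences (the mean rather
than the sum, so frequency does not masquerade as effect), min-max
scaled separately within the positive group (to [0, 1]) and negative
group (to [−1, 0]); each group's mildest member maps to 0, so the
guarantee is that no scaled score has the opposite sign of its raw
mean. Perturbation analysis redraws one feature column uniformly on
`[0, max(F_i)]` (5 iterations by default) and reports the mean F1
change.

**Anchors.** Start and end anchors are positions 0 and L−1. The TATA
anchor is the best TATAWA PWM hit (lightly smoothed, pseudocount 0.05,
relative threshold 0.85 — one non-W mismatch already falls below it)
inside the central 20–80% of the sequence, standing in for an external
promoter predictor; the TSS defaults to TATA + 30 (canonical spacing).
External anchor files (TSV: id, tata, tss; 0-based) override both.
Anchor-centered matrices window each track to anchor ± flank with NaN
out of range; the median profile ignores NaNs, and no smoothing is
applied (a deliberate choice; smoothing before the median is a flag
away in plotting code, not done here).

**Consensus assembly.** Equal-length k-mers connect when they overlap
exactly at a non-zero shift (overlap ≥ k−2 by default) or agree in ≥
k−2 positions at zero shift (stacked variants); connected components
are laid out by offset and multi-letter columns become bracket classes,
e.g. {TATAAA, TATATA} → `TATA[AT]A`.

## CNN filter analysis

First-layer filters are extracted as width × 4 matrices and normalized
as `Ŝ = exp(λ·S/max(S))` with λ = 3 and `max(S)` the global matrix
maximum (a per-column variant is not offered because the formula names
a single max; filters with non-positive maximum carry no preferred base
and are rejected rather than silently shifted). Columns normalize to a
position probability matrix for MEME export. The built-in matcher
scores query/target pairs by the best mean per-column Pearson
correlation over all offsets and both orientations (overlap ≥ 5,
zero-variance columns contribute 0) and reports raw correlations —
E-value calibration is delegated to an external motif-comparison tool
when available.

## Edge tetramer analysis

Terminal (first 4, last 4) tetramer pairs are tallied exactly.
Complementarity counts positions where the 3′ tetramer equals the
reverse complement of the 5′ tetramer. Canonical assignment considers
the identity and three 1-bp shift corrections (prepend T/drop last at
the 5′ end; drop first/append A at the 3′ end — the two ways an
annotation shifted one base into the element loses the TG…CA
signature), accepts a shift only when it does not reduce
complementarity, and picks the candidate maximizing (TG-prefix and
CA-suffix present, complementarity), identity preferred on ties; shifts
beyond 1 bp are not considered. Summaries assign the top-n most
frequent pairs (ties broken lexicographically for determinism), conserve
counts, and report percentages over the summarized counts rounded to
integers.

## Synthetic data: what it emulates, and what it does not

The generator plants recoverable LTR organization on a uniform or
Markov background: superfamily-specific terminal tetramers
(Copia `TGTT..AACA`, Gypsy `TGAT..ATCA`), a TATAWA box at a fixed
fraction of the length (0.45 — centrally positioned, as in real LTRs),
two instances of a shared "core" motif and one instance each of three
family-specific motifs per sequence, all drawn from sharp consensus
PWMs (width 10, per-column consensus probability jittered on
0.93–0.99 — the jitter keeps relative-threshold scanning away from
exact score ties). Decoy motifs are generated for the scan panel but
never planted. Every planted coordinate lands in a truth table, and
regeneration under a fixed seed is byte-identical.

Negatives follow the negative-set recipes (uniform, patchy-GC genomic
windows, per-family Markov resamples — the known family partition
stands in for similarity clustering here). For explainability studies a
*shortcut-free* configuration hardens them: negatives receive matched
family-motif content, independent 5′/3′ decoy edge signatures, and
optionally a positioned decoy TATAWA, so that no single feature
separates the classes and a model must integrate several signals. The
*planted-TATA* construction used for positional-attribution checks
additionally drops the shared core motif and extends the conserved
terminus by 4 bases (real LTR conservation extends beyond the terminal
tetramer into U3/U5): under it, start, TATA and end each carry partial
signal (decoy rates 0.5/0.35/0.5) and the trained network demonstrably
attends all three.

What passing on this data does **not** show: real LTRs have no sharp
planted motifs, their TATA position varies, family signals are weak and
distributed, sequence backgrounds are repeat-rich and methylation-
shaped, and class boundaries are annotation-noisy. Synthetic results
validate the machinery (recovery of known structure at desk scale), not
field performance.

## Problem sizes used by the shipped checks

The acceptance-style tests run, by the package's own choice of desk
scale: model-performance checks on 2000 + 2000 sequences of 300–1000 bp
(`L_max` 1024, 32 filters, pool 128, lr 3e-3, the standard 15-epoch /
patience-3 regime); the positional-attribution study on 2000 + 2000
sequences of 300–500 bp (`L_max` 512, pool 128, lr 1e-3, long-horizon
training with patience 80, attribution over 200 positives with 32
negative references and 12 gradient samples); the difficulty sweep on
600 + 600 sequences at signal strengths 0/0.5/1 × 3 seeds; statistical
calibration on 10,000 simulated null comparisons of length 14 (chosen
because the largest attainable exact level, 0.0494, sits at the nominal
0.05 — the discrete null otherwise under-rejects by construction).
`scripts/acceptance.py` recomputes the edge-assignment totals from the
published top-five tetramer frequencies; that computation is exact and
seed-independent.

## Known limitations

* The transformer-based embedding track ships only with the hash-based
  offline embedder; fine-tuning a genomic language model is out of
  scope, and window pooling is validated against the embedder contract,
  not against any specific pre-trained model.
* The CNN-LSTM optimizer needs few recurrent steps at small sample
  sizes (see above); large-corpus behavior of long-step recurrences is
  not characterized here.
* `tree_shap` covers binary tasks; multiclass ensembles raise rather
  than silently attributing a single class.
* The solo-LTR screen tests full-query infix alignments; partial-LTR
  hits below `min_coverage` of the query are by design not removed.
* Percentages in edge summaries are over the summarized top-n pairs
  only, mirroring the shape of the published table.
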