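"""Filter normalization/matching and the edge tetramer analysis."""

from collections import Counter

import numpy as np
import pytest

from ltrlearn.motifs import (
    EdgeSummary,
    FilterMatrix,
    assign_canonical,
    complementarity,
    edge_tetramers,
    extract_filters,
    match_motifs,
    normalize_filter,
    revcomp,
    summarize_edges,
)
from ltrlearn.seqio import LabeledSequence, PWMotif


class TestNormalizeFilter:
    def test_matches_elementwise_formula(self, rng):
        S = rng.normal(size=(8, 4))
        S.flat[np.argmax(S)] = abs(S).max() + 0.5  # ensure positive max
        out = normalize_filter(S, lam=3.0)
        expected = np.exp(3.0 * S / S.max())
        assert np.allclose(out.normalized, expected, atol=1e-12)

    def test_global_max_maps_to_e_lambda(self, rng):
        S = rng.random((6, 4))
        out = normalize_filter(S, lam=3.0)
        assert out.normalized.max() == pytest.approx(np.e**3)

    def test_constant_filter_gives_uniform_pwm(self):
        out = normalize_filter(np.ones((5, 4)), lam=3.0)
        pwm = out.to_pwm()
        assert np.allclose(pwm.matrix, 0.25)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError, match="max"):
            normalize_filter(-np.ones((4, 4)))

    def test_order_preserving_within_columns(self, rng):
        S = rng.normal(size=(7, 4))
        S[0, 0] = 2.0  # positive max
        out = normalize_filter(S)
        for j in range(7):
            assert np.array_equal(np.argsort(S[j]), np.argsort(out.normalized[j]))


class TestMatchMotifs:
    @staticmethod
    def _pwm(name, consensus, p=0.9):
        m = np.full((4, len(consensus)), (1 - p) / 3)
        for j, b in enumerate(consensus):
            m["ACGT".index(b), j] = p
        return PWMotif(name, m, kind="probabilities")

    def test_self_match_scores_one(self):
        q = self._pwm("q", "ACGTACG")
        df = match_motifs([q], [self._pwm("t", "ACGTACG")])
        assert df.iloc[0]["score"] == pytest.approx(1.0)
        assert df.iloc[0]["offset"] == 0 and df.iloc[0]["orientation"] == "+"

    def test_reverse_complement_match(self):
        q = self._pwm("q", "ACGGATC")
        t = PWMotif("t", q.matrix[::-1, ::-1], kind="probabilities")
        df = match_motifs([q], [t])
        assert df.iloc[0]["score"] == pytest.approx(1.0)
        assert df.iloc[0]["orientation"] == "-"

    def test_uniform_query_degenerate_zero(self):
        q = PWMotif("u", np.full((4, 6), 0.25), kind="probabilities")
        df = match_motifs([q], [self._pwm("t", "ACGTAC")])
        assert df.iloc[0]["score"] == 0.0

    def test_offset_match_found(self):
        q = self._pwm("q", "CGTAC")
        t = self._pwm("t", "AACGTACGG")
        df = match_motifs([q], [t], min_overlap=5)
        assert df.iloc[0]["score"] > 0.9
        assert df.iloc[0]["offset"] == 2


class TestEdgeTetramers:
    def test_single_sequence_tally(self):
        tally, skipped = edge_tetramers([LabeledSequence("s", "TGTTAAACAACA")])
        assert tally == Counter({("TGTT", "AACA"): 1}) and skipped == 0

    def test_short_sequences_skipped(self):
        tally, skipped = edge_tetramers(["ACGTACG", "TGTTCCCCAACA"])
        assert skipped == 1 and sum(tally.values()) == 1

    def test_matches_brute_force_on_random_set(self, random_sequences):
        seqs = random_sequences(1000, 20)
        tally, skipped = edge_tetramers(seqs)
        oracle = Counter((s.sequence[:4], s.sequence[-4:]) for s in seqs)
        assert tally == oracle and sum(tally.values()) == 1000


class TestComplementarity:
    @pytest.mark.parametrize("t5,t3,expected", [
        ("TGTT", "AACA", 4),
        ("TGTA", "AACA", 3),
        ("AAAA", "AAAA", 0),
        ("TGTC", "GACA", 4),
    ])
    def test_examples(self, t5, t3, expected):
        assert complementarity(t5, t3) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            complementarity("TGNN", "AACA")

    def test_revcomp_helper(self):
        assert revcomp("TGTT") == "AACA"


class TestAssignCanonical:
    @pytest.mark.parametrize("pair,canonical,shifted", [
        (("GTTA", "AACA"), ("TGTT", "AACA"), True),
        (("TGTT", "AACA"), ("TGTT", "AACA"), False),
        (("GATA", "ATCA"), ("TGAT", "ATCA"), True),
        (("GATG", "ATCA"), ("TGAT", "ATCA"), True),
        (("GTAA", "AACA"), ("TGTA", "AACA"), True),
        (("TGTA", "AACA"), ("TGTA", "AACA"), False),
        (("TGTC", "GACA"), ("TGTC", "GACA"), False),
    ])
    def test_assignments(self, pair, canonical, shifted):
        assert assign_canonical(pair) == (canonical, shifted)

    def test_never_decreases_complementarity(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(300):
            t5 = "".join(rng.choice(bases, 4))
            t3 = "".join(rng.choice(bases, 4))
            (c5, c3), _ = assign_canonical((t5, t3))
            assert complementarity(c5, c3) >= complementarity(t5, t3)


class TestSummarizeEdges:
    def test_single_pair_is_hundred_percent(self):
        summary = summarize_edges(Counter({("TGTT", "AACA"): 7}), top_n=5)
        assert summary.totals == {("TGTT", "AACA"): 7}
        assert summary.percentages[("TGTT", "AACA")] == 100

    def test_counts_conserved_for_random_tallies(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            tally = Counter({
                ("".join(rng.choice(bases, 4)), "".join(rng.choice(bases, 4))): int(c)
                for c in rng.integers(1, 100, size=6)
            })
            top_n = int(rng.integers(1, 7))
            summary = summarize_edges(tally, top_n=top_n)
            top = sorted(tally.values(), reverse=True)[:top_n]
            top_sum = sum(sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[i][1]
                          for i in range(min(top_n, len(tally))))
            assert sum(summary.totals.values()) == top_sum

    def test_percentages_sum_near_hundred(self, rng):
        tally = Counter({("TGTT", "AACA"): 70, ("GATA", "ATCA"): 20, ("CCCC", "GGGG"): 11})
        summary = summarize_edges(tally, top_n=3)
        assert abs(sum(summary.percentages.values()) - 100) <= 2

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            summarize_edges(Counter())


class TestExtractFilters:
    def test_count_and_roundtrip(self, random_sequences):
        from ltrlearn.models import CnnLstmClassifier

        seqs = [s.sequence for s in random_sequences(30, 80)]
        y = np.array([0, 1] * 15)
        clf = CnnLstmClassifier(n_filters=6, filter_width=8, pool_size=64, lstm_units=4,
                                L_max=96, epochs=2, patience=1, seed=0)
        clf.fit(seqs, y)
        filters = extract_filters(clf)
        assert len(filters) == 6
        assert all(f.raw.shape == (8, 4) for f in filters)
        assert np.array_equal(filters[2].raw, clf.net_.filter_matrices()[2])

    def test_unfitted_rejected(self):
        from ltrlearn.models import CnnLstmClassifier

        with pytest.raises(TypeError):
            extract_filters(CnnLstmClassifier())

    def test_planted_motif_recovered_in_filters(self, rng):
        """A network trained where class 1 always contains one motif should
        devote at least one first-layer filter to it (majority of 3 seeds)."""
        from ltrlearn.models import CnnLstmClassifier

        bases = np.array(list("ACGT"))
        consensus = "ACGTACGTAC"
        target = np.full((4, 10), 0.02)
        for j, b in enumerate(consensus):
            target["ACGT".index(b), j] = 0.94
        target_pwm = PWMotif("planted", target, kind="probabilities")

        def dataset(seed):
            r = np.random.default_rng(seed)
            pos, neg = [], []
            for _ in range(120):
                s = list("".join(r.choice(bases, size=100)))
                at = int(r.integers(10, 80))
                s[at:at + 10] = list(consensus)
                pos.append("".join(s))
                neg.append("".join(r.choice(bases, size=100)))
            return pos + neg, np.array([1] * 120 + [0] * 120)

        successes = 0
        for seed in range(3):
            X, y = dataset(seed)
            clf = CnnLstmClassifier(n_filters=8, filter_width=12, pool_size=128,
                                    lstm_units=8, L_max=128, lr=5e-3, epochs=12,
                                    patience=4, seed=seed)
            clf.fit(X, y)
            pwms = []
            for f in extract_filters(clf):
                try:
                    pwms.append(normalize_filter(f).to_pwm())
                except ValueError:
                    continue
            scores = match_motifs(pwms, [target_pwm], min_overlap=6)
            if len(scores) and scores["score"].max() >= 0.7:
                successes += 1
        assert successes >= 2
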