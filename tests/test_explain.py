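"""Attribution, positional aggregation, anchors and consensus assembly."""

import numpy as np
import pandas as pd
import pytest

from ltrlearn.explain import (
    AttributionSet,
    ImportanceTrack,
    aggregate_kmer_importance,
    assemble_consensus,
    brute_force_shapley,
    center_tracks,
    find_tata,
    load_anchor_file,
    model_agnostic_shap,
    perturbation_importance,
    positional_track_kmer,
    positional_track_onehot,
    predict_anchors,
    tree_shap,
)
from ltrlearn.features import FeatureMatrix
from ltrlearn.models import train_gbdt


def _fm(values, kind="counts"):
    return FeatureMatrix(pd.DataFrame(np.asarray(values, dtype=float),
                                      columns=[f"f{j}" for j in range(np.shape(values)[1])]),
                         kind=kind)


@pytest.fixture
def stump_model(rng):
    """Single informative feature; plenty of data so trees only use it."""
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y * 2.0, np.zeros(n)])
    fm = _fm(X)
    return train_gbdt(fm, y, hyperparams={"n_estimators": 20, "max_depth": 1}, seed=0), fm, y


class TestTreeShap:
    def test_single_feature_attribution_is_margin_shift(self, stump_model):
        handle, fm, _ = stump_model
        att = tree_shap(handle, fm)
        margins = handle.model.decision_function(fm.values)
        phi = np.stack(att.values)
        assert np.allclose(phi[:, 0], margins - att.base_value, atol=1e-10)

    def test_unused_feature_gets_zero(self, stump_model):
        handle, fm, _ = stump_model
        att = tree_shap(handle, fm)
        assert np.all(np.stack(att.values)[:, 1] == 0)

    def test_additivity_exact(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 1] * X[:, 2] > 0).astype(int)
        fm = _fm(X)
        handle = train_gbdt(fm, y, hyperparams={"n_estimators": 40, "max_depth": 3}, seed=1)
        att = tree_shap(handle, fm, max_background=25)
        recon = att.base_value + np.stack(att.values).sum(axis=1)
        assert np.allclose(recon, handle.model.decision_function(X), atol=1e-9)

    def test_matches_brute_force_coalitions(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] - X[:, 1] + 0.5 * X[:, 2] > 0).astype(int)
        fm = _fm(X)
        handle = train_gbdt(fm, y, hyperparams={"n_estimators": 15, "max_depth": 2}, seed=2)
        background = X[:10]
        att = tree_shap(handle, fm, background=background)
        for i in (0, 7, 23):
            oracle = brute_force_shapley(handle.model.decision_function, X[i], background)
            assert np.allclose(att.values[i], oracle, atol=1e-9)

    def test_non_tree_model_rejected(self):
        from sklearn.linear_model import LogisticRegression

        with pytest.raises(TypeError):
            tree_shap(LogisticRegression(), _fm(np.zeros((2, 2))))


class TestModelAgnosticShap:
    def test_linear_model_closed_form(self, rng):
        w = np.array([2.0, -1.0, 0.5])
        predict = lambda X: X @ w
        background = rng.normal(size=(50, 3))
        x = np.array([[1.0, 1.0, 1.0]])
        att = model_agnostic_shap(predict, x, background, n_samples=1000, seed=0)
        expected = w * (x[0] - background.mean(axis=0))
        # Monte-Carlo error ~ |w| * sd(z) / sqrt(n_samples)
        assert np.allclose(att.values[0], expected, atol=0.12)

    def test_constant_model_all_zero(self, rng):
        att = model_agnostic_shap(lambda X: np.full(len(X), 3.0),
                                  rng.normal(size=(4, 5)), rng.normal(size=(10, 5)),
                                  n_samples=30, seed=1)
        assert np.allclose(np.stack(att.values), 0.0)

    def test_more_samples_reduce_variance(self, rng):
        w = rng.normal(size=4)
        predict = lambda X: X @ w + np.sin(X[:, 0])
        background = rng.normal(size=(20, 4))
        x = rng.normal(size=(1, 4))

        def spread(n_samples):
            ests = [
                np.asarray(model_agnostic_shap(predict, x, background,
                                               n_samples=n_samples, seed=s).values[0])
                for s in range(8)
            ]
            return np.var(np.stack(ests), axis=0).sum()

        assert spread(128) < spread(8)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            model_agnostic_shap(lambda X: X.sum(1), np.ones((1, 2)), np.empty((0, 2)))

    def test_seed_determinism(self, rng):
        predict = lambda X: (X**2).sum(axis=1)
        x, bg = rng.normal(size=(2, 3)), rng.normal(size=(5, 3))
        a1 = model_agnostic_shap(predict, x, bg, n_samples=16, seed=7)
        a2 = model_agnostic_shap(predict, x, bg, n_samples=16, seed=7)
        assert np.array_equal(np.stack(a1.values), np.stack(a2.values))


class TestPerturbation:
    def test_ignored_and_decisive_features(self, stump_model):
        handle, fm, y = stump_model
        drops = perturbation_importance(handle, fm, y, ["f0", "f1"], n_iter=5, seed=0)
        assert drops["f1"] == pytest.approx(0.0, abs=0.01)
        assert drops["f0"] >= 0.2

    def test_all_zero_column_reports_zero(self, stump_model):
        handle, fm, y = stump_model
        drops = perturbation_importance(handle, fm, y, ["f1"], seed=0)
        assert drops["f1"] == 0.0

    def test_unknown_feature_rejected(self, stump_model):
        handle, fm, y = stump_model
        with pytest.raises(KeyError):
            perturbation_importance(handle, fm, y, ["nope"])


class TestPositionalTracks:
    def test_onehot_sum_of_squares(self, rng):
        vals = rng.normal(size=(7, 4))
        mask = np.array([True] * 5 + [False] * 2)
        att = AttributionSet(kind="onehot", values=[vals], base_value=0.0,
                             ids=["s"], masks=[mask])
        (track,) = positional_track_onehot(att)
        expected = np.array([sum(vals[p, c] ** 2 for c in range(4)) for p in range(5)])
        assert np.allclose(track.values, expected)
        assert len(track.values) == 5
        assert track.anchors["start"] == 0 and track.anchors["end"] == 4

    def test_onehot_single_nonzero(self):
        vals = np.zeros((4, 4))
        vals[2, 1] = 3.0
        att = AttributionSet(kind="onehot", values=[vals], base_value=0.0,
                             ids=["s"], masks=[np.ones(4, dtype=bool)])
        (track,) = positional_track_onehot(att)
        assert np.allclose(track.values, [0, 0, 9.0, 0])

    def test_kmer_track_uniform(self):
        track = positional_track_kmer(np.full(5, 0.3), k=4)
        assert np.allclose(track.values, 0.3)
        assert len(track.values) == 8

    def test_kmer_track_single_token(self):
        track = positional_track_kmer([2.5], k=6)
        assert np.allclose(track.values, 2.5) and len(track.values) == 6

    def test_kmer_track_matches_coverage_enumeration(self, rng):
        t = rng.normal(size=12)
        k = 5
        track = positional_track_kmer(t, k=k)
        for p in range(len(track.values)):
            covering = [t[j] for j in range(len(t)) if j <= p <= j + k - 1]
            assert track.values[p] == pytest.approx(np.mean(covering))


class TestKmerAggregation:
    def test_single_positive_kmer_scales_to_one(self):
        ki = aggregate_kmer_importance([[0.4, 0.4]], [["AAAA", "AAAA"]])
        assert ki.scores["AAAA"] == 1.0

    def test_two_positive_kmers_min_max(self):
        ki = aggregate_kmer_importance([[2.0, 6.0]], [["AAAA", "CCCC"]])
        assert ki.scores["AAAA"] == 0.0 and ki.scores["CCCC"] == 1.0

    def test_negative_group_scales_to_minus_one(self):
        ki = aggregate_kmer_importance([[-6.0, -2.0, 3.0]], [["AAAA", "CCCC", "GGGG"]])
        assert ki.scores["AAAA"] == -1.0 and ki.scores["CCCC"] == 0.0
        assert ki.scores["GGGG"] == 1.0

    def test_scaled_sign_never_opposes_raw_mean(self, rng):
        # group-wise min-max maps each group's mildest member to 0, so the
        # guarantee is "never the opposite sign", not strict sign equality
        toks = [f"{b}AAA" for b in "ACGT"]
        attribs = rng.normal(size=4)
        ki = aggregate_kmer_importance([attribs], [toks])
        for t in toks:
            assert ki.scores[t] * ki.raw_means[t] >= 0

    def test_mean_over_occurrences(self):
        ki = aggregate_kmer_importance([[1.0, 3.0], [5.0]], [["AAAA", "AAAA"], ["AAAA"]])
        assert ki.raw_means["AAAA"] == pytest.approx(3.0)


class TestAnchors:
    def test_planted_tata_found(self, rng):
        bases = np.array(list("CG"))  # background free of A/T
        seq = "".join(rng.choice(bases, size=1000))
        seq = seq[:300] + "TATAAA" + seq[306:]
        assert find_tata(seq) == 300

    def test_all_c_returns_none(self):
        assert find_tata("C" * 500) is None

    def test_both_w_variants_score_equally(self, rng):
        bases = np.array(list("CG"))
        bg = "".join(rng.choice(bases, size=800))
        for w in "AT":
            seq = bg[:350] + "TATA" + w + "A" + bg[356:]
            assert find_tata(seq) == 350

    def test_outside_window_ignored(self, rng):
        bases = np.array(list("CG"))
        seq = "TATAAA" + "".join(rng.choice(bases, size=600))
        assert find_tata(seq) is None

    def test_predict_anchors_spacing(self, rng):
        bases = np.array(list("CG"))
        bg = "".join(rng.choice(bases, size=1000))
        seq = bg[:400] + "TATAAA" + bg[406:]
        anchors = predict_anchors(seq)
        assert anchors == {"start": 0, "TATA": 400, "TSS": 430, "end": 999}

    def test_anchor_file_roundtrip(self, tmp_path):
        p = tmp_path / "anchors.tsv"
        p.write_text("s1\t120\t150\ns2\t\t\n")
        anchors = load_anchor_file(p)
        assert anchors["s1"] == {"TATA": 120, "TSS": 150}
        assert anchors["s2"] == {"TATA": None, "TSS": None}


class TestCenterTracks:
    def test_start_anchor_left_nulls(self):
        tr = ImportanceTrack("s", np.arange(10.0))
        matrix, median, skipped = center_tracks([tr], "start", flank=2)
        row = matrix.iloc[0].to_numpy()
        assert np.isnan(row[0]) and np.isnan(row[1])
        assert np.allclose(row[2:], [0, 1, 2])
        assert skipped == 0

    def test_median_of_identical_tracks(self):
        tracks = [ImportanceTrack(f"s{i}", np.arange(20.0)) for i in range(5)]
        _, median, _ = center_tracks(tracks, "end", flank=3)
        # end anchor at 19: offsets -3..0 real, +1..+3 out of range
        assert np.allclose(median[:4], [16.0, 17.0, 18.0, 19.0])
        assert np.all(np.isnan(median[4:]))

    def test_spike_at_tata_peaks_at_zero_offset(self, rng):
        tracks = []
        for i in range(20):
            vals = rng.random(100) * 0.01
            t = int(rng.integers(30, 70))
            vals[t] = 5.0
            tracks.append(ImportanceTrack(f"s{i}", vals, anchors={"TATA": t}))
        _, median, _ = center_tracks(tracks, "TATA", flank=10)
        assert int(np.nanargmax(median)) == 10  # column 0 offset

    def test_missing_anchor_skipped_and_counted(self):
        t1 = ImportanceTrack("a", np.ones(10), anchors={"TATA": 5})
        t2 = ImportanceTrack("b", np.ones(10), anchors={"TATA": None})
        matrix, _, skipped = center_tracks([t1, t2], "TATA", flank=2)
        assert len(matrix) == 1 and skipped == 1
        with pytest.raises(ValueError):
            center_tracks([t2], "TATA", flank=2)


class TestConsensusAssembly:
    def test_tata_box_variants_stack(self):
        assert assemble_consensus(["TATAAA", "TATATA"]) == ["TATA[AT]A"]

    def test_disjoint_kmers_stay_separate(self):
        assert assemble_consensus(["AAAAAA", "CCCCCC"]) == ["AAAAAA", "CCCCCC"]

    def test_overlap_five_chains(self):
        assert assemble_consensus(["ACGTAC", "CGTACG"], min_overlap=5) == ["ACGTACG"]

    def test_three_way_chain(self):
        out = assemble_consensus(["TTAACA", "TAACAT", "AACATG"], min_overlap=5)
        assert out == ["TTAACATG"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_consensus(["AAAA", "CCCCC"])
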