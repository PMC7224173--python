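"""Downstream classification protocol: features, F1 samples, KS tests."""

import collections
import itertools

import numpy as np
import pytest

from synthnotes.extrinsic import (
    CNNConfig,
    LabelledDocument,
    LDAFeaturizer,
    ProtocolConfig,
    error_analysis,
    featurize_bow,
    fit_predict,
    ks_two_sample,
    label_documents,
    run_protocol,
)

from conftest import make_document


def make_labelled(doc_id, patient_id, sentences, label, n_classes):
    labels = np.zeros(n_classes, dtype=np.int64)
    labels[label] = 1
    return LabelledDocument(doc_id, patient_id, [list(s) for s in sentences], labels)


def signal_corpus(n_docs, n_classes, seed, marker_strength=1.0, n_sents=3, sent_len=6):
    """Random filler with a class-marker bigram in most sentences."""
    rng = np.random.default_rng(seed)
    filler = [f"w{i}" for i in range(30)]
    docs = []
    for i in range(n_docs):
        cls = i % n_classes
        sents = []
        for _ in range(n_sents):
            toks = [filler[int(j)] for j in rng.integers(0, len(filler), sent_len)]
            if rng.random() < marker_strength:
                toks[2:2] = [f"mark{cls}a", f"mark{cls}b"]
            sents.append(toks + ["."])
        docs.append(make_labelled(f"d{i}", f"p{i // 2}", sents, cls, n_classes))
    return docs


class TestBowFeatures:
    def test_feature_enumeration(self):
        docs = [
            make_labelled("d1", "p1", [["a", "b"]], 0, 2),
            make_labelled("d2", "p2", [["a", "b"]], 1, 2),
        ]
        X, index = featurize_bow(docs, max_n=5, min_df=2)
        assert set(index) == {("a",), ("b",), ("a", "b")}
        assert X.shape == (2, 3)
        assert X.toarray().tolist() == [[1, 1, 1], [1, 1, 1]]

    def test_min_df_prunes_rare_features(self):
        docs = [
            make_labelled("d1", "p1", [["a", "b"]], 0, 2),
            make_labelled("d2", "p2", [["a", "c"]], 1, 2),
        ]
        _, index = featurize_bow(docs, max_n=2, min_df=2)
        assert set(index) == {("a",)}

    def test_ngrams_confined_to_sentences(self):
        docs = [
            make_labelled("d1", "p1", [["a"], ["b"]], 0, 2),
            make_labelled("d2", "p2", [["a", "b"]], 1, 2),
        ]
        _, index = featurize_bow(docs, max_n=2, min_df=2)
        # ("a","b") spans a sentence boundary in d1, so its df is 1
        assert ("a", "b") not in index

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        docs = []
        for i in range(6):
            sents = [
                [f"t{int(j)}" for j in rng.integers(0, 4, int(rng.integers(2, 7)))]
                for _ in range(3)
            ]
            docs.append(make_labelled(f"d{i}", f"p{i}", sents, 0, 1))
        max_n = 3
        X, index = featurize_bow(docs, max_n=max_n, min_df=2)
        dense = X.toarray()
        cols = {g: c for c, g in enumerate(index)} if isinstance(index, list) else index
        for d_idx, doc in enumerate(docs):
            counts = collections.Counter()
            for sent in doc.sentences:
                for n in range(1, max_n + 1):
                    for k in range(len(sent) - n + 1):
                        counts[tuple(sent[k : k + n])] += 1
            for gram, col in cols.items():
                assert dense[d_idx, col] == counts[gram], (doc.document_id, gram)

    def test_shared_feature_index_aligns_train_test(self):
        train = [
            make_labelled("d1", "p1", [["a", "b"]], 0, 2),
            make_labelled("d2", "p2", [["a", "b"]], 1, 2),
        ]
        test = [make_labelled("d3", "p3", [["b", "z"]], 0, 2)]
        _, fi = featurize_bow(train, max_n=2, min_df=2)
        Xte, _ = featurize_bow(test, max_n=2, feature_index=fi)
        assert Xte.shape[1] == len(fi)
        # unseen token "z" contributes nothing
        assert Xte.toarray().sum() == 1  # only ("b",)


class TestLdaFeatures:
    def _reference(self):
        texts = [
            ["the patient had anxiety and panic .", "sleep was poor ."],
            ["mood was low with poor appetite .", "the patient had low mood ."],
        ]
        return [make_document(f"d{i}", f"p{i}", [t]) for i, t in enumerate(texts)]

    def test_rows_are_distributions(self):
        feat = LDAFeaturizer(self._reference(), n_topics=3, seed=0)
        docs = signal_corpus(4, 2, seed=1)
        X = feat.transform(docs)
        assert X.shape == (4, 3)
        assert np.all(X >= 0)
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_deterministic_given_seed(self):
        docs = signal_corpus(4, 2, seed=1)
        a = LDAFeaturizer(self._reference(), n_topics=3, seed=5).transform(docs)
        b = LDAFeaturizer(self._reference(), n_topics=3, seed=5).transform(docs)
        assert np.array_equal(a, b)


class TestFitPredict:
    def test_bow_separates_marked_classes(self):
        docs = signal_corpus(24, 2, seed=2)
        cfg = ProtocolConfig(classifiers=("bow",), rf_estimators=20)
        probs, skipped = fit_predict(docs[:16], docs[16:], "bow", cfg, seed=0)
        assert skipped == []
        labels = np.stack([d.labels for d in docs[16:]])
        assert ((probs >= 0.5).astype(int) == labels).all()

    def test_class_without_positives_skipped(self):
        docs = signal_corpus(8, 2, seed=3)
        for d in docs:
            d.labels[1] = 0  # class 1 never occurs in training
        cfg = ProtocolConfig(classifiers=("bow",), rf_estimators=5)
        probs, skipped = fit_predict(docs[:6], docs[6:], "bow", cfg, seed=0)
        assert skipped == [1]
        assert (probs[:, 1] == 0).all()

    def test_cnn_learns_separable_markers(self):
        docs = signal_corpus(24, 2, seed=4)
        cfg = ProtocolConfig(
            classifiers=("cnn",),
            cnn=CNNConfig(emb_dim=16, n_filters=16, epochs=10, max_len=60),
        )
        probs, _ = fit_predict(docs[:16], docs[16:], "cnn", cfg, seed=0)
        labels = np.stack([d.labels for d in docs[16:]])
        assert ((probs >= 0.5).astype(int) == labels).all()


class TestProtocol:
    def test_cv_mode_f1_sample_size(self):
        """Six binary tasks with five runs give 30 data points per cell."""
        docs = signal_corpus(36, 6, seed=5)
        cfg = ProtocolConfig(
            classifiers=("bow",), n_runs=5, cv_folds=3, rf_estimators=5
        )
        results = run_protocol({"genuine": docs}, docs, cfg, seed=0)
        sample = results[("genuine", "bow")]
        assert sample.data_points.shape == (6, 5)
        assert sample.values.size == 30

    def test_fixed_mode_f1_sample_size(self):
        """Thirteen binary tasks with five runs give 65 data points."""
        train = signal_corpus(52, 13, seed=6)
        test = signal_corpus(26, 13, seed=7)
        # rename test patients so the fixed-mode disjointness check passes
        test = [
            LabelledDocument(d.document_id, "q" + d.patient_id, d.sentences, d.labels)
            for d in test
        ]
        cfg = ProtocolConfig(classifiers=("bow",), n_runs=5, rf_estimators=5)
        results = run_protocol({"genuine": train}, test, cfg, seed=0)
        assert results[("genuine", "bow")].values.size == 65

    def test_fixed_mode_requires_patient_disjointness(self):
        docs = signal_corpus(8, 2, seed=8)
        cfg = ProtocolConfig(classifiers=("bow",), n_runs=1, rf_estimators=5)
        with pytest.raises(ValueError, match="overlap"):
            run_protocol({"genuine": docs}, docs, cfg, seed=0)

    def test_lda_requires_reference(self):
        docs = signal_corpus(8, 2, seed=9)
        cfg = ProtocolConfig(classifiers=("lda",), n_runs=1)
        with pytest.raises(ValueError, match="reference"):
            run_protocol({"genuine": docs[:4]}, docs[4:], cfg, seed=0)


class TestLabelDocuments:
    def test_one_hot_by_diagnosis_code(self, small_corpus):
        docs, _ = small_corpus
        classes = sorted({d.metas[0][0].diagnosis_code for d in docs})
        labelled = label_documents(docs, classes)
        for doc, lab in zip(docs, labelled):
            expected = classes.index(doc.metas[0][0].diagnosis_code)
            assert lab.labels.sum() == 1
            assert lab.labels[expected] == 1
            assert lab.patient_id == doc.patient_id


class TestKs:
    def test_identical_samples_have_zero_distance(self):
        a = [0.1, 0.4, 0.4, 0.9]
        res = ks_two_sample(a, list(a))
        assert res.d_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_samples_have_distance_one(self):
        res = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.d_statistic == pytest.approx(1.0)
        assert res.p_value < 0.2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_ecdf_supremum(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=11)
        b = rng.normal(loc=0.3, size=17)
        res = ks_two_sample(a, b)
        grid = np.concatenate([a, b])
        sup = max(
            abs(np.mean(a <= x) - np.mean(b <= x)) for x in grid
        )
        assert res.d_statistic == pytest.approx(sup, abs=1e-12)
        assert res.n1 == 11 and res.n2 == 17

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestErrorAnalysis:
    def test_hand_tabulated_counts(self):
        labels = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        predictions = {
            "genuine": np.array(
                [[0.9, 0.1], [0.8, 0.1], [0.6, 0.2], [0.1, 0.9]]
            ),
            "artificial": np.array(
                [[0.9, 0.1], [0.8, 0.2], [0.1, 0.6], [0.2, 0.8]]
            ),
        }
        out = error_analysis(predictions, labels, threshold=0.75)
        # genuine: doc 1 predicted class 0 with p=.8 though label is class 1
        # (confident false positive) and missed class 1 with p=.1 (confident
        # false negative)
        assert out["per_regime"]["genuine"] == {
            "false_positives": 1,
            "false_negatives": 1,
        }
        art = out["per_regime"]["artificial"]
        assert art["false_positives"] == 1
        assert art["false_negatives"] == 2
        # shared confident errors: doc 1 on both classes -> overlap 2/2
        assert art["overlap_with_baseline"] == pytest.approx(1.0)

    def test_threshold_validated(self):
        labels = np.array([[1]])
        preds = {"genuine": np.array([[0.9]])}
        with pytest.raises(ValueError):
            error_analysis(preds, labels, threshold=0.5)
        with pytest.raises(ValueError):
            error_analysis(preds, labels, threshold=1.2)

    def test_perfect_predictions_have_no_bad_errors(self):
        labels = np.array([[1, 0], [0, 1]])
        preds = {"genuine": np.array([[0.99, 0.01], [0.01, 0.99]])}
        out = error_analysis(preds, labels)
        assert out["per_regime"]["genuine"] == {
            "false_positives": 0,
            "false_negatives": 0,
        }
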