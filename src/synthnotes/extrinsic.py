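"""Downstream-utility evaluation: train classifiers on genuine vs artificial
text, test both on genuine data, compare the F1 distributions.

Three classifier families of increasing representational power are compared:
an n-gram (up to 5) bag-of-words with random forests, an LDA topic model
(fitted on the generation-training corpus) with random forests, and a
convolutional sentence classifier (parallel filter widths, max-over-time
pooling).  Each diagnosis label is cast as a binary task.  A training regime
(genuine, or one of the generation setups) yields, per classifier, a sample
of per-class per-run F1 values; two regimes are compared with the two-sample
Kolmogorov-Smirnov test.  Useful artificial data should both track the
genuine F1 distribution and preserve the ranking between classifier families.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .corpus import Document
from .memorisation import sentence_ngrams
from .nn.autograd import Tensor, bce_with_logits, concat, dropout, embedding
from .nn.layers import Adam, Embedding, Linear, Module, max_axis

CLASSIFIERS = ("bow", "lda", "cnn")


@dataclass
class LabelledDocument:
    """A whole document with a binary label vector over the configured classes."""

    document_id: str
    patient_id: str
    sentences: list[list[str]]
    labels: np.ndarray  # shape (n_classes,), values {0, 1}

    @property
    def tokens(self) -> list[str]:
        return [t for s in self.sentences for t in s]


def label_documents(
    docs: Sequence[Document], classes: Sequence[str]
) -> list[LabelledDocument]:
    """Label genuine documents by their diagnosis code (one-hot over classes)."""
    out = []
    class_idx = {c: i for i, c in enumerate(classes)}
    for doc in docs:
        labels = np.zeros(len(classes), dtype=np.int64)
        for _, meta in doc.sentences():
            if meta.diagnosis_code in class_idx:
                labels[class_idx[meta.diagnosis_code]] = 1
        out.append(
            LabelledDocument(
                doc.document_id,
                doc.patient_id,
                [list(s.tokens) for par in doc.paragraphs for s in par],
                labels,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Feature extraction


def featurize_bow(
    docs: Sequence[LabelledDocument],
    max_n: int = 5,
    min_df: int = 2,
    feature_index: dict[tuple[str, ...], int] | None = None,
):
    """Within-sentence n-gram (1..max_n) count matrix.

    Without a ``feature_index``, features with document frequency below
    ``min_df`` are dropped and a deterministic (sorted) index is built;
    passing an index projects *docs* onto an existing feature space.
    """
    if not docs:
        raise ValueError("empty corpus")
    doc_counts: list[Counter] = []
    for doc in docs:
        c: Counter = Counter()
        for sent in doc.sentences:
            for n in range(1, max_n + 1):
                c.update(sentence_ngrams(sent, n))
        doc_counts.append(c)
    if feature_index is None:
        df: Counter = Counter()
        for c in doc_counts:
            df.update(c.keys())
        feats = sorted(g for g, d in df.items() if d >= min_df)
        feature_index = {g: i for i, g in enumerate(feats)}
    rows, cols, vals = [], [], []
    for i, c in enumerate(doc_counts):
        for g, v in c.items():
            j = feature_index.get(g)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(v)
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(feature_index)), dtype=np.float64
    )
    return X, feature_index


class LDAFeaturizer:
    """Topic-proportion features from an LDA model fitted on the
    generation-training corpus (never on the classification training set)."""

    def __init__(
        self,
        reference_corpus: Sequence[Document],
        n_topics: int = 150,
        seed: int = 0,
        min_df: int = 2,
    ):
        if n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        ref_docs = [
            [t for par in doc.paragraphs for s in par for t in s.tokens]
            for doc in reference_corpus
        ]
        df: Counter = Counter()
        for toks in ref_docs:
            df.update(set(toks))
        vocab = sorted(w for w, d in df.items() if d >= min_df)
        if not vocab:
            raise ValueError("reference corpus vocabulary is empty")
        self.vocab_index = {w: i for i, w in enumerate(vocab)}
        X = self._count(ref_docs)
        self.model = LatentDirichletAllocation(
            n_components=n_topics, random_state=seed
        )
        self.model.fit(X)

    def _count(self, token_docs: Sequence[Sequence[str]]) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i, toks in enumerate(token_docs):
            for w, v in Counter(toks).items():
                j = self.vocab_index.get(w)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(v)
        return sp.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(token_docs), len(self.vocab_index)),
            dtype=np.float64,
        )

    def transform(self, docs: Sequence[LabelledDocument]) -> np.ndarray:
        props = self.model.transform(self._count([d.tokens for d in docs]))
        return props / props.sum(axis=1, keepdims=True)


def featurize_lda(
    train_reference_corpus: Sequence[Document],
    docs: Sequence[LabelledDocument],
    n_topics: int = 150,
    seed: int = 0,
) -> np.ndarray:
    """One-shot convenience wrapper around :class:`LDAFeaturizer`."""
    return LDAFeaturizer(train_reference_corpus, n_topics, seed).transform(docs)


# ---------------------------------------------------------------------------
# Convolutional sentence classifier


@dataclass
class CNNConfig:
    emb_dim: int = 32
    filter_widths: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 100
    dropout: float = 0.5
    epochs: int = 8
    learning_rate: float = 2e-3
    batch_size: int = 16
    max_len: int = 400
    min_token_freq: int = 1


class TextCNN(Module):
    """Parallel convolution filters over word embeddings with max-over-time
    pooling and a binary decision layer."""

    def __init__(self, rng: np.random.Generator, vocab_size: int, cfg: CNNConfig):
        self.cfg = cfg
        self.emb = Embedding(rng, vocab_size, cfg.emb_dim)
        self.filters = [
            Linear(rng, w * cfg.emb_dim, cfg.n_filters) for w in cfg.filter_widths
        ]
        self.out = Linear(rng, cfg.n_filters * len(cfg.filter_widths), 1)

    def forward(
        self, ids: np.ndarray, lengths: np.ndarray, rng: np.random.Generator,
        training: bool,
    ) -> Tensor:
        B, T = ids.shape
        pooled = []
        for w, lin in zip(self.cfg.filter_widths, self.filters):
            L = max(T - w + 1, 1)
            win_idx = ids[:, np.arange(L)[:, None] + np.arange(w)[None, :]]
            x = embedding(self.emb.w, win_idx).reshape(B, L, w * self.cfg.emb_dim)
            scores = lin(x).relu()
            # block windows that overlap padding
            valid = (np.arange(L)[None, :] + w) <= np.maximum(lengths, w)[:, None]
            mask = np.where(valid, 0.0, -1e9)[:, :, None]
            pooled.append(max_axis(scores + Tensor(mask), axis=1))
        h = concat(pooled, axis=-1)
        h = dropout(h, self.cfg.dropout, rng, training)
        return self.out(h).reshape(B)


class CNNBinaryClassifier:
    """One binary CNN, trained on token sequences."""

    def __init__(self, cfg: CNNConfig, seed: int):
        self.cfg = cfg
        self.seed = seed
        self.vocab: dict[str, int] | None = None
        self.model: TextCNN | None = None

    def _encode(self, docs: Sequence[LabelledDocument]):
        assert self.vocab is not None
        seqs = [
            [self.vocab.get(t, 1) for t in d.tokens[: self.cfg.max_len]]
            for d in docs
        ]
        T = max((len(s) for s in seqs), default=1)
        T = max(T, max(self.cfg.filter_widths))
        ids = np.zeros((len(seqs), T), dtype=np.int64)
        lengths = np.zeros(len(seqs), dtype=np.int64)
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            lengths[i] = max(len(s), 1)
        return ids, lengths

    def fit(self, docs: Sequence[LabelledDocument], y: np.ndarray) -> "CNNBinaryClassifier":
        counts: Counter = Counter()
        for d in docs:
            counts.update(d.tokens)
        kept = sorted(
            t for t, c in counts.items() if c >= self.cfg.min_token_freq
        )
        self.vocab = {t: i + 2 for i, t in enumerate(kept)}  # 0 pad, 1 unk
        rng = np.random.default_rng(self.seed)
        self.model = TextCNN(rng, len(self.vocab) + 2, self.cfg)
        opt = Adam(self.model.parameters(), lr=self.cfg.learning_rate)
        ids, lengths = self._encode(docs)
        y = np.asarray(y, dtype=np.float64)
        n = len(docs)
        for _ in range(self.cfg.epochs):
            perm = rng.permutation(n)
            for s in range(0, n, self.cfg.batch_size):
                b = perm[s : s + self.cfg.batch_size]
                logits = self.model.forward(ids[b], lengths[b], rng, training=True)
                loss = bce_with_logits(logits, y[b])
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, docs: Sequence[LabelledDocument]) -> np.ndarray:
        assert self.model is not None
        ids, lengths = self._encode(docs)
        rng = np.random.default_rng(0)
        probs = []
        for s in range(0, len(docs), 64):
            logits = self.model.forward(
                ids[s : s + 64], lengths[s : s + 64], rng, training=False
            )
            probs.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(probs)


# ---------------------------------------------------------------------------
# Training + protocol


@dataclass
class ProtocolConfig:
    classifiers: tuple[str, ...] = CLASSIFIERS
    n_runs: int = 5
    cv_folds: int | None = None
    bow_max_n: int = 5
    bow_min_df: int = 2
    rf_estimators: int = 100
    lda_topics: int = 150
    cnn: CNNConfig = field(default_factory=CNNConfig)


@dataclass
class F1Sample:
    regime: str
    classifier: str
    data_points: np.ndarray  # shape (n_classes, n_runs)
    skipped_classes: list[int] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.data_points.reshape(-1)

    @property
    def per_class_means(self) -> np.ndarray:
        return self.data_points.mean(axis=1)

    @property
    def mean(self) -> float:
        return float(self.data_points.mean())


def fit_predict(
    train_docs: Sequence[LabelledDocument],
    test_docs: Sequence[LabelledDocument],
    classifier: str,
    config: ProtocolConfig,
    seed: int,
    lda_featurizer: "LDAFeaturizer | None" = None,
) -> tuple[np.ndarray, list[int]]:
    """Per-class fit + predict; returns (probs (n_test, n_classes), skipped).

    Classes without a positive training example are flagged and skipped
    (their probability column is all zeros)."""
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    n_classes = len(train_docs[0].labels)
    y_train = np.stack([d.labels for d in train_docs])
    probs = np.zeros((len(test_docs), n_classes))
    skipped: list[int] = []
    if classifier == "bow":
        Xtr, fi = featurize_bow(train_docs, config.bow_max_n, config.bow_min_df)
        Xte, _ = featurize_bow(test_docs, config.bow_max_n, feature_index=fi)
    elif classifier == "lda":
        if lda_featurizer is None:
            raise ValueError("lda classifier requires a fitted LDAFeaturizer")
        Xtr = lda_featurizer.transform(train_docs)
        Xte = lda_featurizer.transform(test_docs)
    for c in range(n_classes):
        y = y_train[:, c]
        if y.sum() == 0:
            skipped.append(c)
            continue
        if y.sum() == len(y):
            probs[:, c] = 1.0
            continue
        if classifier in ("bow", "lda"):
            rf = RandomForestClassifier(
                n_estimators=config.rf_estimators, random_state=(seed + c) % 2**31
            )
            rf.fit(Xtr, y)
            pos = list(rf.classes_).index(1)
            probs[:, c] = rf.predict_proba(Xte)[:, pos]
        else:
            cnn = CNNBinaryClassifier(config.cnn, seed=(seed + c) % 2**31)
            cnn.fit(train_docs, y)
            probs[:, c] = cnn.predict_proba(test_docs)
    return probs, skipped


def _f1_per_class(
    probs: np.ndarray, labels: np.ndarray, skipped: Sequence[int]
) -> np.ndarray:
    n_classes = labels.shape[1]
    out = np.zeros(n_classes)
    for c in range(n_classes):
        if c in skipped:
            out[c] = np.nan
            continue
        out[c] = f1_score(labels[:, c], (probs[:, c] >= 0.5).astype(int), zero_division=0)
    return out


def _patient_folds(docs: Sequence[LabelledDocument], k: int, seed: int):
    patients = sorted({d.patient_id for d in docs})
    rng = np.random.default_rng(seed)
    perm = [patients[i] for i in rng.permutation(len(patients))]
    folds = [set(perm[i::k]) for i in range(k)]
    return folds


def run_protocol(
    train_by_regime: dict[str, Sequence[LabelledDocument]],
    test_docs: Sequence[LabelledDocument],
    config: ProtocolConfig,
    seed: int = 0,
    lda_reference: Sequence[Document] | None = None,
) -> dict[tuple[str, str], F1Sample]:
    """Fig.-2 protocol: per (regime, classifier), an F1 sample of shape
    (n_classes, n_runs).

    With ``cv_folds`` set, patient-disjoint folds are carved out of
    ``test_docs``; per run, F1 is averaged over folds, giving one data point
    per (class, run).  Without CV the test set is fixed and every training
    regime must be patient-disjoint from it.
    """
    lda_feat = None
    if "lda" in config.classifiers:
        if lda_reference is None:
            raise ValueError("lda classifier requires lda_reference corpus")
        lda_feat = LDAFeaturizer(lda_reference, config.lda_topics, seed)
    test_labels = np.stack([d.labels for d in test_docs])
    results: dict[tuple[str, str], F1Sample] = {}
    for regime, train_docs in train_by_regime.items():
        train_docs = list(train_docs)
        if config.cv_folds is None:
            overlap = {d.patient_id for d in train_docs} & {
                d.patient_id for d in test_docs
            }
            if overlap:
                raise ValueError(
                    f"patient overlap between regime {regime!r} training data "
                    f"and the test set: {sorted(overlap)[:5]}"
                )
        for clf in config.classifiers:
            n_classes = test_labels.shape[1]
            points = np.zeros((n_classes, config.n_runs))
            skipped_all: set[int] = set()
            for run in range(config.n_runs):
                run_seed = (seed * 100003 + run * 7919) % 2**31
                if config.cv_folds is None:
                    probs, skipped = fit_predict(
                        train_docs, test_docs, clf, config, run_seed, lda_feat
                    )
                    f1s = _f1_per_class(probs, test_labels, skipped)
                else:
                    folds = _patient_folds(test_docs, config.cv_folds, seed)
                    fold_f1 = []
                    for fold_patients in folds:
                        tr = [
                            d for d in train_docs if d.patient_id not in fold_patients
                        ]
                        te = [d for d in test_docs if d.patient_id in fold_patients]
                        if not tr or not te:
                            continue
                        probs, skipped = fit_predict(
                            tr, te, clf, config, run_seed, lda_feat
                        )
                        fold_f1.append(
                            _f1_per_class(
                                probs, np.stack([d.labels for d in te]), skipped
                            )
                        )
                    f1s = np.nanmean(np.stack(fold_f1), axis=0)
                nan_mask = np.isnan(f1s)
                skipped_all.update(np.where(nan_mask)[0].tolist())
                points[:, run] = np.where(nan_mask, 0.0, f1s)
            results[(regime, clf)] = F1Sample(
                regime, clf, points, sorted(skipped_all)
            )
    return results


# ---------------------------------------------------------------------------
# Statistics


@dataclass(frozen=True)
class KSComparison:
    d_statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float], exact: bool = False) -> KSComparison:
    """Two-sample Kolmogorov-Smirnov equality test (asymptotic p by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    return KSComparison(float(res.statistic), float(res.pvalue), a.size, b.size)


# ---------------------------------------------------------------------------
# Error analysis


def error_analysis(
    predictions: dict[str, np.ndarray],
    labels: np.ndarray,
    threshold: float = 0.75,
    baseline_regime: str = "genuine",
) -> dict:
    """High-confidence ("bad") errors per regime and their overlap with the
    baseline regime's errors.

    ``predictions``: regime -> positive-class probabilities (n_docs, n_classes).
    A bad error is a wrong prediction whose confidence max(p, 1-p) >= threshold.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    out: dict = {"per_regime": {}}
    bad_sets: dict[str, set] = {}
    for regime, probs in predictions.items():
        pred = probs >= 0.5
        conf = np.maximum(probs, 1 - probs)
        wrong = pred != labels.astype(bool)
        bad = wrong & (conf >= threshold)
        fp = bad & pred
        fn = bad & ~pred
        bad_sets[regime] = set(zip(*np.where(bad)))
        out["per_regime"][regime] = {
            "false_positives": int(fp.sum()),
            "false_negatives": int(fn.sum()),
        }
    base = bad_sets.get(baseline_regime, set())
    for regime, errs in bad_sets.items():
        if regime == baseline_regime:
            continue
        out["per_regime"][regime]["overlap_with_baseline"] = (
            len(errs & base) / len(base) if base else 0.0
        )
    return out
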