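"""Shared fixtures: small seeded corpora and tiny trained generators.

Heavy fixtures are session-scoped so several test modules can reuse the same
trained model instead of retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from synthnotes.corpus import ClinicalMeta, Document, Sentence, split_by_patient
from synthnotes.generator import GeneratorConfig, train
from synthnotes.keyphrases import ConditionedPair, load_stopwords
from synthnotes.synthetic import SyntheticCorpusConfig, generate_corpus


def make_meta(**overrides) -> ClinicalMeta:
    base = dict(
        diagnosis_code="f20",
        diagnosis_description="schizophrenia",
        gender="female",
        age=34,
        death_flag=False,
        relative_timestamp=3,
        section_label="summary",
        sentence_ordinal=1,
    )
    base.update(overrides)
    return ClinicalMeta(**base)


def make_pair(
    input_tokens,
    target_tokens,
    setup="all",
    phrases=(),
    document_id="d0",
    paragraph_index=0,
    sentence_index=0,
) -> ConditionedPair:
    return ConditionedPair(
        input_tokens=tuple(input_tokens),
        target_tokens=tuple(target_tokens),
        setup=setup,
        meta=make_meta(),
        phrases=tuple(tuple(p) for p in phrases),
        document_id=document_id,
        paragraph_index=paragraph_index,
        sentence_index=sentence_index,
    )


def make_document(doc_id: str, patient_id: str, paragraph_texts, **meta_overrides):
    """Build a Document from lists of sentence strings, one list per paragraph."""
    from synthnotes.corpus import SECTION_LABELS

    paragraphs, metas = [], []
    ordinals: dict[str, int] = {}
    for p_idx, texts in enumerate(paragraph_texts):
        section = SECTION_LABELS[p_idx % len(SECTION_LABELS)]
        sents, ms = [], []
        for s_idx, text in enumerate(texts):
            ordinals[section] = ordinals.get(section, 0) + 1
            sents.append(Sentence(text, doc_id, p_idx, s_idx))
            ms.append(
                make_meta(
                    section_label=section,
                    sentence_ordinal=ordinals[section],
                    **meta_overrides,
                )
            )
        paragraphs.append(sents)
        metas.append(ms)
    doc = Document(doc_id, patient_id, paragraphs, metas)
    doc.validate()
    return doc


def copy_task_pairs(n_pairs: int, seed: int, alphabet=None, length=(3, 6)):
    """Pairs whose target equals the input: an easy, fully learnable task."""
    rng = np.random.default_rng(seed)
    alphabet = alphabet or [f"tok{i}" for i in range(12)]
    pairs = []
    for i in range(n_pairs):
        n = int(rng.integers(length[0], length[1] + 1))
        toks = [alphabet[int(j)] for j in rng.integers(0, len(alphabet), size=n)]
        pairs.append(make_pair(toks, toks, document_id=f"d{i}"))
    return pairs


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


@pytest.fixture(scope="session")
def small_corpus():
    """A small labelled corpus with planted rare n-grams and its answer key."""
    cfg = SyntheticCorpusConfig(
        n_patients=12,
        docs_per_patient=2,
        sentences_per_doc=(6, 9),
        n_classes=2,
        class_signal_strength=0.8,
        vocab_size=150,
        n_planted_rare=8,
        seed=11,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_split(small_corpus):
    docs, _ = small_corpus
    return split_by_patient(docs, (0.8, 0.1, 0.1), seed=11)


@pytest.fixture(scope="session")
def copy_generator():
    """A tiny transformer overfitted on a 120-pair copy task."""
    pairs = copy_task_pairs(120, seed=5)
    cfg = GeneratorConfig(
        d_model=32,
        n_layers=1,
        n_heads=2,
        d_ff=64,
        epochs=40,
        batch_size=32,
        learning_rate=3e-3,
        seed=5,
    )
    return train(pairs, [], cfg), pairs
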