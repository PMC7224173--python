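"""Synthetic fixture corpora with controlled statistical structure.

The generator emulates the statistics a discharge-summary pipeline exploits,
without any clinical content: multi-section documents grouped by patient,
diagnosis-correlated marker phrases, a long-tailed (Zipf-like) filler token
distribution, and rare n-grams planted exactly once corpus-wide.  Filler text
comes from a small template grammar of stopword-scaffolded clauses so that
stopword-delimited content runs exist for key-phrase extraction.

Every generated corpus ships with an answer key: the marker-phrase-to-class
map and the exact location of every planted rare n-gram.  This makes class
separability and memorisation leakage directly checkable downstream.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import ClinicalMeta, Document, Sentence, SECTION_LABELS

# Hand-picked content words for the most frequent ranks (readability of
# examples); the tail is generated.  None of these are in the stopword list.
_COMMON_CONTENT = [
    "mood", "sleep", "medication", "appetite", "anxiety", "risk", "ward",
    "review", "insight", "energy", "thoughts", "plan", "dose", "symptoms",
    "contact", "family", "home", "team", "concerns", "support", "voices",
    "memory", "alcohol", "appointment", "progress", "behaviour", "speech",
    "weight", "history", "stress", "therapy", "leave", "care", "referral",
    "assessment", "improvement", "side", "effects", "follow", "clinic",
]

_DIAGNOSES = [
    ("F20", "schizophrenia"),
    ("F32", "depressive episode"),
    ("F60", "personality disorder"),
    ("F31", "bipolar affective disorder"),
    ("F25", "schizoaffective disorder"),
    ("F10", "alcohol use disorder"),
    ("F41", "anxiety disorder"),
    ("F43", "stress reaction"),
    ("F42", "obsessive compulsive disorder"),
    ("F33", "recurrent depression"),
]

# Clause templates: scaffolding tokens are all stopwords, so key-phrase
# candidates are exactly the content runs (plus "patient" where it appears).
_TEMPLATES = [
    ("the", "patient", "has", "{A}", "and", "{B}", "."),
    ("he", "was", "very", "{A}", "with", "{B}", "."),
    ("she", "has", "been", "{A}", "and", "has", "{B}", "."),
    ("there", "was", "no", "{A}", "on", "the", "{B}", "."),
    ("they", "did", "not", "have", "{A}", "or", "{B}", "."),
    ("we", "will", "have", "{A}", "for", "the", "{B}", "."),
]


@dataclass
class SyntheticCorpusConfig:
    n_patients: int = 60
    docs_per_patient: int = 2
    sentences_per_doc: tuple[int, int] = (8, 14)
    n_classes: int = 3
    class_signal_strength: float = 0.8
    vocab_size: int = 300
    zipf_exponent: float = 1.3
    n_planted_rare: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "docs_per_patient", "n_classes", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_rare < 0:
            raise ValueError("n_planted_rare must be non-negative")
        if not 0.0 <= self.class_signal_strength <= 1.0:
            raise ValueError("class_signal_strength must be in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.n_classes > len(_DIAGNOSES):
            raise ValueError(f"at most {len(_DIAGNOSES)} classes supported")


@dataclass(frozen=True)
class PlantedNGram:
    tokens: tuple[str, ...]
    document_id: str
    paragraph_index: int
    sentence_index: int


@dataclass
class AnswerKey:
    """Ground truth for a generated corpus."""

    marker_phrases: dict[str, tuple[str, str]]  # diagnosis_code -> 2-gram
    planted: list[PlantedNGram] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_phrases": {k: list(v) for k, v in self.marker_phrases.items()},
            "planted": [
                {
                    "tokens": list(p.tokens),
                    "document_id": p.document_id,
                    "paragraph_index": p.paragraph_index,
                    "sentence_index": p.sentence_index,
                }
                for p in self.planted
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnswerKey":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            marker_phrases={
                k: tuple(v) for k, v in payload["marker_phrases"].items()
            },
            planted=[
                PlantedNGram(
                    tuple(p["tokens"]),
                    p["document_id"],
                    p["paragraph_index"],
                    p["sentence_index"],
                )
                for p in payload["planted"]
            ],
        )


def _filler_vocab(n: int) -> list[str]:
    vocab = list(_COMMON_CONTENT[:n])
    i = 0
    while len(vocab) < n:
        vocab.append(f"w{i:04d}")
        i += 1
    return vocab


def generate_corpus(
    config: SyntheticCorpusConfig,
) -> tuple[list[Document], AnswerKey]:
    """Generate a fixture corpus and its answer key, reproducibly from the seed."""
    n_reserved = 2 * config.n_classes + 2 * config.n_planted_rare
    n_filler = config.vocab_size - n_reserved
    if n_filler < 20:
        raise ValueError(
            f"vocab_size {config.vocab_size} too small to host "
            f"{config.n_classes} marker phrases and {config.n_planted_rare} "
            f"planted n-grams plus filler vocabulary"
        )
    rng = np.random.default_rng(config.seed)
    filler = _filler_vocab(n_filler)
    ranks = np.arange(1, n_filler + 1, dtype=float)
    probs = ranks ** (-config.zipf_exponent)
    probs /= probs.sum()

    classes = _DIAGNOSES[: config.n_classes]
    markers = {
        code: (f"marker{k}a", f"marker{k}b") for k, (code, _) in enumerate(classes)
    }
    rare_ngrams = [
        (f"rare{j}a", f"rare{j}b") for j in range(config.n_planted_rare)
    ]

    def draw_run(length: int) -> list[str]:
        idx = rng.choice(n_filler, size=length, p=probs)
        return [filler[i] for i in idx]

    docs: list[Document] = []
    all_sentences: list[tuple[str, int, int]] = []  # (doc_id, par, sent) for planting
    sentence_tokens: dict[tuple[str, int, int], list[str]] = {}
    doc_records: list[dict] = []

    for p in range(config.n_patients):
        patient_id = f"p{p:05d}"
        cls_idx = int(rng.integers(config.n_classes))
        code, desc = classes[cls_idx]
        gender = "female" if rng.random() < 0.5 else "male"
        age = int(rng.integers(18, 91))
        death = bool(rng.random() < 0.07)
        for d in range(config.docs_per_patient):
            doc_id = f"d{p:05d}_{d}"
            rel_ts = int(rng.integers(-10, 31))
            lo, hi = config.sentences_per_doc
            n_sent = int(rng.integers(lo, hi + 1))
            # chunk into paragraphs of 2-4 sentences
            sizes: list[int] = []
            remaining = n_sent
            while remaining > 0:
                s = int(min(remaining, rng.integers(2, 5)))
                sizes.append(s)
                remaining -= s
            par_tokens: list[list[list[str]]] = []
            for p_idx, size in enumerate(sizes):
                par: list[list[str]] = []
                for s_idx in range(size):
                    tpl = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
                    if rng.random() < config.class_signal_strength:
                        run_a: list[str] = list(markers[code])
                    else:
                        run_a = draw_run(int(rng.integers(1, 4)))
                    run_b = draw_run(int(rng.integers(1, 4)))
                    toks: list[str] = []
                    for t in tpl:
                        if t == "{A}":
                            toks.extend(run_a)
                        elif t == "{B}":
                            toks.extend(run_b)
                        else:
                            toks.append(t)
                    par.append(toks)
                    all_sentences.append((doc_id, p_idx, s_idx))
                    sentence_tokens[(doc_id, p_idx, s_idx)] = toks
                par_tokens.append(par)
            doc_records.append(
                {
                    "doc_id": doc_id,
                    "patient_id": patient_id,
                    "code": code,
                    "desc": desc,
                    "gender": gender,
                    "age": age,
                    "death": death,
                    "rel_ts": rel_ts,
                    "par_tokens": par_tokens,
                }
            )

    if config.n_planted_rare > len(all_sentences):
        raise ValueError(
            f"cannot plant {config.n_planted_rare} rare n-grams into "
            f"{len(all_sentences)} sentences"
        )

    # Plant each rare n-gram exactly once, in its own sentence, as an extra
    # content run before the final period; add a 3-token decoy run so the
    # planted phrase is rarely the top-scored candidate of its sentence.
    # Each rare token also reappears once alone elsewhere, keeping its unigram
    # frequency at 2 so vocabulary pruning (min frequency 2) retains it.
    planted: list[PlantedNGram] = []
    pick = rng.choice(len(all_sentences), size=config.n_planted_rare, replace=False)
    picked_set = set(int(i) for i in pick)
    free = [i for i in range(len(all_sentences)) if i not in picked_set]
    companion_slots = rng.choice(
        len(free), size=2 * config.n_planted_rare, replace=True
    )
    for j, si in enumerate(sorted(picked_set)):
        doc_id, p_idx, s_idx = all_sentences[si]
        toks = sentence_tokens[(doc_id, p_idx, s_idx)]
        decoy = draw_run(3)
        insertion = list(rare_ngrams[j]) + ["and"] + decoy
        toks[-1:-1] = ["with"] + insertion  # before final "."
        planted.append(PlantedNGram(rare_ngrams[j], doc_id, p_idx, s_idx))
        for t_off, tok in enumerate(rare_ngrams[j]):
            ci = free[int(companion_slots[2 * j + t_off])]
            c_doc, c_p, c_s = all_sentences[ci]
            ctoks = sentence_tokens[(c_doc, c_p, c_s)]
            ctoks[-1:-1] = ["and", tok]

    # Assemble Document objects with per-sentence metadata.
    for rec in doc_records:
        paragraphs: list[list[Sentence]] = []
        metas: list[list[ClinicalMeta]] = []
        ordinals: dict[str, int] = {}
        for p_idx, par in enumerate(rec["par_tokens"]):
            section = SECTION_LABELS[p_idx % len(SECTION_LABELS)]
            sents: list[Sentence] = []
            ms: list[ClinicalMeta] = []
            for s_idx, toks in enumerate(par):
                ordinals[section] = ordinals.get(section, 0) + 1
                text = " ".join(toks)
                sents.append(Sentence(text, rec["doc_id"], p_idx, s_idx))
                ms.append(
                    ClinicalMeta(
                        diagnosis_code=rec["code"],
                        diagnosis_description=rec["desc"],
                        gender=rec["gender"],
                        age=rec["age"],
                        death_flag=rec["death"],
                        relative_timestamp=rec["rel_ts"],
                        section_label=section,
                        sentence_ordinal=ordinals[section],
                    )
                )
            paragraphs.append(sents)
            metas.append(ms)
        doc = Document(rec["doc_id"], rec["patient_id"], paragraphs, metas)
        doc.validate()
        docs.append(doc)

    key = AnswerKey(marker_phrases=markers, planted=planted)
    return docs, key


def corpus_statistics(docs: list[Document]) -> dict:
    """Exact token/sentence counts, mean sentence length, unigram spectrum."""
    if not docs:
        raise ValueError("empty corpus")
    counts: Counter[str] = Counter()
    n_sent = 0
    n_tok = 0
    for doc in docs:
        for sent, _ in doc.sentences():
            n_sent += 1
            n_tok += len(sent.tokens)
            counts.update(sent.tokens)
    if n_sent == 0:
        raise ValueError("corpus has no sentences")
    spectrum = sorted(counts.values(), reverse=True)
    return {
        "n_tokens": n_tok,
        "n_sentences": n_sent,
        "mean_sentence_length": n_tok / n_sent,
        "unigram_spectrum": spectrum,
        "n_types": len(counts),
    }
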