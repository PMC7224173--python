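"""Core document model and corpus exchange format.

A corpus is a collection of :class:`Document` objects, each owned by one
patient and structured as paragraphs of sentences.  Every sentence carries a
:class:`ClinicalMeta` record (diagnosis, demographics, record section,
position) so that metadata can travel with the text into conditioning inputs.

The on-disk exchange format is UTF-8 JSON-lines: one record per sentence with
the fields ``document_id, patient_id, paragraph_index, sentence_index, text``
plus a ``meta`` object.  Writing then reading a valid corpus is the identity
(see ``FORMAT.md`` in the repository root for the normative definition).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

SECTION_LABELS = ("summary", "discharge_plan", "comments")

_PUNCT = set(string.punctuation)


def tokenize(text: str) -> list[str]:
    """Lowercase and split *text* into tokens.

    Splits on whitespace, then detaches any leading/trailing punctuation
    characters as standalone tokens ("allergies." -> ["allergies", "."]).
    Internal punctuation (hyphens, apostrophes) is kept inside the token.
    Total and deterministic; idempotent under join-with-spaces + re-tokenise.
    """
    out: list[str] = []
    for word in text.lower().split():
        out.extend(_split_word(word))
    return out


def _split_word(word: str) -> list[str]:
    lead: list[str] = []
    trail: list[str] = []
    i, j = 0, len(word)
    while i < j and word[i] in _PUNCT:
        lead.append(word[i])
        i += 1
    while j > i and word[j - 1] in _PUNCT:
        trail.append(word[j - 1])
        j -= 1
    core = word[i:j]
    return lead + ([core] if core else []) + trail[::-1]


def is_punctuation(token: str) -> bool:
    return bool(token) and all(c in _PUNCT for c in token)


def is_numeric(token: str) -> bool:
    stripped = token.replace(".", "", 1).replace("-", "", 1)
    return bool(stripped) and stripped.isdigit()


@dataclass(frozen=True)
class ClinicalMeta:
    """Per-sentence clinical metadata attached to a discharge-summary line."""

    diagnosis_code: str
    diagnosis_description: str
    gender: str
    age: int
    death_flag: bool
    relative_timestamp: int
    section_label: str
    sentence_ordinal: int

    def __post_init__(self) -> None:
        if self.section_label not in SECTION_LABELS:
            raise ValueError(
                f"unknown section_label {self.section_label!r}; "
                f"expected one of {SECTION_LABELS}"
            )
        if self.sentence_ordinal < 1:
            raise ValueError("sentence_ordinal must be >= 1")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    def to_dict(self) -> dict:
        return {
            "diagnosis_code": self.diagnosis_code,
            "diagnosis_description": self.diagnosis_description,
            "gender": self.gender,
            "age": self.age,
            "death_flag": self.death_flag,
            "relative_timestamp": self.relative_timestamp,
            "section_label": self.section_label,
            "sentence_ordinal": self.sentence_ordinal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalMeta":
        return cls(**d)


@dataclass(frozen=True)
class Sentence:
    """One sentence of a document; ``tokens`` is the tokenisation of ``raw_text``."""

    raw_text: str
    document_id: str
    paragraph_index: int
    sentence_index_in_paragraph: int
    tokens: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.paragraph_index < 0 or self.sentence_index_in_paragraph < 0:
            raise ValueError("sentence indices must be non-negative")
        object.__setattr__(self, "tokens", tuple(tokenize(self.raw_text)))


@dataclass
class Document:
    """A discharge summary: paragraphs of sentences with aligned metadata."""

    document_id: str
    patient_id: str
    paragraphs: list[list[Sentence]]
    metas: list[list[ClinicalMeta]]

    def validate(self) -> None:
        if len(self.paragraphs) != len(self.metas):
            raise ValueError(f"{self.document_id}: paragraphs/metas length mismatch")
        ordinals: dict[str, int] = {}
        for par, mpar in zip(self.paragraphs, self.metas):
            if len(par) != len(mpar):
                raise ValueError(f"{self.document_id}: sentence/meta length mismatch")
            for sent, meta in zip(par, mpar):
                if sent.document_id != self.document_id:
                    raise ValueError(
                        f"sentence document_id {sent.document_id!r} != "
                        f"{self.document_id!r}"
                    )
                prev = ordinals.get(meta.section_label, 0)
                if meta.sentence_ordinal != prev + 1:
                    raise ValueError(
                        f"{self.document_id}: section {meta.section_label!r} "
                        f"ordinal {meta.sentence_ordinal} after {prev}"
                    )
                ordinals[meta.section_label] = meta.sentence_ordinal

    def sentences(self) -> Iterator[tuple[Sentence, ClinicalMeta]]:
        for par, mpar in zip(self.paragraphs, self.metas):
            yield from zip(par, mpar)

    @property
    def n_sentences(self) -> int:
        return sum(len(p) for p in self.paragraphs)


@dataclass
class CorpusSplit:
    train: list[Document]
    validation: list[Document]
    test: list[Document]

    def validate(self) -> None:
        parts = [
            {d.patient_id for d in docs}
            for docs in (self.train, self.validation, self.test)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                common = parts[i] & parts[j]
                if common:
                    raise ValueError(f"patient overlap between split parts: {common}")


# ---------------------------------------------------------------------------
# Exchange format


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    """Serialise *docs* to JSON-lines, one record per sentence, grouped by document."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            doc.validate()
            for p_idx, (par, mpar) in enumerate(zip(doc.paragraphs, doc.metas)):
                for s_idx, (sent, meta) in enumerate(zip(par, mpar)):
                    rec = {
                        "document_id": doc.document_id,
                        "patient_id": doc.patient_id,
                        "paragraph_index": p_idx,
                        "sentence_index": s_idx,
                        "text": sent.raw_text,
                        "meta": meta.to_dict(),
                    }
                    fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSON-lines corpus; documents are reassembled in file order."""
    path = Path(path)
    builders: dict[str, dict] = {}
    order: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                doc_id = rec["document_id"]
                patient_id = rec["patient_id"]
                p_idx = int(rec["paragraph_index"])
                s_idx = int(rec["sentence_index"])
                text = rec["text"]
                meta = ClinicalMeta.from_dict(rec["meta"])
            except ValueError as exc:  # includes json + meta validation errors
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}")
            except KeyError as exc:
                raise ValueError(f"{path}: missing field {exc} at line {lineno}")
            if doc_id not in builders:
                builders[doc_id] = {"patient_id": patient_id, "sents": []}
                order.append(doc_id)
            builders[doc_id]["sents"].append(
                (p_idx, s_idx, Sentence(text, doc_id, p_idx, s_idx), meta)
            )
    docs = []
    for doc_id in order:
        b = builders[doc_id]
        paragraphs: list[list[Sentence]] = []
        metas: list[list[ClinicalMeta]] = []
        for p_idx, s_idx, sent, meta in sorted(b["sents"], key=lambda t: (t[0], t[1])):
            while len(paragraphs) <= p_idx:
                paragraphs.append([])
                metas.append([])
            paragraphs[p_idx].append(sent)
            metas[p_idx].append(meta)
        doc = Document(doc_id, b["patient_id"], paragraphs, metas)
        doc.validate()
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# Patient-grouped splitting


def split_by_patient(
    docs: Sequence[Document],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> CorpusSplit:
    """Partition documents into train/validation/test by patient.

    All documents of a patient land in one part, preventing leakage across
    parts.  Deterministic given *seed*; realised patient counts are within one
    patient of the requested fractions.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must have exactly three entries")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    patients = sorted({d.patient_id for d in docs})
    if len(patients) < 3:
        raise ValueError(f"need at least 3 distinct patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    perm = [patients[i] for i in rng.permutation(len(patients))]
    n = len(perm)
    b1 = round(fractions[0] * n)
    b2 = round((fractions[0] + fractions[1]) * n)
    assign = {p: 0 for p in perm[:b1]}
    assign.update({p: 1 for p in perm[b1:b2]})
    assign.update({p: 2 for p in perm[b2:]})
    parts: tuple[list[Document], ...] = ([], [], [])
    for doc in docs:
        parts[assign[doc.patient_id]].append(doc)
    split = CorpusSplit(*parts)
    split.validate()
    return split
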