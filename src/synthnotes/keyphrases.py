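"""Key-phrase extraction (RAKE) and conditioning-pair construction.

Key phrases are extracted per paragraph and matched back to the sentence they
came from; the conditioning input for a sentence is an optional block of
metadata abbreviation tokens followed by the sentence's selected key-phrase
tokens, with no boundary markers between phrases.  Four conditioning setups
are supported:

``all``       every extracted phrase, no metadata block;
``top_meta``  metadata block + the paragraph's top-scored phrases;
``one_meta``  metadata block + at most one best phrase per sentence;
``key``       the copy baseline — the phrases themselves are both input
              and reference output (no model fills any context).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from math import ceil
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import ClinicalMeta, Document, Sentence, is_punctuation

SETUPS = ("all", "top_meta", "one_meta", "key")


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stopword list (one token per line); defaults to the packaged list."""
    if path is None:
        text = (
            resources.files("synthnotes.data").joinpath("stopwords.txt").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class KeyPhrase:
    tokens: tuple[str, ...]
    score: float
    paragraph_index: int
    matched_sentence: int  # sentence index within the paragraph
    start: int  # token offset of the run within its sentence

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")


def rake_extract(
    paragraph: Sequence[Sentence], stopwords: frozenset[str]
) -> list[KeyPhrase]:
    """RAKE over one paragraph: stopword/punctuation-delimited content runs,
    scored by the sum of member word scores deg(w)/freq(w).

    freq(w) counts candidate occurrences containing *w* (with multiplicity);
    deg(w) sums candidate lengths over those occurrences.  Candidates are
    tagged with the sentence they came from.
    """
    if not paragraph:
        raise ValueError("empty paragraph")
    if not stopwords:
        raise ValueError("empty stopword list")
    candidates: list[tuple[tuple[str, ...], int, int]] = []  # (run, sent_idx, start)
    for s_idx, sent in enumerate(paragraph):
        run: list[str] = []
        start = 0
        for t_idx, tok in enumerate(sent.tokens):
            if tok in stopwords or is_punctuation(tok):
                if run:
                    candidates.append((tuple(run), s_idx, start))
                    run = []
            else:
                if not run:
                    start = t_idx
                run.append(tok)
        if run:
            candidates.append((tuple(run), s_idx, start))
    freq: Counter[str] = Counter()
    deg: Counter[str] = Counter()
    for run, _, _ in candidates:
        for w in run:
            freq[w] += 1
            deg[w] += len(run)
    phrases = []
    p_idx = paragraph[0].paragraph_index
    for run, s_idx, start in candidates:
        score = sum(deg[w] / freq[w] for w in run)
        phrases.append(KeyPhrase(run, score, p_idx, s_idx, start))
    return phrases


def select_phrases(
    phrases: Sequence[KeyPhrase],
    setup: str,
    keep_fraction: float = 0.6,
) -> list[KeyPhrase]:
    """Select the conditioning phrases of one paragraph for a setup.

    ``all``/``key`` keep everything.  ``top_meta`` keeps the paragraph's top
    score quantile (``keep_fraction`` of phrases, ties broken by earlier
    position) plus each sentence's best phrase, so that no sentence loses its
    strongest anchor.  ``one_meta`` keeps exactly the best phrase per sentence.
    Within-sentence positional order is preserved in the result.
    """
    if setup not in SETUPS:
        raise ValueError(f"unknown setup {setup!r}; expected one of {SETUPS}")
    if setup in ("all", "key"):
        return list(phrases)
    order = sorted(
        range(len(phrases)),
        key=lambda i: (-phrases[i].score, phrases[i].matched_sentence, phrases[i].start),
    )
    best_per_sentence: dict[int, int] = {}
    for i in order:
        best_per_sentence.setdefault(phrases[i].matched_sentence, i)
    if setup == "one_meta":
        chosen = set(best_per_sentence.values())
    else:  # top_meta
        k = ceil(keep_fraction * len(phrases))
        chosen = set(order[:k]) | set(best_per_sentence.values())
    return sorted(
        (phrases[i] for i in chosen),
        key=lambda p: (p.matched_sentence, p.start),
    )


# ---------------------------------------------------------------------------
# Metadata rendering: each field becomes exactly one abbreviation token.


def render_meta(meta: ClinicalMeta) -> list[str]:
    ts = meta.relative_timestamp
    ts_tok = "t_pre" if ts < 0 else ("t_wk1" if ts <= 7 else "t_late")
    return [
        meta.diagnosis_code.lower(),
        meta.gender,
        f"age_{(meta.age // 10) * 10}s",
        "died" if meta.death_flag else "alive",
        ts_tok,
        f"sec_{meta.section_label}",
        f"ord_{min(meta.sentence_ordinal, 10)}",
    ]


@dataclass(frozen=True)
class ConditionedPair:
    """One training/generation example: conditioning input -> original sentence."""

    input_tokens: tuple[str, ...]
    target_tokens: tuple[str, ...]
    setup: str
    meta: ClinicalMeta
    phrases: tuple[tuple[str, ...], ...]  # selected phrase runs, in order
    document_id: str
    paragraph_index: int
    sentence_index: int

    @property
    def phrase_tokens(self) -> tuple[str, ...]:
        out: list[str] = []
        for ph in self.phrases:
            out.extend(ph)
        return tuple(out)


def build_conditioned_pairs(
    doc: Document,
    setup: str,
    stopwords: frozenset[str],
    keep_fraction: float = 0.6,
) -> list[ConditionedPair]:
    """Build one conditioned pair per sentence of *doc* under *setup*.

    Metadata-bearing setups (``top_meta``, ``one_meta``) prepend the rendered
    metadata block; ``all`` uses phrases only.  For ``key`` the target is the
    concatenated phrases themselves (the copy baseline's reference output).
    Sentences with no selected phrase still yield a pair (metadata-only input
    for meta setups, empty input otherwise) to keep paragraph alignment.
    """
    if setup not in SETUPS:
        raise ValueError(f"unknown setup {setup!r}; expected one of {SETUPS}")
    pairs: list[ConditionedPair] = []
    for p_idx, (par, mpar) in enumerate(zip(doc.paragraphs, doc.metas)):
        if not par:
            continue
        phrases = rake_extract(par, stopwords)
        selected = select_phrases(phrases, setup, keep_fraction)
        by_sentence: dict[int, list[KeyPhrase]] = {}
        for ph in selected:
            by_sentence.setdefault(ph.matched_sentence, []).append(ph)
        for s_idx, (sent, meta) in enumerate(zip(par, mpar)):
            sel = sorted(by_sentence.get(s_idx, []), key=lambda p: p.start)
            phrase_toks = [t for ph in sel for t in ph.tokens]
            if setup in ("top_meta", "one_meta"):
                input_toks = tuple(render_meta(meta)) + tuple(phrase_toks)
            else:
                input_toks = tuple(phrase_toks)
            if setup == "key":
                target = tuple(phrase_toks)
            else:
                target = sent.tokens
            pairs.append(
                ConditionedPair(
                    input_tokens=input_toks,
                    target_tokens=target,
                    setup=setup,
                    meta=meta,
                    phrases=tuple(ph.tokens for ph in sel),
                    document_id=doc.document_id,
                    paragraph_index=p_idx,
                    sentence_index=s_idx,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Vocabulary

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<s>", "</s>"
SPECIALS = (PAD, UNK, BOS, EOS)


class Vocabulary:
    """Token-index mapping with reserved specials and a frequency floor.

    Tokens seen fewer than ``min_frequency`` times in the training pairs are
    excluded from the mapping and encode to the unknown symbol; with the
    default floor of 2 no frequency-1 unigram enters the vocabulary.
    """

    def __init__(self, counts: Counter, min_frequency: int = 2):
        if min_frequency < 2:
            raise ValueError("min_frequency must be >= 2")
        self.min_frequency = min_frequency
        kept = [t for t, c in counts.items() if c >= min_frequency]
        kept.sort(key=lambda t: (-counts[t], t))
        self.index_to_token: list[str] = list(SPECIALS) + kept
        self.token_to_index: dict[str, int] = {
            t: i for i, t in enumerate(self.index_to_token)
        }

    def __len__(self) -> int:
        return len(self.index_to_token)

    @property
    def pad(self) -> int:
        return self.token_to_index[PAD]

    @property
    def unk(self) -> int:
        return self.token_to_index[UNK]

    @property
    def bos(self) -> int:
        return self.token_to_index[BOS]

    @property
    def eos(self) -> int:
        return self.token_to_index[EOS]

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        unk = self.unk
        return np.array(
            [self.token_to_index.get(t, unk) for t in tokens], dtype=np.int64
        )

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.index_to_token[i] for i in ids]

    def to_dict(self) -> dict:
        return {
            "min_frequency": self.min_frequency,
            "tokens": self.index_to_token[len(SPECIALS):],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        vocab = cls.__new__(cls)
        vocab.min_frequency = d["min_frequency"]
        vocab.index_to_token = list(SPECIALS) + list(d["tokens"])
        vocab.token_to_index = {t: i for i, t in enumerate(vocab.index_to_token)}
        return vocab


def build_vocabulary(
    pairs: Sequence[ConditionedPair], min_frequency: int = 2
) -> Vocabulary:
    """Vocabulary over input and target tokens of the training pairs."""
    if not pairs:
        raise ValueError("cannot build a vocabulary from an empty pair set")
    counts: Counter[str] = Counter()
    for pair in pairs:
        counts.update(pair.input_tokens)
        counts.update(pair.target_tokens)
    return Vocabulary(counts, min_frequency)


# ---------------------------------------------------------------------------
# Key-phrase-removal ablation


@dataclass
class BareDocument:
    """A document reduced to labelled sentences (for ablation classifiers)."""

    document_id: str
    patient_id: str
    diagnosis_code: str
    sentences: list[list[str]]


def _delete_runs(tokens: list[str], runs: list[tuple[str, ...]]) -> list[str]:
    out = list(tokens)
    for run in sorted(set(runs), key=len, reverse=True):
        n = len(run)
        if n == 0:
            continue
        i = 0
        res: list[str] = []
        while i < len(out):
            if tuple(out[i : i + n]) == run:
                i += n
            else:
                res.append(out[i])
                i += 1
        out = res
    return out


def strip_common_keyphrases(
    genuine: Sequence[Document],
    artificial: Sequence["BareDocument"],
    phrases: Iterable[tuple[str, ...]],
) -> tuple[list[BareDocument], list[BareDocument]]:
    """Delete every occurrence of each selected phrase from both corpora.

    Sentences emptied entirely are dropped.  Returns context-only corpora for
    the ablation classifiers; longer phrases are deleted first so overlapping
    runs resolve deterministically.
    """
    runs = [tuple(p) for p in phrases]

    def strip_doc(doc_id, patient_id, code, sentences) -> BareDocument | None:
        kept = [r for s in sentences if (r := _delete_runs(list(s), runs))]
        return BareDocument(doc_id, patient_id, code, kept)

    out_gen: list[BareDocument] = []
    for doc in genuine:
        code = next(iter(doc.sentences()))[1].diagnosis_code if doc.n_sentences else ""
        sents = [list(s.tokens) for par in doc.paragraphs for s in par]
        bare = strip_doc(doc.document_id, doc.patient_id, code, sents)
        if bare is not None:
            out_gen.append(bare)
    out_art: list[BareDocument] = []
    for doc in artificial:
        bare = strip_doc(
            doc.document_id, doc.patient_id, doc.diagnosis_code, doc.sentences
        )
        if bare is not None:
            out_art.append(bare)
    return out_gen, out_art
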