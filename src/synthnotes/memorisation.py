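"""Memorisation audit: do rare training n-grams resurface in generated text?

The audit regenerates training sentences that contain a rare (lower frequency
quartile) or frequent (upper quartile) n-gram and measures how often the
target n-gram was already present in the conditioning key phrases (%, in)
versus present in the regenerated output (%, out).  The gap between the two
is the memorised-beyond-input rate — rare content the model restored without
being given it.  Forced-decoding perplexity of the sampled original sentences
quantifies how confidently the model reproduces them, and a token-composition
breakdown shows what fraction of leaked tokens are stopwords, punctuation or
numbers (content that a rule-based filter could remove).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Sequence

import numpy as np

from .corpus import Document, is_numeric, is_punctuation
from .generator import TrainedGenerator, generate, perplexity
from .keyphrases import ConditionedPair, build_conditioned_pairs

DEFAULT_NS = (2, 3, 5)


@dataclass
class NGramFrequencyIndex:
    """Per-n n-gram frequencies and quartile thresholds over distinct n-grams."""

    counts: dict[int, Counter]
    thresholds: dict[int, tuple[int, int]]  # n -> (lower, upper)


def _quartile_thresholds(freqs: Sequence[int]) -> tuple[int, int]:
    """Conservative quartiles of the distinct-n-gram frequency distribution:
    lower rank floor((N+1)/4), upper rank ceil(3(N+1)/4), 1-based, clipped."""
    s = sorted(freqs)
    n = len(s)
    lo_rank = min(max(floor((n + 1) / 4), 1), n)
    hi_rank = min(max(ceil(3 * (n + 1) / 4), 1), n)
    return s[lo_rank - 1], s[hi_rank - 1]


def sentence_ngrams(tokens: Sequence[str], n: int):
    """Within-sentence n-grams; never crosses sentence boundaries."""
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def build_ngram_index(
    train_docs: Sequence[Document], ns: Sequence[int] = DEFAULT_NS
) -> NGramFrequencyIndex:
    if not train_docs:
        raise ValueError("empty corpus")
    counts: dict[int, Counter] = {n: Counter() for n in ns}
    for doc in train_docs:
        for sent, _ in doc.sentences():
            for n in ns:
                counts[n].update(sentence_ngrams(sent.tokens, n))
    thresholds = {}
    for n in ns:
        if not counts[n]:
            raise ValueError(f"corpus contains no {n}-grams")
        thresholds[n] = _quartile_thresholds(list(counts[n].values()))
    return NGramFrequencyIndex(counts, thresholds)


@dataclass(frozen=True)
class SampleItem:
    document: Document
    paragraph_index: int
    sentence_index: int
    target: tuple[str, ...]


@dataclass
class QuartileSample:
    n: int
    quartile: str  # "low" | "high"
    items: list[SampleItem]
    shortfall: int = 0


def sample_sentences_by_quartile(
    train_docs: Sequence[Document],
    index: NGramFrequencyIndex,
    n: int,
    quartile: str,
    k: int = 1000,
    seed: int = 0,
) -> QuartileSample:
    """Sample k unique sentences containing an n-gram in the requested
    frequency-quartile class; one target n-gram per sentence (the lowest- or
    highest-frequency one, earliest position on ties)."""
    if n not in index.counts:
        raise ValueError(f"{n}-grams not present in the index")
    if quartile not in ("low", "high"):
        raise ValueError("quartile must be 'low' or 'high'")
    lower, upper = index.thresholds[n]
    counts = index.counts[n]
    eligible: list[SampleItem] = []
    for doc in train_docs:
        for p_idx, par in enumerate(doc.paragraphs):
            for s_idx, sent in enumerate(par):
                grams = sentence_ngrams(sent.tokens, n)
                if quartile == "low":
                    in_class = [g for g in grams if counts[g] <= lower]
                    pick = min(in_class, key=counts.get, default=None)
                else:
                    in_class = [g for g in grams if counts[g] >= upper]
                    pick = max(in_class, key=counts.get, default=None)
                if pick is not None:
                    eligible.append(SampleItem(doc, p_idx, s_idx, pick))
    rng = np.random.default_rng(seed)
    if k >= len(eligible):
        return QuartileSample(n, quartile, eligible, shortfall=k - len(eligible))
    idx = sorted(rng.choice(len(eligible), size=k, replace=False))
    return QuartileSample(n, quartile, [eligible[i] for i in idx])


@dataclass
class MemorisationRow:
    n: int
    quartile: str
    sample_size: int
    shortfall: int
    pct_in: float
    pct_out: float
    pct_out_beyond_input: float
    mean_ppl: float | None
    composition: dict[str, float] = field(default_factory=dict)


def _contains(stream: Sequence[str], target: tuple[str, ...]) -> bool:
    n = len(target)
    return any(tuple(stream[i : i + n]) == target for i in range(len(stream) - n + 1))


def _in_input(pair: ConditionedPair, target: tuple[str, ...], within_phrase_only: bool) -> bool:
    if within_phrase_only:
        return any(_contains(ph, target) for ph in pair.phrases)
    return _contains(pair.phrase_tokens, target)


def audit(
    gen: TrainedGenerator,
    sample: QuartileSample,
    setup: str,
    stopwords: frozenset[str],
    keep_fraction: float = 0.6,
    within_phrase_only: bool = False,
) -> MemorisationRow:
    """One report row: %in, %out, memorised-beyond-input rate, forced PPL and
    leaked-token composition for the sampled sentences.

    ``within_phrase_only`` restricts input containment to a single key
    phrase's token run; the default checks the concatenated phrase stream,
    which makes the copy baseline satisfy pct_out == pct_in exactly.
    """
    if gen.train_setup is not None and gen.train_setup != setup:
        raise ValueError(
            f"setup mismatch: model trained with {gen.train_setup!r}, audit "
            f"requested {setup!r}"
        )
    pairs: list[ConditionedPair] = []
    pair_cache: dict[str, dict[tuple[int, int], ConditionedPair]] = {}
    for item in sample.items:
        doc_id = item.document.document_id
        if doc_id not in pair_cache:
            pair_cache[doc_id] = {
                (p.paragraph_index, p.sentence_index): p
                for p in build_conditioned_pairs(
                    item.document, setup, stopwords, keep_fraction
                )
            }
        pairs.append(pair_cache[doc_id][(item.paragraph_index, item.sentence_index)])
    outputs = generate(gen, pairs)
    n_items = len(sample.items)
    if n_items == 0:
        raise ValueError("empty sample")
    in_flags = [
        _in_input(pair, item.target, within_phrase_only)
        for pair, item in zip(pairs, sample.items)
    ]
    out_flags = [
        _contains(seq, item.target)
        for seq, item in zip(outputs.sequences, sample.items)
    ]
    absent = [i for i in range(n_items) if not in_flags[i]]
    beyond = (
        100.0 * sum(out_flags[i] for i in absent) / len(absent) if absent else 0.0
    )
    mean_ppl = None if gen.is_copy_baseline else perplexity(gen, pairs)
    leaked = [
        sample.items[i].target for i in range(n_items) if out_flags[i]
    ]
    return MemorisationRow(
        n=sample.n,
        quartile=sample.quartile,
        sample_size=n_items,
        shortfall=sample.shortfall,
        pct_in=100.0 * sum(in_flags) / n_items,
        pct_out=100.0 * sum(out_flags) / n_items,
        pct_out_beyond_input=beyond,
        mean_ppl=mean_ppl,
        composition=composition_of_leaks(leaked, stopwords),
    )


def composition_of_leaks(
    leaked: Sequence[tuple[str, ...]], stopwords: frozenset[str]
) -> dict[str, float]:
    """Token-level fractions over all tokens of the leaked n-grams.

    Classification priority: punctuation, numeric, stopword, other; the four
    fractions sum to 1 (all zero for an empty leaked set).
    """
    tokens = [t for gram in leaked for t in gram]
    if not tokens:
        return {"stopword": 0.0, "punctuation": 0.0, "numeric": 0.0, "other": 0.0}
    n = len(tokens)
    punct = sum(is_punctuation(t) for t in tokens)
    numeric = sum(is_numeric(t) for t in tokens if not is_punctuation(t))
    stop = sum(
        t in stopwords
        for t in tokens
        if not is_punctuation(t) and not is_numeric(t)
    )
    other = n - punct - numeric - stop
    return {
        "stopword": stop / n,
        "punctuation": punct / n,
        "numeric": numeric / n,
        "other": other / n,
    }


# ---------------------------------------------------------------------------
# Report formatting


def format_report(rows: Sequence[MemorisationRow]) -> str:
    """Delimited table: one column per (n, quartile), rows %in / %out / PPL."""
    cols = sorted(rows, key=lambda r: (r.n, r.quartile == "low"))
    header = "metric\t" + "\t".join(f"{r.n}-gram_{r.quartile}" for r in cols)
    lines = [
        header,
        "pct_in\t" + "\t".join(f"{r.pct_in:.1f}" for r in cols),
        "pct_out\t" + "\t".join(f"{r.pct_out:.1f}" for r in cols),
        "pct_out_beyond_input\t"
        + "\t".join(f"{r.pct_out_beyond_input:.1f}" for r in cols),
        "mean_ppl\t"
        + "\t".join("-" if r.mean_ppl is None else f"{r.mean_ppl:.2f}" for r in cols),
    ]
    return "\n".join(lines) + "\n"


def report_to_keyvalue(rows: Sequence[MemorisationRow]) -> dict[str, float]:
    out: dict[str, float] = {}
    for r in rows:
        key = f"{r.n}gram_{r.quartile}"
        out[f"{key}_pct_in"] = r.pct_in
        out[f"{key}_pct_out"] = r.pct_out
        out[f"{key}_pct_out_beyond_input"] = r.pct_out_beyond_input
        if r.mean_ppl is not None:
            out[f"{key}_mean_ppl"] = r.mean_ppl
        for cls, frac in r.composition.items():
            out[f"{key}_leak_{cls}_fraction"] = frac
    return out
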