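"""Text-preservation metrics comparing generated to genuine sentences.

ROUGE-L is reported in recall form (longest common subsequence length over
reference length).  BLEU is the corpus-level geometric mean of clipped n-gram
precisions (n = 1..4 by default, no smoothing) times the brevity penalty, on
the 0-100 scale.  TER counts the minimum substitutions, insertions, deletions
and word-span shifts (each shift costs 1) needed to turn the hypothesis into
the reference, normalised by reference length; the shift search is greedy
(accept the shift that most reduces the remaining edit distance), which upper-
bounds at the plain edit distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import exp, log
from pathlib import Path
from typing import Sequence

from .corpus import Document

TokenSeq = Sequence[str]

# Above this hypothesis length the shift search considers only spans that
# occur verbatim in the reference (the classic TER constraint), keeping the
# search polynomial on real sentences.
_EXHAUSTIVE_SHIFT_LEN = 12
_MAX_SHIFT_SPAN = 10


def lcs_length(a: TokenSeq, b: TokenSeq) -> int:
    """Longest common subsequence length by dynamic programming."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(hypothesis: TokenSeq, reference: TokenSeq) -> float:
    """LCS(hypothesis, reference) / |reference| (recall form)."""
    if not reference:
        raise ValueError("empty reference")
    return lcs_length(hypothesis, reference) / len(reference)


def edit_distance(a: TokenSeq, b: TokenSeq) -> int:
    """Levenshtein distance (substitution/insertion/deletion, unit costs)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i]
        for j, y in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (0 if x == y else 1))
            )
        prev = cur
    return prev[-1]


def _apply_shift(seq: list, i: int, l: int, j: int) -> list:
    span = seq[i : i + l]
    rest = seq[:i] + seq[i + l :]
    return rest[:j] + span + rest[j:]


def _candidate_shifts(hyp: list, ref: TokenSeq):
    n = len(hyp)
    if n <= _EXHAUSTIVE_SHIFT_LEN:
        spans = [(i, l) for i in range(n) for l in range(1, n - i + 1)]
    else:
        ref_spans = {
            tuple(ref[i : i + l])
            for l in range(1, min(len(ref), _MAX_SHIFT_SPAN) + 1)
            for i in range(len(ref) - l + 1)
        }
        spans = [
            (i, l)
            for i in range(n)
            for l in range(1, min(n - i, _MAX_SHIFT_SPAN) + 1)
            if tuple(hyp[i : i + l]) in ref_spans
        ]
    for i, l in spans:
        for j in range(n - l + 1):
            if j == i:
                continue
            yield i, l, j


def ter(hypothesis: TokenSeq, reference: TokenSeq) -> float:
    """Translation edit rate with a greedy shift search.

    Guaranteed <= edit_distance(hypothesis, reference) / |reference| since
    every accepted shift strictly reduces the remaining edit distance.
    """
    if not reference:
        raise ValueError("empty reference")
    hyp = list(hypothesis)
    shifts = 0
    cur = edit_distance(hyp, reference)
    while cur > 0 and len(hyp) > 1:
        best = None  # (new_ed, i, l, j)
        for i, l, j in _candidate_shifts(hyp, reference):
            new_ed = edit_distance(_apply_shift(hyp, i, l, j), reference)
            if new_ed < cur and (best is None or new_ed < best[0]):
                best = (new_ed, i, l, j)
        if best is None:
            break
        cur, i, l, j = best
        hyp = _apply_shift(hyp, i, l, j)
        shifts += 1
    return (shifts + cur) / len(reference)


def bleu(
    hypotheses: Sequence[TokenSeq],
    references: Sequence[TokenSeq],
    max_n: int = 4,
) -> float:
    """Corpus BLEU on the 0-100 scale, no smoothing.

    Geometric mean of clipped n-gram precisions for n = 1..max_n times the
    brevity penalty exp(min(0, 1 - ref_len/hyp_len)).  Any empty modified
    precision yields 0 (documented behaviour, not an error).
    """
    if not hypotheses:
        raise ValueError("empty hypothesis set")
    if len(hypotheses) != len(references):
        raise ValueError(
            f"misaligned collections: {len(hypotheses)} hypotheses vs "
            f"{len(references)} references"
        )
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    matched = [0] * max_n
    total = [0] * max_n
    hyp_len = 0
    ref_len = 0
    for hyp, ref in zip(hypotheses, references):
        hyp_len += len(hyp)
        ref_len += len(ref)
        for n in range(1, max_n + 1):
            hyp_grams = Counter(tuple(hyp[i : i + n]) for i in range(len(hyp) - n + 1))
            ref_grams = Counter(tuple(ref[i : i + n]) for i in range(len(ref) - n + 1))
            total[n - 1] += sum(hyp_grams.values())
            matched[n - 1] += sum(
                min(c, ref_grams[g]) for g, c in hyp_grams.items()
            )
    if hyp_len == 0 or any(t == 0 for t in total) or any(m == 0 for m in matched):
        return 0.0
    log_prec = sum(log(m / t) for m, t in zip(matched, total)) / max_n
    bp = exp(min(0.0, 1.0 - ref_len / hyp_len))
    return 100.0 * bp * exp(log_prec)


# ---------------------------------------------------------------------------
# Corpus-level report


@dataclass
class MetricReport:
    rouge_l: float
    bleu: float
    ter: float
    mean_sentence_length: float
    ppl: float | None = None
    per_sentence_ter: list[float] = field(default_factory=list)

    def to_files(self, path: str | Path) -> None:
        """Flat key-value report plus a one-value-per-line TER vector."""
        path = Path(path)
        lines = [
            f"rouge_l\t{self.rouge_l:.6f}",
            f"bleu\t{self.bleu:.6f}",
            f"ter\t{self.ter:.6f}",
            f"mean_sentence_length\t{self.mean_sentence_length:.6f}",
        ]
        if self.ppl is not None:
            lines.append(f"ppl\t{self.ppl:.6f}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        ter_path = path.with_suffix(path.suffix + ".ter")
        ter_path.write_text(
            "\n".join(f"{v:.6f}" for v in self.per_sentence_ter) + "\n",
            encoding="utf-8",
        )


def _flatten(corpus) -> tuple[list[list[str]], list[str]]:
    """Flatten Documents (or token-sequence lists) to sentences + owner labels."""
    sents: list[list[str]] = []
    owners: list[str] = []
    for item in corpus:
        if isinstance(item, Document):
            for sent, _ in item.sentences():
                sents.append(list(sent.tokens))
                owners.append(item.document_id)
        else:
            sents.append(list(item))
            owners.append("<sequence>")
    return sents, owners


def evaluate_corpus(
    generated,
    genuine,
    model_ppl: float | None = None,
) -> MetricReport:
    """Sentence-aligned comparison: per-sentence ROUGE-L/TER averages,
    corpus-level BLEU, generated mean sentence length."""
    gen_sents, gen_owners = _flatten(generated)
    ref_sents, ref_owners = _flatten(genuine)
    if len(gen_sents) != len(ref_sents):
        first = (
            gen_owners[len(ref_sents)]
            if len(gen_sents) > len(ref_sents)
            else ref_owners[len(gen_sents)]
        )
        raise ValueError(
            f"alignment mismatch: {len(gen_sents)} generated vs "
            f"{len(ref_sents)} genuine sentences (first unmatched document: "
            f"{first})"
        )
    if not gen_sents:
        raise ValueError("empty corpora")
    rouges = [rouge_l(h, r) for h, r in zip(gen_sents, ref_sents)]
    ters = [ter(h, r) for h, r in zip(gen_sents, ref_sents)]
    return MetricReport(
        rouge_l=sum(rouges) / len(rouges),
        bleu=bleu(gen_sents, ref_sents),
        ter=sum(ters) / len(ters),
        mean_sentence_length=sum(len(s) for s in gen_sents) / len(gen_sents),
        ppl=model_ppl,
        per_sentence_ter=ters,
    )


@dataclass
class TERCDF:
    bin_edges: list[float]
    cumulative: list[float]

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.bin_edges[1:], self.bin_edges)):
            raise ValueError("bin edges must be strictly increasing")
        if any(b > a + 1e-12 for a, b in zip(self.cumulative[1:], self.cumulative)):
            raise ValueError("cumulative frequencies must be non-decreasing")
        if abs(self.cumulative[-1] - 1.0) > 1e-12:
            raise ValueError("final cumulative frequency must be 1.0")


def ter_cdf(per_sentence_ter: Sequence[float], bin_width: float = 0.1) -> TERCDF:
    """Right-closed TER bins from 0; values above the last regular edge pool
    into a final overflow bin so the CDF always ends at 1."""
    if not per_sentence_ter:
        raise ValueError("empty TER value sequence")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = 1
    while n_bins * bin_width < 1.0 - 1e-12:
        n_bins += 1
    edges = [round((i + 1) * bin_width, 10) for i in range(n_bins)]
    n = len(per_sentence_ter)
    cum = [sum(1 for v in per_sentence_ter if v <= e) / n for e in edges]
    if cum[-1] < 1.0:
        edges.append(float("inf"))
        cum.append(1.0)
    return TERCDF(edges, cum)
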