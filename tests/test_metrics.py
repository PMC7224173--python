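"""Intrinsic metrics: hand-computed examples plus brute-force oracles."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from synthnotes.metrics import (
    bleu,
    edit_distance,
    evaluate_corpus,
    lcs_length,
    rouge_l,
    ter,
    ter_cdf,
)

from conftest import make_document


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the library implementations)


def oracle_lcs(a, b):
    """Longest common subsequence by exhaustive subsequence enumeration."""
    best = 0
    for r in range(len(a), 0, -1):
        for comb in itertools.combinations(range(len(a)), r):
            sub = tuple(a[i] for i in comb)
            it = iter(b)
            if all(tok in it for tok in sub):
                return r
    return best


def oracle_edit_distance(a, b):
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        cost = 0 if a[i] == b[j] else 1
        return min(rec(i + 1, j + 1) + cost, rec(i + 1, j) + 1, rec(i, j + 1) + 1)

    return rec(0, 0)


def oracle_bleu(hyps, refs, max_n=4):
    """Corpus BLEU: pooled clipped n-gram counts, geometric mean, brevity
    penalty; zero if any order has zero precision."""
    import collections

    log_precisions = []
    for n in range(1, max_n + 1):
        match = total = 0
        for h, r in zip(hyps, refs):
            hc = collections.Counter(tuple(h[i : i + n]) for i in range(len(h) - n + 1))
            rc = collections.Counter(tuple(r[i : i + n]) for i in range(len(r) - n + 1))
            match += sum(min(c, rc[g]) for g, c in hc.items())
            total += sum(hc.values())
        if total == 0 or match == 0:
            return 0.0
        log_precisions.append(math.log(match / total))
    c = sum(len(h) for h in hyps)
    r = sum(len(r_) for r_ in refs)
    bp = 1.0 if c > r else math.exp(1 - r / c)
    return 100.0 * bp * math.exp(sum(log_precisions) / max_n)


def random_pair(rng, alphabet_size=4, max_len=6):
    n1 = int(rng.integers(0, max_len + 1))
    n2 = int(rng.integers(1, max_len + 1))
    toks = [f"w{i}" for i in range(alphabet_size)]
    a = [toks[int(i)] for i in rng.integers(0, alphabet_size, n1)]
    b = [toks[int(i)] for i in rng.integers(0, alphabet_size, n2)]
    return a, b


class TestLcsRouge:
    def test_hand_examples(self):
        assert lcs_length("abcde", "ace") == 3
        assert rouge_l(["the", "cat", "sat"], ["the", "black", "cat", "sat"]) == 0.75
        assert rouge_l([], ["a"]) == 0.0
        assert rouge_l(["a"], ["a"]) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_lcs_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            a, b = random_pair(rng)
            assert lcs_length(a, b) == oracle_lcs(a, b), (a, b)

    def test_rouge_is_lcs_recall(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b = random_pair(rng)
            assert rouge_l(a, b) == pytest.approx(oracle_lcs(a, b) / len(b))


class TestEditDistanceTer:
    def test_hand_examples(self):
        assert edit_distance("kitten", "sitting") == 3
        assert edit_distance([], ["a", "b"]) == 2
        # one substitution over five reference tokens
        hyp = ["the", "patient", "was", "quite", "well"]
        ref = ["the", "patient", "was", "very", "well"]
        assert ter(hyp, ref) == pytest.approx(0.2)
        # a block move counts once: shift cost 1 over four tokens
        assert ter(["d", "a", "b", "c"], ["a", "b", "c", "d"]) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(4))
    def test_edit_distance_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(60):
            a, b = random_pair(rng)
            assert edit_distance(tuple(a), tuple(b)) == oracle_edit_distance(
                tuple(a), tuple(b)
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_ter_bounded_by_levenshtein_and_zero_iff_equal(self, seed):
        rng = np.random.default_rng(200 + seed)
        for _ in range(80):
            a, b = random_pair(rng)
            t = ter(a, b)
            assert t <= edit_distance(a, b) / len(b) + 1e-12
            assert t >= 0.0
            if a == b:
                assert t == 0.0
            if t == 0.0:
                assert a == b

    def test_shift_only_helps_when_profitable(self):
        # reversing a long block cannot be fixed by one move; TER stays at the
        # plain edit distance bound
        hyp = ["c", "b", "a"]
        ref = ["a", "b", "c"]
        assert ter(hyp, ref) <= edit_distance(hyp, ref) / 3

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ter(["a"], [])


class TestBleu:
    def test_identity_is_100(self):
        h = [["the", "patient", "was", "well", "."]]
        assert bleu(h, h) == pytest.approx(100.0)

    def test_brevity_penalty_closed_form(self):
        hyp = [["a", "b", "c", "d"]]
        ref = [["a", "b", "c", "d", "e"]]
        # all clipped precisions are 1; BP = exp(1 - 5/4)
        assert bleu(hyp, ref) == pytest.approx(100.0 * math.exp(-0.25), abs=1e-9)

    def test_zero_precision_gives_zero(self):
        assert bleu([["a", "a", "a"]], [["a", "a"]]) == 0.0
        assert bleu([["x", "y", "z", "w"]], [["a", "b", "c", "d"]]) == 0.0

    def test_corpus_pooling_not_sentence_average(self):
        hyps = [["a", "b", "c", "d", "e"], ["a", "b", "c", "d"]]
        refs = [["a", "b", "c", "d", "e"], ["f", "g", "h", "i"]]
        pooled = bleu(hyps, refs)
        per_sent = [bleu([h], [r]) for h, r in zip(hyps, refs)]
        assert pooled > 0.0
        assert pooled != pytest.approx(sum(per_sent) / 2)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_implementation(self, seed):
        rng = np.random.default_rng(300 + seed)
        hyps, refs = [], []
        for _ in range(12):
            a, b = random_pair(rng, alphabet_size=3, max_len=8)
            hyps.append(a or ["w0"])
            refs.append(b)
        assert bleu(hyps, refs) == pytest.approx(oracle_bleu(hyps, refs), abs=1e-9)

    def test_alignment_required(self):
        with pytest.raises(ValueError):
            bleu([["a"]], [["a"], ["b"]])


class TestEvaluateCorpus:
    def test_identity_report(self):
        sents = [["the", "cat", "sat", "."], ["mood", "was", "low", "."]]
        rep = evaluate_corpus(sents, sents)
        assert rep.rouge_l == pytest.approx(1.0)
        assert rep.ter == pytest.approx(0.0)
        assert rep.bleu == pytest.approx(100.0)
        assert rep.mean_sentence_length == pytest.approx(4.0)
        assert rep.per_sentence_ter == [0.0, 0.0]

    def test_accepts_documents(self):
        doc = make_document("d1", "p1", [["the patient was well .", "mood low ."]])
        rep = evaluate_corpus([doc], [doc])
        assert rep.rouge_l == pytest.approx(1.0)

    def test_mismatch_names_document(self):
        doc_a = make_document("d1", "p1", [["one sentence ."]])
        doc_b = make_document("d2", "p2", [["one sentence .", "two sentences ."]])
        with pytest.raises(ValueError, match="d2"):
            evaluate_corpus([doc_a], [doc_b])

    def test_report_files(self, tmp_path):
        sents = [["a", "b"], ["a", "c"]]
        rep = evaluate_corpus(sents, [["a", "b"], ["a", "b"]])
        rep.to_files(tmp_path / "report")
        text = (tmp_path / "report").read_text(encoding="utf-8")
        assert "rouge_l" in text and "bleu" in text
        ter_lines = (
            (tmp_path / "report.ter").read_text(encoding="utf-8").strip().splitlines()
        )
        assert [float(x) for x in ter_lines] == rep.per_sentence_ter


class TestTerCdf:
    def test_cdf_ends_at_one_and_matches_empirical_fractions(self):
        values = [0.0, 0.05, 0.1, 0.3, 0.95, 2.4]
        cdf = ter_cdf(values, bin_width=0.1)
        assert cdf.cumulative[-1] == pytest.approx(1.0)
        arr = np.asarray(values)
        for edge, cum in zip(cdf.bin_edges, cdf.cumulative):
            if math.isfinite(edge):
                assert cum == pytest.approx(np.mean(arr <= edge + 1e-12))

    def test_all_zero_values(self):
        cdf = ter_cdf([0.0, 0.0, 0.0])
        assert cdf.cumulative[-1] == pytest.approx(1.0)
        assert cdf.cumulative[0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ter_cdf([])
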