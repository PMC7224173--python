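"""RAKE extraction, setup selection, metadata rendering, vocabulary."""

import collections

import numpy as np
import pytest

from synthnotes.corpus import Sentence, is_punctuation
from synthnotes.keyphrases import (
    Vocabulary,
    build_conditioned_pairs,
    build_vocabulary,
    rake_extract,
    render_meta,
    select_phrases,
    strip_common_keyphrases,
)

from conftest import make_document, make_meta, make_pair


def _sents(token_lists):
    return [Sentence(" ".join(toks), "d0", 0, i) for i, toks in enumerate(token_lists)]


def brute_force_rake(sentences, stopwords):
    """Independent reimplementation of RAKE phrase scoring for one paragraph.

    Candidates are maximal runs of non-stopword, non-punctuation tokens;
    word score is degree/frequency over candidate co-occurrence; a phrase
    scores the sum of its word scores.
    """
    candidates = []
    for s_idx, toks in enumerate(sentences):
        run, start = [], 0
        for i, t in enumerate(toks + ["."]):
            if t in stopwords or is_punctuation(t):
                if run:
                    candidates.append((tuple(run), s_idx, start))
                run = []
            else:
                if not run:
                    start = i
                run.append(t)
    freq = collections.Counter()
    degree = collections.Counter()
    for phrase, _, _ in candidates:
        for w in phrase:
            freq[w] += 1
            degree[w] += len(phrase)
    return [
        (phrase, s_idx, start, sum(degree[w] / freq[w] for w in phrase))
        for phrase, s_idx, start in candidates
    ]


class TestRake:
    def test_hand_example(self):
        sw = frozenset({"the", "reports", "and"})
        phrases = rake_extract(
            _sents([["the", "patient", "reports", "low", "mood",
                     "and", "poor", "sleep", "."]]), sw)
        scored = {tuple(p.tokens): p.score for p in phrases}
        assert scored == {
            ("patient",): 1.0,
            ("low", "mood"): 4.0,
            ("poor", "sleep"): 4.0,
        }

    def test_repeated_word_raises_degree(self):
        sw = frozenset({"and"})
        phrases = rake_extract(_sents([["deep", "sleep", "and", "sleep", "."]]), sw)
        scored = {tuple(p.tokens): p.score for p in phrases}
        # sleep: freq 2, degree 2+1=3; deep: freq 1, degree 2.
        assert scored[("deep", "sleep")] == pytest.approx(2.0 + 1.5)
        assert scored[("sleep",)] == pytest.approx(1.5)

    def test_stopword_only_paragraph_has_no_phrases(self, stopwords):
        assert rake_extract(_sents([["the", "and", "was", "."]]), stopwords) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed, stopwords):
        rng = np.random.default_rng(seed)
        content = ["alpha", "beta", "gamma", "delta", "x9"]
        stops = ["the", "and", "was", "with", ",", "."]
        sentences = []
        for _ in range(4):
            toks = [
                (content if rng.random() < 0.5 else stops)[
                    int(rng.integers(0, 5 if rng.random() < 0.5 else 6)) % 5
                ]
                for _ in range(int(rng.integers(4, 12)))
            ]
            sentences.append(toks)
        got = sorted(
            (tuple(p.tokens), p.matched_sentence, p.start, p.score)
            for p in rake_extract(_sents(sentences), stopwords)
        )
        want = sorted(brute_force_rake(sentences, stopwords))
        assert [(g[0], g[1], g[2]) for g in got] == [(w[0], w[1], w[2]) for w in want]
        for g, w in zip(got, want):
            assert g[3] == pytest.approx(w[3])


class TestSelection:
    def _phrases(self, stopwords):
        sentences = [
            ["severe", "anxiety", "and", "panic", "attacks", "with", "poor", "sleep", "."],
            ["the", "mood", "was", "low", "."],
        ]
        return rake_extract(_sents(sentences), stopwords)

    def test_all_keeps_everything(self, stopwords):
        phrases = self._phrases(stopwords)
        assert select_phrases(phrases, "all") == list(phrases)
        assert select_phrases(phrases, "key") == list(phrases)

    def test_one_meta_keeps_best_per_sentence(self, stopwords):
        phrases = self._phrases(stopwords)
        chosen = select_phrases(phrases, "one_meta")
        by_sent = collections.Counter(p.matched_sentence for p in chosen)
        assert all(v == 1 for v in by_sent.values())
        for p in chosen:
            best = max(
                q.score for q in phrases if q.matched_sentence == p.matched_sentence
            )
            assert p.score == pytest.approx(best)

    def test_setup_nesting(self, stopwords, small_corpus):
        """one_meta selects a subset of top_meta, which selects a subset of all."""
        docs, _ = small_corpus
        for doc in docs[:6]:
            for par in doc.paragraphs:
                phrases = rake_extract(par, stopwords)
                key = lambda p: (p.matched_sentence, p.start, tuple(p.tokens))
                sel = {
                    s: {key(p) for p in select_phrases(phrases, s)}
                    for s in ("all", "top_meta", "one_meta")
                }
                assert sel["one_meta"] <= sel["top_meta"] <= sel["all"]

    def test_unknown_setup_rejected(self, stopwords):
        with pytest.raises(ValueError, match="setup"):
            select_phrases(self._phrases(stopwords), "every")


class TestMeta:
    def test_render_meta_tokens(self):
        meta = make_meta(
            diagnosis_code="F20",
            gender="male",
            age=47,
            death_flag=True,
            relative_timestamp=-2,
            section_label="discharge_plan",
            sentence_ordinal=3,
        )
        assert render_meta(meta) == [
            "f20", "male", "age_40s", "died", "t_pre", "sec_discharge_plan", "ord_3",
        ]

    def test_timestamp_buckets(self):
        assert render_meta(make_meta(relative_timestamp=-1))[4] == "t_pre"
        assert render_meta(make_meta(relative_timestamp=0))[4] == "t_wk1"
        assert render_meta(make_meta(relative_timestamp=7))[4] == "t_wk1"
        assert render_meta(make_meta(relative_timestamp=8))[4] == "t_late"

    def test_ordinal_capped(self):
        assert render_meta(make_meta(sentence_ordinal=23))[6] == "ord_10"


class TestConditionedPairs:
    def test_pairs_align_with_sentences(self, stopwords, small_corpus):
        docs, _ = small_corpus
        doc = docs[0]
        pairs = build_conditioned_pairs(doc, "top_meta", stopwords)
        assert len(pairs) == doc.n_sentences
        for pair in pairs:
            sent = doc.paragraphs[pair.paragraph_index][pair.sentence_index]
            assert pair.target_tokens == tuple(sent.tokens)
            meta = doc.metas[pair.paragraph_index][pair.sentence_index]
            assert pair.input_tokens[:7] == tuple(render_meta(meta))
            # phrase tokens all come from the target sentence
            assert set(pair.phrase_tokens) <= set(sent.tokens)

    def test_all_setup_has_no_meta(self, stopwords, small_corpus):
        docs, _ = small_corpus
        pairs = build_conditioned_pairs(docs[0], "all", stopwords)
        for pair in pairs:
            assert pair.input_tokens == pair.phrase_tokens

    def test_key_setup_targets_phrases(self, stopwords, small_corpus):
        docs, _ = small_corpus
        pairs = build_conditioned_pairs(docs[0], "key", stopwords)
        for pair in pairs:
            assert pair.target_tokens == pair.phrase_tokens

    def test_one_meta_at_most_one_phrase(self, stopwords, small_corpus):
        docs, _ = small_corpus
        for pair in build_conditioned_pairs(docs[0], "one_meta", stopwords):
            assert len(pair.phrases) <= 1


class TestVocabulary:
    def test_frequency_floor_excludes_singletons(self):
        pairs = [make_pair(["a", "a", "b"], ["b", "c"])]
        vocab = build_vocabulary(pairs)
        assert "a" in vocab.token_to_index
        assert "b" in vocab.token_to_index
        assert "c" not in vocab.token_to_index
        assert list(vocab.encode(["c"])) == [vocab.unk]

    def test_ordering_frequency_then_lexicographic(self):
        vocab = Vocabulary(collections.Counter({"b": 5, "a": 5, "z": 7, "q": 2}))
        assert vocab.index_to_token[4:] == ["z", "a", "b", "q"]

    def test_specials_reserved(self):
        vocab = Vocabulary(collections.Counter({"a": 2}))
        assert (vocab.pad, vocab.unk, vocab.bos, vocab.eos) == (0, 1, 2, 3)
        assert vocab.decode(vocab.encode(["a"])) == ["a"]

    def test_min_frequency_floor_enforced(self):
        with pytest.raises(ValueError):
            Vocabulary(collections.Counter({"a": 5}), min_frequency=1)
        with pytest.raises(ValueError):
            build_vocabulary([])

    def test_round_trip(self):
        vocab = Vocabulary(collections.Counter({"a": 3, "b": 2}))
        back = Vocabulary.from_dict(vocab.to_dict())
        assert back.index_to_token == vocab.index_to_token


class TestStripCommonKeyphrases:
    def test_common_phrases_removed(self):
        from synthnotes.keyphrases import BareDocument

        doc = make_document(
            "da",
            "pa",
            [[
                "the patient has severe anxiety and low mood .",
                "severe anxiety was noted with poor sleep .",
            ]],
        )
        art = BareDocument("db", "pb", "F20", [["severe", "anxiety", "today", "."]])
        stripped_gen, stripped_art = strip_common_keyphrases(
            [doc], [art], [("severe", "anxiety")]
        )
        remaining = " ".join(t for d in stripped_gen for s in d.sentences for t in s)
        assert "anxiety" not in remaining and "severe" not in remaining
        assert "sleep" in remaining  # untargeted phrases survive
        assert stripped_art[0].sentences == [["today", "."]]

    def test_emptied_sentences_dropped(self):
        from synthnotes.keyphrases import BareDocument

        art = BareDocument("db", "pb", "F20", [["low", "mood"], ["kept", "line"]])
        _, stripped = strip_common_keyphrases([], [art], [("low", "mood")])
        assert stripped[0].sentences == [["kept", "line"]]
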