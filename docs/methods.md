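# Methods note

This note records the precise conventions implemented in `synthnotes`,
including every place where a published description leaves room for
interpretation and a concrete choice had to be made.

## 1. Corpus model

A corpus is a set of documents (discharge summaries), each owned by one
patient and structured as paragraphs of sentences. Every sentence carries
metadata: diagnosis code and description, gender, age, death flag, a
relative timestamp in days, the record section (`summary`,
`discharge_plan`, `comments`) and the 1-based sentence ordinal within its
section. Splits are **patient-grouped**: all documents of a patient land in
the same train/validation/test part, so no patient's language straddles a
split boundary. `FORMAT.md` defines the on-disk format normatively.

Tokenisation is deliberately simple and total: lowercase, whitespace split,
detach leading/trailing punctuation. It is idempotent, so serialised token
streams re-tokenise to themselves.

## 2. Key-phrase conditioning

Key phrases are extracted per paragraph with RAKE: candidate phrases are
maximal runs of tokens delimited by stopwords or punctuation; each word
scores deg(w)/freq(w), where freq counts candidate occurrences containing
the word and deg additionally weights them by candidate length; a phrase
scores the sum of its word scores. The packaged English stopword list
(`synthnotes/data/stopwords.txt`) is part of the method definition.

Setups:

- `all`: every candidate phrase, in sentence order; no metadata.
- `top_meta`: metadata tokens + the paragraph's top-scoring 60 %
  (`keep_fraction`, ties broken by earlier position) **union** each
  sentence's best phrase. The union guarantees the selection nesting
  `one_meta ⊆ top_meta ⊆ all`, which the monotonicity results rely on.
- `one_meta`: metadata tokens + exactly the best phrase of each sentence.
- `key`: like `all`, but the target of each example is the phrase stream
  itself — the copy baseline's training view.

Metadata is rendered as one abbreviation token per field: lowercased
diagnosis code, gender, age decade (`age_40s`), `died`/`alive`, a timestamp
bucket (`t_pre` before admission, `t_wk1` days 0–7, `t_late` after),
`sec_<section>`, and `ord_<n>` with ordinals capped at 10 (beyond that,
position within a section carries no extra signal and the token vocabulary
would fragment).

The vocabulary maps tokens seen at least twice in the training pairs;
singletons encode to the unknown symbol. This frequency floor is load-bearing
for the memorisation analysis: a model cannot emit a token it cannot encode,
so frequency-1 *unigrams* are structurally protected, and the audit therefore
concentrates on rare n-grams of frequency ≥ 1 whose member tokens are
individually frequent enough to survive.

## 3. Generator

A post-norm encoder–decoder transformer (default 2 layers, model width 64,
2 heads, feed-forward width 128, learned positional embeddings) trained with
Adam (learning rate 2e-3, gradient clipping at 5.0) on token cross-entropy
including the end-of-sentence symbol. All arithmetic is float64 on a
self-contained numpy reverse-mode autograd — there is no GPU nondeterminism,
and closed-form perplexity identities hold to 1e-9. Decoding is batched
greedy by default (beam search available; beam width 1 reproduces greedy
exactly). Pad and begin symbols are blocked from being emitted.

Perplexity is forced-decoding perplexity: exp of the mean per-token negative
log-likelihood of the *reference* under the model, pooled over all tokens of
all pairs, end symbol included. Two exact anchors are tested: a model with a
zeroed output layer has perplexity equal to its vocabulary size, and a
crafted output bias putting 0.8/0.2 mass on a two-symbol continuation gives
exactly 2.5.

## 4. Intrinsic metrics

- **ROUGE-L** = LCS(hyp, ref) / |ref| (recall form), averaged per sentence.
- **BLEU** is corpus-level: clipped n-gram counts (n ≤ 4) pooled over all
  sentence pairs, geometric mean, brevity penalty, scale 0–100, no
  smoothing (any zero precision gives 0).
- **TER** counts insertions, deletions, substitutions and block shifts, each
  cost 1, divided by |ref|. The shift search is greedy: at each step the
  single block move that most reduces the remaining Levenshtein distance is
  applied, and only strictly improving moves are accepted — so TER never
  exceeds plain Levenshtein/|ref|. For hypotheses of ≤ 12 tokens all spans
  are enumerated; beyond that, only spans that occur verbatim in the
  reference (length ≤ 10) are considered. The greedy search is a heuristic
  (true TER is NP-hard); the tests pin its laws (bounds, zero iff equal,
  hand-computed shift examples) rather than global optimality.
- **TER CDF**: right-closed bins of width 0.1 from 0, with one overflow bin,
  so the CDF always ends at 1.

## 5. Memorisation audit

All training n-grams (n ∈ {2, 3, 5}) are indexed within sentences. Over the
list of *distinct* n-gram frequencies sorted ascending, the lower quartile
threshold is the value at 1-based rank ⌊(N+1)/4⌋ and the upper at
⌈3(N+1)/4⌉. This nearest-rank convention reproduces the worked example
frozen in the tests: frequencies {1,1,2,3,5,8,13,21} give thresholds (1, 13).
A sentence is eligible for the low (high) class if it contains an n-gram
with frequency ≤ lower (≥ upper); its target is its lowest- (highest-)
frequency n-gram, earliest on ties; each sentence is sampled at most once,
and a shortfall is reported when fewer eligible sentences exist than
requested.

Per sampled sentence the audit reports: **%in** — the target occurs
contiguously in the concatenated key-phrase stream of the model input;
**%out** — it occurs contiguously in the generated sentence; the
**beyond-input** rate — fraction of outputs containing targets absent from
the input (memorisation proper); mean forced perplexity of the sampled
sentences; and the composition of leaked targets' tokens classified with
priority punctuation → numeric → stopword → other.

The default %in convention checks the *concatenated* phrase stream rather
than each phrase run separately. This is what makes the copy-baseline
identity exact — the baseline's output *is* the concatenated stream, so
%out ≡ %in for every n and quartile, which the tests assert to 1e-12. The
stricter per-phrase reading is available as `within_phrase_only=True` and
can only lower %in.

Sensitivity is validated on a fixture with 50 bigrams planted exactly once
(each planted next to a 3-token decoy run so single-phrase conditioning
rarely includes it, and each rare token given one companion occurrence so it
survives the vocabulary floor): a generator overfitted to that corpus
regenerates ≥ 50 points more planted bigrams than its inputs contain, while
a 1-epoch generator shows no excess.

## 6. Extrinsic protocol

Document classification is per-class binary (one-vs-rest), three classifier
families:

- **BoW + RF**: within-sentence n-gram counts (n ≤ 5, document frequency
  ≥ 2) + random forest;
- **LDA + RF**: document-topic distributions from an LDA model fitted on the
  *generation-training* reference corpus (not the classification training
  set, so genuine and artificial regimes share one feature space) + random
  forest;
- **CNN**: a small text CNN (window widths 3/4/5, max-over-time pooling,
  dropout 0.5) on the numpy autograd.

Per (training regime, classifier family) the protocol collects an F1 sample
of shape (n_classes × n_runs): 6 classes × 5 runs = 30 points with
patient-disjoint cross-validation folds, or 13 × 5 = 65 points with a fixed
test set (which must then be patient-disjoint from every training regime).
Samples are compared with the two-sample Kolmogorov–Smirnov test
(asymptotic p by default, exact available). A confident-error analysis
counts wrong predictions with confidence ≥ 0.75 (threshold required in
(0.5, 1]) and the overlap of each regime's confident errors with the
genuine-trained baseline's.

Ranking preservation between regimes is assessed pairwise: a classifier pair
constrains the comparison only when the KS test finds its pooled F1 samples
significantly different (5 % level) in *both* regimes; the test then
requires the directions to agree. Near-ties impose no constraint, which is
the honest reading of "the ranking is preserved" for samples of this size.

## 7. Synthetic fixture corpus

The generator produces documents from six stopword-scaffolded clause
templates with content slots filled from a Zipf-distributed filler
vocabulary (exponent 1.3 by default; the exponent controls the singleton
tail, which the tests check). Class signal is a per-class two-token marker
phrase inserted into each sentence with probability `class_signal_strength`;
markers never appear in other classes' documents, so strength 1.0 yields a
fully separable classification problem. Rare n-grams (`rareJa rareJb`) are
planted exactly once corpus-wide, with companions and decoys as described in
§5, and recorded in a JSON answer key.

What it deliberately does **not** emulate: real clinical vocabulary,
discourse structure across sentences, label noise, or realistic metadata
correlations. It reproduces only the structural properties the pipeline's
claims depend on (patient grouping, Zipf tail, separable class signal,
frequency-1 n-grams with known locations).

## 8. Pipeline and reproducibility

`run_pipeline` chains: fixture corpus (or an existing corpus file) →
patient split → per-setup conditioning, training, generation, intrinsic
report and audit → extrinsic comparison of genuine versus per-setup
artificial training text. Each stage's seed is derived as
SHA-256(`"{master_seed}:{stage}"`) mod 2³¹. The run manifest records every
output file's SHA-256; an unchanged configuration re-run verifies digests
and skips completed stages, and two fresh runs with the same master seed
produce byte-identical artifacts (asserted by the tests).

## 9. Known limitations

- The TER shift search is greedy and span-limited; it upper-bounds true TER.
- The transformer is small and CPU-bound; the defaults target corpora of
  10²–10³ documents, not real-scale clinical archives.
- LDA features come from scikit-learn's variational LDA; topic values are
  deterministic given a seed but depend on scikit-learn's implementation.
- The asymptotic KS p-value is approximate for the small F1 samples used in
  the protocol; the exact method is available where it matters.
- RAKE quality (and hence conditioning quality) depends entirely on the
  stopword list; domain-specific stopwords are the caller's responsibility.
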