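# Corpus exchange format

This file is the normative definition of the serialised formats used by
`synthnotes`. The reader (`synthnotes.corpus.read_corpus`) rejects any file
that deviates from it, naming the offending line.

## Corpus files (`*.jsonl`)

A corpus is a UTF-8 JSON-lines file: one JSON object per line, one line per
**sentence**. Sentences of one document must be contiguous; documents appear
in file order. Blank lines are ignored.

Each record has exactly these fields:

| field | type | meaning |
|---|---|---|
| `document_id` | string | identifier of the discharge summary |
| `patient_id` | string | identifier of the patient (several documents may share it) |
| `paragraph_index` | int ≥ 0 | position of the sentence's paragraph within the document |
| `sentence_index` | int ≥ 0 | position of the sentence within its paragraph |
| `text` | string | the raw sentence text |
| `meta` | object | sentence-level clinical metadata (below) |

The `meta` object:

| field | type | meaning |
|---|---|---|
| `diagnosis_code` | string | primary diagnosis code (e.g. `"F20"`) |
| `diagnosis_description` | string | free-text description of the code |
| `gender` | string | patient gender |
| `age` | int ≥ 0 | age in years at discharge |
| `death_flag` | bool | whether the patient died |
| `relative_timestamp` | int | days relative to discharge (negative = before) |
| `section_label` | string | one of `summary`, `discharge_plan`, `comments` |
| `sentence_ordinal` | int ≥ 1 | 1-based position of the sentence within its section; must increase by exactly 1 per section |

Tokenisation is defined by `synthnotes.corpus.tokenize`: lowercase,
whitespace split, leading/trailing punctuation detached as standalone tokens,
internal punctuation kept. It is idempotent under join-with-spaces and
re-tokenisation.

## Conditioned pair files (`<stem>.input.txt` / `<stem>.target.txt`)

Training/generation examples are stored as two aligned plain-text files: line
*i* of `.input.txt` is the space-joined conditioning input of example *i*,
line *i* of `.target.txt` the space-joined target sentence. These files carry
tokens only; sentence-level metadata is not round-tripped through them.

## Answer key (`answer_key.json`)

Ground truth for a synthetic fixture corpus:

```json
{
  "marker_phrases": {"F20": ["marker0a", "marker0b"]},
  "planted": [
    {"tokens": ["rare0a", "rare0b"], "document_id": "...",
     "paragraph_index": 0, "sentence_index": 3}
  ]
}
```

`marker_phrases` maps each diagnosis code to its class-marker 2-gram;
`planted` lists every planted rare n-gram with the exact sentence it occurs
in (it occurs exactly once corpus-wide).

## Generator checkpoints

A checkpoint is a directory with `meta.json` (format tag
`synthnotes-generator-v1`, the generator configuration, vocabulary, loss
traces, and training setup) and `params.npz` (float64 parameter arrays keyed
by parameter name).

## Run manifests (`manifest.json`)

A pipeline run directory contains `manifest.json` recording the exact run
configuration and, per stage, the seed used, wall-clock seconds, and the
SHA-256 digest of every file the stage wrote. Re-running with an unchanged
configuration verifies digests and skips completed stages.
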