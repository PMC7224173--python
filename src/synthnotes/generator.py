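"""Conditional sequence-to-sequence generation: fill text around key phrases.

The generator is a small encoder-decoder transformer trained on the
gap-filling task: the encoder reads the conditioning input (metadata
abbreviation tokens plus key-phrase tokens) and the decoder is trained by
teacher forcing to reconstruct the full original sentence.  Each paragraph is
generated sentence by sentence; paragraph coherence comes from the shared
paragraph-level key-phrase pool, not from cross-sentence decoder state.

A no-model copy baseline ("key" setup) reproduces the key-phrase portion of
the input verbatim — the worst possible generator, copying without context.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .keyphrases import ConditionedPair, Vocabulary, build_vocabulary
from .nn.autograd import Tensor, cross_entropy_logits, log_softmax_np
from .nn.layers import (
    Adam,
    DecoderLayer,
    Embedding,
    EncoderLayer,
    Linear,
    Module,
    causal_mask,
    pad_mask,
)

CHECKPOINT_FORMAT = "synthnotes-generator-v1"


@dataclass
class GeneratorConfig:
    architecture: str = "transformer_ed"  # or "copy_baseline"
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 2
    d_ff: int = 128
    dropout: float = 0.0
    max_input_len: int = 48
    max_output_len: int = 32
    learning_rate: float = 2e-3
    batch_size: int = 32
    epochs: int = 30
    decoding: str = "greedy"  # or "beam"
    beam_width: int = 1
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("transformer_ed", "copy_baseline"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.max_input_len < 1 or self.max_output_len < 1:
            raise ValueError("sequence length limits must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class Seq2SeqTransformer(Module):
    def __init__(self, rng: np.random.Generator, vocab_size: int, cfg: GeneratorConfig):
        self.cfg = cfg
        d = cfg.d_model
        self.src_emb = Embedding(rng, vocab_size, d)
        self.tgt_emb = Embedding(rng, vocab_size, d)
        self.src_pos = Embedding(rng, cfg.max_input_len + 1, d)
        self.tgt_pos = Embedding(rng, cfg.max_output_len + 1, d)
        self.enc_layers = [
            EncoderLayer(rng, d, cfg.n_heads, cfg.d_ff) for _ in range(cfg.n_layers)
        ]
        self.dec_layers = [
            DecoderLayer(rng, d, cfg.n_heads, cfg.d_ff) for _ in range(cfg.n_layers)
        ]
        self.out = Linear(rng, d, vocab_size)

    def encode(self, src: np.ndarray, src_lens: np.ndarray):
        B, Ts = src.shape
        mask = pad_mask(src_lens, Ts)
        x = self.src_emb(src) + self.src_pos(np.arange(Ts)[None, :])
        for layer in self.enc_layers:
            x = layer(x, mask)
        return x, mask

    def decode(self, enc, cross_mask: np.ndarray, tgt_in: np.ndarray) -> Tensor:
        B, Tt = tgt_in.shape
        x = self.tgt_emb(tgt_in) + self.tgt_pos(np.arange(Tt)[None, :])
        cmask = causal_mask(Tt)
        for layer in self.dec_layers:
            x = layer(x, enc, cmask, cross_mask)
        return self.out(x)

    def forward(self, src, src_lens, tgt_in) -> Tensor:
        enc, mask = self.encode(src, src_lens)
        return self.decode(enc, mask, tgt_in)


@dataclass
class GenerationOutput:
    """Generated token sequences aligned with the pairs that conditioned them."""

    sequences: list[list[str]]
    scores: list[float]  # per-sequence mean log-likelihood (0.0 for the baseline)


@dataclass
class TrainedGenerator:
    config: GeneratorConfig
    vocab: Vocabulary
    model: Seq2SeqTransformer | None
    loss_trace: list[float] = field(default_factory=list)
    val_loss_trace: list[float] = field(default_factory=list)
    train_setup: str | None = None  # conditioning setup of the training pairs

    @property
    def is_copy_baseline(self) -> bool:
        return self.config.architecture == "copy_baseline"


def _encode_batch(
    vocab: Vocabulary, pairs: Sequence[ConditionedPair], cfg: GeneratorConfig
):
    """Pad-encode inputs ([BOS] + tokens) and targets for teacher forcing."""
    srcs, tgt_ins, tgt_outs = [], [], []
    for p in pairs:
        s = [vocab.bos] + list(vocab.encode(p.input_tokens)[: cfg.max_input_len])
        t = list(vocab.encode(p.target_tokens)[: cfg.max_output_len - 1])
        srcs.append(s)
        tgt_ins.append([vocab.bos] + t)
        tgt_outs.append(t + [vocab.eos])
    B = len(pairs)
    Ts = max(len(s) for s in srcs)
    Tt = max(len(t) for t in tgt_ins)
    src = np.full((B, Ts), vocab.pad, dtype=np.int64)
    tgt_in = np.full((B, Tt), vocab.pad, dtype=np.int64)
    tgt_out = np.full((B, Tt), vocab.pad, dtype=np.int64)
    src_lens = np.zeros(B, dtype=np.int64)
    mask = np.zeros((B, Tt))
    for i, (s, ti, to) in enumerate(zip(srcs, tgt_ins, tgt_outs)):
        src[i, : len(s)] = s
        src_lens[i] = len(s)
        tgt_in[i, : len(ti)] = ti
        tgt_out[i, : len(to)] = to
        mask[i, : len(to)] = 1.0
    return src, src_lens, tgt_in, tgt_out, mask


def _batch_loss(model, vocab, batch_pairs, cfg) -> tuple[Tensor, float]:
    src, src_lens, tgt_in, tgt_out, mask = _encode_batch(vocab, batch_pairs, cfg)
    logits = model.forward(src, src_lens, tgt_in)
    V = len(vocab)
    flat = logits.reshape(-1, V)
    loss = cross_entropy_logits(flat, tgt_out.reshape(-1), mask.reshape(-1))
    return loss, float(mask.sum())


def train(
    pairs: Sequence[ConditionedPair],
    val_pairs: Sequence[ConditionedPair],
    config: GeneratorConfig,
    vocab: Vocabulary | None = None,
) -> TrainedGenerator:
    """Fit the generator by maximising target likelihood under teacher forcing.

    The vocabulary is built from the training pairs only; passing a vocabulary
    containing tokens absent from the training pairs raises (validation-set
    leakage into the vocabulary).  Fully reproducible from ``config.seed``.
    """
    if not pairs:
        raise ValueError("empty training set")
    setups = {p.setup for p in pairs}
    train_setup = setups.pop() if len(setups) == 1 else None
    if config.architecture == "copy_baseline":
        return TrainedGenerator(
            config, build_vocabulary(pairs), None, train_setup=train_setup
        )
    if vocab is None:
        vocab = build_vocabulary(pairs)
    else:
        from collections import Counter

        counts: Counter[str] = Counter()
        for p in pairs:
            counts.update(p.input_tokens)
            counts.update(p.target_tokens)
        bad = [
            t
            for t in vocab.index_to_token[4:]
            if counts[t] < vocab.min_frequency
        ]
        if bad:
            raise ValueError(
                f"vocabulary contains tokens not supported by the training "
                f"pairs (built on validation data?): {bad[:5]}"
            )
    rng = np.random.default_rng(config.seed)
    model = Seq2SeqTransformer(rng, len(vocab), config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    gen = TrainedGenerator(config, vocab, model, train_setup=train_setup)
    n = len(pairs)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        tot_loss, tot_tok = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            batch = [pairs[i] for i in perm[start : start + config.batch_size]]
            loss, n_tok = _batch_loss(model, vocab, batch, config)
            opt.zero_grad()
            loss.backward()
            _clip_grads(model.parameters(), config.grad_clip)
            opt.step()
            tot_loss += float(loss.data) * n_tok
            tot_tok += n_tok
        gen.loss_trace.append(tot_loss / max(tot_tok, 1.0))
        if val_pairs:
            vloss, vtok = 0.0, 0.0
            for start in range(0, len(val_pairs), config.batch_size):
                batch = val_pairs[start : start + config.batch_size]
                loss, n_tok = _batch_loss(model, vocab, batch, config)
                vloss += float(loss.data) * n_tok
                vtok += n_tok
            gen.val_loss_trace.append(vloss / max(vtok, 1.0))
    return gen


def _clip_grads(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


# ---------------------------------------------------------------------------
# Decoding


def generate(gen: TrainedGenerator, pairs: Sequence[ConditionedPair]) -> GenerationOutput:
    """Decode one output sequence per pair (greedy by default, beam optional)."""
    if gen.is_copy_baseline:
        return run_copy_baseline(pairs)
    if gen.model is None:
        raise ValueError("generator has not been trained")
    if gen.config.decoding == "beam" and gen.config.beam_width > 1:
        seqs, scores = [], []
        for p in pairs:
            ids, sc = _beam_decode(gen, p)
            seqs.append(gen.vocab.decode(ids))
            scores.append(sc)
        return GenerationOutput(seqs, scores)
    return _greedy_decode_batch(gen, pairs)


def _prepare_src(gen: TrainedGenerator, pairs: Sequence[ConditionedPair]):
    vocab, cfg = gen.vocab, gen.config
    srcs = [
        [vocab.bos] + list(vocab.encode(p.input_tokens)[: cfg.max_input_len])
        for p in pairs
    ]
    B = len(srcs)
    Ts = max(len(s) for s in srcs)
    src = np.full((B, Ts), vocab.pad, dtype=np.int64)
    src_lens = np.zeros(B, dtype=np.int64)
    for i, s in enumerate(srcs):
        src[i, : len(s)] = s
        src_lens[i] = len(s)
    return src, src_lens


def _step_logprobs(gen: TrainedGenerator, enc, cross_mask, tgt_in: np.ndarray):
    logits = gen.model.decode(enc, cross_mask, tgt_in).data[:, -1, :]
    # never emit padding or the start symbol
    logits[:, gen.vocab.pad] = -1e9
    logits[:, gen.vocab.bos] = -1e9
    return log_softmax_np(logits)


def _greedy_decode_batch(
    gen: TrainedGenerator, pairs: Sequence[ConditionedPair]
) -> GenerationOutput:
    vocab, cfg = gen.vocab, gen.config
    if not pairs:
        return GenerationOutput([], [])
    src, src_lens = _prepare_src(gen, pairs)
    enc, cross_mask = gen.model.encode(src, src_lens)
    B = src.shape[0]
    tgt = np.full((B, 1), vocab.bos, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    logp_sums = np.zeros(B)
    lengths = np.zeros(B, dtype=np.int64)
    for _ in range(cfg.max_output_len):
        logp = _step_logprobs(gen, enc, cross_mask, tgt)
        nxt = logp.argmax(axis=-1)
        nxt[done] = vocab.pad
        step_lp = logp[np.arange(B), nxt]
        logp_sums += np.where(done, 0.0, step_lp)
        lengths += (~done).astype(np.int64)
        tgt = np.concatenate([tgt, nxt[:, None]], axis=1)
        done |= nxt == vocab.eos
        if done.all():
            break
    seqs, scores = [], []
    for i in range(B):
        ids = [t for t in tgt[i, 1:] if t not in (vocab.pad,)]
        if vocab.eos in ids:
            ids = ids[: ids.index(vocab.eos)]
        seqs.append(vocab.decode(ids))
        scores.append(float(logp_sums[i] / max(lengths[i], 1)))
    return GenerationOutput(seqs, scores)


def _beam_decode(gen: TrainedGenerator, pair: ConditionedPair):
    """Beam search; returns the highest-scoring completed hypothesis."""
    vocab, cfg = gen.vocab, gen.config
    src, src_lens = _prepare_src(gen, [pair])
    enc, cross_mask = gen.model.encode(src, src_lens)
    beams: list[tuple[list[int], float, bool]] = [([vocab.bos], 0.0, False)]
    width = cfg.beam_width
    for _ in range(cfg.max_output_len):
        if all(done for _, _, done in beams):
            break
        candidates: list[tuple[list[int], float, bool]] = []
        for ids, lp, done in beams:
            if done:
                candidates.append((ids, lp, True))
                continue
            tgt = np.array([ids], dtype=np.int64)
            logp = _step_logprobs(gen, enc, cross_mask, tgt)[0]
            top = np.argsort(-logp)[:width]
            for t in top:
                candidates.append(
                    (ids + [int(t)], lp + float(logp[t]), int(t) == vocab.eos)
                )
        candidates.sort(key=lambda c: -c[1])
        beams = candidates[:width]
    best = max(beams, key=lambda c: c[1])
    ids = best[0][1:]
    if vocab.eos in ids:
        ids = ids[: ids.index(vocab.eos)]
    return ids, best[1] / max(len(best[0]) - 1, 1)


def run_copy_baseline(pairs: Sequence[ConditionedPair]) -> GenerationOutput:
    """The ``key`` baseline: output the key-phrase portion of the input verbatim."""
    for p in pairs:
        if p.setup != "key":
            raise ValueError(
                f"copy baseline requires pairs built with setup='key', got "
                f"{p.setup!r}"
            )
    return GenerationOutput(
        [list(p.phrase_tokens) for p in pairs], [0.0] * len(pairs)
    )


# ---------------------------------------------------------------------------
# Perplexity


def perplexity(gen: TrainedGenerator, pairs: Sequence[ConditionedPair]) -> float:
    """exp of the mean per-token negative log-likelihood of the targets.

    Tokens are pooled across pairs; the end symbol counts as a target token.
    """
    if gen.is_copy_baseline or gen.model is None:
        raise ValueError("perplexity requires a trained model")
    if not pairs or all(len(p.target_tokens) == 0 for p in pairs):
        raise ValueError("empty target set")
    total_nll, total_tok = forced_nll(gen, pairs)
    return float(np.exp(total_nll / total_tok))


def forced_nll(
    gen: TrainedGenerator, pairs: Sequence[ConditionedPair]
) -> tuple[float, float]:
    """Summed negative log-likelihood and token count under forced decoding."""
    vocab, cfg = gen.vocab, gen.config
    total_nll, total_tok = 0.0, 0.0
    bs = max(cfg.batch_size, 1)
    for start in range(0, len(pairs), bs):
        batch = pairs[start : start + bs]
        src, src_lens, tgt_in, tgt_out, mask = _encode_batch(vocab, batch, cfg)
        logits = gen.model.forward(src, src_lens, tgt_in)
        logp = log_softmax_np(logits.data)
        B, T = tgt_out.shape
        picked = logp[np.arange(B)[:, None], np.arange(T)[None, :], tgt_out]
        total_nll += float(-(picked * mask).sum())
        total_tok += float(mask.sum())
    return total_nll, total_tok


# ---------------------------------------------------------------------------
# Checkpointing


def save_generator(gen: TrainedGenerator, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": asdict(gen.config),
        "vocab": gen.vocab.to_dict(),
        "loss_trace": gen.loss_trace,
        "val_loss_trace": gen.val_loss_trace,
        "train_setup": gen.train_setup,
    }
    (path / "meta.json").write_text(json.dumps(meta), encoding="utf-8")
    if gen.model is not None:
        np.savez(path / "params.npz", **gen.model.state_dict())


def load_generator(path: str | Path) -> TrainedGenerator:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text(encoding="utf-8"))
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unrecognised checkpoint format {meta.get('format')!r}")
    config = GeneratorConfig(**meta["config"])
    vocab = Vocabulary.from_dict(meta["vocab"])
    model = None
    if config.architecture == "transformer_ed":
        rng = np.random.default_rng(config.seed)
        model = Seq2SeqTransformer(rng, len(vocab), config)
        with np.load(path / "params.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
    gen = TrainedGenerator(config, vocab, model, train_setup=meta.get("train_setup"))
    gen.loss_trace = list(meta["loss_trace"])
    gen.val_loss_trace = list(meta["val_loss_trace"])
    return gen
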