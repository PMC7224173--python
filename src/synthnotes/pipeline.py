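"""End-to-end orchestration: fixture corpus -> conditioning -> training ->
generation -> intrinsic metrics -> memorisation audit -> extrinsic protocol.

Every stage reads and writes plain serialized files under the run directory,
so stages can be re-driven independently; a run manifest records the config
snapshot, per-stage seeds, wall-clock and a digest of every produced file.
Re-invoking a completed pipeline with an unchanged config is a no-op (digest
short-circuit).  Per-stage seeds derive from the master seed by hashing the
stage name, so any stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import Document, read_corpus, split_by_patient, write_corpus
from .extrinsic import (
    F1Sample,
    LabelledDocument,
    ProtocolConfig,
    ks_two_sample,
    label_documents,
    run_protocol,
)
from .generator import (
    GeneratorConfig,
    TrainedGenerator,
    generate,
    load_generator,
    perplexity,
    run_copy_baseline,
    save_generator,
    train,
)
from .keyphrases import ConditionedPair, build_conditioned_pairs, load_stopwords
from .memorisation import (
    MemorisationRow,
    audit,
    build_ngram_index,
    format_report,
    report_to_keyvalue,
    sample_sentences_by_quartile,
)
from .metrics import MetricReport, evaluate_corpus
from .synthetic import SyntheticCorpusConfig, generate_corpus


@dataclass
class RunConfig:
    corpus: SyntheticCorpusConfig = field(default_factory=SyntheticCorpusConfig)
    corpus_path: str | None = None  # pre-existing corpus overrides the fixture
    setups: tuple[str, ...] = ("top_meta",)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    keep_fraction: float = 0.6
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    audit_ns: tuple[int, ...] = (2, 3)
    audit_k: int = 1000
    run_extrinsic: bool = True
    extrinsic: ProtocolConfig = field(default_factory=ProtocolConfig)
    out_dir: str = "runs/default"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = dict(raw)
        if "corpus" in kwargs:
            kwargs["corpus"] = SyntheticCorpusConfig(**kwargs["corpus"])
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
        if "extrinsic" in kwargs:
            ex = dict(kwargs["extrinsic"])
            if "cnn" in ex:
                from .extrinsic import CNNConfig

                ex["cnn"] = CNNConfig(**{
                    k: tuple(v) if k == "filter_widths" else v
                    for k, v in ex["cnn"].items()
                })
            if "classifiers" in ex:
                ex["classifiers"] = tuple(ex["classifiers"])
            kwargs["extrinsic"] = ProtocolConfig(**ex)
        for key in ("setups", "audit_ns", "split_fractions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=list))


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % 2**31


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # stage -> {files, seed, seconds}

    def record(self, stage: str, seed: int, seconds: float, files: Sequence[Path]):
        self.stages[stage] = {
            "seed": seed,
            "seconds": round(seconds, 3),
            "files": {str(p): _file_digest(Path(p)) for p in files},
        }

    def save(self, path: Path) -> None:
        path.write_text(
            json.dumps({"config": self.config, "stages": self.stages}, indent=2),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        raw = json.loads(path.read_text(encoding="utf-8"))
        return cls(raw["config"], raw["stages"])

    def digests(self) -> dict[str, str]:
        out = {}
        for stage in self.stages.values():
            out.update(stage.get("files", {}))
        return out


def write_pairs(pairs: Sequence[ConditionedPair], stem: Path) -> list[Path]:
    """Serialise pairs as two aligned line files (space-joined tokens)."""
    inp = stem.with_suffix(".input.txt")
    tgt = stem.with_suffix(".target.txt")
    inp.write_text(
        "\n".join(" ".join(p.input_tokens) for p in pairs) + "\n", encoding="utf-8"
    )
    tgt.write_text(
        "\n".join(" ".join(p.target_tokens) for p in pairs) + "\n", encoding="utf-8"
    )
    return [inp, tgt]


def read_pairs(stem: Path, setup: str) -> list[ConditionedPair]:
    """Load pairs from the aligned line files (training-grade: no phrase
    boundaries or metadata, sufficient for fitting a generator)."""
    from .corpus import ClinicalMeta

    dummy = ClinicalMeta("f00", "", "female", 0, False, 0, "summary", 1)
    inputs = stem.with_suffix(".input.txt").read_text(encoding="utf-8").splitlines()
    targets = stem.with_suffix(".target.txt").read_text(encoding="utf-8").splitlines()
    if len(inputs) != len(targets):
        raise ValueError(f"misaligned pair files at {stem}")
    return [
        ConditionedPair(
            tuple(i.split()), tuple(t.split()), setup, dummy, (), f"l{k}", 0, 0
        )
        for k, (i, t) in enumerate(zip(inputs, targets))
    ]


def _labelled_from_generated(
    docs: Sequence[Document],
    pairs: Sequence[ConditionedPair],
    sequences: Sequence[Sequence[str]],
    classes: Sequence[str],
) -> list[LabelledDocument]:
    """Reassemble generated sentences into labelled artificial documents."""
    import numpy as np

    by_doc: dict[str, list[list[str]]] = {}
    for pair, seq in zip(pairs, sequences):
        by_doc.setdefault(pair.document_id, []).append(list(seq))
    class_idx = {c: i for i, c in enumerate(classes)}
    out = []
    for doc in docs:
        sents = by_doc.get(doc.document_id, [])
        labels = np.zeros(len(classes), dtype=np.int64)
        for _, meta in doc.sentences():
            if meta.diagnosis_code in class_idx:
                labels[class_idx[meta.diagnosis_code]] = 1
        out.append(
            LabelledDocument(doc.document_id, doc.patient_id, sents, labels)
        )
    return out


@dataclass
class PipelineResult:
    manifest: RunManifest
    intrinsic: dict[str, MetricReport]
    audit_rows: dict[str, list[MemorisationRow]]
    extrinsic: dict[tuple[str, str], F1Sample] | None
    ppl: dict[str, float]


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    snapshot = config.snapshot()
    if manifest_path.exists():
        old = RunManifest.load(manifest_path)
        if old.config == snapshot and all(
            Path(p).exists() and _file_digest(Path(p)) == d
            for p, d in old.digests().items()
        ):
            return _reload_result(config, old, out_dir)
    manifest = RunManifest(snapshot)
    stopwords = load_stopwords()

    # -- corpus stage
    t0 = time.time()
    corpus_file = out_dir / "corpus.jsonl"
    if config.corpus_path:
        docs = read_corpus(config.corpus_path)
        write_corpus(docs, corpus_file)
        files = [corpus_file]
    else:
        cfg = SyntheticCorpusConfig(
            **{
                **asdict(config.corpus),
                "seed": stage_seed(config.master_seed, "corpus"),
            }
        )
        docs, key = generate_corpus(cfg)
        write_corpus(docs, corpus_file)
        key_file = out_dir / "answer_key.json"
        key.to_json(key_file)
        files = [corpus_file, key_file]
    manifest.record(
        "corpus", stage_seed(config.master_seed, "corpus"), time.time() - t0, files
    )

    split = split_by_patient(
        docs, config.split_fractions, stage_seed(config.master_seed, "split")
    )
    classes = sorted(
        {m.diagnosis_code for d in docs for _, m in d.sentences()}
    )

    intrinsic: dict[str, MetricReport] = {}
    audit_rows: dict[str, list[MemorisationRow]] = {}
    ppls: dict[str, float] = {}
    regimes: dict[str, list[LabelledDocument]] = {}
    index = build_ngram_index(split.train, config.audit_ns)

    test_sentences = [
        list(s.tokens) for doc in split.test for par in doc.paragraphs for s in par
    ]

    for setup in config.setups:
        seed = stage_seed(config.master_seed, f"train:{setup}")
        t0 = time.time()
        cond = lambda dl, s=setup: [
            p
            for d in dl
            for p in build_conditioned_pairs(d, s, stopwords, config.keep_fraction)
        ]
        train_pairs = cond(split.train)
        val_pairs = cond(split.validation)
        test_pairs = cond(split.test)
        pair_files = write_pairs(train_pairs, out_dir / f"pairs_{setup}_train")
        pair_files += write_pairs(test_pairs, out_dir / f"pairs_{setup}_test")

        gen_cfg = GeneratorConfig(
            **{
                **asdict(config.generator),
                "seed": seed,
                "architecture": (
                    "copy_baseline" if setup == "key" else "transformer_ed"
                ),
            }
        )
        gen = train(train_pairs, val_pairs, gen_cfg)
        ckpt = out_dir / f"model_{setup}"
        save_generator(gen, ckpt)
        manifest.record(
            f"train:{setup}",
            seed,
            time.time() - t0,
            pair_files + [ckpt / "meta.json"],
        )

        # -- generation + intrinsic metrics on the test split
        t0 = time.time()
        output = generate(gen, test_pairs)
        gen_file = out_dir / f"generated_{setup}.txt"
        gen_file.write_text(
            "\n".join(" ".join(s) for s in output.sequences) + "\n", encoding="utf-8"
        )
        model_ppl = None
        if not gen.is_copy_baseline:
            model_ppl = perplexity(gen, test_pairs)
            ppls[setup] = model_ppl
        report = evaluate_corpus(output.sequences, test_sentences, model_ppl)
        report_file = out_dir / f"intrinsic_{setup}.tsv"
        report.to_files(report_file)
        intrinsic[setup] = report
        manifest.record(
            f"generate:{setup}",
            seed,
            time.time() - t0,
            [gen_file, report_file, report_file.with_suffix(".tsv.ter")],
        )

        # -- memorisation audit on the training split
        t0 = time.time()
        rows = []
        audit_seed = stage_seed(config.master_seed, f"audit:{setup}")
        for n in config.audit_ns:
            for quartile in ("low", "high"):
                sample = sample_sentences_by_quartile(
                    split.train, index, n, quartile, config.audit_k, audit_seed
                )
                rows.append(
                    audit(gen, sample, setup, stopwords, config.keep_fraction)
                )
        audit_rows[setup] = rows
        audit_file = out_dir / f"audit_{setup}.tsv"
        audit_file.write_text(format_report(rows), encoding="utf-8")
        kv_file = out_dir / f"audit_{setup}.json"
        kv_file.write_text(
            json.dumps(report_to_keyvalue(rows), indent=2), encoding="utf-8"
        )
        manifest.record(
            f"audit:{setup}", audit_seed, time.time() - t0, [audit_file, kv_file]
        )

        # -- artificial training regime for the extrinsic stage
        if config.run_extrinsic:
            train_out = generate(gen, train_pairs)
            regimes[setup] = _labelled_from_generated(
                split.train, train_pairs, train_out.sequences, classes
            )

    extr = None
    if config.run_extrinsic:
        t0 = time.time()
        seed = stage_seed(config.master_seed, "extrinsic")
        regimes["genuine"] = label_documents(split.train, classes)
        test_labelled = label_documents(split.test, classes)
        extr = run_protocol(
            regimes, test_labelled, config.extrinsic, seed, lda_reference=split.train
        )
        table = format_extrinsic(extr, baseline_regime="genuine")
        extr_file = out_dir / "extrinsic.tsv"
        extr_file.write_text(table, encoding="utf-8")
        manifest.record("extrinsic", seed, time.time() - t0, [extr_file])
    else:
        manifest.stages["extrinsic"] = {"skipped": True}

    manifest.save(manifest_path)
    return PipelineResult(manifest, intrinsic, audit_rows, extr, ppls)


def _reload_result(
    config: RunConfig, manifest: RunManifest, out_dir: Path
) -> PipelineResult:
    """Short-circuit path: reconstruct the light-weight summary from disk."""
    intrinsic: dict[str, MetricReport] = {}
    ppls: dict[str, float] = {}
    for setup in config.setups:
        report_file = out_dir / f"intrinsic_{setup}.tsv"
        vals = dict(
            line.split("\t")
            for line in report_file.read_text(encoding="utf-8").splitlines()
        )
        ter_vals = [
            float(v)
            for v in (out_dir / f"intrinsic_{setup}.tsv.ter")
            .read_text(encoding="utf-8")
            .split()
        ]
        report = MetricReport(
            rouge_l=float(vals["rouge_l"]),
            bleu=float(vals["bleu"]),
            ter=float(vals["ter"]),
            mean_sentence_length=float(vals["mean_sentence_length"]),
            ppl=float(vals["ppl"]) if "ppl" in vals else None,
            per_sentence_ter=ter_vals,
        )
        intrinsic[setup] = report
        if report.ppl is not None:
            ppls[setup] = report.ppl
    return PipelineResult(manifest, intrinsic, {}, None, ppls)


def compare_setups(
    results: dict[str, MetricReport], genuine_mean_length: float | None = None
) -> str:
    """Cross-setup summary table (one row per setup; genuine row carries only
    the mean sentence length)."""
    lines = ["setup\tppl\trouge_l\tbleu\tter\tmean_len"]
    if genuine_mean_length is not None:
        lines.append(f"genuine\t-\t-\t-\t-\t{genuine_mean_length:.2f}")
    for setup, r in results.items():
        ppl = "-" if r.ppl is None else f"{r.ppl:.2f}"
        lines.append(
            f"{setup}\t{ppl}\t{r.rouge_l:.3f}\t{r.bleu:.2f}\t{r.ter:.3f}"
            f"\t{r.mean_sentence_length:.2f}"
        )
    return "\n".join(lines) + "\n"


def format_extrinsic(
    samples: dict[tuple[str, str], F1Sample], baseline_regime: str = "genuine"
) -> str:
    """Results table mirroring the protocol layout: per (classifier, regime),
    per-class mean F1, overall mean, and KS D/p against the baseline regime."""
    lines = ["classifier\tregime\tper_class_f1\tmean_f1\tks_d\tks_p"]
    for (regime, clf), sample in sorted(samples.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        base = samples.get((baseline_regime, clf))
        if base is None or regime == baseline_regime:
            d, p = "-", "-"
        else:
            ks = ks_two_sample(base.values, sample.values)
            d, p = f"{ks.d_statistic:.3f}", f"{ks.p_value:.3g}"
        per_class = ",".join(f"{v:.3f}" for v in sample.per_class_means)
        lines.append(
            f"{clf}\t{regime}\t{per_class}\t{sample.mean:.3f}\t{d}\t{p}"
        )
    return "\n".join(lines) + "\n"
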