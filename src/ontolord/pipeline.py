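"""End-to-end orchestration of the three-phase training pipeline.

One declarative config drives: contrastive phase -> self-distillation across
several head seeds -> uniform weight averaging -> optional cross-lingual
distillation.  Every phase writes a checkpoint and a metrics snapshot; the
run manifest records the config hash, all seeds, per-phase metrics and wall
times.  All randomness flows through named seeds, so a rerun with the same
config reproduces the reference-encoder checkpoints bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import crosslingual as xl
from . import evalsuite as ev
from .contrastive import ContrastiveConfig, sts_adapt, train_contrastive_phase
from .corpus import CorpusOptions, build_contrastive_corpus
from .encoder import make_reference_encoder, save_encoder
from .exceptions import ConfigurationError
from .selfdistill import (
    DistillConfig,
    ProjectionHead,
    build_concept_embedding_bank,
    distillation_variants,
    fit_pca,
    make_distillation_targets,
    train_self_distillation,
)
from .soup import soup_encoders
from .synth import Benchmarks, SynthConfig, generate_benchmarks, generate_synthetic_ontology

_PHASE_ORDER = ("contrastive", "distill", "soup", "crosslingual")


def default_pipeline_config(seed: int = 0, output_dir: str = "out") -> dict:
    """The desk-scale defaults: synthetic fixture + reference encoder."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "data": {"synth": {"seed": seed}},
        "encoder": {"dimension": 64, "hash_buckets": 16384, "ngram_range": [2, 3], "seed": seed},
        "phases": {"contrastive": True, "distill": True, "soup": True, "crosslingual": True},
        "corpus": {"max_templates_per_concept": 2, "seed": seed},
        "contrastive": {"seed": seed},
        "distill": {"d": 48, "seeds": [seed + 1, seed + 2, seed + 3]},
        "crosslingual": {"seed": seed},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _validate_phase_order(phases: dict) -> None:
    enabled = [p for p in _PHASE_ORDER if phases.get(p)]
    for later, earlier in (("distill", "contrastive"), ("soup", "distill"), ("crosslingual", "soup")):
        if phases.get(later) and not phases.get(earlier):
            raise ConfigurationError(f"phase {later!r} requires phase {earlier!r} to be enabled")
    del enabled


def evaluate_encoder(enc, bench: Benchmarks) -> dict[str, float]:
    """The standard metrics snapshot taken after every phase."""
    return {
        "sts_pearson": ev.eval_sts(enc, bench.sts_test),
        "bcr_spearman": ev.eval_bcr(enc, bench.bcr),
        "nel_top1": ev.eval_nel_topk(enc, bench.nel_examples, bench.dictionary, k=1),
    }


def crosslingual_metrics(student, bench: Benchmarks, language: str) -> dict[str, float]:
    held = bench.parallel_heldout[language]
    Es = student.encode([p.source_text for p in held])
    Et = student.encode([p.target_text for p in held])
    return {
        "heldout_pair_cosine": float(np.mean((Es * Et).sum(axis=1))),
        "xnel_top1": ev.eval_nel_topk(student, bench.xnel_examples[language], bench.dictionary, 1),
    }


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the enabled phases in order and return the run manifest."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = copy.deepcopy(config)
    phases = config.get("phases", {})
    _validate_phase_order(phases)

    outdir = Path(config.get("output_dir", "out"))
    outdir.mkdir(parents=True, exist_ok=True)

    data_cfg = config.get("data", {})
    if "synth" not in data_cfg:
        raise ConfigurationError("pipeline config currently requires a data.synth section")
    synth_cfg = SynthConfig(**data_cfg["synth"])
    graph = generate_synthetic_ontology(synth_cfg)
    bench = generate_benchmarks(graph, synth_cfg)

    enc_cfg = config.get("encoder", {})
    base = make_reference_encoder(
        dimension=enc_cfg.get("dimension", 64),
        hash_buckets=enc_cfg.get("hash_buckets", 16384),
        ngram_range=tuple(enc_cfg.get("ngram_range", (2, 3))),
        seed=enc_cfg.get("seed", config.get("seed", 0)),
    )

    corpus = build_contrastive_corpus(graph, CorpusOptions(**config.get("corpus", {})))
    sts_train = [(p.sentence1, p.sentence2, p.gold) for p in bench.sts_train]

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seeds": {
            "pipeline": config.get("seed", 0),
            "encoder": base.seed,
            "distill": config.get("distill", {}).get("seeds", []),
        },
        "encoder_dimension": base.dimension,
        "phases": [],
    }
    timing: dict[str, float] = {}

    def record(name: str, enc, extra: dict | None = None) -> None:
        ckpt = save_encoder(enc, outdir / name)
        metrics = evaluate_encoder(enc, bench)
        if extra:
            metrics.update(extra)
        manifest["phases"].append(
            {"name": name, "checkpoint": str(ckpt), "metrics": metrics, "dimension": enc.dimension}
        )

    teacher = None
    if phases.get("contrastive"):
        t0 = time.perf_counter()
        teacher = base.copy()
        teacher, _history = train_contrastive_phase(
            teacher, corpus, sts_train, ContrastiveConfig(**config.get("contrastive", {}))
        )
        timing["contrastive"] = time.perf_counter() - t0
        record("contrastive", teacher)

    students = []
    if phases.get("distill"):
        t0 = time.perf_counter()
        distill_cfg = dict(config.get("distill", {}))
        d = distill_cfg.pop("d", 48)
        seeds = distill_cfg.pop("seeds", [1, 2, 3])
        bank = build_concept_embedding_bank(teacher, graph)
        pca = fit_pca(bank, d=d)
        targets = make_distillation_targets(bank, pca)
        variants = distillation_variants(graph)
        c_cfg = ContrastiveConfig(**config.get("contrastive", {}))
        student_init = base.copy()
        if sts_train:  # students start from the STS-adapted base
            sts_adapt(student_init, sts_train, c_cfg.sts_epochs, c_cfg.sts_learning_rate)
        for s in seeds:
            student = student_init.copy()
            head = ProjectionHead.initialize(d, student.dimension, seed=s)
            cfg_s = DistillConfig(seed=s, **distill_cfg)
            student, head, _hist = train_self_distillation(student, head, variants, targets, cfg_s)
            students.append(student)
        timing["distill"] = time.perf_counter() - t0
        for s, student in zip(seeds, students):
            record(f"distill_seed{s}", student)

    souped = None
    if phases.get("soup"):
        t0 = time.perf_counter()
        souped = soup_encoders(students)
        timing["soup"] = time.perf_counter() - t0
        record("soup", souped)

    if phases.get("crosslingual"):
        t0 = time.perf_counter()
        xl_cfg = dict(config.get("crosslingual", {}))
        language = xl_cfg.pop("language", synth_cfg.languages[0])
        student = souped.copy()
        student, _hist = xl.train_crosslingual_distillation(
            student, souped, bench.parallel_train[language], xl.XlingualConfig(**xl_cfg)
        )
        timing["crosslingual"] = time.perf_counter() - t0
        record("crosslingual", student, extra=crosslingual_metrics(student, bench, language))

    manifest["timing_seconds"] = {k: round(v, 3) for k, v in timing.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def manifests_equivalent(m1: dict, m2: dict) -> bool:
    """Equality modulo wall-clock timing."""
    a, b = copy.deepcopy(m1), copy.deepcopy(m2)
    a.pop("timing_seconds", None)
    b.pop("timing_seconds", None)
    return a == b
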