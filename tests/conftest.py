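"""Shared fixtures: the synthetic study fixture and trained models.

Heavy artifacts (the contrastive teacher, distilled students, the souped and
cross-lingually distilled encoders) are session-scoped and built lazily, so
light unit tests never pay for them and training runs once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import ontolord as ol
from ontolord.contrastive import sts_adapt
from ontolord.crosslingual import XlingualConfig, train_crosslingual_distillation
from ontolord.selfdistill import (
    DistillConfig,
    ProjectionHead,
    build_concept_embedding_bank,
    distillation_variants,
    fit_pca,
    make_distillation_targets,
    train_self_distillation,
)

SEED = 0
DISTILL_D = 48
DISTILL_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def synth_cfg():
    return ol.SynthConfig(seed=SEED)


@pytest.fixture(scope="session")
def graph(synth_cfg):
    return ol.generate_synthetic_ontology(synth_cfg)


@pytest.fixture(scope="session")
def bench(graph, synth_cfg):
    return ol.generate_benchmarks(graph, synth_cfg)


@pytest.fixture(scope="session")
def sts_train(bench):
    return [(p.sentence1, p.sentence2, p.gold) for p in bench.sts_train]


@pytest.fixture(scope="session")
def corpus(graph):
    return ol.build_contrastive_corpus(graph, ol.CorpusOptions(seed=SEED))


@pytest.fixture(scope="session")
def base_encoder():
    return ol.make_reference_encoder(seed=SEED)


@pytest.fixture(scope="session")
def adapted_base(base_encoder, sts_train):
    """The base encoder after STS adaptation (student initialization)."""
    return sts_adapt(base_encoder.copy(), sts_train)


@pytest.fixture(scope="session")
def teacher_and_history(base_encoder, corpus, sts_train):
    enc = base_encoder.copy()
    return ol.train_contrastive_phase(enc, corpus, sts_train, ol.ContrastiveConfig(seed=SEED))


@pytest.fixture(scope="session")
def teacher(teacher_and_history):
    return teacher_and_history[0]


@pytest.fixture(scope="session")
def distilled(teacher, graph, adapted_base):
    """Teacher bank, reduced targets, and the three distilled students."""
    bank = build_concept_embedding_bank(teacher, graph)
    pca = fit_pca(bank, d=DISTILL_D)
    targets = make_distillation_targets(bank, pca)
    variants = distillation_variants(graph)
    students = []
    for s in DISTILL_SEEDS:
        student = adapted_base.copy()
        head = ProjectionHead.initialize(DISTILL_D, student.dimension, seed=s)
        student, head, _ = train_self_distillation(
            student, head, variants, targets, DistillConfig(seed=s)
        )
        students.append(student)
    return {"bank": bank, "pca": pca, "targets": targets, "variants": variants,
            "students": students}


@pytest.fixture(scope="session")
def souped(distilled):
    return ol.soup_encoders(distilled["students"])


@pytest.fixture(scope="session")
def ml_student(souped, bench):
    """Cross-lingually distilled multilingual student (teacher = soup)."""
    student = souped.copy()
    student, _ = train_crosslingual_distillation(
        student, souped, bench.parallel_train["xx"], XlingualConfig(seed=SEED)
    )
    return student


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
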