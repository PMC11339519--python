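"""Embedding banks, PCA reduction, targets, and self-distillation training."""

import numpy as np
import pytest

import ontolord as ol
from ontolord.corpus import TextualVariant
from ontolord.exceptions import InputError
from ontolord.kg import Concept, ConceptName, Definition, KnowledgeGraph
from ontolord.selfdistill import (
    ConceptEmbeddingBank,
    DistillConfig,
    ProjectionHead,
    build_concept_embedding_bank,
    check_target_consistency,
    distillation_variants,
    fit_pca,
    make_distillation_targets,
    train_self_distillation,
)


def toy_bank(rng, n=50, D=8):
    names = rng.normal(size=(n, D))
    defs = rng.normal(size=(n, D))
    return ConceptEmbeddingBank([f"C{i}" for i in range(n)], names, defs)


def test_bank_average_matches_elementwise_loop(graph, teacher):
    bank = build_concept_embedding_bank(teacher, graph)
    for i in range(min(5, len(bank))):
        for k in range(bank.dimension):
            expected = (bank.name_embeddings[i][k] + bank.definition_embeddings[i][k]) / 2.0
            assert abs(bank.averaged[i][k] - expected) < 1e-9


def test_bank_uses_name_embedding_when_no_definition():
    g = KnowledgeGraph()
    g.add_concept(Concept("C1", [ConceptName("nodefword")]))
    enc = ol.make_reference_encoder(dimension=8, hash_buckets=256, seed=0)
    bank = build_concept_embedding_bank(enc, g)
    assert np.array_equal(bank.name_embeddings, bank.definition_embeddings)
    assert np.allclose(bank.averaged, bank.name_embeddings)


def test_bank_definition_policy_order():
    g = KnowledgeGraph()
    g.add_concept(Concept("C1", [ConceptName("alpha")],
                          [Definition("human text", "human"), Definition("generated text", "generated")]))
    enc = ol.make_reference_encoder(dimension=8, hash_buckets=256, seed=0)
    gen_first = build_concept_embedding_bank(enc, g, "generated_first")
    hum_first = build_concept_embedding_bank(enc, g, "human_first")
    assert np.array_equal(gen_first.definition_embeddings[0], enc.encode(["generated text"])[0])
    assert np.array_equal(hum_first.definition_embeddings[0], enc.encode(["human text"])[0])


def test_pca_matches_eigendecomposition_oracle(rng):
    bank = toy_bank(rng)
    pca = fit_pca(bank, d=3)
    X = bank.averaged
    C = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    assert np.allclose(pca.explained_variance, evals[:3], atol=1e-8)
    for k in range(3):
        dot = abs(evecs[:, k] @ pca.components[k])
        assert abs(dot - 1.0) < 1e-8  # same direction up to sign
    # sign convention: the largest-magnitude coordinate is positive
    for row in pca.components:
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_exact_on_low_rank_data(rng):
    basis = np.linalg.qr(rng.normal(size=(8, 3)))[0][:, :3].T
    coords = rng.normal(size=(40, 3))
    X = coords @ basis + rng.normal(size=8)
    bank = ConceptEmbeddingBank([f"C{i}" for i in range(40)], X.copy(), X.copy())
    pca = fit_pca(bank, d=3)
    recon = pca.inverse_transform(pca.transform(X))
    assert np.allclose(recon, X, atol=1e-8)


def test_pca_full_dimension_is_invertible(rng):
    bank = toy_bank(rng, n=30, D=6)
    pca = fit_pca(bank, d=6)
    X = bank.averaged
    assert np.allclose(pca.inverse_transform(pca.transform(X)), X, atol=1e-8)
    assert np.all(np.diff(pca.explained_variance) <= 1e-12)


def test_pca_rank_and_dimension_errors(rng):
    with pytest.raises(InputError):
        fit_pca(toy_bank(rng, n=5, D=8), d=6)
    with pytest.raises(InputError):
        fit_pca(toy_bank(rng, n=50, D=8), d=9)


def test_pca_default_reduces_to_64_dimensions(rng):
    bank = toy_bank(rng, n=80, D=96)
    assert fit_pca(bank).components.shape == (64, 96)


def test_targets_match_matrix_oracle(rng):
    bank = toy_bank(rng, n=20, D=8)
    pca = fit_pca(bank, d=4)
    targets = make_distillation_targets(bank, pca)
    for i, cid in enumerate(bank.concept_ids[:5]):
        oracle = pca.components @ (bank.averaged[i] - pca.mean)
        assert np.allclose(targets[cid], oracle, atol=1e-10)


def test_target_at_pca_mean_is_zero(rng):
    bank = toy_bank(rng, n=20, D=8)
    pca = fit_pca(bank, d=4)
    assert np.allclose(pca.transform(pca.mean[None, :]), 0.0, atol=1e-10)


def test_target_variance_equals_top_eigenvalue_sum(rng):
    bank = toy_bank(rng)
    pca = fit_pca(bank, d=4)
    Z = pca.transform(bank.averaged)
    total = np.var(Z, axis=0, ddof=1).sum()
    assert abs(total - pca.explained_variance.sum()) < 1e-6


def test_dimension_mismatch_rejected(rng):
    pca = fit_pca(toy_bank(rng, n=20, D=8), d=4)
    with pytest.raises(InputError):
        make_distillation_targets(toy_bank(rng, n=10, D=6), pca)


def test_name_and_definition_variants_share_identical_targets(graph, distilled):
    variants = distilled["variants"]
    targets = distilled["targets"]
    check_target_consistency(variants, targets)
    for concept in list(graph)[:10]:
        cid = concept.concept_id
        per_kind = {v.source_kind for v in variants if v.concept_id == cid}
        assert "name" in per_kind and per_kind & {"human_definition", "generated_definition"}
        # one target object serves every variant of the concept: exact equality
        assert targets[cid] is targets[cid]


def test_zero_epochs_leaves_student_unchanged(graph, distilled):
    student = ol.make_reference_encoder(seed=0)
    W0 = student.W.copy()
    head = ProjectionHead.initialize(48, student.dimension, seed=1)
    train_self_distillation(student, head, distilled["variants"], distilled["targets"],
                            DistillConfig(epochs=0))
    assert np.array_equal(student.W, W0)


def test_missing_target_names_the_concept():
    student = ol.make_reference_encoder(dimension=8, hash_buckets=256, seed=0)
    head = ProjectionHead.initialize(2, 8, seed=0)
    variants = [TextualVariant("GHOST", "text", "name")]
    with pytest.raises(InputError) as exc:
        train_self_distillation(student, head, variants, {}, DistillConfig())
    assert "GHOST" in str(exc.value)


def test_single_variant_training_converges_to_zero_loss():
    student = ol.make_reference_encoder(dimension=8, hash_buckets=256, seed=1)
    head = ProjectionHead.initialize(3, 8, seed=1)
    variants = [TextualVariant("C1", "solo concept name", "name")]
    targets = {"C1": np.array([0.3, -0.2, 0.5])}
    _, _, history = train_self_distillation(
        student, head, variants, targets,
        DistillConfig(epochs=400, learning_rate=0.2, head_weight_decay=0.0, seed=0),
    )
    assert history[-1]["loss"] < 1e-4


def test_distillation_is_seed_reproducible(adapted_base, distilled):
    cfg = DistillConfig(epochs=3, seed=4)
    outs = []
    for _ in range(2):
        student = adapted_base.copy()
        head = ProjectionHead.initialize(48, student.dimension, seed=4)
        student, head, _ = train_self_distillation(
            student, head, distilled["variants"], distilled["targets"], cfg
        )
        outs.append((student.W.copy(), head.weights.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])


def test_nearest_neighbor_concept_agreement_with_teacher(teacher, distilled, bench):
    """Dictionary retrieval: the student assigns each held-out mention the same
    nearest concept as the teacher for >= 80% of mentions."""
    from ontolord.evalsuite import nel_rankings

    student = distilled["students"][0]
    t_rank = nel_rankings(teacher, bench.nel_examples, bench.dictionary)
    s_rank = nel_rankings(student, bench.nel_examples, bench.dictionary)
    agree = np.mean([t[0] == s[0] for t, s in zip(t_rank, s_rank)])
    assert agree >= 0.8
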