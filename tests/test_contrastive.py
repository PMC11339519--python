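"""InfoNCE loss, batch sampling, STS adaptation, and the phase driver."""

import math

import numpy as np
import pytest

import ontolord as ol
from ontolord.contrastive import (
    ContrastiveConfig,
    info_nce_loss,
    sample_batch,
    sts_adaptation_step,
    train_contrastive_phase,
)
from ontolord.corpus import ContrastivePair, TextualVariant
from ontolord.exceptions import InputError, SamplingError


def make_corpus(n_concepts, pairs_per_concept=2):
    corpus = []
    for c in range(n_concepts):
        anchor = TextualVariant(f"C{c}", f"name{c}", "name")
        for p in range(pairs_per_concept):
            corpus.append(
                ContrastivePair(anchor, TextualVariant(f"C{c}", f"def{c}x{p}", "generated_definition"))
            )
    return corpus


def brute_force_info_nce(A, P, tau, symmetric):
    """Explicit-loop oracle: no matrix operations."""
    B = len(A)

    def direction(anchors, positives, transpose):
        total = 0.0
        for i in range(B):
            logits = []
            for j in range(B):
                s = sum(anchors[i][k] * positives[j][k] for k in range(len(A[0]))) / tau
                logits.append(s)
            if transpose:
                logits = [
                    sum(anchors[j][k] * positives[i][k] for k in range(len(A[0]))) / tau
                    for j in range(B)
                ]
            denom = sum(math.exp(l) for l in logits)
            true = logits[i]
            total += -math.log(math.exp(true) / denom)
        return total / B

    row = direction(A, P, transpose=False)
    if not symmetric:
        return row
    col = direction(A, P, transpose=True)
    return 0.5 * (row + col)


def random_unit_rows(rng, B, D):
    X = rng.normal(size=(B, D))
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def test_info_nce_single_pair_is_exactly_zero():
    e = np.array([[1.0, 0.0]])
    assert info_nce_loss(e, e, temperature=1.0) == 0.0


def test_info_nce_orthogonal_identity_case():
    # two concepts, anchors equal positives, orthogonal embeddings, tau = 1
    A = np.eye(2)
    expected = -math.log(math.e / (math.e + 1.0))
    assert abs(info_nce_loss(A, A, temperature=1.0, symmetric=False) - expected) < 1e-6
    assert abs(info_nce_loss(A, A, temperature=1.0, symmetric=True) - expected) < 1e-6


@pytest.mark.parametrize("symmetric", [False, True])
def test_info_nce_matches_bruteforce_on_random_batches(symmetric):
    rng = np.random.default_rng(11)
    for _ in range(25):
        B = int(rng.choice([2, 4, 8]))
        A = random_unit_rows(rng, B, 6)
        P = random_unit_rows(rng, B, 6)
        tau = float(rng.uniform(0.05, 1.0))
        ours = info_nce_loss(A, P, tau, symmetric)
        oracle = brute_force_info_nce(A.tolist(), P.tolist(), tau, symmetric)
        assert abs(ours - oracle) < 1e-6
        assert ours >= 0.0


def test_info_nce_permutation_equivariance():
    rng = np.random.default_rng(5)
    A = random_unit_rows(rng, 6, 8)
    P = random_unit_rows(rng, 6, 8)
    perm = rng.permutation(6)
    assert abs(info_nce_loss(A, P, 0.2) - info_nce_loss(A[perm], P[perm], 0.2)) < 1e-9


def test_info_nce_asymmetric_equals_row_term():
    rng = np.random.default_rng(9)
    A = random_unit_rows(rng, 4, 8)
    P = random_unit_rows(rng, 4, 8)
    row = info_nce_loss(A, P, 0.2, symmetric=False)
    col = info_nce_loss(P, A, 0.2, symmetric=False)
    sym = info_nce_loss(A, P, 0.2, symmetric=True)
    assert abs(sym - 0.5 * (row + col)) < 1e-9


def test_info_nce_rejects_bad_inputs():
    with pytest.raises(InputError):
        info_nce_loss(np.empty((0, 4)), np.empty((0, 4)), 0.1)
    bad = np.full((2, 4), 0.9)
    with pytest.raises(InputError):
        info_nce_loss(bad, bad, 0.1)


def test_sample_batch_covers_all_concepts_at_full_batch(rng):
    corpus = make_corpus(4)
    batch = sample_batch(corpus, 4, rng)
    assert sorted(batch.concept_ids) == [f"C{i}" for i in range(4)]


def test_sample_batch_requires_enough_concepts(rng):
    with pytest.raises(SamplingError):
        sample_batch(make_corpus(3), 4, rng)


def test_sample_batch_uniform_over_concepts():
    from scipy import stats

    corpus = make_corpus(5)
    rng = np.random.default_rng(17)
    counts = {f"C{i}": 0 for i in range(5)}
    draws = 10_000
    for _ in range(draws):
        for cid in sample_batch(corpus, 2, rng).concept_ids:
            counts[cid] += 1
    observed = np.array(list(counts.values()))
    _, p = stats.chisquare(observed)
    assert p > 0.01


def test_sts_gold_outside_range_rejected():
    enc = ol.make_reference_encoder(dimension=8, hash_buckets=256, seed=0)
    with pytest.raises(InputError):
        sts_adaptation_step(enc, [("a b", "c d", 5.5)], 0.1)


def test_sts_adaptation_moves_cosine_toward_target():
    enc = ol.make_reference_encoder(dimension=16, hash_buckets=1024, seed=2)
    pair = [("doleka rovasi", "mutefi sonalu", 5.0)]  # target cosine 1.0
    gaps = []
    for step in range(200):
        if step % 50 == 0:
            E = enc.encode([pair[0][0], pair[0][1]])
            gaps.append(1.0 - float(E[0] @ E[1]))
        sts_adaptation_step(enc, pair, 0.5)
    # recorded trajectory: the gap to the target shrinks at every checkpoint
    assert all(b < a for a, b in zip(gaps, gaps[1:]))


def test_phase_noop_leaves_parameters_identical(corpus, sts_train):
    enc = ol.make_reference_encoder(seed=0)
    W0 = enc.W.copy()
    cfg = ContrastiveConfig(epochs=0, sts_before=False, sts_after=False, seed=0)
    out, history = train_contrastive_phase(enc, corpus, sts_train, cfg)
    assert np.array_equal(out.W, W0)
    assert history == []


def test_phase_is_bit_reproducible(corpus, sts_train):
    cfg = ContrastiveConfig(epochs=3, sts_epochs=3, seed=12)
    a, _ = train_contrastive_phase(ol.make_reference_encoder(seed=0), corpus, sts_train, cfg)
    b, _ = train_contrastive_phase(ol.make_reference_encoder(seed=0), corpus, sts_train, cfg)
    assert np.array_equal(a.W, b.W)


def test_contrastive_loss_decreases_over_training(teacher_and_history):
    _, history = teacher_and_history
    losses = [h["loss"] for h in history if h["phase"] == "contrastive"]
    assert len(losses) > 10
    early = np.mean(losses[:3])
    late = np.mean(losses[-3:])
    assert late < 0.5 * early
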