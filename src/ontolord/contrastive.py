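"""Phase 1 — contrastive training of names against definitions (LORD).

Batches pair B distinct concepts' names with their definitions or relation
verbalizations.  The InfoNCE objective treats the B x B cosine-similarity
matrix (divided by a temperature) as classification logits whose true class
is the diagonal: each name is attracted to its own definition and repelled
from the other concepts' definitions in the batch.  Distinct concepts per
batch are enforced by the sampler so no in-batch negative is a false
negative.

A lightweight semantic-textual-similarity (STS) adaptation — regressing the
pair cosine onto the human 0-5 score divided by 5 — is run before and again
after the contrastive epochs, which counteracts drift away from sentence-level
judgment during concept learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import ContrastivePair
from .encoder import HashingNgramEncoder
from .exceptions import InputError, SamplingError


@dataclass(frozen=True)
class ContrastiveBatch:
    anchors: list  # TextualVariant, source_kind == "name"
    positives: list  # TextualVariant, definitions / templates
    concept_ids: list

    def __post_init__(self):
        if not (len(self.anchors) == len(self.positives) == len(self.concept_ids)):
            raise InputError("batch lists must share one length")
        if len(set(self.concept_ids)) != len(self.concept_ids):
            raise InputError("concept ids within a batch must be pairwise distinct")


@dataclass
class ContrastiveConfig:
    batch_size: int = 8
    temperature: float = 0.2
    symmetric: bool = True
    epochs: int = 120
    learning_rate: float = 1.0
    seed: int = 0
    # STS multi-task adaptation inserted before and after the contrastive epochs
    sts_before: bool = True
    sts_after: bool = True
    sts_epochs: int = 50
    sts_learning_rate: float = 2.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise InputError("temperature must be positive")
        if self.batch_size < 2:
            raise InputError("batch_size must be >= 2 for a meaningful loss")


def _group_by_concept(corpus: list[ContrastivePair]) -> dict[str, list[ContrastivePair]]:
    groups: dict[str, list[ContrastivePair]] = {}
    for pair in corpus:
        groups.setdefault(pair.concept_id, []).append(pair)
    return groups


def sample_batch(
    corpus: list[ContrastivePair],
    batch_size: int,
    rng: np.random.Generator,
    groups: dict[str, list[ContrastivePair]] | None = None,
) -> ContrastiveBatch:
    """Draw B pairs with pairwise-distinct concepts, uniform per concept."""
    if groups is None:
        groups = _group_by_concept(corpus)
    concept_ids = list(groups)
    if len(concept_ids) < batch_size:
        raise SamplingError(
            f"need {batch_size} distinct concepts, corpus has {len(concept_ids)}"
        )
    chosen = rng.choice(len(concept_ids), size=batch_size, replace=False)
    anchors, positives, ids = [], [], []
    for ci in chosen:
        cid = concept_ids[ci]
        pool = groups[cid]
        pair = pool[rng.integers(len(pool))]
        anchors.append(pair.anchor)
        positives.append(pair.positive)
        ids.append(cid)
    return ContrastiveBatch(anchors, positives, ids)


def _check_normalized(embs: np.ndarray, label: str) -> None:
    norms = np.linalg.norm(embs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise InputError(f"{label} embeddings are not unit-normalized")


def info_nce_loss(
    anchor_embs: np.ndarray,
    positive_embs: np.ndarray,
    temperature: float = 0.05,
    symmetric: bool = True,
) -> float:
    """In-batch-negative softmax cross-entropy over the cosine logit matrix.

    Row direction classifies each name against the batch's definitions; the
    symmetric variant averages it with the column (definition -> name)
    direction.  B = 1 degenerates to a single-logit softmax and returns 0.
    """
    loss, _, _ = _info_nce_with_grads(anchor_embs, positive_embs, temperature, symmetric)
    return loss


def _info_nce_with_grads(
    anchor_embs: np.ndarray,
    positive_embs: np.ndarray,
    temperature: float,
    symmetric: bool,
) -> tuple[float, np.ndarray, np.ndarray]:
    A = np.asarray(anchor_embs, dtype=np.float64)
    P = np.asarray(positive_embs, dtype=np.float64)
    if A.ndim != 2 or A.shape != P.shape or A.shape[0] == 0:
        raise InputError("anchor and positive embeddings must be equal-shape, non-empty 2-D arrays")
    if temperature <= 0:
        raise InputError("temperature must be positive")
    _check_normalized(A, "anchor")
    _check_normalized(P, "positive")
    B = A.shape[0]
    S = (A @ P.T) / temperature

    def logsumexp(M: np.ndarray, axis: int) -> np.ndarray:
        m = M.max(axis=axis, keepdims=True)
        return (m + np.log(np.exp(M - m).sum(axis=axis, keepdims=True))).squeeze(axis)

    # row direction: softmax over each row, true class = diagonal
    row_lse = logsumexp(S, axis=1)
    loss_row = float(np.mean(row_lse - np.diag(S)))
    soft_row = np.exp(S - row_lse[:, None])
    dS = (soft_row - np.eye(B)) / B

    if symmetric:
        col_lse = logsumexp(S, axis=0)
        loss_col = float(np.mean(col_lse - np.diag(S)))
        soft_col = np.exp(S - col_lse[None, :])
        dS = 0.5 * (dS + (soft_col - np.eye(B)) / B)
        loss = 0.5 * (loss_row + loss_col)
    else:
        loss = loss_row

    dA = (dS @ P) / temperature
    dP = (dS.T @ A) / temperature
    return loss, dA, dP


def sts_adaptation_step(
    enc: HashingNgramEncoder,
    pairs: list[tuple[str, str, float]],
    learning_rate: float,
) -> float:
    """One full-batch gradient step of cosine-vs-gold/5 mean squared error."""
    if not pairs:
        raise InputError("no STS pairs given")
    golds = np.array([g for _, _, g in pairs], dtype=np.float64)
    if np.any((golds < 0) | (golds > 5)):
        raise InputError("gold STS scores must lie in [0, 5]")
    s1 = [a for a, _, _ in pairs]
    s2 = [b for _, b, _ in pairs]
    E1, cache1 = enc.forward(s1)
    E2, cache2 = enc.forward(s2)
    cos = (E1 * E2).sum(axis=1)
    target = golds / 5.0
    resid = cos - target
    loss = float(np.mean(resid**2))
    dcos = 2.0 * resid / len(pairs)
    enc.sgd_update([(cache1, dcos[:, None] * E2), (cache2, dcos[:, None] * E1)], learning_rate)
    return loss


def sts_adapt(
    enc: HashingNgramEncoder,
    pairs: list[tuple[str, str, float]],
    epochs: int = 50,
    learning_rate: float = 2.0,
) -> HashingNgramEncoder:
    """Stand-alone STS adaptation (the 'base-STS' model used to initialize
    the self-distillation student); updates ``enc`` in place and returns it."""
    for _ in range(epochs):
        sts_adaptation_step(enc, pairs, learning_rate)
    return enc


def train_contrastive_phase(
    enc: HashingNgramEncoder,
    corpus: list[ContrastivePair],
    sts_data: list[tuple[str, str, float]] | None,
    cfg: ContrastiveConfig,
) -> tuple[HashingNgramEncoder, list[dict]]:
    """STS adaptation -> contrastive epochs -> STS adaptation, in that order.

    Each sub-phase is skippable through the config; the encoder is updated in
    place and also returned.  Bit-reproducible for a fixed seed.
    """
    history: list[dict] = []
    rng = np.random.default_rng(cfg.seed)

    def run_sts(tag: str) -> None:
        if sts_data is None:
            return
        for epoch in range(cfg.sts_epochs):
            loss = sts_adaptation_step(enc, sts_data, cfg.sts_learning_rate)
            history.append({"phase": tag, "epoch": epoch, "loss": loss})

    if cfg.sts_before:
        run_sts("sts_pre")

    if cfg.epochs > 0 and corpus:
        groups = _group_by_concept(corpus)
        if len(groups) < cfg.batch_size:
            raise SamplingError(
                f"corpus has {len(groups)} distinct concepts, batch size is {cfg.batch_size}"
            )
        steps_per_epoch = max(1, len(corpus) // cfg.batch_size)
        for epoch in range(cfg.epochs):
            epoch_losses = []
            for _ in range(steps_per_epoch):
                batch = sample_batch(corpus, cfg.batch_size, rng, groups)
                EA, cacheA = enc.forward([v.text for v in batch.anchors])
                EP, cacheP = enc.forward([v.text for v in batch.positives])
                loss, dA, dP = _info_nce_with_grads(EA, EP, cfg.temperature, cfg.symmetric)
                enc.sgd_update([(cacheA, dA), (cacheP, dP)], cfg.learning_rate)
                epoch_losses.append(loss)
            history.append(
                {"phase": "contrastive", "epoch": epoch, "loss": float(np.mean(epoch_losses))}
            )

    if cfg.sts_after:
        run_sts("sts_post")

    return enc, history
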