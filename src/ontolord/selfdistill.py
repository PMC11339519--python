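"""Phase 2 — supervised self-distillation onto reduced concept embeddings.

The contrastive model (the teacher) embeds every concept's preferred name and
one definition; the two vectors are averaged per concept, the averaged bank is
compressed with principal component analysis (64 dimensions at full scale),
and a fresh student — one that has *not* undergone contrastive training —
is regressed onto these reduced targets through a randomly initialized linear
projection head with a plain mean-squared-error loss.  Every textual variant
of a concept (all its names and its definitions) regresses to the one shared
target.  The head is discarded at export: the deliverable is the student's own
full-dimension embedding.

Because the student's gradient arrives only through the head's d x D matrix,
updates to the embedding geometry are confined to a d-dimensional subspace,
which is what lets this phase acquire the teacher's concept geometry while
disturbing the rest of the embedding space far less than contrastive training
does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .corpus import TextualVariant
from .encoder import HashingNgramEncoder
from .exceptions import InputError, ValidationError
from .kg import GENERATED, HUMAN, KnowledgeGraph


@dataclass
class ConceptEmbeddingBank:
    """Per-concept teacher embeddings: name, definition, and their mean."""

    concept_ids: list[str]
    name_embeddings: np.ndarray  # (n, D)
    definition_embeddings: np.ndarray  # (n, D)

    @property
    def averaged(self) -> np.ndarray:
        return 0.5 * (self.name_embeddings + self.definition_embeddings)

    @property
    def dimension(self) -> int:
        return self.name_embeddings.shape[1]

    def __len__(self) -> int:
        return len(self.concept_ids)


@dataclass
class PcaTransform:
    mean: np.ndarray  # (D,)
    components: np.ndarray  # (d, D), orthonormal rows
    explained_variance: np.ndarray  # (d,)
    explained_variance_ratio: np.ndarray  # (d,)

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z) @ self.components + self.mean


@dataclass
class ProjectionHead:
    """Trainable linear head mapping student embeddings (D) to targets (d)."""

    weights: np.ndarray  # (d, D)
    bias: np.ndarray  # (d,)
    seed: int

    @classmethod
    def initialize(cls, d: int, dimension: int, seed: int, scale: float = 0.1) -> "ProjectionHead":
        rng = np.random.default_rng(seed)
        return cls(rng.normal(0.0, scale, size=(d, dimension)), np.zeros(d), seed)

    def __call__(self, embeddings: np.ndarray) -> np.ndarray:
        return embeddings @ self.weights.T + self.bias


@dataclass
class DistillConfig:
    epochs: int = 200
    learning_rate: float = 0.5
    batch_size: int = 32
    seed: int = 0
    head_init_scale: float = 0.1
    # decay on the head only: forces the student embedding, not the head, to
    # carry the target geometry, while leaving the complement subspace intact
    head_weight_decay: float = 0.01


def build_concept_embedding_bank(
    teacher,
    graph: KnowledgeGraph,
    definition_policy: str = "generated_first",
) -> ConceptEmbeddingBank:
    """Embed each concept's preferred name and one definition with the teacher.

    ``definition_policy`` picks the definition when several exist
    ("generated_first" or "human_first"); a concept with no definition uses its
    name embedding in both slots, so its average is the name embedding itself.
    """
    if definition_policy not in ("generated_first", "human_first"):
        raise InputError(f"unknown definition policy {definition_policy!r}")
    first, second = (
        (GENERATED, HUMAN) if definition_policy == "generated_first" else (HUMAN, GENERATED)
    )
    ids, names, defs = [], [], []
    for concept in graph:
        ids.append(concept.concept_id)
        names.append(concept.preferred_name)
        pick = concept.definitions_by_source(first) or concept.definitions_by_source(second)
        defs.append(pick[0].text if pick else concept.preferred_name)
    E_names = teacher.encode(names)
    E_defs = teacher.encode(defs)
    return ConceptEmbeddingBank(ids, E_names, E_defs)


def fit_pca(bank: ConceptEmbeddingBank, d: int = 64) -> PcaTransform:
    """Top-d principal directions of the averaged bank vectors.

    Components are sign-fixed (largest-magnitude coordinate positive) so the
    transform is reproducible across runs and linear-algebra backends.
    """
    if d < 1:
        raise InputError("d must be >= 1")
    X = bank.averaged
    if len(bank) < d:
        raise InputError(f"need at least {d} bank entries to fit a rank-{d} transform, have {len(bank)}")
    if d > bank.dimension:
        raise InputError(f"d={d} exceeds embedding dimension {bank.dimension}")
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaTransform(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def make_distillation_targets(bank: ConceptEmbeddingBank, pca: PcaTransform) -> dict[str, np.ndarray]:
    """Reduced regression target per concept: components . (averaged - mean)."""
    if pca.components.shape[1] != bank.dimension:
        raise InputError(
            f"transform dimension {pca.components.shape[1]} != bank dimension {bank.dimension}"
        )
    Z = pca.transform(bank.averaged)
    return {cid: Z[i] for i, cid in enumerate(bank.concept_ids)}


def distillation_variants(
    graph: KnowledgeGraph,
    include_templates: bool = False,
    template_texts: dict[str, list[str]] | None = None,
    augment_names: int = 3,
    augment_noise_rate: float = 0.1,
    seed: int = 0,
) -> list[TextualVariant]:
    """The training set of phase 2: all names and all definitions per concept
    (relation verbalizations optionally included).

    As in corpus construction, each name also contributes ``augment_names``
    character-perturbed copies regressing to the same concept target, so the
    student inherits the teacher's robustness to informal spelling variation.
    """
    from .corpus import character_noise

    rng = np.random.default_rng(seed)
    variants: list[TextualVariant] = []
    for concept in graph:
        cid = concept.concept_id
        for name in concept.names:
            variants.append(TextualVariant(cid, name.text, "name"))
            for _ in range(augment_names):
                noisy = character_noise(name.text, augment_noise_rate, rng)
                variants.append(TextualVariant(cid, noisy, "name"))
        for definition in concept.definitions:
            kind = "human_definition" if definition.source == HUMAN else "generated_definition"
            variants.append(TextualVariant(cid, definition.text, kind))
        if include_templates and template_texts:
            for text in template_texts.get(cid, ()):
                variants.append(TextualVariant(cid, text, "relation_template"))
    return variants


def train_self_distillation(
    student: HashingNgramEncoder,
    head: ProjectionHead,
    variants: list[TextualVariant],
    targets: dict[str, np.ndarray],
    cfg: DistillConfig,
) -> tuple[HashingNgramEncoder, ProjectionHead, list[dict]]:
    """Minimize mean ||head(student(text)) - target||^2 over all variants.

    The loss is averaged over the batch and summed over target coordinates.
    Student and head train jointly by stochastic gradient descent; both are
    updated in place and returned with a per-epoch loss history.
    """
    if cfg.epochs < 0:
        raise InputError("epochs must be >= 0")
    missing = [v.concept_id for v in variants if v.concept_id not in targets]
    if missing:
        raise InputError(f"variants reference concepts without targets: {sorted(set(missing))[:5]}")
    if head.weights.shape[1] != student.dimension:
        raise InputError("projection head width does not match the student dimension")

    history: list[dict] = []
    if cfg.epochs == 0 or not variants:
        return student, head, history

    texts = [v.text for v in variants]
    T = np.stack([targets[v.concept_id] for v in variants])
    n = len(variants)
    rng = np.random.default_rng(cfg.seed)
    batch = max(1, min(cfg.batch_size, n))

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            E, cache = student.forward([texts[i] for i in sel])
            pred = head(E)
            resid = pred - T[sel]
            loss = float(np.mean(np.sum(resid**2, axis=1)))
            dpred = 2.0 * resid / len(sel)
            gWh = dpred.T @ E
            gb = dpred.sum(axis=0)
            dE = dpred @ head.weights
            student.sgd_update([(cache, dE)], cfg.learning_rate)
            head.weights -= cfg.learning_rate * (gWh + cfg.head_weight_decay * head.weights)
            head.bias -= cfg.learning_rate * gb
            epoch_losses.append(loss)
        history.append({"phase": "distill", "epoch": epoch, "loss": float(np.mean(epoch_losses))})
    return student, head, history


def concept_similarity_spearman(
    teacher_bank: ConceptEmbeddingBank,
    student_bank: ConceptEmbeddingBank,
    centered: bool = True,
) -> float:
    """Spearman correlation between the two banks' pairwise concept cosines.

    By default each bank is mean-centered first, the usual convention when
    comparing representational geometries across models: the common-mean
    (anisotropy) component is exactly what self-distillation is designed not
    to transfer, so it is removed from the comparison.
    """
    from scipy import stats

    if teacher_bank.concept_ids != student_bank.concept_ids:
        raise InputError("banks must cover the same concepts in the same order")

    def sims(bank: ConceptEmbeddingBank) -> np.ndarray:
        X = bank.averaged
        if centered:
            X = X - X.mean(axis=0)
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
        iu = np.triu_indices(len(bank), 1)
        return (X @ X.T)[iu]

    return float(stats.spearmanr(sims(teacher_bank), sims(student_bank)).statistic)


def check_target_consistency(variants: list[TextualVariant], targets: dict[str, np.ndarray]) -> None:
    """Assert that name and definition variants of one concept share an
    identical (not merely close) target vector."""
    seen: dict[str, np.ndarray] = {}
    for v in variants:
        t = targets[v.concept_id]
        if v.concept_id in seen and seen[v.concept_id] is not t and not np.array_equal(seen[v.concept_id], t):
            raise ValidationError(f"concept {v.concept_id!r} has diverging targets")
        seen[v.concept_id] = t
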