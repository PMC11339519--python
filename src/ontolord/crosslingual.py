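"""Cross-lingual distillation of a monolingual teacher into a multilingual student.

Given a parallel corpus of (source text, translation) pairs, the student is
trained so that both sides map to the frozen teacher's embedding of the
source text:

    L = MSE(student(src), teacher(src)) + MSE(student(tgt), teacher(src))

so "Fever", "Fiebre" and "Fieber" all land on one vector.  Parallel pairs can
be supplied directly or mined from per-language name lists by mutual-best
cosine alignment under a pluggable scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoder import HashingNgramEncoder
from .exceptions import ConfigurationError, InputError, ParseError


@dataclass(frozen=True)
class ParallelPair:
    source_text: str
    target_text: str
    concept_id: str | None = None
    alignment_score: float = 1.0

    def __post_init__(self):
        if not self.source_text or not self.target_text:
            raise InputError("parallel pair texts must be non-empty")


def mine_parallel_pairs(
    source_names: list[str],
    target_names: list[str],
    scorer,
    threshold: float = 0.8,
    strategy: str = "mutual_best",
) -> list[ParallelPair]:
    """Bitext mining: keep (i, j) that are mutual best matches with score >= threshold.

    ``scorer`` is any encoder-like object; scores are cosines of its
    normalized embeddings.  Mutual-best matching uses each side at most once
    by construction.
    """
    if strategy != "mutual_best":
        raise ConfigurationError(f"unknown mining strategy {strategy!r}")
    if not source_names or not target_names:
        raise InputError("name lists must be non-empty")
    if not -1.0 <= threshold <= 1.0:
        raise InputError("threshold must lie in [-1, 1]")
    S = scorer.encode(source_names) @ scorer.encode(target_names).T
    best_tgt = np.argmax(S, axis=1)
    best_src = np.argmax(S, axis=0)
    pairs = []
    for i, j in enumerate(best_tgt):
        if best_src[j] == i and S[i, j] >= threshold:
            pairs.append(
                ParallelPair(source_names[i], target_names[j], alignment_score=float(S[i, j]))
            )
    return pairs


@dataclass
class XlingualConfig:
    epochs: int = 200
    learning_rate: float = 0.5
    batch_size: int = 32
    seed: int = 0


def train_crosslingual_distillation(
    student: HashingNgramEncoder,
    teacher,
    pairs: list[ParallelPair],
    cfg: XlingualConfig,
) -> tuple[HashingNgramEncoder, list[dict]]:
    """SGD on the two-term distillation loss; the teacher is never updated.

    Teacher targets are computed once up front (the teacher stays frozen); the
    student is updated in place and returned with a loss history.
    """
    if student.dimension != teacher.dimension:
        raise ConfigurationError(
            f"student dimension {student.dimension} != teacher dimension {teacher.dimension}"
        )
    history: list[dict] = []
    if cfg.epochs == 0 or not pairs:
        return student, history

    sources = [p.source_text for p in pairs]
    targets_text = [p.target_text for p in pairs]
    T = teacher.encode(sources)  # frozen targets
    n = len(pairs)
    rng = np.random.default_rng(cfg.seed)
    batch = max(1, min(cfg.batch_size, n))

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            Tb = T[sel]
            Es, cache_s = student.forward([sources[i] for i in sel])
            Et, cache_t = student.forward([targets_text[i] for i in sel])
            rs = Es - Tb
            rt = Et - Tb
            loss = float(np.mean(np.sum(rs**2, axis=1)) + np.mean(np.sum(rt**2, axis=1)))
            student.sgd_update(
                [(cache_s, 2.0 * rs / len(sel)), (cache_t, 2.0 * rt / len(sel))],
                cfg.learning_rate,
            )
            epoch_losses.append(loss)
        history.append({"phase": "xlingual", "epoch": epoch, "loss": float(np.mean(epoch_losses))})
    return student, history


# ---- parallel-corpus IO (TSV: source, target, language code, score) ------


def write_parallel_corpus(pairs: list[ParallelPair], path: str | Path, language: str) -> None:
    lines = [
        "\t".join([p.source_text, p.target_text, language, f"{p.alignment_score:.6f}"])
        for p in pairs
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_parallel_corpus(path: str | Path) -> list[ParallelPair]:
    path = Path(path)
    pairs = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"expected 4 tab-separated fields, found {len(fields)}",
                             filename=path.name, line=lineno)
        src, tgt, _lang, score = fields
        pairs.append(ParallelPair(src, tgt, alignment_score=float(score)))
    return pairs
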