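"""Evaluation harness: STS, concept-relatedness (BCR), and entity linking (NEL).

Three protocols, all driven by cosine similarity of the encoder's unit-norm
embeddings:

* STS — Pearson correlation between pair cosines and human 0-5 similarity
  judgments;
* BCR — Spearman rank correlation between term-pair cosines and human
  relatedness ratings (average ranks on ties);
* NEL — Top-k retrieval accuracy of free-text mentions against a concept
  dictionary; a concept is scored by its best-scoring name and ties break by
  stable dictionary order.

A semantic-type filter reproduces the cross-lingual evaluation practice of
excluding mention types a dictionary cannot sensibly resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import InputError, ParseError, UndefinedCorrelationError


@dataclass(frozen=True)
class StsPair:
    sentence1: str
    sentence2: str
    gold: float

    def __post_init__(self):
        if not 0.0 <= self.gold <= 5.0:
            raise InputError(f"gold STS score {self.gold} outside [0, 5]")


@dataclass(frozen=True)
class BcrPair:
    term1: str
    term2: str
    gold: float


@dataclass(frozen=True)
class NelExample:
    mention: str
    gold_concept_id: str


@dataclass
class ConceptDictionary:
    """Flat (concept_id, name, semantic_type) rows; a concept may repeat with
    several names.  Row order is the documented tie-break order."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for _, name, _ in self.entries]

    @property
    def concept_ids(self) -> list[str]:
        return [cid for cid, _, _ in self.entries]

    def semantic_type_of(self, concept_id: str) -> str:
        for cid, _, sem in self.entries:
            if cid == concept_id:
                return sem
        raise KeyError(concept_id)

    def n_concepts(self) -> int:
        return len(dict.fromkeys(self.concept_ids))


def _scores_or_raise(x: np.ndarray, y: np.ndarray) -> None:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("one score series has zero variance")


def model_scores(enc, pairs) -> np.ndarray:
    """Cosine similarity per pair under the encoder."""
    left = [p.sentence1 if isinstance(p, StsPair) else p.term1 for p in pairs]
    right = [p.sentence2 if isinstance(p, StsPair) else p.term2 for p in pairs]
    E1 = enc.encode(left)
    E2 = enc.encode(right)
    return (E1 * E2).sum(axis=1)


def eval_sts(enc, pairs: list[StsPair]) -> float:
    """Pearson r between model cosines and gold 0-5 judgments."""
    if len(pairs) < 2:
        raise InputError("need at least 2 STS pairs")
    scores = model_scores(enc, pairs)
    golds = np.array([p.gold for p in pairs])
    _scores_or_raise(scores, golds)
    return float(stats.pearsonr(scores, golds).statistic)


def eval_bcr(enc, pairs: list[BcrPair]) -> float:
    """Spearman rho between model cosines and gold relatedness ratings."""
    if len(pairs) < 2:
        raise InputError("need at least 2 term pairs")
    scores = model_scores(enc, pairs)
    golds = np.array([p.gold for p in pairs])
    _scores_or_raise(scores, golds)
    return float(stats.spearmanr(scores, golds).statistic)


def nel_rankings(enc, examples: list[NelExample], dictionary: ConceptDictionary) -> list[list[str]]:
    """Concept ids ranked best-first per mention (best name per concept,
    ties broken by first dictionary occurrence)."""
    if not dictionary.entries:
        raise InputError("dictionary is empty")
    E_names = enc.encode(dictionary.names)
    M = enc.encode([ex.mention for ex in examples])
    S = M @ E_names.T  # (n_mentions, n_names)

    concept_order = list(dict.fromkeys(dictionary.concept_ids))
    concept_index = {cid: i for i, cid in enumerate(concept_order)}
    name_to_concept = np.array([concept_index[cid] for cid in dictionary.concept_ids])
    n_concepts = len(concept_order)

    rankings = []
    for row in S:
        best = np.full(n_concepts, -np.inf)
        np.maximum.at(best, name_to_concept, row)
        order = np.lexsort((np.arange(n_concepts), -best))  # score desc, dict order on ties
        rankings.append([concept_order[i] for i in order])
    return rankings


def eval_nel_topk(enc, examples: list[NelExample], dictionary: ConceptDictionary, k: int = 1) -> float:
    """Fraction of mentions whose gold concept is within the top-k retrieved."""
    if k < 1:
        raise InputError("k must be >= 1")
    if not examples:
        raise InputError("no NEL examples given")
    rankings = nel_rankings(enc, examples, dictionary)
    hits = sum(ex.gold_concept_id in rank[:k] for ex, rank in zip(examples, rankings))
    return hits / len(examples)


def filter_by_semantic_type(
    examples: list[NelExample],
    dictionary: ConceptDictionary,
    excluded_types: set[str],
) -> tuple[list[NelExample], dict[str, int]]:
    """Drop examples whose gold concept carries an excluded semantic type."""
    sem = {cid: s for cid, _, s in dictionary.entries}
    kept = [ex for ex in examples if sem.get(ex.gold_concept_id) not in excluded_types]
    report = {"n_input": len(examples), "n_kept": len(kept), "n_excluded": len(examples) - len(kept)}
    return kept, report


# ---- benchmark file IO (tab-separated, documented columns) ----------------


def _read_tsv(path: str | Path, n_fields: int) -> list[tuple[int, list[str]]]:
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ParseError(f"expected {n_fields} tab-separated fields, found {len(fields)}",
                             filename=path.name, line=lineno)
        rows.append((lineno, fields))
    return rows


def read_sts_file(path: str | Path) -> list[StsPair]:
    """Columns: sentence1, sentence2, gold score in [0, 5]."""
    return [StsPair(a, b, float(g)) for _, (a, b, g) in _read_tsv(path, 3)]


def write_sts_file(pairs: list[StsPair], path: str | Path) -> None:
    lines = [f"{p.sentence1}\t{p.sentence2}\t{p.gold:.17g}" for p in pairs]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_bcr_file(path: str | Path) -> list[BcrPair]:
    """Columns: term1, term2, gold relatedness."""
    return [BcrPair(a, b, float(g)) for _, (a, b, g) in _read_tsv(path, 3)]


def write_bcr_file(pairs: list[BcrPair], path: str | Path) -> None:
    lines = [f"{p.term1}\t{p.term2}\t{p.gold:.17g}" for p in pairs]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_nel_file(path: str | Path) -> list[NelExample]:
    """Columns: mention, gold concept id."""
    return [NelExample(m, cid) for _, (m, cid) in _read_tsv(path, 2)]


def write_nel_file(examples: list[NelExample], path: str | Path) -> None:
    lines = [f"{ex.mention}\t{ex.gold_concept_id}" for ex in examples]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_dictionary_file(path: str | Path) -> ConceptDictionary:
    """Columns: concept id, name, semantic type."""
    return ConceptDictionary([(cid, name, sem) for _, (cid, name, sem) in _read_tsv(path, 3)])


def write_dictionary_file(dictionary: ConceptDictionary, path: str | Path) -> None:
    lines = [f"{cid}\t{name}\t{sem}" for cid, name, sem in dictionary.entries]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
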