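"""Contrastive training corpus: (concept name, positive text) pairs.

A concept name is the anchor; its positives are the concept's definitions
(human written and machine generated alike, which play the same attraction
role) and short template verbalizations of the knowledge-graph relations the
concept participates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParseError, TemplateError
from .kg import GENERATED, HUMAN, KnowledgeGraph, Relation

SOURCE_KINDS = ("name", "human_definition", "generated_definition", "relation_template")

#: Default wording for relation verbalization; "{s}", "{o}" and "{p}" expand to
#: the subject's preferred name, the object's preferred name and the predicate.
DEFAULT_TEMPLATES: dict[str, str] = {
    "may_treat": "{s} is a concept that may treat {o}",
    "may_prevent": "{s} is a concept that may prevent {o}",
    "isa": "{s} is a kind of {o}",
    "part_of": "{s} is a part of {o}",
    "associated_with": "{s} is associated with {o}",
    "co_occurs_with": "{s} frequently co-occurs with {o}",
}

FALLBACK_TEMPLATE = "{s} is related to {o} (via {p})"


@dataclass(frozen=True)
class TextualVariant:
    concept_id: str
    text: str
    source_kind: str

    def __post_init__(self):
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.source_kind!r}")
        if not self.text:
            raise ValueError("variant text must be non-empty")


@dataclass(frozen=True)
class ContrastivePair:
    anchor: TextualVariant
    positive: TextualVariant

    def __post_init__(self):
        if self.anchor.source_kind != "name":
            raise ValueError("anchor must be a name variant")
        if self.positive.source_kind == "name":
            raise ValueError("positive must be a definition or template variant")
        if self.anchor.concept_id != self.positive.concept_id:
            raise ValueError("anchor and positive must share one concept")

    @property
    def concept_id(self) -> str:
        return self.anchor.concept_id


def character_noise(text: str, noise_rate: float, rng: np.random.Generator) -> str:
    """Character-level swap/delete/duplicate noise, each non-space position hit
    with probability ``noise_rate`` — the informal-variation model used both
    for mention generation and for anchor augmentation."""
    chars = list(text)
    out: list[str] = []
    i = 0
    while i < len(chars):
        if chars[i] != " " and rng.random() < noise_rate:
            op = rng.integers(3)
            if op == 0 and i + 1 < len(chars) and chars[i + 1] != " ":  # swap
                out.extend([chars[i + 1], chars[i]])
                i += 2
                continue
            if op == 1:  # delete
                i += 1
                continue
            out.extend([chars[i], chars[i]])  # duplicate
            i += 1
            continue
        out.append(chars[i])
        i += 1
    return "".join(out) or text


@dataclass
class CorpusOptions:
    use_human_defs: bool = True
    use_generated_defs: bool = True
    use_relation_templates: bool = True
    max_templates_per_concept: int = 2
    mirror_templates_to_object: bool = False
    templates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    fallback_template: str | None = FALLBACK_TEMPLATE
    # noisy anchor copies: robustness to informal spelling variation
    augment_names: int = 3  # extra perturbed copies per (name, positive) pair
    augment_noise_rate: float = 0.1
    seed: int = 0


def verbalize_relation(
    rel: Relation,
    graph: KnowledgeGraph,
    templates: dict[str, str] | None = None,
    fallback_template: str | None = FALLBACK_TEMPLATE,
) -> TextualVariant:
    """Render one relation as natural-language text attached to its subject."""
    templates = DEFAULT_TEMPLATES if templates is None else templates
    template = templates.get(rel.predicate)
    if template is None:
        if fallback_template is None:
            raise TemplateError(f"no template for predicate {rel.predicate!r}")
        template = fallback_template
    subject = graph[rel.subject_id].preferred_name
    obj = graph[rel.object_id].preferred_name
    text = template.format(s=subject, o=obj, p=rel.predicate.replace("_", " "))
    return TextualVariant(rel.subject_id, text, "relation_template")


def build_contrastive_corpus(graph: KnowledgeGraph, options: CorpusOptions | None = None) -> list[ContrastivePair]:
    """Emit every admissible (name, positive) combination per concept.

    Relation verbalizations are sampled without replacement down to
    ``max_templates_per_concept`` with the options seed; with templates off the
    output is seed-independent.  Concepts with no admissible positive emit
    nothing.
    """
    options = options or CorpusOptions()
    rng = np.random.default_rng(options.seed)

    by_subject: dict[str, list[Relation]] = {}
    if options.use_relation_templates:
        for rel in graph.relations:
            by_subject.setdefault(rel.subject_id, []).append(rel)
            if options.mirror_templates_to_object:
                mirrored = Relation(rel.object_id, rel.predicate, rel.subject_id)
                by_subject.setdefault(rel.object_id, []).append(mirrored)

    pairs: list[ContrastivePair] = []
    for cid in graph.concepts:  # insertion order: deterministic
        concept = graph[cid]
        positives: list[TextualVariant] = []
        for d in concept.definitions:
            if d.source == HUMAN and options.use_human_defs:
                positives.append(TextualVariant(cid, d.text, "human_definition"))
            elif d.source == GENERATED and options.use_generated_defs:
                positives.append(TextualVariant(cid, d.text, "generated_definition"))
        rels = by_subject.get(cid, [])
        if rels:
            keep = min(options.max_templates_per_concept, len(rels))
            if keep < len(rels):
                idx = sorted(rng.choice(len(rels), size=keep, replace=False))
                rels = [rels[i] for i in idx]
            for rel in rels:
                positives.append(
                    verbalize_relation(rel, graph, options.templates, options.fallback_template)
                )
        if not positives:
            continue
        for name in concept.names:
            anchors = [TextualVariant(cid, name.text, "name")]
            for _ in range(options.augment_names):
                noisy = character_noise(name.text, options.augment_noise_rate, rng)
                anchors.append(TextualVariant(cid, noisy, "name"))
            for anchor in anchors:
                for pos in positives:
                    pairs.append(ContrastivePair(anchor, pos))
    return pairs


def write_corpus(pairs: list[ContrastivePair], path: str | Path) -> None:
    """Tab-separated (concept_id, anchor, positive, source_kind); tabs and
    newlines inside texts are escaped as \\t and \\n."""

    def esc(s: str) -> str:
        return s.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")

    lines = [
        "\t".join([p.concept_id, esc(p.anchor.text), esc(p.positive.text), p.positive.source_kind])
        for p in pairs
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_corpus(path: str | Path) -> list[ContrastivePair]:
    def unesc(s: str) -> str:
        out, i = [], 0
        while i < len(s):
            if s[i] == "\\" and i + 1 < len(s):
                out.append({"\\": "\\", "t": "\t", "n": "\n"}.get(s[i + 1], s[i + 1]))
                i += 2
            else:
                out.append(s[i])
                i += 1
        return "".join(out)

    path = Path(path)
    pairs = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"expected 4 tab-separated fields, found {len(fields)}",
                             filename=path.name, line=lineno)
        cid, anchor, positive, kind = fields
        pairs.append(
            ContrastivePair(
                TextualVariant(cid, unesc(anchor), "name"),
                TextualVariant(cid, unesc(positive), kind),
            )
        )
    return pairs
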