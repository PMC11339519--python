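"""Knowledge-graph data model and table IO.

The on-disk representation is a deliberately minimal, pipe-delimited dialect
of the meta-thesaurus "rich release format" family: a concept/synonym table
(id, language, name[, semantic type]), a definition table (id, source tag,
text) and a relation table (subject, predicate, object).  Real release files
carry many more columns; the :class:`TableDialect` column-index map lets those
extra columns be skipped rather than re-modelled.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .exceptions import ParseError, ValidationError

HUMAN = "human"
GENERATED = "generated"
_DEF_SOURCES = (HUMAN, GENERATED)


@dataclass(frozen=True)
class ConceptName:
    text: str
    language: str = "en"


@dataclass(frozen=True)
class Definition:
    text: str
    source: str  # "human" | "generated"

    def __post_init__(self):
        if self.source not in _DEF_SOURCES:
            raise ValidationError(f"unknown definition source {self.source!r}")


@dataclass
class Concept:
    """A single ontology concept: an opaque id, its surface names and definitions.

    The first name is the preferred term.  Duplicate (name, language) entries
    are collapsed at load time.
    """

    concept_id: str
    names: list[ConceptName] = field(default_factory=list)
    definitions: list[Definition] = field(default_factory=list)
    semantic_type: str = ""

    @property
    def preferred_name(self) -> str:
        return self.names[0].text

    def definitions_by_source(self, source: str) -> list[Definition]:
        return [d for d in self.definitions if d.source == source]


@dataclass(frozen=True)
class Relation:
    subject_id: str
    predicate: str
    object_id: str


@dataclass
class KnowledgeGraph:
    concepts: dict[str, Concept] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[concept_id]

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts.values())

    def add_concept(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise ValidationError(f"duplicate concept id {concept.concept_id!r}")
        if not concept.names or any(not n.text for n in concept.names):
            raise ValidationError(f"concept {concept.concept_id!r} has empty or missing names")
        self.concepts[concept.concept_id] = concept

    def add_relation(self, relation: Relation) -> None:
        for endpoint in (relation.subject_id, relation.object_id):
            if endpoint not in self.concepts:
                raise ValidationError(f"relation endpoint {endpoint!r} not in graph")
        self.relations.append(relation)

    def relations_of(self, concept_id: str) -> list[Relation]:
        return [r for r in self.relations if r.subject_id == concept_id]

    def validate(self) -> None:
        """Re-check referential integrity and per-concept invariants."""
        for cid, concept in self.concepts.items():
            if cid != concept.concept_id:
                raise ValidationError(f"key {cid!r} does not match concept id {concept.concept_id!r}")
            if not concept.names:
                raise ValidationError(f"concept {cid!r} has no names")
            if any(not n.text for n in concept.names):
                raise ValidationError(f"concept {cid!r} has an empty name")
        for rel in self.relations:
            if rel.subject_id not in self.concepts or rel.object_id not in self.concepts:
                raise ValidationError(f"dangling relation {rel}")

    def canonical_form(self) -> tuple:
        """A hashable form invariant to input-row order, for logical comparison."""
        concepts = tuple(
            (
                cid,
                frozenset((n.text, n.language) for n in c.names),
                frozenset((d.text, d.source) for d in c.definitions),
                c.semantic_type,
            )
            for cid, c in sorted(self.concepts.items())
        )
        relations = tuple(sorted((r.subject_id, r.predicate, r.object_id) for r in self.relations))
        return concepts, relations


@dataclass(frozen=True)
class TableDialect:
    """Column layout of the pipe-delimited tables.

    Indices are 0-based positions inside each row; rows may carry extra
    trailing columns (they are ignored), which is how the 18-column real
    release files are consumed.
    """

    delimiter: str = "|"
    has_header: bool = False
    concept_id_col: int = 0
    language_col: int = 1
    name_col: int = 2
    semantic_type_col: int | None = 3  # used only when the row is long enough
    def_concept_id_col: int = 0
    def_source_col: int = 1
    def_text_col: int = 2
    rel_subject_col: int = 0
    rel_predicate_col: int = 1
    rel_object_col: int = 2


DEFAULT_DIALECT = TableDialect()


@dataclass
class LoadReport:
    """Row-level accounting for one :func:`load_knowledge_graph` call."""

    n_concepts: int = 0
    n_names: int = 0
    n_definitions_human: int = 0
    n_definitions_generated: int = 0
    n_relations: int = 0
    n_duplicate_names: int = 0
    n_empty_names: int = 0
    n_orphan_definitions: int = 0
    n_empty_definitions: int = 0
    n_orphan_relations: int = 0
    n_self_relations: int = 0

    def to_text(self) -> str:
        lines = [f"{k}\t{v}" for k, v in vars(self).items()]
        return "\n".join(lines) + "\n"


@dataclass
class AttachReport:
    n_attached: int = 0
    n_skipped_unknown: int = 0
    n_rejected_empty: int = 0

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in vars(self).items()) + "\n"


def _iter_rows(path: str | Path, dialect: TableDialect, min_cols: int) -> Iterator[tuple[int, list[str]]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for lineno, row in enumerate(reader, start=1):
            if dialect.has_header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) < min_cols:
                raise ParseError(
                    f"expected at least {min_cols} columns, found {len(row)}",
                    filename=path.name,
                    line=lineno,
                )
            yield lineno, row


def load_knowledge_graph(
    concept_table: str | Path,
    definition_table: str | Path | None = None,
    relation_table: str | Path | None = None,
    dialect: TableDialect = DEFAULT_DIALECT,
    allow_self_predicates: frozenset[str] = frozenset(),
) -> tuple[KnowledgeGraph, LoadReport]:
    """Load and validate a knowledge graph from its serialized tables.

    Definition and relation rows whose concept ids do not resolve are dropped
    and counted in the report; a malformed row (too few columns) raises
    :class:`ParseError` with file and line, and conflicting semantic types for
    one concept id raise :class:`ValidationError`.
    """
    graph = KnowledgeGraph()
    report = LoadReport()

    n_cols = max(dialect.concept_id_col, dialect.language_col, dialect.name_col) + 1
    for lineno, row in _iter_rows(concept_table, dialect, n_cols):
        cid = row[dialect.concept_id_col].strip()
        lang = row[dialect.language_col].strip() or "en"
        name = row[dialect.name_col].strip()
        sem = ""
        if dialect.semantic_type_col is not None and len(row) > dialect.semantic_type_col:
            sem = row[dialect.semantic_type_col].strip()
        if not name:
            report.n_empty_names += 1
            continue
        concept = graph.concepts.get(cid)
        if concept is None:
            concept = Concept(concept_id=cid, semantic_type=sem)
            graph.concepts[cid] = concept
        elif sem and concept.semantic_type and sem != concept.semantic_type:
            raise ValidationError(
                f"concept {cid!r} has conflicting semantic types "
                f"{concept.semantic_type!r} and {sem!r} (line {lineno})"
            )
        elif sem and not concept.semantic_type:
            concept.semantic_type = sem
        entry = ConceptName(name, lang)
        if entry in concept.names:
            report.n_duplicate_names += 1
        else:
            concept.names.append(entry)
            report.n_names += 1

    report.n_concepts = len(graph.concepts)

    if definition_table is not None:
        n_cols = max(dialect.def_concept_id_col, dialect.def_source_col, dialect.def_text_col) + 1
        for _lineno, row in _iter_rows(definition_table, dialect, n_cols):
            cid = row[dialect.def_concept_id_col].strip()
            source = row[dialect.def_source_col].strip() or HUMAN
            text = row[dialect.def_text_col].strip()
            if not text:
                report.n_empty_definitions += 1
                continue
            if cid not in graph.concepts:
                report.n_orphan_definitions += 1
                continue
            graph.concepts[cid].definitions.append(Definition(text, source))
            if source == HUMAN:
                report.n_definitions_human += 1
            else:
                report.n_definitions_generated += 1

    if relation_table is not None:
        n_cols = max(dialect.rel_subject_col, dialect.rel_predicate_col, dialect.rel_object_col) + 1
        for _lineno, row in _iter_rows(relation_table, dialect, n_cols):
            subj = row[dialect.rel_subject_col].strip()
            pred = row[dialect.rel_predicate_col].strip()
            obj = row[dialect.rel_object_col].strip()
            if subj not in graph.concepts or obj not in graph.concepts:
                report.n_orphan_relations += 1
                continue
            if subj == obj and pred not in allow_self_predicates:
                report.n_self_relations += 1
                continue
            graph.relations.append(Relation(subj, pred, obj))
        report.n_relations = len(graph.relations)

    graph.validate()
    return graph, report


def attach_generated_definitions(
    graph: KnowledgeGraph,
    agct_table: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> AttachReport:
    """Append machine-generated definitions (concept_id, text rows) to the graph.

    Existing human definitions are never overwritten; rows for unknown
    concepts or with empty text are skipped and counted.
    """
    report = AttachReport()
    # the generated-definition table has two roles: id and text
    for _lineno, row in _iter_rows(agct_table, dialect, 2):
        cid = row[0].strip()
        text = row[-1].strip() if len(row) == 2 else row[1].strip()
        if not text:
            report.n_rejected_empty += 1
            continue
        if cid not in graph.concepts:
            report.n_skipped_unknown += 1
            continue
        graph.concepts[cid].definitions.append(Definition(text, GENERATED))
        report.n_attached += 1
    return report


def _write_table(rows: Iterable[Iterable[str]], path: str | Path, dialect: TableDialect) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=dialect.delimiter, lineterminator="\n")
    for row in rows:
        writer.writerow(list(row))
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_knowledge_graph(
    graph: KnowledgeGraph,
    concept_table: str | Path,
    definition_table: str | Path | None = None,
    relation_table: str | Path | None = None,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Serialize a graph back to its tables, concepts sorted by id.

    Name and definition order within a concept is preserved (the first name is
    the preferred term), so write -> load -> write is byte-stable.
    """
    concept_rows = []
    def_rows = []
    for cid in sorted(graph.concepts):
        c = graph.concepts[cid]
        for n in c.names:
            concept_rows.append([cid, n.language, n.text, c.semantic_type])
        for d in c.definitions:
            def_rows.append([cid, d.source, d.text])
    _write_table(concept_rows, concept_table, dialect)
    if definition_table is not None:
        _write_table(def_rows, definition_table, dialect)
    if relation_table is not None:
        rel_rows = sorted((r.subject_id, r.predicate, r.object_id) for r in graph.relations)
        _write_table(rel_rows, relation_table, dialect)


def write_graph_dir(graph: KnowledgeGraph, directory: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> dict[str, Path]:
    """Write the three tables under one directory with conventional names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "concepts": directory / "concepts.psv",
        "definitions": directory / "definitions.psv",
        "relations": directory / "relations.psv",
    }
    write_knowledge_graph(graph, paths["concepts"], paths["definitions"], paths["relations"], dialect)
    return paths


def load_graph_dir(directory: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> tuple[KnowledgeGraph, LoadReport]:
    directory = Path(directory)
    definitions = directory / "definitions.psv"
    relations = directory / "relations.psv"
    return load_knowledge_graph(
        directory / "concepts.psv",
        definitions if definitions.exists() else None,
        relations if relations.exists() else None,
        dialect,
    )
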