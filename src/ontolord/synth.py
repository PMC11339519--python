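"""Deterministic synthetic ontology, benchmarks and parallel corpora.

The generator emulates the statistical structure the pipeline assumes of its
real inputs without any download:

* concepts are grouped into latent **topics**; a concept's definitions mix
  topic-level tokens (shared within the topic) with concept-specific tokens,
  the way real definitions mix domain vocabulary with term-specific content;
* a concept's synonyms are **lexically unrelated** surface forms (as brand
  vs generic drug names are) — linking them is only possible through the
  shared definitions, which is precisely the regime definition-grounded
  contrastive learning targets;
* all tokens are built from a small consonant-vowel syllable inventory, so
  the character-n-gram space is compact and a modest parallel corpus covers
  it;
* "languages" are deterministic bijective character ciphers standing in for
  real translations: pair structure without external resources;
* evaluation sets carry graded gold labels derived from the latent structure
  (same concept > same topic > unrelated) with bounded uniform jitter, so
  perfect correlations are unattainable by construction;
* entity-linking mentions are character-perturbed held-out synonyms that
  never string-match a dictionary entry, forcing generalization over lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.utils.murmurhash import murmurhash3_32

from .corpus import character_noise
from .crosslingual import ParallelPair, write_parallel_corpus
from .evalsuite import (
    BcrPair,
    ConceptDictionary,
    NelExample,
    StsPair,
    write_bcr_file,
    write_dictionary_file,
    write_nel_file,
    write_sts_file,
)
from .exceptions import ConfigurationError, MappingError
from .kg import Concept, ConceptName, Definition, KnowledgeGraph, Relation, write_graph_dir

ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]

_PREDICATES = ("associated_with", "co_occurs_with", "part_of")


@dataclass
class SynthConfig:
    n_topics: int = 5
    concepts_per_topic: int = 10
    names_per_concept: int = 4
    vocab_size: int = 40  # shared filler vocabulary mixed into definitions
    noise_rate: float = 0.1  # per-character perturbation probability for mentions
    languages: tuple[str, ...] = ("xx",)  # cipher-language codes
    seed: int = 0
    # benchmark shape
    dict_names_per_concept: int = 2
    n_sts_pairs: int = 90
    n_general_sts_pairs: int = 60
    n_bcr_pairs: int = 60
    sts_jitter: float = 0.5
    heldout_concept_fraction: float = 0.2  # concepts held out of parallel training
    human_definition_fraction: float = 0.3
    # broad-coverage parallel prose (real mined bitext dwarfs the term list);
    # sentences of fresh syllable tokens so the cipher is covered n-gram-wise
    n_parallel_prose: int = 6000

    def __post_init__(self):
        if min(self.n_topics, self.concepts_per_topic, self.names_per_concept) < 0:
            raise ConfigurationError("counts must be >= 0")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigurationError("noise_rate must lie in [0, 1]")
        if self.dict_names_per_concept >= self.names_per_concept and self.names_per_concept > 0:
            raise ConfigurationError(
                "names_per_concept must exceed dict_names_per_concept to hold out mentions"
            )


# ---- tokens ---------------------------------------------------------------


def _make_token(rng: np.random.Generator, seen: set[str], n_syllables: int = 3) -> str:
    while True:
        idx = rng.integers(0, len(SYLLABLES), size=n_syllables)
        t = "".join(SYLLABLES[i] for i in idx)
        if t not in seen:
            seen.add(t)
            return t


# ---- ontology -------------------------------------------------------------


def generate_synthetic_ontology(cfg: SynthConfig) -> KnowledgeGraph:
    """Clustered toy ontology, fully reproducible from ``cfg.seed``.

    Topic ``t`` owns ``concepts_per_topic`` concepts tagged with semantic type
    ``T<t>``; every concept gets a generated definition, a fraction also get a
    human one, and typed relations link same-topic neighbours in a ring.
    """
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    fillers = [_make_token(rng, seen) for _ in range(cfg.vocab_size)]
    graph = KnowledgeGraph()

    for t in range(cfg.n_topics):
        topic_tokens = [_make_token(rng, seen) for _ in range(3)]
        topic_ids = []
        for c in range(cfg.concepts_per_topic):
            cid = f"C{t:03d}{c:04d}"
            names = [ConceptName(_make_token(rng, seen)) for _ in range(cfg.names_per_concept)]
            own = [_make_token(rng, seen) for _ in range(2)]

            def def_tokens() -> list[str]:
                toks = topic_tokens + own + ([fillers[rng.integers(len(fillers))]] if fillers else [])
                perm = rng.permutation(len(toks))
                return [toks[i] for i in perm]

            definitions = [Definition(" ".join(def_tokens()), "generated")]
            if rng.random() < cfg.human_definition_fraction:
                definitions.append(Definition(" ".join(def_tokens()), "human"))
            graph.add_concept(
                Concept(cid, names=names, definitions=definitions, semantic_type=f"T{t:02d}")
            )
            topic_ids.append(cid)
        k = len(topic_ids)
        if k >= 2:
            for i, cid in enumerate(topic_ids):
                graph.add_relation(Relation(cid, _PREDICATES[i % len(_PREDICATES)],
                                            topic_ids[(i + 1) % k]))
    graph.validate()
    return graph


def topic_of(concept_id: str, graph: KnowledgeGraph) -> str:
    return graph[concept_id].semantic_type


def latent_similarity(cid1: str, cid2: str, graph: KnowledgeGraph) -> float:
    """Concept/topic overlap on a 0-1 scale: 1 same concept, 0.5 same topic."""
    if cid1 == cid2:
        return 1.0
    if topic_of(cid1, graph) == topic_of(cid2, graph):
        return 0.5
    return 0.0


# ---- ciphers --------------------------------------------------------------


def make_cipher(language_code: str, seed: int = 0) -> dict[str, str]:
    """Bijective character map over the generator alphabet (space fixed)."""
    rng = np.random.default_rng([seed, murmurhash3_32(language_code, positive=True)])
    perm = rng.permutation(len(ALPHABET))
    cipher = {a: ALPHABET[p] for a, p in zip(ALPHABET, perm)}
    cipher[" "] = " "
    return cipher


def cipher_translate(text: str, cipher: dict[str, str]) -> str:
    """Deterministic, invertible character substitution."""
    values = list(cipher.values())
    if len(set(values)) != len(values):
        raise MappingError("cipher is not bijective")
    try:
        return "".join(cipher[ch] for ch in text)
    except KeyError as exc:
        raise MappingError(f"character {exc.args[0]!r} outside the cipher alphabet") from None


def invert_cipher(cipher: dict[str, str]) -> dict[str, str]:
    return {v: k for k, v in cipher.items()}


# ---- perturbation ---------------------------------------------------------


#: Mention perturbation reuses the corpus module's informal-variation model.
perturb = character_noise


# ---- benchmarks -----------------------------------------------------------


@dataclass
class Benchmarks:
    sts_train: list[StsPair]
    sts_test: list[StsPair]
    sts_general: list[StsPair]  # general-language pairs, never used in training
    bcr: list[BcrPair]
    nel_examples: list[NelExample]
    dictionary: ConceptDictionary
    parallel_train: dict[str, list[ParallelPair]]
    parallel_heldout: dict[str, list[ParallelPair]]
    xnel_examples: dict[str, list[NelExample]]
    ciphers: dict[str, dict[str, str]]
    latent: dict[str, tuple[str, str]]  # text -> (topic tag, concept id)


def _sentence(graph: KnowledgeGraph, cid: str, rng: np.random.Generator) -> str:
    """A sentence realization of a concept: a fresh shuffle of its definition
    tokens (with one token dropped half the time)."""
    tokens = graph[cid].definitions[0].text.split()
    perm = rng.permutation(len(tokens))
    tokens = [tokens[i] for i in perm]
    if len(tokens) > 3 and rng.random() < 0.5:
        tokens = tokens[:-1]
    return " ".join(tokens)


def generate_benchmarks(graph: KnowledgeGraph, cfg: SynthConfig) -> Benchmarks:
    """STS/BCR/NEL benchmarks and parallel corpora consistent with the graph's
    latent topic/concept structure; reproducible from ``cfg.seed``."""
    rng = np.random.default_rng([cfg.seed, 1])
    cids = list(graph.concepts)
    latent: dict[str, tuple[str, str]] = {}

    def note(text: str, cid: str) -> str:
        latent[text] = (topic_of(cid, graph), cid)
        return text

    by_topic: dict[str, list[str]] = {}
    for cid in cids:
        by_topic.setdefault(topic_of(cid, graph), []).append(cid)
        for name in graph[cid].names:
            note(name.text, cid)

    # --- STS: thirds of same-concept / same-topic / cross-topic pairs -----
    def gold_for(sim: float) -> float:
        jitter = rng.uniform(-cfg.sts_jitter, cfg.sts_jitter)
        return float(np.clip(5.0 * sim + jitter, 0.0, 5.0))

    sts: list[StsPair] = []
    topics = [t for t in by_topic if len(by_topic[t]) >= 2]
    if cids:
        for i in range(cfg.n_sts_pairs):
            kind = i % 3
            if kind == 0 or not topics or len(by_topic) < 2:
                cid = cids[rng.integers(len(cids))]
                s1, s2 = note(_sentence(graph, cid, rng), cid), note(_sentence(graph, cid, rng), cid)
                sim = 1.0
            elif kind == 1:
                t = topics[rng.integers(len(topics))]
                c1, c2 = rng.choice(len(by_topic[t]), size=2, replace=False)
                cid1, cid2 = by_topic[t][c1], by_topic[t][c2]
                s1, s2 = note(_sentence(graph, cid1, rng), cid1), note(_sentence(graph, cid2, rng), cid2)
                sim = 0.5
            else:
                t1, t2 = rng.choice(len(by_topic), size=2, replace=False)
                keys = list(by_topic)
                cid1 = by_topic[keys[t1]][rng.integers(len(by_topic[keys[t1]]))]
                cid2 = by_topic[keys[t2]][rng.integers(len(by_topic[keys[t2]]))]
                s1, s2 = note(_sentence(graph, cid1, rng), cid1), note(_sentence(graph, cid2, rng), cid2)
                sim = 0.0
            sts.append(StsPair(s1, s2, gold_for(sim)))
    sts_train, sts_test = sts[0::2], sts[1::2]

    # --- general-language STS: filler-vocabulary sentences -----------------
    # The shared filler vocabulary is reconstructed from the seed (it is the
    # first thing the ontology generator draws).  These pairs play the role of
    # general-domain similarity benchmarks: no training phase ever sees them,
    # so they measure what concept training does to the rest of the space.
    gen_rng = np.random.default_rng(cfg.seed)
    gen_seen: set[str] = set()
    fillers = [_make_token(gen_rng, gen_seen) for _ in range(cfg.vocab_size)]
    sts_general: list[StsPair] = []
    if len(fillers) >= 10:
        for i in range(cfg.n_general_sts_pairs):
            kind = i % 3
            idx = rng.choice(len(fillers), size=10, replace=False)
            a = [fillers[j] for j in idx[:5]]
            if kind == 0:  # same token set, reshuffled
                b_tokens = [a[j] for j in rng.permutation(5)]
                sim = 1.0
            elif kind == 1:  # half overlap
                b_tokens = a[:3] + [fillers[j] for j in idx[5:7]]
                b_tokens = [b_tokens[j] for j in rng.permutation(5)]
                sim = 0.5
            else:  # disjoint
                b_tokens = [fillers[j] for j in idx[5:]]
                sim = 0.0
            sts_general.append(StsPair(" ".join(a), " ".join(b_tokens), gold_for(sim)))

    # --- BCR: term-level pairs with the same latent grading ---------------
    bcr: list[BcrPair] = []
    if cids:
        for i in range(cfg.n_bcr_pairs):
            kind = i % 3
            if kind == 0 or not topics or len(by_topic) < 2:
                cid = cids[rng.integers(len(cids))]
                n1, n2 = rng.choice(cfg.names_per_concept, size=2, replace=False)
                t1, t2 = graph[cid].names[n1].text, graph[cid].names[n2].text
                note(t1, cid), note(t2, cid)
                sim = 1.0
            elif kind == 1:
                t = topics[rng.integers(len(topics))]
                c1, c2 = rng.choice(len(by_topic[t]), size=2, replace=False)
                cid1, cid2 = by_topic[t][c1], by_topic[t][c2]
                t1 = note(graph[cid1].names[0].text, cid1)
                t2 = note(graph[cid2].names[0].text, cid2)
                sim = 0.5
            else:
                keys = list(by_topic)
                i1, i2 = rng.choice(len(keys), size=2, replace=False)
                cid1 = by_topic[keys[i1]][rng.integers(len(by_topic[keys[i1]]))]
                cid2 = by_topic[keys[i2]][rng.integers(len(by_topic[keys[i2]]))]
                t1 = note(graph[cid1].names[0].text, cid1)
                t2 = note(graph[cid2].names[0].text, cid2)
                sim = 0.0
            bcr.append(BcrPair(t1, t2, gold_for(sim)))

    # --- NEL: dictionary from the first names, mentions from the rest -----
    entries = []
    for cid in cids:
        for name in graph[cid].names[: cfg.dict_names_per_concept]:
            entries.append((cid, name.text, topic_of(cid, graph)))
    dictionary = ConceptDictionary(entries)
    dict_names = set(dictionary.names)

    nel: list[NelExample] = []
    for cid in cids:
        for name in graph[cid].names[cfg.dict_names_per_concept :]:
            mention = perturb(name.text, cfg.noise_rate, rng)
            while mention in dict_names:
                mention = perturb(name.text, max(cfg.noise_rate, 0.15), rng)
            nel.append(NelExample(note(mention, cid), cid))

    # --- parallel corpora per cipher language ------------------------------
    n_held = int(round(cfg.heldout_concept_fraction * len(cids)))
    held_idx = set(rng.choice(len(cids), size=n_held, replace=False).tolist()) if n_held else set()
    held_cids = {cids[i] for i in held_idx}

    ciphers = {lang: make_cipher(lang, cfg.seed) for lang in cfg.languages}
    prose_rng = np.random.default_rng([cfg.seed, 2])
    prose_seen: set[str] = set()
    prose = [
        " ".join(
            _make_token(prose_rng, prose_seen, int(prose_rng.integers(2, 5)))
            for _ in range(int(prose_rng.integers(1, 3)))
        )
        for _ in range(cfg.n_parallel_prose)
    ]
    parallel_train: dict[str, list[ParallelPair]] = {}
    parallel_heldout: dict[str, list[ParallelPair]] = {}
    xnel: dict[str, list[NelExample]] = {}
    for lang, cipher in ciphers.items():
        train = [ParallelPair(p, cipher_translate(p, cipher)) for p in prose]
        held = []
        for cid in cids:
            concept = graph[cid]
            name_pairs = [
                ParallelPair(n.text, cipher_translate(n.text, cipher), cid) for n in concept.names
            ]
            if cid in held_cids:
                held.extend(name_pairs)
            else:
                train.extend(name_pairs)
                train.extend(
                    ParallelPair(d.text, cipher_translate(d.text, cipher), cid)
                    for d in concept.definitions
                )
        parallel_train[lang] = train
        parallel_heldout[lang] = held
        xnel[lang] = [
            NelExample(cipher_translate(ex.mention, cipher), ex.gold_concept_id) for ex in nel
        ]

    return Benchmarks(
        sts_train=sts_train,
        sts_test=sts_test,
        sts_general=sts_general,
        bcr=bcr,
        nel_examples=nel,
        dictionary=dictionary,
        parallel_train=parallel_train,
        parallel_heldout=parallel_heldout,
        xnel_examples=xnel,
        ciphers=ciphers,
        latent=latent,
    )


# ---- sanity encoders ------------------------------------------------------


class OracleEncoder:
    """Upper-bound encoder that reads the latent assignment of each text.

    Embeds concept identity (weight 1) and topic identity (weight 0.7) as
    indicator coordinates, normalized — so same-concept texts have cosine 1,
    same-topic about 0.33, unrelated 0.
    """

    architecture_tag = "oracle"

    def __init__(self, latent: dict[str, tuple[str, str]]):
        self.latent = latent
        topics = sorted({t for t, _ in latent.values()})
        concepts = sorted({c for _, c in latent.values()})
        self._t = {t: i for i, t in enumerate(topics)}
        self._c = {c: i for i, c in enumerate(concepts)}
        self.dimension = len(topics) + len(concepts)

    def encode(self, texts: list[str], normalize: bool = True) -> np.ndarray:
        E = np.zeros((len(texts), self.dimension))
        for i, text in enumerate(texts):
            topic, cid = self.latent[text]
            E[i, self._c[cid]] = 1.0
            E[i, len(self._c) + self._t[topic]] = 0.7
        if normalize:
            E /= np.linalg.norm(E, axis=1, keepdims=True)
        return E

    def parameters(self) -> dict[str, np.ndarray]:
        return {}


class RandomEncoder:
    """Chance-level encoder: a reproducible random unit vector per distinct text."""

    architecture_tag = "random"

    def __init__(self, dimension: int = 32, seed: int = 0):
        self.dimension = dimension
        self.seed = seed

    def encode(self, texts: list[str], normalize: bool = True) -> np.ndarray:
        E = np.empty((len(texts), self.dimension))
        for i, text in enumerate(texts):
            rng = np.random.default_rng([self.seed, murmurhash3_32(text, positive=True)])
            E[i] = rng.normal(size=self.dimension)
        if normalize:
            E /= np.linalg.norm(E, axis=1, keepdims=True)
        return E

    def parameters(self) -> dict[str, np.ndarray]:
        return {}


# ---- fixture export -------------------------------------------------------


def write_fixture_dir(graph: KnowledgeGraph, bench: Benchmarks, directory: str | Path) -> dict[str, Path]:
    """Write every fixture file in the dialect its consumer reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_graph_dir(graph, directory / "graph")
    out = {f"graph_{k}": v for k, v in paths.items()}
    io_map = {
        "sts_train": (write_sts_file, bench.sts_train, "sts_train.tsv"),
        "sts_test": (write_sts_file, bench.sts_test, "sts_test.tsv"),
        "sts_general": (write_sts_file, bench.sts_general, "sts_general.tsv"),
        "bcr": (write_bcr_file, bench.bcr, "bcr.tsv"),
        "nel": (write_nel_file, bench.nel_examples, "nel.tsv"),
        "dictionary": (write_dictionary_file, bench.dictionary, "dictionary.tsv"),
    }
    for key, (writer, data, fname) in io_map.items():
        path = directory / fname
        writer(data, path)
        out[key] = path
    for lang in bench.ciphers:
        p1 = directory / f"parallel_{lang}_train.tsv"
        p2 = directory / f"parallel_{lang}_heldout.tsv"
        write_parallel_corpus(bench.parallel_train[lang], p1, lang)
        write_parallel_corpus(bench.parallel_heldout[lang], p2, lang)
        out[f"parallel_{lang}_train"] = p1
        out[f"parallel_{lang}_heldout"] = p2
    return out
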