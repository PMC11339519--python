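"""STS / BCR / NEL metric harness against formula and enumeration oracles."""

import math

import numpy as np
import pytest

from ontolord.encoder import FunctionEncoder
from ontolord.evalsuite import (
    BcrPair,
    ConceptDictionary,
    NelExample,
    StsPair,
    eval_bcr,
    eval_nel_topk,
    eval_sts,
    filter_by_semantic_type,
    read_dictionary_file,
    read_nel_file,
    read_sts_file,
    write_dictionary_file,
    write_nel_file,
    write_sts_file,
)
from ontolord.exceptions import InputError, ParseError, UndefinedCorrelationError


def planar(angle):
    return np.array([math.cos(angle), math.sin(angle)])


def angle_encoder(table):
    return FunctionEncoder(lambda ts: np.array([table[t] for t in ts]), 2)


def test_sts_perfect_linear_relation_gives_one():
    # cosine of (s_i, anchor) proportional to gold by construction
    golds = [0.0, 1.0, 2.5, 4.0, 5.0]
    table = {"anchor": planar(0.0)}
    pairs = []
    for i, g in enumerate(golds):
        name = f"s{i}"
        table[name] = planar(math.acos(g / 5.0))
        pairs.append(StsPair(name, "anchor", g))
    assert abs(eval_sts(angle_encoder(table), pairs) - 1.0) < 1e-9


def test_sts_anticorrelation_gives_minus_one():
    golds = [1.0, 2.0, 3.0]
    table = {"anchor": planar(0.0)}
    pairs = []
    for i, g in enumerate(golds):
        table[f"s{i}"] = planar(math.acos(1.0 - g / 5.0))  # cosine = 1 - g/5
        pairs.append(StsPair(f"s{i}", "anchor", g))
    assert abs(eval_sts(angle_encoder(table), pairs) + 1.0) < 1e-9


def test_sts_matches_hand_expanded_pearson_formula():
    table = {"anchor": planar(0.0)}
    cosines = [0.9, 0.1, 0.5, 0.7, 0.2]
    golds = [4.0, 1.0, 2.0, 5.0, 0.0]
    pairs = []
    for i, c in enumerate(cosines):
        table[f"s{i}"] = planar(math.acos(c))
        pairs.append(StsPair(f"s{i}", "anchor", golds[i]))
    n = 5
    sx, sy = sum(cosines), sum(golds)
    sxx = sum(c * c for c in cosines)
    syy = sum(g * g for g in golds)
    sxy = sum(c * g for c, g in zip(cosines, golds))
    oracle = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    assert abs(eval_sts(angle_encoder(table), pairs) - oracle) < 1e-9


def test_sts_invariant_to_affine_positive_rescaling_of_scores():
    rng = np.random.default_rng(2)
    table = {"anchor": planar(0.0)}
    pairs, pairs_scaled = [], []
    for i in range(8):
        c = rng.uniform(-0.9, 0.9)
        table[f"s{i}"] = planar(math.acos(c))
        g = float(rng.uniform(0, 5))
        pairs.append(StsPair(f"s{i}", "anchor", g))
        pairs_scaled.append(StsPair(f"s{i}", "anchor", g * 0.6 + 1.0))
    enc = angle_encoder(table)
    assert abs(eval_sts(enc, pairs) - eval_sts(enc, pairs_scaled)) < 1e-9


def test_sts_zero_variance_raises():
    table = {"a": planar(0.0), "b": planar(0.5)}
    pairs = [StsPair("a", "b", 3.0), StsPair("a", "b", 3.0)]
    with pytest.raises(UndefinedCorrelationError):
        eval_sts(angle_encoder(table), pairs)


def test_bcr_identical_and_reversed_rankings():
    table = {"anchor": planar(0.0)}
    pairs = []
    cosines = [0.1, 0.4, 0.8]
    for i, c in enumerate(cosines):
        table[f"t{i}"] = planar(math.acos(c))
        pairs.append(BcrPair(f"t{i}", "anchor", float(i)))
    enc = angle_encoder(table)
    assert abs(eval_bcr(enc, pairs) - 1.0) < 1e-9
    reversed_pairs = [BcrPair(p.term1, p.term2, -p.gold) for p in pairs]
    assert abs(eval_bcr(enc, reversed_pairs) + 1.0) < 1e-9


def test_bcr_with_tie_matches_rank_then_pearson_oracle():
    from scipy import stats

    table = {"anchor": planar(0.0)}
    cosines = [0.9, 0.7, 0.5, 0.3, 0.2, 0.1]
    golds = [4.0, 4.0, 3.0, 2.0, 1.5, 0.0]  # one tie -> average ranks
    pairs = []
    for i, c in enumerate(cosines):
        table[f"t{i}"] = planar(math.acos(c))
        pairs.append(BcrPair(f"t{i}", "anchor", golds[i]))
    ranks_x = stats.rankdata(cosines)
    ranks_y = stats.rankdata(golds)
    oracle = stats.pearsonr(ranks_x, ranks_y).statistic
    assert abs(eval_bcr(angle_encoder(table), pairs) - oracle) < 1e-9


def test_bcr_invariant_under_strictly_monotone_gold_transform():
    table = {"anchor": planar(0.0)}
    pairs, transformed = [], []
    cosines = [0.8, 0.3, 0.6, 0.1]
    golds = [3.0, 1.0, 2.0, 0.5]
    for i, c in enumerate(cosines):
        table[f"t{i}"] = planar(math.acos(c))
        pairs.append(BcrPair(f"t{i}", "anchor", golds[i]))
        transformed.append(BcrPair(f"t{i}", "anchor", math.exp(golds[i])))
    enc = angle_encoder(table)
    assert abs(eval_bcr(enc, pairs) - eval_bcr(enc, transformed)) < 1e-9


@pytest.fixture
def toy_nel():
    e = np.eye(4)
    table = {
        "m0": e[0], "m1": e[1] * 0.9 + e[2] * 0.436, "m2": e[3],
        "nameA1": e[0], "nameA2": e[1], "nameB": e[2], "nameC": e[3],
    }
    dictionary = ConceptDictionary([
        ("A", "nameA1", "T1"),
        ("A", "nameA2", "T1"),
        ("B", "nameB", "T2"),
        ("C", "nameC", "T3"),
    ])
    examples = [NelExample("m0", "A"), NelExample("m1", "B"), NelExample("m2", "C")]
    return angle_table(table), examples, dictionary


def angle_table(table):
    dim = len(next(iter(table.values())))
    return FunctionEncoder(lambda ts: np.array([table[t] for t in ts], dtype=float), dim)


def test_nel_matches_exhaustive_ranking_oracle(toy_nel):
    enc, examples, dictionary = toy_nel
    # oracle by hand: m0 -> A (hit), m1 best name is nameA2 (concept A) so
    # top-1 misses gold B but top-2 contains it, m2 -> C (hit)
    assert eval_nel_topk(enc, examples, dictionary, k=1) == pytest.approx(2 / 3)
    assert eval_nel_topk(enc, examples, dictionary, k=2) == pytest.approx(1.0)


def test_nel_topk_monotone_in_k(toy_nel):
    enc, examples, dictionary = toy_nel
    accs = [eval_nel_topk(enc, examples, dictionary, k) for k in range(1, 5)]
    assert all(b >= a for a, b in zip(accs, accs[1:]))
    assert accs[-1] == 1.0  # k >= number of concepts is exhaustive


def test_nel_exact_string_match_is_top1_hit(teacher, bench):
    example = [NelExample(bench.dictionary.names[0], bench.dictionary.concept_ids[0])]
    assert eval_nel_topk(teacher, example, bench.dictionary, k=1) == 1.0


def test_nel_scores_concept_by_its_best_name():
    e = np.eye(2)
    table = {"m": e[0], "good": e[0], "bad": e[1], "other": e[1] * 0.9 + e[0] * 0.436}
    dictionary = ConceptDictionary([("X", "bad", "T"), ("X", "good", "T"), ("Y", "other", "T")])
    enc = angle_table(table)
    assert eval_nel_topk(enc, [NelExample("m", "X")], dictionary, k=1) == 1.0


def test_nel_tie_breaks_by_dictionary_order():
    e = np.eye(2)
    table = {"m": e[0], "tie1": e[0], "tie2": e[0]}
    d1 = ConceptDictionary([("P", "tie1", "T"), ("Q", "tie2", "T")])
    d2 = ConceptDictionary([("Q", "tie2", "T"), ("P", "tie1", "T")])
    enc = angle_table(table)
    assert eval_nel_topk(enc, [NelExample("m", "P")], d1, k=1) == 1.0
    assert eval_nel_topk(enc, [NelExample("m", "P")], d2, k=1) == 0.0


def test_nel_input_validation(toy_nel):
    enc, examples, dictionary = toy_nel
    with pytest.raises(InputError):
        eval_nel_topk(enc, examples, ConceptDictionary([]), k=1)
    with pytest.raises(InputError):
        eval_nel_topk(enc, examples, dictionary, k=0)


def test_semantic_type_filter_counts():
    dictionary = ConceptDictionary([(f"C{i}", f"n{i}", "TX" if i < 2 else "TY")
                                    for i in range(5)])
    examples = [NelExample(f"m{i}", f"C{i}") for i in range(5)]
    same, report = filter_by_semantic_type(examples, dictionary, set())
    assert same == examples and report["n_excluded"] == 0
    none_left, _ = filter_by_semantic_type(examples, dictionary, {"TX", "TY"})
    assert none_left == []
    kept, report = filter_by_semantic_type(examples, dictionary, {"TX"})
    assert len(kept) == 3 and report["n_excluded"] == 2


def test_benchmark_file_roundtrips_and_errors(tmp_path):
    sts = [StsPair("a b", "c d", 3.5)]
    write_sts_file(sts, tmp_path / "sts.tsv")
    assert read_sts_file(tmp_path / "sts.tsv") == sts

    nel = [NelExample("mention text", "C1")]
    write_nel_file(nel, tmp_path / "nel.tsv")
    assert read_nel_file(tmp_path / "nel.tsv") == nel

    d = ConceptDictionary([("C1", "name", "T1")])
    write_dictionary_file(d, tmp_path / "dict.tsv")
    assert read_dictionary_file(tmp_path / "dict.tsv").entries == d.entries

    (tmp_path / "bad.tsv").write_text("only two\tfields\n", encoding="utf-8")
    with pytest.raises(ParseError) as exc:
        read_sts_file(tmp_path / "bad.tsv")
    assert exc.value.line == 1
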