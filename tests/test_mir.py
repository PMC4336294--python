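"""Maximally informative relations, provenance classes, sufficiency, questions."""

import pytest

from taxalign import (
    BaseRelation,
    RelationSet,
    algebraic_closure,
    compute_mir,
    enumerate_worlds,
    mir_table,
    next_question,
    perelleschus,
    sufficient_subset,
)
from taxalign.mir import _closure_network

EQ, PI, IPI, OV, DJ = (
    BaseRelation.EQ,
    BaseRelation.PI,
    BaseRelation.IPI,
    BaseRelation.OV,
    BaseRelation.DJ,
)


def _entry(entries, left, right):
    for e in entries:
        if e.left.qualified_id == left and e.right.qualified_id == right:
            return e
    raise AssertionError(f"no MIR entry for ({left}, {right})")


@pytest.mark.parametrize(
    "alignment,reading,count",
    [(1, "OST", 8), (1, "INT_OST", 12), (2, "OST_ORIGINAL", 16)],
)
def test_mir_covers_all_ordered_cross_pairs(alignment, reading, count):
    problem = perelleschus(alignment, reading)
    entries = mir_table(problem)
    assert len(entries) == count
    assert len(entries) == len(problem.t1.concepts) * len(problem.t2.concepts)


def test_alignment1_ost_mir_is_fully_resolved_with_4_deduced_4_inferred(alignment1_ost):
    entries = mir_table(alignment1_ost)
    assert all(e.resolved for e in entries)
    deduced = [e for e in entries if e.is_deduced]
    inferred = [e for e in entries if not e.is_deduced]
    assert len(deduced) == 4 and len(inferred) == 4
    # the three species-level inputs plus the deduced genus-species inclusion
    assert {(e.left.qualified_id, e.right.qualified_id) for e in deduced} == {
        ("1954.Pcarlud", "1936.ELLcarlud"),
        ("1954.Prectir", "1936.ELLcarlud"),
        ("1954.Psubcin", "1936.ELLcarlud"),
        ("1954.PER", "1936.ELLcarlud"),
    }
    # the genus-level relation is inferred, not deduced
    genus = _entry(entries, "1954.PER", "1936.ELL")
    assert genus.provenance == "inferred"
    assert genus.realized == RelationSet.of(PI)


def test_provenance_partitions_entries_and_inputs_are_deduced(alignment1_int_ost):
    entries = mir_table(alignment1_int_ost)
    assert all(e.provenance in ("input", "deduced", "inferred") for e in entries)
    inputs = {
        (a.left.qualified_id, a.right.qualified_id)
        for a in alignment1_int_ost.articulations
        if a.relation.is_singleton
    }
    for e in entries:
        pair = (e.left.qualified_id, e.right.qualified_id)
        if pair in inputs:
            assert e.provenance == "input" and e.is_deduced


def test_realized_sets_are_within_the_closure_bound(alignment1_int_ost):
    closure = algebraic_closure(_closure_network(alignment1_int_ost))
    for e in mir_table(alignment1_int_ost):
        pair = (e.left.qualified_id, e.right.qualified_id)
        assert e.realized.issubset(closure[pair])


def test_underspecified_input_leaves_disjunctive_entries():
    problem = perelleschus(1, "underspec_L1")
    entries = mir_table(problem)
    unresolved = [e for e in entries if not e.resolved]
    assert unresolved, "8 worlds must leave some pair ambiguous"
    assert all(e.provenance == "inferred" for e in unresolved)


def test_mir_requires_a_consistent_problem(alignment1_ost):
    with pytest.raises(ValueError):
        compute_mir(alignment1_ost, [])


# ---------------------------------------------------------------------------
# Sufficiency
# ---------------------------------------------------------------------------

def test_sufficient_subset_drops_the_redundant_genus_articulation():
    problem = perelleschus(1, "OST_ORIGINAL")  # includes the disjunctive genus articulation
    target = [w.sort_key for w in enumerate_worlds(problem)]
    kept = sufficient_subset(problem)
    # the overspecified genus-level disjunction is always eliminated
    assert all(a.left.label != "PER" for a in kept)
    restricted = problem.with_articulations(kept)
    assert [w.sort_key for w in enumerate_worlds(restricted)] == target
    # minimal under deletion: dropping any retained articulation changes the worlds
    for i in range(len(kept)):
        smaller = problem.with_articulations(kept[:i] + kept[i + 1 :])
        assert [w.sort_key for w in enumerate_worlds(smaller)] != target


def test_sufficient_subset_removes_a_duplicated_articulation(alignment1_int_ost):
    problem = alignment1_int_ost.with_articulations(
        alignment1_int_ost.articulations + [alignment1_int_ost.articulations[0]]
    )
    kept = sufficient_subset(problem)
    key = lambda a: (a.left.qualified_id, a.relation.mask, a.right.qualified_id)
    assert sorted(map(key, kept)) == sorted(set(map(key, kept)))


def test_single_load_bearing_articulation_is_retained():
    problem = perelleschus(1, "INT")
    kept = sufficient_subset(problem)
    # the intensional genus articulation changes the world set, so it stays
    assert any(a.relation == RelationSet.of(IPI) for a in kept)


# ---------------------------------------------------------------------------
# Decision-tree questions
# ---------------------------------------------------------------------------

def test_no_question_when_a_single_world_remains(alignment1_ost):
    assert next_question(enumerate_worlds(alignment1_ost)) is None


def test_question_targets_the_floating_implied_child():
    worlds = enumerate_worlds(perelleschus(1, "underspec_L1"))
    assert len(worlds) == 8
    (left, right), realized = next_question(worlds)
    # the ambiguity created by the unconstrained implied child: the chosen pair
    # has the largest realized set, of the {<, ><, |} scale
    assert right in ("1936.ELL", "1936.ELL_IC")
    assert realized == RelationSet.of(IPI, OV, DJ)
    sizes = set()
    for pair in worlds[0].cross_pairs():
        mask = 0
        for w in worlds:
            mask |= w.relation(*pair).value
        sizes.add(bin(mask).count("1"))
    assert len(realized) == max(sizes)


def test_answering_the_question_partitions_the_world_set():
    problem = perelleschus(1, "underspec_L1")
    worlds = enumerate_worlds(problem)
    (left, right), realized = next_question(worlds)
    total = 0
    seen = set()
    from conftest import cross_articulation

    for rel in realized:
        answered = problem.with_articulations(
            problem.articulations
            + [cross_articulation(problem.t2, problem.t1, left.split(".", 1)[1], rel, right.split(".", 1)[1])]
        )
        sub = enumerate_worlds(answered)
        keys = {w.sort_key for w in sub}
        assert not keys & seen  # no world duplicated
        seen |= keys
        total += len(sub)
    assert total == len(worlds)  # no world lost
    assert seen == {w.sort_key for w in worlds}


def test_two_worlds_differing_in_one_pair_yield_that_pair():
    from conftest import single_concept_pair

    problem = single_concept_pair([(EQ, PI)])  # ambiguous: congruent or wider
    worlds = enumerate_worlds(problem)
    assert len(worlds) == 2
    q = next_question(worlds)
    assert q is not None
    (left, right), realized = q
    assert (left, right) == ("tb.B", "ta.A")
    assert realized == RelationSet.of(EQ, PI)
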