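"""Algebra of the five RCC-5 relations and the 32-element articulation lattice."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxalign.rcc5 import (
    BASE_ORDER,
    COMPOSITION,
    InconsistentNetworkError,
    RelationSet,
    ZonePattern,
    algebraic_closure,
    compose,
    compose_sets,
    composition_table_from_set_models,
    converse,
    relation_from_zones,
)

EQ, PI, IPI, OV, DJ = BASE_ORDER


def test_lattice_has_exactly_32_distinct_values():
    values = RelationSet.all_values()
    assert len(values) == 32
    assert len(set(values)) == 32
    assert RelationSet.empty() in values and RelationSet.full() in values


def test_base_relation_converse_pairs():
    assert EQ.converse is EQ
    assert PI.converse is IPI and IPI.converse is PI
    assert OV.converse is OV and DJ.converse is DJ


@pytest.mark.parametrize(
    "given_set,expected",
    [
        (RelationSet.of(EQ), RelationSet.of(EQ)),
        (RelationSet.of(PI, OV), RelationSet.of(IPI, OV)),
        (RelationSet.empty(), RelationSet.empty()),
    ],
)
def test_converse_examples(given_set, expected):
    assert converse(given_set) == expected


def test_converse_is_involutive_on_all_32_values():
    for r in RelationSet.all_values():
        assert converse(converse(r)) == r


def test_composition_table_matches_set_model_oracle():
    """The frozen table equals brute-force enumeration over all triples of
    non-empty subsets of a 4-point universe, for every one of the 25 cases."""
    oracle = composition_table_from_set_models()
    for r1, r2 in itertools.product(BASE_ORDER, repeat=2):
        assert COMPOSITION[(r1, r2)] == oracle[(r1, r2)], (r1, r2)


@pytest.mark.parametrize(
    "r1,r2,expected",
    [
        (EQ, PI, RelationSet.of(PI)),
        (PI, PI, RelationSet.of(PI)),
        (PI, DJ, RelationSet.of(PI, OV, DJ)),
        (OV, OV, RelationSet.full()),
    ],
)
def test_compose_examples(r1, r2, expected):
    assert compose(r1, r2) == expected


def test_compose_respects_converse_duality():
    # converse(r1 ∘ r2) == converse(r2) ∘ converse(r1)
    for r1, r2 in itertools.product(BASE_ORDER, repeat=2):
        assert converse(compose(r1, r2)) == compose_sets(
            RelationSet.of(r2.converse), RelationSet.of(r1.converse)
        )


@pytest.mark.parametrize(
    "zones,expected",
    [
        ((False, True, False), EQ),
        ((True, True, False), PI),
        ((False, True, True), IPI),
        ((True, True, True), OV),
        ((True, False, True), DJ),
    ],
)
def test_relation_from_zones_mapping(zones, expected):
    assert relation_from_zones(zones) is expected
    assert relation_from_zones(ZonePattern(*zones)) is expected


@pytest.mark.parametrize("zones", [(False, False, False), (True, False, False), (False, False, True)])
def test_relation_from_zones_rejects_empty_concepts(zones):
    with pytest.raises(ValueError):
        relation_from_zones(zones)


@given(mask=st.integers(min_value=0, max_value=31))
@settings(derandomize=True)
def test_relation_set_roundtrips_through_members(mask):
    rset = RelationSet(mask)
    assert RelationSet.from_iterable(list(rset)) == rset
    assert len(rset) == bin(mask).count("1")


# ---------------------------------------------------------------------------
# Algebraic closure
# ---------------------------------------------------------------------------

def test_closure_substitution():
    network = {("A", "B"): RelationSet.of(EQ), ("B", "C"): RelationSet.of(PI)}
    closed = algebraic_closure(network)
    assert closed[("A", "C")] == RelationSet.of(PI)


def test_closure_detects_reciprocal_inclusion():
    network = {("A", "B"): RelationSet.of(PI), ("B", "A"): RelationSet.of(PI)}
    with pytest.raises(InconsistentNetworkError):
        algebraic_closure(network)


def test_closure_fixpoint_on_atomic_consistent_network():
    # A > B > C with all pairwise relations spelled out: already path-consistent
    network = {
        ("A", "B"): RelationSet.of(PI),
        ("B", "C"): RelationSet.of(PI),
        ("A", "C"): RelationSet.of(PI),
    }
    closed = algebraic_closure(network)
    for pair, rset in network.items():
        assert closed[pair] == rset


def _random_set_network(rng: random.Random, n_nodes: int):
    """A consistent network derived from real set extensions, with the true
    atomic relations recorded."""
    points = range(6)
    ext = {}
    for i in range(n_nodes):
        ext[f"N{i}"] = frozenset(p for p in points if rng.random() < 0.5) or frozenset({0})
    truth = {}
    for a, b in itertools.combinations(sorted(ext), 2):
        A, B = ext[a], ext[b]
        if A == B:
            truth[(a, b)] = EQ
        elif A > B:
            truth[(a, b)] = PI
        elif A < B:
            truth[(a, b)] = IPI
        elif A & B:
            truth[(a, b)] = OV
        else:
            truth[(a, b)] = DJ
    # loosen some pairs to disjunctions containing the truth
    network = {}
    for pair, rel in truth.items():
        mask = rel.value
        for r in BASE_ORDER:
            if rng.random() < 0.3:
                mask |= r.value
        network[pair] = RelationSet(mask)
    return network, truth


def test_closure_is_monotone_idempotent_and_sound():
    rng = random.Random(20260930)
    for _ in range(25):
        network, truth = _random_set_network(rng, rng.randint(3, 5))
        closed = algebraic_closure(network)
        # monotone: never adds relations
        for pair, rset in network.items():
            assert closed[pair].issubset(rset)
        # sound: the true atomic relation survives
        for pair, rel in truth.items():
            assert rel in closed[pair]
        # idempotent
        assert algebraic_closure(closed) == closed
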