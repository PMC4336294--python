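"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import re

import pytest

from taxalign import (
    AlignmentProblem,
    Articulation,
    BaseRelation,
    RelationSet,
    Taxonomy,
    perelleschus,
)

ALIGNMENT_1_READINGS = ("OST", "OST_ORIGINAL", "INT", "INT_OST", "underspec_L1", "underspec_L2")


@pytest.fixture
def alignment1_ost() -> AlignmentProblem:
    return perelleschus(1, "OST")


@pytest.fixture
def alignment1_int_ost() -> AlignmentProblem:
    return perelleschus(1, "INT_OST")


@pytest.fixture
def alignment2() -> AlignmentProblem:
    return perelleschus(2, "OST_ORIGINAL")


def cross_articulation(
    t2: Taxonomy, t1: Taxonomy, left: str, relation, right: str
) -> Articulation:
    """Articulation with T2 concept first, accepting a relation or a tuple."""
    rset = (
        RelationSet.of(*relation)
        if isinstance(relation, (tuple, list))
        else RelationSet.of(relation)
    )
    return Articulation(left=t2.concept(left), right=t1.concept(right), relation=rset)


def single_concept_pair(rel_specs) -> AlignmentProblem:
    """Two one-concept taxonomies A (t1) and B (t2) with the given relations
    asserted from B to A."""
    t1 = Taxonomy("ta", "taxonomy A", extra_concepts=["A"])
    t2 = Taxonomy("tb", "taxonomy B", extra_concepts=["B"])
    arts = [cross_articulation(t2, t1, "B", spec, "A") for spec in rel_specs]
    return AlignmentProblem(t1, t2, arts)


def genus_overlap_conflict() -> AlignmentProblem:
    """The alignment-3 inconsistency pattern: an outgroup genus whose only
    child is congruent to a species inside the other genus, yet the genera are
    asserted to overlap."""
    t1 = Taxonomy("1986", "Wibmer & O'Brien 1986", edges={"PER": ["Pcarlud", "Prectir", "Psubcin"]})
    t2 = Taxonomy(
        "2001",
        "Franz & O'Brien 2001",
        edges={"DER": ["PER", "PHY"], "PER": ["Pcarlud", "Prectir"], "PHY": ["PHYsubcin"]},
    )
    EQ, OV = BaseRelation.EQ, BaseRelation.OV
    arts = [
        cross_articulation(t2, t1, "Pcarlud", EQ, "Pcarlud"),
        cross_articulation(t2, t1, "Prectir", EQ, "Prectir"),
        cross_articulation(t2, t1, "PHYsubcin", EQ, "Psubcin"),
        cross_articulation(t2, t1, "PHY", OV, "PER"),
    ]
    return AlignmentProblem(t1, t2, arts)


def problems_equivalent(p1: AlignmentProblem, p2: AlignmentProblem) -> bool:
    """Structural equivalence up to articulation ordering."""

    def tax_key(t: Taxonomy):
        return (
            t.taxonomy_id,
            t.display_name,
            {p: tuple(cs) for p, cs in t.edges.items()},
            frozenset(t.coverage_off),
            frozenset(t.labels),
        )

    def art_key(a: Articulation):
        return (a.left.qualified_id, a.relation.mask, a.right.qualified_id, a.reading_tag)

    return (
        tax_key(p1.t1) == tax_key(p2.t1)
        and tax_key(p1.t2) == tax_key(p2.t2)
        and sorted(map(art_key, p1.articulations)) == sorted(map(art_key, p2.articulations))
        and p1.toggles == p2.toggles
    )


_DOT_NODE = re.compile(r'^\s*\w+ \[label=".*", shape=\w+, fillcolor=\w+\];$')
_DOT_EDGE = re.compile(r"^\s*\w+ -> \w+( \[[\w=, ]+\])?;$")


def assert_valid_dot(text: str) -> None:
    """Structural DOT well-formedness: header, balanced braces, statement shapes."""
    lines = text.strip().splitlines()
    assert lines[0].startswith("digraph ") and lines[0].endswith("{")
    assert lines[-1] == "}"
    assert text.count("{") == text.count("}")
    for line in lines[1:-1]:
        stripped = line.strip()
        if stripped == "node [style=filled];":
            continue
        assert _DOT_NODE.match(line) or _DOT_EDGE.match(line), f"bad DOT line: {line!r}"
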