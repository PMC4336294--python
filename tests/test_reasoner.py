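"""Possible-world solver: candidate regions, consistency, enumeration, oracle."""

import pytest

from taxalign import (
    AlignmentProblem,
    BaseRelation,
    ConstraintToggles,
    candidate_regions,
    check_world,
    enumerate_worlds,
    is_consistent,
    oracle_worlds,
    perelleschus,
    random_problem,
)
from taxalign.fixtures import GeneratorConfig
from taxalign.reasoner import OracleTooLargeError
from conftest import ALIGNMENT_1_READINGS, cross_articulation, single_concept_pair

EQ, PI, IPI, OV, DJ = (
    BaseRelation.EQ,
    BaseRelation.PI,
    BaseRelation.IPI,
    BaseRelation.OV,
    BaseRelation.DJ,
)


# ---------------------------------------------------------------------------
# Candidate regions
# ---------------------------------------------------------------------------

def test_single_concept_pair_has_three_regions():
    problem = single_concept_pair([])
    regions = candidate_regions(problem)
    memberships = {r.membership for r in regions}
    assert memberships == {
        frozenset({"ta.A"}),
        frozenset({"tb.B"}),
        frozenset({"ta.A", "tb.B"}),
    }


def _check_region_invariants(problem: AlignmentProblem) -> None:
    for region in candidate_regions(problem):
        for t in (problem.t1, problem.t2):
            members = {
                q.split(".", 1)[1] for q in region.membership if q.startswith(t.taxonomy_id + ".")
            }
            for lab in members:
                parent = t.parent.get(lab)
                assert parent is None or parent in members, "not upward closed"
                if problem.toggles.sibling_disjointness and parent is not None:
                    siblings = set(t.children(parent)) & members
                    assert siblings == {lab}, "sibling co-occurrence"
                if t.covered(lab, problem.toggles.coverage_default):
                    assert set(t.children(lab)) & members, "covered parent without child"


def test_region_invariants_and_chain_bound(alignment1_ost):
    _check_region_invariants(alignment1_ost)
    regions = candidate_regions(alignment1_ost)
    # one root-to-terminal path in the 1936 tree, three in the 1954 tree
    assert len(regions) <= (1 + 1) * (3 + 1) - 1
    # restricted to one taxonomy every pattern is a root chain or empty
    for region in regions:
        for t in (alignment1_ost.t1, alignment1_ost.t2):
            members = {
                q.split(".", 1)[1] for q in region.membership if q.startswith(t.taxonomy_id + ".")
            }
            if members:
                deepest = max(members, key=lambda lab: len(t.ancestors(lab)))
                assert members == {deepest, *t.ancestors(deepest)}


def test_relaxing_sibling_disjointness_adds_patterns(alignment1_ost):
    relaxed = AlignmentProblem(
        alignment1_ost.t1,
        alignment1_ost.t2,
        alignment1_ost.articulations,
        ConstraintToggles(sibling_disjointness=False),
    )
    assert len(candidate_regions(relaxed)) > len(candidate_regions(alignment1_ost))
    _check_region_invariants(relaxed)


# ---------------------------------------------------------------------------
# Consistency
# ---------------------------------------------------------------------------

def test_alignment1_ost_is_consistent(alignment1_ost):
    ok, witness = is_consistent(alignment1_ost)
    assert ok and witness is not None
    assert witness.relation("1954.PER", "1936.ELL") is PI


def test_genus_overlap_without_implied_child_is_inconsistent(alignment1_ost):
    alignment1_ost.articulations.append(
        cross_articulation(alignment1_ost.t2, alignment1_ost.t1, "PER", OV, "ELL")
    )
    assert not is_consistent(alignment1_ost)


def test_reciprocal_inclusion_is_inconsistent():
    problem = single_concept_pair([PI, IPI])
    assert not is_consistent(problem)
    assert oracle_worlds(problem) == []


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "reading,count",
    [("OST", 1), ("OST_ORIGINAL", 1), ("INT", 1), ("INT_OST", 1), ("underspec_L1", 8), ("underspec_L2", 17)],
)
def test_world_counts_across_the_underspecification_ladder(reading, count):
    ws = enumerate_worlds(perelleschus(1, reading))
    assert len(ws) == count
    assert not ws.truncated


def test_enumeration_is_deterministic_and_lexicographic():
    ws = enumerate_worlds(perelleschus(1, "underspec_L2"))
    keys = [w.sort_key for w in ws]
    assert keys == sorted(keys)
    assert len(set(keys)) == len(keys)
    again = enumerate_worlds(perelleschus(1, "underspec_L2"))
    assert [w.sort_key for w in again] == keys


def test_world_cap_sets_truncation_flag():
    ws = enumerate_worlds(perelleschus(1, "underspec_L2"), cap=5)
    assert len(ws) == 5 and ws.truncated
    full = enumerate_worlds(perelleschus(1, "underspec_L2"), cap=17)
    assert len(full) == 17 and not full.truncated


def test_removing_an_articulation_never_removes_worlds():
    problem = perelleschus(1, "INT_OST")
    ws_full = enumerate_worlds(problem)
    keys_full = {w.sort_key for w in ws_full}
    for i in range(len(problem.articulations)):
        ws = enumerate_worlds(problem.without_articulations([i]))
        assert keys_full <= {w.sort_key for w in ws}


def _world_satisfies_problem(problem, world) -> None:
    """Zone check of every articulation and region invariants of the witness."""
    for art in problem.articulations:
        l, r = art.left.qualified_id, art.right.qualified_id
        lo = any(l in g and r not in g for g in world.occupied_regions)
        sh = any(l in g and r in g for g in world.occupied_regions)
        ro = any(r in g and l not in g for g in world.occupied_regions)
        from taxalign import relation_from_zones

        assert relation_from_zones((lo, sh, ro)) in art.relation
        assert world.relation(l, r) in art.relation
    allowed = {r.membership for r in candidate_regions(problem)}
    for g in world.occupied_regions:
        assert g.membership in allowed
    for c in world.concepts:  # non-emptiness
        assert any(c in g for g in world.occupied_regions)


def test_every_enumerated_world_is_sound():
    for reading in ALIGNMENT_1_READINGS:
        problem = perelleschus(1, reading)
        for world in enumerate_worlds(problem):
            _world_satisfies_problem(problem, world)


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def test_solver_matches_oracle_on_fixtures():
    fixtures = [perelleschus(1, r) for r in ALIGNMENT_1_READINGS]
    fixtures += [perelleschus(2, "OST"), perelleschus(2, "OST_ORIGINAL")]
    for problem in fixtures:
        solver = [w.sort_key for w in enumerate_worlds(problem)]
        oracle = [w.sort_key for w in oracle_worlds(problem)]
        assert solver == oracle


def test_solver_matches_oracle_on_seeded_random_problems():
    for seed in range(30):
        problem, planted = random_problem(
            GeneratorConfig(n1=4, n2=4, articulation_density=0.8, seed=seed)
        )
        solver = enumerate_worlds(problem)
        assert [w.sort_key for w in solver] == [w.sort_key for w in oracle_worlds(problem)]
        assert planted in solver.worlds
        assert check_world(problem, planted)


def test_oracle_refuses_oversized_instances():
    problem, _ = random_problem(GeneratorConfig(n1=12, n2=12, seed=1))
    with pytest.raises(OracleTooLargeError):
        oracle_worlds(problem)


def test_reasoning_requires_non_emptiness():
    problem = single_concept_pair([EQ])
    problem.toggles = ConstraintToggles(non_emptiness=False)
    with pytest.raises(ValueError):
        enumerate_worlds(problem)
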