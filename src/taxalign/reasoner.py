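"""Consistency and possible-world enumeration for alignment problems.

Semantics.  A *possible world* is a consistent assignment of one RCC-5 base
relation to every concept pair (within and across the two taxonomies) that is
realizable by finite non-empty extensions respecting the taxonomies and the
active constraints.  Realizability is decided over *candidate regions*: a
region is a set of concepts that may jointly contain a point.  Within one
taxonomy a region restricted to that taxonomy is upward closed (a point in a
child is in every ancestor), avoids sibling co-occurrence when sibling
disjointness is on, and extends through every covered parent into at least one
child (coverage: a parent is the union of its children).  A world is witnessed
by a set of occupied regions; the relation of a pair is read off the emptiness
pattern of its three Euler zones, and the occupancy of a zone is the existence
of an occupied region inside it.

Solver.  :func:`enumerate_worlds` searches over atomic relation assignments
pair by pair, propagating with the RCC-5 composition table, and accepts a full
assignment iff it is region-realizable.  Realizability is exact, not
heuristic: given an atomic assignment, the set of candidate regions not
forbidden by any required-empty zone is the canonical maximal witness, and the
assignment is a world iff that witness occupies every required zone.
:func:`oracle_worlds` is an independent brute-force check that enumerates
every subset of candidate regions directly; both must return identical world
sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

from .model import AlignmentProblem, Taxonomy, validate
from .rcc5 import (
    BASE_ORDER,
    BaseRelation,
    CONVERSE_MASK,
    COMPOSITION_MASK_TABLE,
    FULL_MASK,
    relation_from_zones,
)

__all__ = [
    "Region",
    "PossibleWorld",
    "WorldSet",
    "ConsistencyResult",
    "candidate_regions",
    "is_consistent",
    "enumerate_worlds",
    "oracle_worlds",
    "check_world",
    "OracleTooLargeError",
    "DEFAULT_WORLD_CAP",
    "ORACLE_REGION_LIMIT",
]

DEFAULT_WORLD_CAP = 1000
ORACLE_REGION_LIMIT = 22

_BASE_LIST = list(BASE_ORDER)
_BASE_INDEX = {r: i for i, r in enumerate(_BASE_LIST)}

# For a region occupying zone-class z of pair (a, b), the base relations that
# permit the zone to be inhabited:  both -> not DJ; a-only -> {PI, OV, DJ};
# b-only -> {IPI, OV, DJ}.
_ALLOW_BOTH = FULL_MASK & ~BaseRelation.DJ.value
_ALLOW_LEFT = BaseRelation.PI.value | BaseRelation.OV.value | BaseRelation.DJ.value
_ALLOW_RIGHT = BaseRelation.IPI.value | BaseRelation.OV.value | BaseRelation.DJ.value

# Required zone occupancy (left-only, shared, right-only) per base relation.
_REL_ZONES = {
    BaseRelation.EQ: (False, True, False),
    BaseRelation.PI: (True, True, False),
    BaseRelation.IPI: (False, True, True),
    BaseRelation.OV: (True, True, True),
    BaseRelation.DJ: (True, False, True),
}


class OracleTooLargeError(ValueError):
    """The brute-force oracle refuses instances above its region limit."""


@dataclass(frozen=True)
class Region:
    """A set of concepts (by qualified id) whose extensions share a point."""

    membership: frozenset[str]

    def __contains__(self, qualified_id: str) -> bool:
        return qualified_id in self.membership

    def __repr__(self) -> str:
        return "Region{" + " ".join(sorted(self.membership)) + "}"

    def __lt__(self, other: "Region") -> bool:
        return sorted(self.membership) < sorted(other.membership)


class PossibleWorld:
    """One consistent alignment: a base relation for every concept pair.

    World identity (equality, hashing, ordering) is the pairwise relation
    mapping, not the witnessing region set: worlds differing only in which
    regions witness the same relations are the same alignment.
    """

    __slots__ = ("concepts", "taxonomy_ids", "_rel", "_key", "occupied_regions")

    def __init__(
        self,
        concepts: Sequence[str],
        taxonomy_ids: tuple[str, str],
        relations: Mapping[tuple[str, str], BaseRelation],
        occupied_regions: tuple[Region, ...] = (),
    ):
        self.concepts = tuple(sorted(concepts))
        self.taxonomy_ids = taxonomy_ids
        rel: dict[tuple[str, str], BaseRelation] = {}
        for (a, b), r in relations.items():
            rel[(a, b)] = r
            rel[(b, a)] = r.converse
        self._rel = rel
        self.occupied_regions = occupied_regions
        pairs = [
            (a, b)
            for ia, a in enumerate(self.concepts)
            for b in self.concepts[ia + 1 :]
        ]
        self._key = tuple(_BASE_INDEX[self._rel[p]] for p in pairs)

    def relation(self, a: str, b: str) -> BaseRelation:
        if a == b:
            return BaseRelation.EQ
        return self._rel[(a, b)]

    @property
    def relations(self) -> dict[tuple[str, str], BaseRelation]:
        return dict(self._rel)

    def cross_pairs(self) -> list[tuple[str, str]]:
        """Ordered cross-taxonomy pairs, T2 concept first (listing convention)."""
        t1, t2 = self.taxonomy_ids
        lefts = sorted(c for c in self.concepts if c.split(".", 1)[0] == t2)
        rights = sorted(c for c in self.concepts if c.split(".", 1)[0] == t1)
        return [(l, r) for l in lefts for r in rights]

    @property
    def sort_key(self) -> tuple[int, ...]:
        return self._key

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PossibleWorld)
            and self.concepts == other.concepts
            and self._key == other._key
        )

    def __hash__(self) -> int:
        return hash((self.concepts, self._key))

    def __lt__(self, other: "PossibleWorld") -> bool:
        return self._key < other._key

    def __repr__(self) -> str:
        return f"PossibleWorld({len(self.concepts)} concepts, key={self._key})"


@dataclass
class WorldSet:
    """Enumeration result: distinct worlds in deterministic lexicographic
    order, with an overflow flag when the cap was hit before exhaustion."""

    worlds: list[PossibleWorld]
    truncated: bool = False

    def __iter__(self) -> Iterator[PossibleWorld]:
        return iter(self.worlds)

    def __len__(self) -> int:
        return len(self.worlds)

    def __getitem__(self, i):
        return self.worlds[i]

    def __bool__(self) -> bool:
        return bool(self.worlds)


@dataclass
class ConsistencyResult:
    consistent: bool
    witness: Optional[PossibleWorld] = None

    def __bool__(self) -> bool:
        return self.consistent

    def __iter__(self):  # allow ``ok, world = is_consistent(p)``
        yield self.consistent
        yield self.witness


# ---------------------------------------------------------------------------
# Candidate regions
# ---------------------------------------------------------------------------

def _taxonomy_patterns(t: Taxonomy, sibling_disjointness: bool, coverage_default: bool) -> list[frozenset[str]]:
    """All per-taxonomy membership patterns a region may take (excluding ∅).

    With sibling disjointness these are root chains ending at a leaf or at a
    non-covered parent; without it, any non-empty upward-closed set whose
    covered members each retain a child.
    """
    root = t.root
    if sibling_disjointness:
        chains: list[frozenset[str]] = []

        def walk(label: str, path: tuple[str, ...]) -> None:
            path = path + (label,)
            if not t.covered(label, coverage_default):
                chains.append(frozenset(path))
            for child in t.children(label):
                walk(child, path)

        walk(root, ())
        return chains

    # relaxed sibling disjointness: upward-closed subsets
    order = []

    def topo(label: str) -> None:
        order.append(label)
        for child in t.children(label):
            topo(child)

    topo(root)
    patterns: list[frozenset[str]] = []

    def extend(i: int, current: set[str]) -> None:
        if i == len(order):
            if current and all(
                not t.covered(lab, coverage_default)
                or any(c in current for c in t.children(lab))
                for lab in current
            ):
                patterns.append(frozenset(current))
            return
        label = order[i]
        parent = t.parent.get(label)
        if parent is None or parent in current:
            current.add(label)
            extend(i + 1, current)
            current.discard(label)
        extend(i + 1, current)

    extend(0, set())
    return patterns


def candidate_regions(problem: AlignmentProblem) -> list[Region]:
    """Every membership pattern an occupied region may take, jointly over both
    taxonomies.  Complete: every occupied region of every world is listed."""
    tog = problem.toggles
    out: list[Region] = []
    for t in (problem.t1, problem.t2):
        if not t.concepts:
            raise ValueError(f"taxonomy {t.taxonomy_id} has no concepts")
    p1 = [frozenset()] + _taxonomy_patterns(problem.t1, tog.sibling_disjointness, tog.coverage_default)
    p2 = [frozenset()] + _taxonomy_patterns(problem.t2, tog.sibling_disjointness, tog.coverage_default)
    q1 = [{f"{problem.t1.taxonomy_id}.{lab}" for lab in s} for s in p1]
    q2 = [{f"{problem.t2.taxonomy_id}.{lab}" for lab in s} for s in p2]
    for s1 in q1:
        for s2 in q2:
            if s1 or s2:
                out.append(Region(frozenset(s1 | s2)))
    return sorted(out)


# ---------------------------------------------------------------------------
# Encoding shared by solver and oracle
# ---------------------------------------------------------------------------

class _Encoding:
    def __init__(self, problem: AlignmentProblem):
        if not problem.toggles.non_emptiness:
            raise ValueError(
                "reasoning requires the non-emptiness constraint: RCC-5 "
                "relations are undefined for empty extensions"
            )
        diags = validate(problem)
        if diags:
            raise ValueError(
                "problem fails validation: " + "; ".join(str(d) for d in diags)
            )
        self.problem = problem
        self.concepts: list[str] = sorted(
            c.qualified_id for c in problem.all_concepts()
        )
        self.index = {q: i for i, q in enumerate(self.concepts)}
        self.n = len(self.concepts)
        self.regions = candidate_regions(problem)
        self.region_masks = [
            sum(1 << self.index[q] for q in r.membership) for r in self.regions
        ]
        self.pairs: list[tuple[int, int]] = [
            (i, j) for i in range(self.n) for j in range(i + 1, self.n)
        ]
        self.pair_index = {p: k for k, p in enumerate(self.pairs)}

        # zone existence over all candidate regions, per ordered (i, j)
        exist_only = [[False] * self.n for _ in range(self.n)]
        exist_shared = [[False] * self.n for _ in range(self.n)]
        for m in self.region_masks:
            for i, j in self.pairs:
                bi = m >> i & 1
                bj = m >> j & 1
                if bi and bj:
                    exist_shared[i][j] = True
                elif bi:
                    exist_only[i][j] = True
                elif bj:
                    exist_only[j][i] = True

        # structural domain per pair: a base relation is feasible only if each
        # zone it requires occupied has at least one candidate region
        self.domains: list[int] = []
        for i, j in self.pairs:
            mask = 0
            for r in _BASE_LIST:
                lo, sh, ro = _REL_ZONES[r]
                if lo and not exist_only[i][j]:
                    continue
                if sh and not exist_shared[i][j]:
                    continue
                if ro and not exist_only[j][i]:
                    continue
                mask |= r.value
            self.domains.append(mask)

        # articulations restrict their pair's domain
        for art in problem.articulations:
            li = self.index[art.left.qualified_id]
            ri = self.index[art.right.qualified_id]
            if li < ri:
                k = self.pair_index[(li, ri)]
                self.domains[k] &= art.relation.mask
            else:
                k = self.pair_index[(ri, li)]
                self.domains[k] &= CONVERSE_MASK[art.relation.mask]

        # per-region (pair, zone-allowance) entries for the realizability check
        self.region_pair_zones: list[list[tuple[int, int, int]]] = []
        for m in self.region_masks:
            entries = []
            for k, (i, j) in enumerate(self.pairs):
                bi = m >> i & 1
                bj = m >> j & 1
                if bi and bj:
                    entries.append((k, _ALLOW_BOTH, 1))  # zone slot 1 = shared
                elif bi:
                    entries.append((k, _ALLOW_LEFT, 0))  # slot 0 = left-only
                elif bj:
                    entries.append((k, _ALLOW_RIGHT, 2))  # slot 2 = right-only
            self.region_pair_zones.append(entries)

        self.taxonomy_ids = (problem.t1.taxonomy_id, problem.t2.taxonomy_id)

    # -- realizability -----------------------------------------------------
    def realize(self, assignment: list[int]) -> Optional[list[int]]:
        """Exact model check for an atomic assignment (one bit per pair).

        Returns the indices of the maximal witness region set if the
        assignment is realizable, else None.
        """
        allowed: list[int] = []
        occupancy = [[False, False, False] for _ in self.pairs]
        for ridx, entries in enumerate(self.region_pair_zones):
            ok = True
            for k, allow_mask, _slot in entries:
                if not assignment[k] & allow_mask:
                    ok = False
                    break
            if ok:
                allowed.append(ridx)
                for k, _allow_mask, slot in entries:
                    occupancy[k][slot] = True
        for k in range(len(self.pairs)):
            r = _mask_to_relation(assignment[k])
            lo, sh, ro = _REL_ZONES[r]
            occ = occupancy[k]
            if (lo and not occ[0]) or (sh and not occ[1]) or (ro and not occ[2]):
                return None
        return allowed

    def world_from_assignment(
        self, assignment: list[int], witness: list[int]
    ) -> PossibleWorld:
        relations = {
            (self.concepts[i], self.concepts[j]): _mask_to_relation(assignment[k])
            for k, (i, j) in enumerate(self.pairs)
        }
        regions = tuple(self.regions[r] for r in witness)
        return PossibleWorld(self.concepts, self.taxonomy_ids, relations, regions)


def _mask_to_relation(mask: int) -> BaseRelation:
    return BaseRelation(mask)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _propagate(matrix: list[list[int]], n: int, seeds: list[tuple[int, int]]) -> bool:
    """Incremental path consistency from the seed arcs; False on wipe-out."""
    comp = COMPOSITION_MASK_TABLE
    conv = CONVERSE_MASK
    queue = list(seeds)
    in_queue = set(queue)
    while queue:
        i, j = queue.pop()
        in_queue.discard((i, j))
        rij = matrix[i][j]
        row_i = matrix[i]
        row_j = matrix[j]
        for k in range(n):
            if k == i or k == j:
                continue
            new_ik = row_i[k] & comp[rij][row_j[k]]
            if new_ik != row_i[k]:
                if not new_ik:
                    return False
                row_i[k] = new_ik
                matrix[k][i] = conv[new_ik]
                for arc in ((i, k), (k, i)):
                    if arc not in in_queue:
                        queue.append(arc)
                        in_queue.add(arc)
            new_kj = matrix[k][j] & comp[matrix[k][i]][rij]
            if new_kj != matrix[k][j]:
                if not new_kj:
                    return False
                matrix[k][j] = new_kj
                matrix[j][k] = conv[new_kj]
                for arc in ((k, j), (j, k)):
                    if arc not in in_queue:
                        queue.append(arc)
                        in_queue.add(arc)
    return True


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def enumerate_worlds(
    problem: AlignmentProblem, cap: int = DEFAULT_WORLD_CAP
) -> WorldSet:
    """All distinct possible worlds of the problem, up to ``cap``.

    Deterministic: worlds are produced in lexicographic order of their
    relation assignment over the sorted concept-pair list.  ``truncated`` is
    set when the cap was reached with candidates remaining.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    enc = _Encoding(problem)
    n = enc.n
    matrix = [[FULL_MASK] * n for _ in range(n)]
    for i in range(n):
        matrix[i][i] = BaseRelation.EQ.value
    for k, (i, j) in enumerate(enc.pairs):
        if not enc.domains[k]:
            return WorldSet([], False)
        matrix[i][j] = enc.domains[k]
        matrix[j][i] = CONVERSE_MASK[enc.domains[k]]
    result = WorldSet([], False)
    if not _propagate(matrix, n, list(enc.pairs) + [(j, i) for i, j in enc.pairs]):
        return result

    pairs = enc.pairs

    def search(matrix: list[list[int]]) -> bool:
        """DFS; returns False to abort (cap overflow)."""
        # next unassigned pair in canonical order
        target = -1
        for k, (i, j) in enumerate(pairs):
            m = matrix[i][j]
            if m & (m - 1):
                target = k
                break
        if target < 0:
            assignment = [matrix[i][j] for i, j in pairs]
            witness = enc.realize(assignment)
            if witness is not None:
                if len(result.worlds) >= cap:
                    result.truncated = True
                    return False
                result.worlds.append(enc.world_from_assignment(assignment, witness))
            return True
        i, j = pairs[target]
        m = matrix[i][j]
        for base in _BASE_LIST:
            if not m & base.value:
                continue
            child = [row[:] for row in matrix]
            child[i][j] = base.value
            child[j][i] = base.converse.value
            if _propagate(child, n, [(i, j), (j, i)]):
                if not search(child):
                    return False
        return True

    search(matrix)
    return result


def is_consistent(problem: AlignmentProblem) -> ConsistencyResult:
    """True iff at least one possible world exists; returns a witness if so."""
    ws = enumerate_worlds(problem, cap=1)
    if ws.worlds:
        return ConsistencyResult(True, ws.worlds[0])
    return ConsistencyResult(False, None)


def check_world(problem: AlignmentProblem, world: PossibleWorld) -> bool:
    """Whether a full relation mapping is a possible world of the problem."""
    enc = _Encoding(problem)
    if tuple(sorted(world.concepts)) != tuple(enc.concepts):
        return False
    assignment = []
    for k, (i, j) in enumerate(enc.pairs):
        r = world.relation(enc.concepts[i], enc.concepts[j])
        if not enc.domains[k] & r.value:
            return False
        assignment.append(r.value)
    return enc.realize(assignment) is not None


def oracle_worlds(problem: AlignmentProblem) -> list[PossibleWorld]:
    """Independent brute-force world enumeration for small instances.

    Enumerates every subset of the candidate regions as the occupied set,
    keeps those where every concept is inhabited and every articulation's zone
    pattern lies in its asserted relation set, projects each survivor to its
    pairwise relation mapping, deduplicates, and returns the worlds sorted in
    the solver's order.  Refuses instances with more candidate regions than
    ORACLE_REGION_LIMIT.
    """
    enc = _Encoding(problem)
    k = len(enc.regions)
    if k > ORACLE_REGION_LIMIT:
        raise OracleTooLargeError(
            f"{k} candidate regions exceed the oracle limit of {ORACLE_REGION_LIMIT}"
        )
    n = enc.n
    # per-concept region-index masks
    concept_masks = [0] * n
    for ridx, m in enumerate(enc.region_masks):
        for i in range(n):
            if m >> i & 1:
                concept_masks[i] |= 1 << ridx
    # per ordered pair (i, j): region-index masks for the three zones
    zone_masks: dict[tuple[int, int], tuple[int, int, int]] = {}
    for i, j in enc.pairs:
        lo = sh = ro = 0
        for ridx, m in enumerate(enc.region_masks):
            bi = m >> i & 1
            bj = m >> j & 1
            if bi and bj:
                sh |= 1 << ridx
            elif bi:
                lo |= 1 << ridx
            elif bj:
                ro |= 1 << ridx
        zone_masks[(i, j)] = (lo, sh, ro)
    # articulation constraints as (zone masks, allowed relation mask)
    art_constraints = []
    for art in problem.articulations:
        li = enc.index[art.left.qualified_id]
        ri = enc.index[art.right.qualified_id]
        if li < ri:
            zm = zone_masks[(li, ri)]
            allowed = art.relation.mask
        else:
            lo, sh, ro = zone_masks[(ri, li)]
            zm = (ro, sh, lo)
            allowed = art.relation.mask
        art_constraints.append((zm, allowed))

    seen: dict[tuple[int, ...], PossibleWorld] = {}
    for s in range(1, 1 << k):
        if any(not s & cm for cm in concept_masks):
            continue
        ok = True
        for (lo, sh, ro), allowed in art_constraints:
            rel = relation_from_zones((bool(s & lo), bool(s & sh), bool(s & ro)))
            if not rel.value & allowed:
                ok = False
                break
        if not ok:
            continue
        relations = {}
        for i, j in enc.pairs:
            lo, sh, ro = zone_masks[(i, j)]
            relations[(enc.concepts[i], enc.concepts[j])] = relation_from_zones(
                (bool(s & lo), bool(s & sh), bool(s & ro))
            )
        regions = tuple(
            enc.regions[r] for r in range(k) if s >> r & 1
        )
        world = PossibleWorld(enc.concepts, enc.taxonomy_ids, relations, regions)
        seen.setdefault(world.sort_key, world)
    return [seen[key] for key in sorted(seen)]
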