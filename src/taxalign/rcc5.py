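"""The RCC-5 relation algebra.

RCC-5 characterizes the relationship between the referential extensions of two
taxonomic concepts (modelled as finite non-empty sets) with five base relations:

====================  ======  ===========================================
relation              glyph   set semantics (A vs. B)
====================  ======  ===========================================
congruence            ``==``  A = B
proper inclusion      ``>``   A ⊃ B
inverse p. inclusion  ``<``   A ⊂ B
overlap               ``><``  A∩B, A\\B and B\\A all non-empty
exclusion             ``|``   A∩B = ∅
====================  ======  ===========================================

An expert who is unsure may assert a *disjunction* of base relations; the 2^5
subsets of the base relations form a 32-element lattice, from the empty set
(contradiction) to the maximally ambiguous disjunction of all five.  The empty
set is representable but is reserved as the closure's inconsistency signal; it
is never legal as user input.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

__all__ = [
    "BaseRelation",
    "RelationSet",
    "ZonePattern",
    "converse",
    "compose",
    "compose_sets",
    "relation_from_zones",
    "algebraic_closure",
    "composition_table_from_set_models",
    "InconsistentNetworkError",
    "COMPOSITION",
]


class BaseRelation(enum.Enum):
    """One of the five RCC-5 base relations (bit values index the lattice)."""

    EQ = 1   # congruence, ==
    PI = 2   # proper inclusion, >   (left properly includes right)
    IPI = 4  # inverse proper inclusion, <
    OV = 8   # overlap, ><
    DJ = 16  # exclusion, |

    @property
    def glyph(self) -> str:
        return _GLYPH[self]

    @property
    def keyword(self) -> str:
        """ASCII surface keyword used in the text problem format."""
        return _KEYWORD[self]

    @property
    def converse(self) -> "BaseRelation":
        return _CONVERSE[self]

    def __lt__(self, other: "BaseRelation") -> bool:  # canonical EQ<PI<IPI<OV<DJ
        return self.value < other.value


_GLYPH = {
    BaseRelation.EQ: "==",
    BaseRelation.PI: ">",
    BaseRelation.IPI: "<",
    BaseRelation.OV: "><",
    BaseRelation.DJ: "|",
}
_KEYWORD = {
    BaseRelation.EQ: "equals",
    BaseRelation.PI: "includes",
    BaseRelation.IPI: "is_included_in",
    BaseRelation.OV: "overlaps",
    BaseRelation.DJ: "disjoint",
}
_CONVERSE = {
    BaseRelation.EQ: BaseRelation.EQ,
    BaseRelation.PI: BaseRelation.IPI,
    BaseRelation.IPI: BaseRelation.PI,
    BaseRelation.OV: BaseRelation.OV,
    BaseRelation.DJ: BaseRelation.DJ,
}

BASE_ORDER = (
    BaseRelation.EQ,
    BaseRelation.PI,
    BaseRelation.IPI,
    BaseRelation.OV,
    BaseRelation.DJ,
)
KEYWORD_TO_RELATION = {r.keyword: r for r in BASE_ORDER}
GLYPH_TO_RELATION = {r.glyph: r for r in BASE_ORDER}
FULL_MASK = 0b11111


@dataclass(frozen=True)
class RelationSet:
    """An element of the 32-member articulation lattice: a set of base relations.

    Internally a 5-bit mask.  Immutable, hashable, iterable in canonical order.
    """

    mask: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mask <= FULL_MASK:
            raise ValueError(f"relation mask out of range: {self.mask}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def of(cls, *relations: BaseRelation) -> "RelationSet":
        mask = 0
        for r in relations:
            mask |= r.value
        return cls(mask)

    @classmethod
    def from_iterable(cls, relations: Iterable[BaseRelation]) -> "RelationSet":
        return cls.of(*relations)

    @classmethod
    def full(cls) -> "RelationSet":
        return cls(FULL_MASK)

    @classmethod
    def empty(cls) -> "RelationSet":
        return cls(0)

    @classmethod
    def all_values(cls) -> list["RelationSet"]:
        """All 32 lattice elements, in mask order."""
        return [cls(m) for m in range(FULL_MASK + 1)]

    # -- set protocol ------------------------------------------------------
    def __iter__(self) -> Iterator[BaseRelation]:
        return (r for r in BASE_ORDER if self.mask & r.value)

    def __len__(self) -> int:
        return bin(self.mask).count("1")

    def __contains__(self, relation: BaseRelation) -> bool:
        return bool(self.mask & relation.value)

    def __bool__(self) -> bool:
        return self.mask != 0

    def __or__(self, other: "RelationSet") -> "RelationSet":
        return RelationSet(self.mask | other.mask)

    def __and__(self, other: "RelationSet") -> "RelationSet":
        return RelationSet(self.mask & other.mask)

    def issubset(self, other: "RelationSet") -> bool:
        return self.mask & ~other.mask == 0

    @property
    def is_singleton(self) -> bool:
        return len(self) == 1

    @property
    def single(self) -> BaseRelation:
        if not self.is_singleton:
            raise ValueError(f"not a singleton relation set: {self}")
        return next(iter(self))

    def converse(self) -> "RelationSet":
        return RelationSet.of(*(r.converse for r in self))

    # -- display -----------------------------------------------------------
    def keywords(self) -> str:
        """Surface form: bare keyword for singletons, brace-wrapped otherwise."""
        words = [r.keyword for r in self]
        if len(words) == 1:
            return words[0]
        return "{" + " ".join(words) + "}"

    def glyphs(self) -> str:
        return " or ".join(r.glyph for r in self) if self.mask else "Ø"

    def __repr__(self) -> str:
        return f"RelationSet[{self.glyphs()}]"


def converse(r: RelationSet) -> RelationSet:
    """Member-wise converse of a relation set (involutive)."""
    return r.converse()


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def composition_table_from_set_models(
    universe_size: int = 4,
) -> dict[tuple[BaseRelation, BaseRelation], RelationSet]:
    """Derive the composition table by brute force over small set models.

    For every ordered pair (r1, r2) of base relations, enumerates all triples
    (A, B, C) of non-empty subsets of a ``universe_size``-element universe with
    r1 between A,B and r2 between B,C, and collects the realized relations
    between A and C.  A four-point universe realizes every composition case;
    the stored :data:`COMPOSITION` constant is checked against this oracle in
    the test suite.
    """
    points = range(universe_size)
    subsets = [
        frozenset(c)
        for size in range(1, universe_size + 1)
        for c in itertools.combinations(points, size)
    ]

    def rel(a: frozenset, b: frozenset) -> BaseRelation:
        if a == b:
            return BaseRelation.EQ
        if a > b:
            return BaseRelation.PI
        if a < b:
            return BaseRelation.IPI
        if a & b:
            return BaseRelation.OV
        return BaseRelation.DJ

    table: dict[tuple[BaseRelation, BaseRelation], int] = {
        (r1, r2): 0 for r1 in BASE_ORDER for r2 in BASE_ORDER
    }
    for a, b in itertools.product(subsets, repeat=2):
        rab = rel(a, b)
        for c in subsets:
            table[(rab, rel(b, c))] |= rel(a, c).value
    return {key: RelationSet(mask) for key, mask in table.items()}


# Frozen composition table, generated once by composition_table_from_set_models
# (eliminates transcription error; re-derived and compared in the test suite).
_E, _P, _I, _O, _D = (r.value for r in BASE_ORDER)
_COMPOSITION_MASKS = {
    (_E, _E): _E, (_E, _P): _P, (_E, _I): _I, (_E, _O): _O, (_E, _D): _D,
    (_P, _E): _P, (_P, _P): _P, (_P, _I): _E | _P | _I | _O,
    (_P, _O): _P | _O, (_P, _D): _P | _O | _D,
    (_I, _E): _I, (_I, _P): FULL_MASK, (_I, _I): _I,
    (_I, _O): _I | _O | _D, (_I, _D): _D,
    (_O, _E): _O, (_O, _P): _P | _O | _D, (_O, _I): _I | _O,
    (_O, _O): FULL_MASK, (_O, _D): _P | _O | _D,
    (_D, _E): _D, (_D, _P): _D, (_D, _I): _I | _O | _D,
    (_D, _O): _I | _O | _D, (_D, _D): FULL_MASK,
}
COMPOSITION: dict[tuple[BaseRelation, BaseRelation], RelationSet] = {
    (r1, r2): RelationSet(_COMPOSITION_MASKS[(r1.value, r2.value)])
    for r1 in BASE_ORDER
    for r2 in BASE_ORDER
}


def compose(r1: BaseRelation, r2: BaseRelation) -> RelationSet:
    """All base relations realizable between A and C given r1(A,B) and r2(B,C)."""
    return COMPOSITION[(r1, r2)]


def compose_sets(r1: RelationSet, r2: RelationSet) -> RelationSet:
    """Union of compose over all pairs of members (weak composition on sets)."""
    mask = 0
    for b1 in r1:
        for b2 in r2:
            mask |= COMPOSITION[(b1, b2)].mask
    return RelationSet(mask)


# Precomputed mask-level composition for the solver's hot path.
COMPOSITION_MASK_TABLE: list[list[int]] = [[0] * 32 for _ in range(32)]
for _m1 in range(32):
    for _m2 in range(32):
        _acc = 0
        for _r1 in BASE_ORDER:
            if _m1 & _r1.value:
                for _r2 in BASE_ORDER:
                    if _m2 & _r2.value:
                        _acc |= _COMPOSITION_MASKS[(_r1.value, _r2.value)]
        COMPOSITION_MASK_TABLE[_m1][_m2] = _acc

# Converse at mask level.
CONVERSE_MASK: list[int] = [0] * 32
for _m in range(32):
    _acc = 0
    for _r in BASE_ORDER:
        if _m & _r.value:
            _acc |= _r.converse.value
    CONVERSE_MASK[_m] = _acc


# ---------------------------------------------------------------------------
# Zone semantics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZonePattern:
    """Emptiness status of the three Euler zones A\\B, A∩B, B\\A of a pair.

    Two non-empty concepts partition their union into at most three merge
    regions; which of them are inhabited determines the base relation.
    """

    left_only_nonempty: bool
    shared_nonempty: bool
    right_only_nonempty: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.left_only_nonempty, self.shared_nonempty, self.right_only_nonempty)


_ZONE_TO_RELATION = {
    (False, True, False): BaseRelation.EQ,
    (True, True, False): BaseRelation.PI,
    (False, True, True): BaseRelation.IPI,
    (True, True, True): BaseRelation.OV,
    (True, False, True): BaseRelation.DJ,
}

# Inverse direction: which zones must be occupied (True) / empty (False) for a
# base relation between two non-empty concepts.
RELATION_TO_ZONES: dict[BaseRelation, tuple[bool, bool, bool]] = {
    rel: zones for zones, rel in _ZONE_TO_RELATION.items()
}


def relation_from_zones(z: ZonePattern | tuple[bool, bool, bool]) -> BaseRelation:
    """Base relation determined by which of the three zones are inhabited.

    Raises ValueError for patterns that violate non-emptiness of either
    concept (all-False, or a pattern where one concept has no inhabited zone).
    """
    zones = z.as_tuple() if isinstance(z, ZonePattern) else tuple(z)
    try:
        return _ZONE_TO_RELATION[zones]
    except KeyError:
        raise ValueError(
            f"zone pattern {zones} violates non-emptiness of a concept"
        ) from None


# ---------------------------------------------------------------------------
# Algebraic closure (path consistency)
# ---------------------------------------------------------------------------

class InconsistentNetworkError(ValueError):
    """Raised when closure refines some pair's relation set to the empty set."""

    def __init__(self, pair: tuple[str, str]):
        self.pair = pair
        super().__init__(f"relation network inconsistent at pair {pair}")


def algebraic_closure(
    network: Mapping[tuple[str, str], RelationSet],
) -> dict[tuple[str, str], RelationSet]:
    """Path-consistent refinement of a qualitative constraint network.

    ``network`` maps ordered node pairs to relation sets; missing pairs default
    to the full lattice top.  The result contains both orientations of every
    pair among the mentioned nodes, refined by repeated intersection with
    converse entries and with compositions through every intermediate node,
    until fixpoint.  The output is member-wise a subset of the input
    (monotone) and the operation is idempotent.

    Raises InconsistentNetworkError if any pair's set becomes empty (also
    covering converse clashes such as A > B together with B > A).
    """
    nodes = sorted({n for pair in network for n in pair})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rel = [[FULL_MASK] * n for _ in range(n)]
    for i in range(n):
        rel[i][i] = BaseRelation.EQ.value
    for (a, b), rset in network.items():
        i, j = idx[a], idx[b]
        if i == j:
            if BaseRelation.EQ not in rset:
                raise InconsistentNetworkError((a, b))
            continue
        rel[i][j] &= rset.mask
        rel[j][i] &= CONVERSE_MASK[rset.mask]
    for i in range(n):
        for j in range(n):
            if i != j and rel[i][j] == 0:
                raise InconsistentNetworkError((nodes[i], nodes[j]))

    comp = COMPOSITION_MASK_TABLE
    queue = [(i, j) for i in range(n) for j in range(n) if i != j]
    in_queue = set(queue)
    while queue:
        i, j = queue.pop()
        in_queue.discard((i, j))
        rij = rel[i][j]
        for k in range(n):
            if k == i or k == j:
                continue
            new_ik = rel[i][k] & comp[rij][rel[j][k]]
            if new_ik != rel[i][k]:
                if new_ik == 0:
                    raise InconsistentNetworkError((nodes[i], nodes[k]))
                rel[i][k] = new_ik
                rel[k][i] = CONVERSE_MASK[new_ik]
                for pair in ((i, k), (k, i)):
                    if pair not in in_queue:
                        queue.append(pair)
                        in_queue.add(pair)
            new_kj = rel[k][j] & comp[rel[k][i]][rij]
            if new_kj != rel[k][j]:
                if new_kj == 0:
                    raise InconsistentNetworkError((nodes[k], nodes[j]))
                rel[k][j] = new_kj
                rel[j][k] = CONVERSE_MASK[new_kj]
                for pair in ((k, j), (j, k)):
                    if pair not in in_queue:
                        queue.append(pair)
                        in_queue.add(pair)

    return {
        (a, b): RelationSet(rel[idx[a]][idx[b]])
        for a in nodes
        for b in nodes
        if a != b
    }
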