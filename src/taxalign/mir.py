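"""Maximally informative relations (MIR) and input-sufficiency analysis.

The MIR of a consistent alignment assigns to every ordered cross-taxonomy
concept pair the tightest relation set entailed by the input: the union, over
all possible worlds, of the base relation that pair takes.  A pair is
*resolved* when a single relation remains.  Entries are classified by
provenance:

* ``input`` — the pair was asserted with a singleton relation by the expert;
* ``deduced`` — a singleton relation already follows from algebraic closure of
  the input articulations plus the taxonomy edges alone (edges contribute
  non-strict inclusion; no coverage reasoning) — the "immediately deducible"
  entries;
* ``inferred`` — resolved (or constrained) only by full model-based reasoning
  over the possible worlds.

Input entries are trivially deducible, so input ⊆ deduced for counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .model import AlignmentProblem, Concept
from .rcc5 import (
    BaseRelation,
    RelationSet,
    algebraic_closure,
)
from .reasoner import (
    DEFAULT_WORLD_CAP,
    PossibleWorld,
    WorldSet,
    enumerate_worlds,
)

__all__ = [
    "MIREntry",
    "compute_mir",
    "classify_entries",
    "mir_table",
    "sufficient_subset",
    "next_question",
]

PROVENANCE_ORDER = {"input": 0, "deduced": 1, "inferred": 2}


@dataclass(frozen=True)
class MIREntry:
    """One MIR row: the realized relation set of an ordered cross pair."""

    left: Concept   # from T2, the more recent taxonomy
    right: Concept  # from T1
    realized: RelationSet
    provenance: Optional[str] = None  # input | deduced | inferred

    @property
    def resolved(self) -> bool:
        return self.realized.is_singleton

    @property
    def is_deduced(self) -> bool:
        """Immediately deducible (input articulations count as deduced)."""
        return self.provenance in ("input", "deduced")

    def __str__(self) -> str:
        tag = self.provenance or "?"
        return (
            f"{self.left.qualified_id} {self.realized.glyphs()} "
            f"{self.right.qualified_id} [{tag}]"
        )


def compute_mir(
    problem: AlignmentProblem, worlds: Sequence[PossibleWorld] | WorldSet
) -> list[MIREntry]:
    """One entry per ordered cross-taxonomy pair (T2 concept first).

    ``realized`` is the union of the base relations the pair takes across the
    given worlds.  Raises ValueError on an empty world set (the input is
    inconsistent; no MIR is defined).
    """
    world_list = list(worlds)
    if not world_list:
        raise ValueError("no possible worlds: MIR undefined for inconsistent input")
    entries = []
    lefts = sorted(problem.t2.concepts.values())
    rights = sorted(problem.t1.concepts.values())
    for left in lefts:
        for right in rights:
            realized = RelationSet.empty()
            for w in world_list:
                realized |= RelationSet.of(
                    w.relation(left.qualified_id, right.qualified_id)
                )
            entries.append(MIREntry(left, right, realized))
    return entries


def _closure_network(problem: AlignmentProblem) -> dict[tuple[str, str], RelationSet]:
    """Deduction network: articulations plus tree edges as non-strict inclusion."""
    network: dict[tuple[str, str], RelationSet] = {}
    inclusion = RelationSet.of(BaseRelation.EQ, BaseRelation.PI)

    def add(a: str, b: str, rset: RelationSet) -> None:
        network[(a, b)] = network.get((a, b), RelationSet.full()) & rset

    for t in (problem.t1, problem.t2):
        for parent, children in t.edges.items():
            for child in children:
                add(f"{t.taxonomy_id}.{parent}", f"{t.taxonomy_id}.{child}", inclusion)
        # mention isolated concepts so they appear as nodes
        for lab in t.labels:
            network.setdefault(
                (f"{t.taxonomy_id}.{lab}", f"{t.taxonomy_id}.{t.root}"),
                RelationSet.full(),
            )
    for art in problem.articulations:
        add(art.left.qualified_id, art.right.qualified_id, art.relation)
    return network


def classify_entries(
    problem: AlignmentProblem, mir: Sequence[MIREntry]
) -> list[MIREntry]:
    """Fill in provenance for each MIR entry (input / deduced / inferred)."""
    singleton_inputs = {
        (a.left.qualified_id, a.right.qualified_id)
        for a in problem.articulations
        if a.relation.is_singleton
    }
    closure = algebraic_closure(_closure_network(problem))
    out = []
    for entry in mir:
        pair = (entry.left.qualified_id, entry.right.qualified_id)
        closed = closure.get(pair, RelationSet.full())
        if pair in singleton_inputs:
            provenance = "input"
        elif closed.is_singleton:
            provenance = "deduced"
        else:
            provenance = "inferred"
        out.append(replace(entry, provenance=provenance))
    return out


def mir_table(
    problem: AlignmentProblem,
    worlds: Sequence[PossibleWorld] | WorldSet | None = None,
    cap: int = DEFAULT_WORLD_CAP,
) -> list[MIREntry]:
    """Convenience: enumerate worlds (if not given), compute and classify MIR,
    sorted deduced-before-inferred then lexicographically."""
    if worlds is None:
        worlds = enumerate_worlds(problem, cap=cap)
    entries = classify_entries(problem, compute_mir(problem, worlds))
    entries.sort(
        key=lambda e: (
            PROVENANCE_ORDER[e.provenance],
            e.left.qualified_id,
            e.right.qualified_id,
        )
    )
    return entries


def sufficient_subset(problem: AlignmentProblem, cap: int = DEFAULT_WORLD_CAP) -> list:
    """A minimal-under-deletion subset of articulations with the same worlds.

    Greedy elimination in file order: each articulation is dropped permanently
    if dropping it leaves the set of possible worlds (relation mappings)
    unchanged.  The result is sufficient (same world set) and minimal under
    deletion; it is not guaranteed to be a globally minimum subset.
    """
    full = enumerate_worlds(problem, cap=cap)
    if full.truncated:
        raise ValueError("world set truncated at cap; cannot certify sufficiency")
    target = [w.sort_key for w in full]
    if not target:
        raise ValueError("problem is inconsistent; sufficiency undefined")
    kept = list(problem.articulations)
    i = 0
    while i < len(kept):
        trial = kept[:i] + kept[i + 1 :]
        ws = enumerate_worlds(problem.with_articulations(trial), cap=cap)
        if not ws.truncated and [w.sort_key for w in ws] == target:
            kept = trial
        else:
            i += 1
    return kept


def next_question(
    worlds: Sequence[PossibleWorld] | WorldSet,
) -> Optional[tuple[tuple[str, str], RelationSet]]:
    """The most world-partitioning question to put to the expert.

    With more than one world remaining, returns the ordered cross-taxonomy
    pair (T2 concept first) whose realized relation set is largest — i.e. the
    "are these two concepts congruent, or overlapping, or ...?" question whose
    answer discriminates the most — together with that realized set; ties
    break lexicographically.  Returns None when a single world remains.
    """
    world_list = list(worlds)
    if not world_list:
        raise ValueError("no possible worlds")
    if len(world_list) == 1:
        return None
    realized: dict[tuple[str, str], int] = {}
    for pair in world_list[0].cross_pairs():
        mask = 0
        for w in world_list:
            mask |= w.relation(*pair).value
        realized[pair] = mask
    best_size = max(bin(m).count("1") for m in realized.values())
    candidates = sorted(p for p, m in realized.items() if bin(m).count("1") == best_size)
    pair = candidates[0]
    return pair, RelationSet(realized[pair])
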