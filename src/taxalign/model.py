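"""Domain model: concepts, taxonomies, articulations, alignment problems.

A *taxonomic concept* is a name individuated by its source circumscription
("name sec. author"), identified here by ``taxonomy_id.label`` (e.g.
``1954.PER`` for *Perelleschus* sec. Voss 1954).  A taxonomy is a strictly
rooted tree of concepts over ``is_a`` (set inclusion) edges; an alignment
problem pairs two taxonomies with expert RCC-5 articulations between their
concepts and three relaxable global constraints:

* non-emptiness — every concept has at least one instance;
* sibling disjointness — children of one parent are mutually exclusive;
* coverage — a parent is the union of its children (relaxable per parent
  via the "nc" non-coverage flag).

Inclusion edges mean ⊆, not strict ⊂: under coverage a monotypic parent is
extensionally congruent to its single child.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .rcc5 import RelationSet

__all__ = [
    "Concept",
    "Taxonomy",
    "Articulation",
    "ConstraintToggles",
    "AlignmentProblem",
    "Diagnostic",
    "validate",
    "leaves",
    "READING_TAGS",
]

_LABEL_RE = re.compile(r"^[A-Za-z0-9_]+$")
READING_TAGS = ("OST", "INT", "INT/OST")


@dataclass(frozen=True)
class Concept:
    """A taxonomic concept within one taxonomy."""

    taxonomy_id: str
    label: str
    implied_child: bool = False  # user-introduced "IC" concept; reporting only

    @property
    def qualified_id(self) -> str:
        return f"{self.taxonomy_id}.{self.label}"

    def __repr__(self) -> str:
        return f"Concept({self.qualified_id})"

    def __lt__(self, other: "Concept") -> bool:
        return self.qualified_id < other.qualified_id


class Taxonomy:
    """A single-rooted tree of concepts connected by inclusion edges.

    ``edges`` maps a parent label to its ordered child labels.  Concepts not
    mentioned in any edge may be declared via ``extra_concepts`` (needed for a
    one-concept taxonomy).  ``coverage_off`` lists parent labels whose
    extension is only facultatively defined by their children ("nc").
    """

    def __init__(
        self,
        taxonomy_id: str,
        display_name: str,
        edges: dict[str, Sequence[str]] | None = None,
        coverage_off: Iterable[str] = (),
        extra_concepts: Iterable[str] = (),
        implied_children: Iterable[str] = (),
    ):
        self.taxonomy_id = str(taxonomy_id)
        self.display_name = display_name
        self.edges: dict[str, tuple[str, ...]] = {
            p: tuple(cs) for p, cs in (edges or {}).items()
        }
        self.coverage_off: frozenset[str] = frozenset(coverage_off)
        implied = frozenset(implied_children)
        labels: list[str] = []
        for p, cs in self.edges.items():
            for lab in (p, *cs):
                if lab not in labels:
                    labels.append(lab)
        for lab in extra_concepts:
            if lab not in labels:
                labels.append(lab)
        self.concepts: dict[str, Concept] = {
            lab: Concept(self.taxonomy_id, lab, implied_child=lab in implied)
            for lab in labels
        }
        self.parent: dict[str, str] = {}
        for p, cs in self.edges.items():
            for c in cs:
                # validate() reports duplicates; keep the first parent here
                self.parent.setdefault(c, p)

    # -- structure ---------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return list(self.concepts)

    def __contains__(self, label: str) -> bool:
        return label in self.concepts

    def concept(self, label: str) -> Concept:
        return self.concepts[label]

    def children(self, label: str) -> tuple[str, ...]:
        return self.edges.get(label, ())

    def roots(self) -> list[str]:
        return [lab for lab in self.concepts if lab not in self.parent]

    @property
    def root(self) -> str:
        roots = self.roots()
        if len(roots) != 1:
            raise ValueError(
                f"taxonomy {self.taxonomy_id} has {len(roots)} roots; expected 1"
            )
        return roots[0]

    def is_leaf(self, label: str) -> bool:
        return not self.edges.get(label)

    def ancestors(self, label: str) -> list[str]:
        """Proper ancestors, nearest first."""
        out = []
        seen = set()
        cur = label
        while cur in self.parent and cur not in seen:
            seen.add(cur)
            cur = self.parent[cur]
            out.append(cur)
        return out

    def covered(self, label: str, coverage_default: bool = True) -> bool:
        """Whether the coverage constraint applies to this (internal) parent."""
        return (
            coverage_default
            and not self.is_leaf(label)
            and label not in self.coverage_off
        )

    def __repr__(self) -> str:
        return f"Taxonomy({self.taxonomy_id}, {len(self.concepts)} concepts)"


@dataclass(frozen=True)
class Articulation:
    """An RCC-5 statement (possibly disjunctive) between two concepts.

    By convention ``left`` is from the more recently published taxonomy (T2)
    and ``right`` from the earlier one (T1).  ``reading_tag`` records whether
    the expert intended an ostensive and/or intensional reading; it is carried
    as metadata only and never alters reasoning.
    """

    left: Concept
    right: Concept
    relation: RelationSet
    reading_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValueError("articulation relation set must be non-empty")
        if self.left.taxonomy_id == self.right.taxonomy_id:
            raise ValueError(
                "articulation endpoints must belong to different taxonomies"
            )
        if self.reading_tag is not None and self.reading_tag not in READING_TAGS:
            raise ValueError(f"unknown reading tag {self.reading_tag!r}")

    def __str__(self) -> str:
        return (
            f"[{self.left.qualified_id} {self.relation.keywords()} "
            f"{self.right.qualified_id}]"
        )


@dataclass(frozen=True)
class ConstraintToggles:
    """Global taxonomic constraints; all on by default."""

    non_emptiness: bool = True
    sibling_disjointness: bool = True
    coverage_default: bool = True


@dataclass
class AlignmentProblem:
    """Two taxonomies, expert articulations, and constraint toggles."""

    t1: Taxonomy
    t2: Taxonomy
    articulations: list[Articulation] = field(default_factory=list)
    toggles: ConstraintToggles = field(default_factory=ConstraintToggles)

    def taxonomy(self, taxonomy_id: str) -> Taxonomy:
        for t in (self.t1, self.t2):
            if t.taxonomy_id == taxonomy_id:
                return t
        raise KeyError(taxonomy_id)

    def resolve(self, qualified_id: str) -> Concept:
        taxonomy_id, _, label = qualified_id.partition(".")
        t = self.taxonomy(taxonomy_id)
        return t.concept(label)

    def all_concepts(self) -> list[Concept]:
        return [
            t.concept(lab) for t in (self.t1, self.t2) for lab in t.labels
        ]

    def without_articulations(self, drop: Iterable[int]) -> "AlignmentProblem":
        """Copy of the problem with the articulations at ``drop`` removed."""
        dropset = set(drop)
        kept = [a for i, a in enumerate(self.articulations) if i not in dropset]
        return AlignmentProblem(self.t1, self.t2, kept, self.toggles)

    def with_articulations(self, arts: Sequence[Articulation]) -> "AlignmentProblem":
        return AlignmentProblem(self.t1, self.t2, list(arts), self.toggles)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    code: str
    message: str

    def __str__(self) -> str:
        return f"{self.code}: {self.message}"


def _validate_taxonomy(t: Taxonomy) -> list[Diagnostic]:
    out: list[Diagnostic] = []
    for lab in t.concepts:
        if not _LABEL_RE.match(lab):
            out.append(Diagnostic("bad-label", f"label {lab!r} in taxonomy {t.taxonomy_id}"))
    seen_children: dict[str, str] = {}
    for p, cs in t.edges.items():
        counts: dict[str, int] = {}
        for c in cs:
            counts[c] = counts.get(c, 0) + 1
            if c in seen_children and seen_children[c] != p:
                out.append(
                    Diagnostic(
                        "multiple-parents",
                        f"concept {t.taxonomy_id}.{c} listed under parents "
                        f"{seen_children[c]} and {p}",
                    )
                )
            seen_children.setdefault(c, p)
        for c, k in counts.items():
            if k > 1:
                out.append(
                    Diagnostic("duplicate-child", f"{t.taxonomy_id}.{c} repeated under {p}")
                )
    roots = t.roots()
    if len(roots) != 1:
        out.append(
            Diagnostic(
                "root-count",
                f"taxonomy {t.taxonomy_id} has {len(roots)} roots ({roots}); expected 1",
            )
        )
    # cycle / connectivity check: walk up from every concept
    if len(roots) == 1:
        root = roots[0]
        for lab in t.concepts:
            seen: set[str] = set()
            cur = lab
            while cur in t.parent:
                if cur in seen:
                    out.append(Diagnostic("cycle", f"cycle through {t.taxonomy_id}.{cur}"))
                    break
                seen.add(cur)
                cur = t.parent[cur]
            else:
                if cur != root:
                    out.append(
                        Diagnostic(
                            "disconnected",
                            f"{t.taxonomy_id}.{lab} does not reach root {root}",
                        )
                    )
    for lab in t.coverage_off:
        if lab not in t.concepts:
            out.append(
                Diagnostic("dangling-nc", f"nc flag on undeclared {t.taxonomy_id}.{lab}")
            )
        elif t.is_leaf(lab):
            out.append(
                Diagnostic("nc-on-leaf", f"nc flag on leaf concept {t.taxonomy_id}.{lab}")
            )
    return out


def validate(problem: AlignmentProblem) -> list[Diagnostic]:
    """All structural violations of a problem; empty iff structurally valid.

    Returns diagnostics rather than raising: the reasoning operations assume a
    problem that validates cleanly.
    """
    out: list[Diagnostic] = []
    if problem.t1.taxonomy_id == problem.t2.taxonomy_id:
        out.append(
            Diagnostic("duplicate-taxonomy-id", f"both taxonomies are {problem.t1.taxonomy_id!r}")
        )
    out.extend(_validate_taxonomy(problem.t1))
    out.extend(_validate_taxonomy(problem.t2))
    known = {problem.t1.taxonomy_id, problem.t2.taxonomy_id}
    for i, art in enumerate(problem.articulations):
        for endpoint in (art.left, art.right):
            if endpoint.taxonomy_id not in known:
                out.append(
                    Diagnostic(
                        "unknown-taxonomy",
                        f"articulation {i}: {endpoint.qualified_id} references "
                        f"unknown taxonomy {endpoint.taxonomy_id!r}",
                    )
                )
            elif endpoint.label not in problem.taxonomy(endpoint.taxonomy_id):
                out.append(
                    Diagnostic(
                        "dangling-reference",
                        f"articulation {i}: undeclared concept {endpoint.qualified_id}",
                    )
                )
        if not art.relation:
            out.append(Diagnostic("empty-relation", f"articulation {i} has empty relation set"))
    return out


def leaves(taxonomy: Taxonomy) -> set[Concept]:
    """Concepts with no children."""
    return {taxonomy.concept(lab) for lab in taxonomy.labels if taxonomy.is_leaf(lab)}
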