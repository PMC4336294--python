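"""Text formats: the alignment problem dialect, MIR tables (CSV), DOT graphs.

Problem file dialect (one blank line between blocks; ``#`` comments allowed
anywhere; ``#!`` lines are machine-readable directives)::

    # free comment
    #! toggle sibling_disjointness off      (only non-default toggles appear)
    taxonomy 1936 Guenther 1936
    (ELL ELLcarlud ELL_IC)

    taxonomy 1954 Voss 1954
    (PER Pcarlud Prectir Psubcin)

    articulation A
    [1954.Pcarlud equals 1936.ELLcarlud OST]
    [1954.PER {includes overlaps is_included_in} 1936.ELL]

Taxonomy lines are ``(parent child child ... [nc])``; a trailing ``nc``
switches the coverage constraint off for that parent; a bare ``(concept)``
declares a one-concept taxonomy.  Concept references inside the articulation
block are fully qualified (``1954.PER``); inside taxonomy blocks the prefix is
implicit.  Relation keywords are ``equals``, ``includes``, ``is_included_in``,
``overlaps``, ``disjoint``; a brace-wrapped group is a disjunction.  An
optional trailing ``OST`` / ``INT`` / ``INT/OST`` token records the reading of
an articulation (metadata only).  Labels ending in ``_IC`` are recognized as
implied-child concepts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .merge import MergeGraph
from .mir import MIREntry, PROVENANCE_ORDER
from .model import (
    AlignmentProblem,
    Articulation,
    ConstraintToggles,
    Taxonomy,
)
from .rcc5 import KEYWORD_TO_RELATION, RelationSet

__all__ = [
    "ParseError",
    "ProblemDocument",
    "parse_input",
    "parse_document",
    "render_input",
    "write_mir",
    "write_dot",
]

_TOGGLE_NAMES = ("non_emptiness", "sibling_disjointness", "coverage_default")


class ParseError(ValueError):
    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass
class ProblemDocument:
    """A parsed problem file together with its preserved comment lines."""

    text: str
    problem: AlignmentProblem
    comments: list[str] = field(default_factory=list)


def parse_input(text: str) -> AlignmentProblem:
    """Parse the problem dialect; raises ParseError with a line number."""
    return parse_document(text).problem


def parse_document(text: str) -> ProblemDocument:
    comments: list[str] = []
    toggles = {name: True for name in _TOGGLE_NAMES}
    taxonomies: list[dict] = []  # {"id","name","edges","coverage_off","extra"}
    articulations_raw: list[tuple[int, str]] = []
    mode = None  # None | "taxonomy" | "articulation"

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            tokens = line[2:].split()
            if len(tokens) == 3 and tokens[0] == "toggle" and tokens[2] in ("on", "off"):
                if tokens[1] not in _TOGGLE_NAMES:
                    raise ParseError(line_no, f"unknown toggle {tokens[1]!r}")
                toggles[tokens[1]] = tokens[2] == "on"
                continue
            raise ParseError(line_no, f"malformed directive {line!r}")
        if line.startswith("#"):
            comments.append(raw)
            continue
        if line.startswith("taxonomy"):
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(line_no, "taxonomy line needs an id")
            tid = tokens[1]
            if any(t["id"] == tid for t in taxonomies):
                raise ParseError(line_no, f"duplicate taxonomy id {tid!r}")
            taxonomies.append(
                {
                    "id": tid,
                    "name": " ".join(tokens[2:]) or tid,
                    "edges": {},
                    "coverage_off": [],
                    "extra": [],
                }
            )
            mode = "taxonomy"
            continue
        if line.startswith("articulation"):
            mode = "articulation"
            continue
        if line.startswith("("):
            if mode != "taxonomy" or not taxonomies:
                raise ParseError(line_no, "parent-child line outside a taxonomy block")
            if not line.endswith(")"):
                raise ParseError(line_no, "unterminated parent-child line")
            tokens = line[1:-1].split()
            if not tokens:
                raise ParseError(line_no, "empty parent-child line")
            current = taxonomies[-1]
            if tokens[-1] == "nc":
                tokens = tokens[:-1]
                if len(tokens) < 2:
                    raise ParseError(line_no, "nc flag requires a parent with children")
                current["coverage_off"].append(tokens[0])
            if len(tokens) == 1:
                current["extra"].append(tokens[0])
                continue
            parent, children = tokens[0], tokens[1:]
            if parent in current["edges"]:
                current["edges"][parent] = tuple(current["edges"][parent]) + tuple(children)
            else:
                current["edges"][parent] = tuple(children)
            continue
        if line.startswith("["):
            if mode != "articulation":
                raise ParseError(line_no, "articulation outside an articulation block")
            articulations_raw.append((line_no, line))
            continue
        raise ParseError(line_no, f"unrecognized line {line!r}")

    if len(taxonomies) != 2:
        raise ParseError(0, f"expected exactly 2 taxonomy blocks, found {len(taxonomies)}")
    built = []
    for t in taxonomies:
        labels = {lab for p, cs in t["edges"].items() for lab in (p, *cs)} | set(t["extra"])
        built.append(
            Taxonomy(
                t["id"],
                t["name"],
                edges=t["edges"],
                coverage_off=t["coverage_off"],
                extra_concepts=t["extra"],
                implied_children=[lab for lab in labels if lab.endswith("_IC")],
            )
        )
    t1, t2 = built
    problem = AlignmentProblem(
        t1,
        t2,
        [],
        ConstraintToggles(**toggles),
    )
    for line_no, line in articulations_raw:
        problem.articulations.append(_parse_articulation(line_no, line, problem))
    return ProblemDocument(text=text, problem=problem, comments=comments)


def _resolve(line_no: int, problem: AlignmentProblem, ref: str):
    if "." not in ref:
        raise ParseError(line_no, f"concept reference {ref!r} must be qualified (tax.label)")
    tid, _, label = ref.partition(".")
    try:
        taxonomy = problem.taxonomy(tid)
    except KeyError:
        raise ParseError(line_no, f"unknown taxonomy {tid!r} in {ref!r}") from None
    if label not in taxonomy:
        raise ParseError(line_no, f"dangling concept reference {ref!r}")
    return taxonomy.concept(label)


def _parse_articulation(line_no: int, line: str, problem: AlignmentProblem) -> Articulation:
    if not line.endswith("]"):
        raise ParseError(line_no, "unterminated articulation")
    body = line[1:-1].strip()
    m = re.match(r"^(\S+)\s+(\{[^}]*\}|\S+)\s+(\S+)(?:\s+(\S+))?$", body)
    if not m:
        raise ParseError(line_no, f"malformed articulation {line!r}")
    left_ref, rel_text, right_ref, tag = m.groups()
    if rel_text.startswith("{"):
        keywords = rel_text[1:-1].split()
        if not keywords:
            raise ParseError(line_no, "empty relation disjunction")
    else:
        keywords = [rel_text]
    mask = 0
    for kw in keywords:
        if kw not in KEYWORD_TO_RELATION:
            raise ParseError(line_no, f"unknown relation keyword {kw!r}")
        mask |= KEYWORD_TO_RELATION[kw].value
    left = _resolve(line_no, problem, left_ref)
    right = _resolve(line_no, problem, right_ref)
    if tag is not None and tag not in ("OST", "INT", "INT/OST"):
        raise ParseError(line_no, f"unknown reading tag {tag!r}")
    try:
        return Articulation(left=left, right=right, relation=RelationSet(mask), reading_tag=tag)
    except ValueError as exc:
        raise ParseError(line_no, str(exc)) from None


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_taxonomy(t: Taxonomy) -> list[str]:
    lines = [f"taxonomy {t.taxonomy_id} {t.display_name}"]
    if not t.edges:
        lines.append(f"({t.root})")
        return lines
    # deterministic preorder from the root
    stack = [t.root]
    while stack:
        label = stack.pop()
        children = t.children(label)
        if children:
            nc = " nc" if label in t.coverage_off else ""
            lines.append("(" + " ".join((label, *children)) + nc + ")")
            stack.extend(reversed(children))
    return lines


def render_input(problem: AlignmentProblem) -> str:
    """Canonical text for a problem; parse(render(p)) is equivalent to p."""
    blocks: list[list[str]] = []
    directives = [
        f"#! toggle {name} off"
        for name in _TOGGLE_NAMES
        if not getattr(problem.toggles, name)
    ]
    if directives:
        blocks.append(directives)
    blocks.append(_render_taxonomy(problem.t1))
    blocks.append(_render_taxonomy(problem.t2))
    art_lines = ["articulation A"]
    for art in problem.articulations:
        tag = f" {art.reading_tag}" if art.reading_tag else ""
        art_lines.append(
            f"[{art.left.qualified_id} {art.relation.keywords()} "
            f"{art.right.qualified_id}{tag}]"
        )
    blocks.append(art_lines)
    return "\n\n".join("\n".join(b) for b in blocks) + "\n"


# ---------------------------------------------------------------------------
# MIR table
# ---------------------------------------------------------------------------

def write_mir(entries: Sequence[MIREntry]) -> str:
    """CSV text: left, relation-set, right, provenance; one row per ordered
    cross-taxonomy pair, sorted deduced-before-inferred then lexicographically."""
    rows = sorted(
        entries,
        key=lambda e: (
            PROVENANCE_ORDER.get(e.provenance, 3),
            e.left.qualified_id,
            e.right.qualified_id,
        ),
    )
    lines = ["left,relation,right,provenance"]
    for e in rows:
        lines.append(
            f"{e.left.qualified_id},{e.realized.keywords()},"
            f"{e.right.qualified_id},{e.provenance or 'unclassified'}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# DOT output
# ---------------------------------------------------------------------------

_NODE_STYLE = {
    # provenance -> (shape, fill)
    "both": ("box", "grey"),
    "T1_only": ("octagon", "yellow"),
    "T2_only": ("box", "green"),
}


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def write_dot(graph: MergeGraph, style: str | None = None) -> str:
    """Render a merge graph as DOT.

    Node shape and fill encode provenance (both taxonomies -> grey box,
    T1-only -> yellow octagon, T2-only -> green rectangle); overlap edges are
    drawn undirected and dashed.
    """
    style = style or graph.kind
    if style not in ("containment", "merge"):
        raise ValueError(f"unknown style {style!r}")
    lines = [f"digraph {style} {{", "  node [style=filled];"]
    for i, node in enumerate(graph.nodes):
        shape, fill = _NODE_STYLE[node.provenance]
        lines.append(
            f'  n{i} [label="{_dot_escape(node.display())}", '
            f"shape={shape}, fillcolor={fill}];"
        )
    for parent, child in sorted(graph.inclusion_edges):
        lines.append(f"  n{parent} -> n{child};")
    if style == "containment":
        for a, b in sorted(graph.overlap_edges):
            lines.append(f"  n{a} -> n{b} [dir=none, style=dashed, constraint=false];")
    lines.append("}")
    return "\n".join(lines) + "\n"
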