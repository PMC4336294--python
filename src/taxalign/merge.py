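"""Merge visual products of a single possible world.

Two graph views summarize how the aligned taxonomies fit together:

* the *containment-with-overlap graph* collapses congruent concepts into
  clusters and draws the proper-inclusion hierarchy among clusters
  (transitively reduced), with undirected overlap edges where clusters
  overlap;
* the *merge-concept graph* resolves each overlapping cluster pair (A, B)
  into its occupied Euler regions — unique-to-A (``A\\B``), shared (``A*B``),
  unique-to-B (``B\\A``) — attached into the inclusion hierarchy, leaving no
  overlap edges.

Region-node existence is semantic: a region is drawn only if the world's
occupied regions inhabit it.  When an Euler region coincides extensionally
with an existing cluster, its label is added to that cluster's node rather
than duplicating it (e.g. the part of *Elleschus* sec. 1936 outside
*Perelleschus* sec. 1954 is the implied-child cluster itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import networkx as nx

from .model import AlignmentProblem
from .rcc5 import BaseRelation
from .reasoner import PossibleWorld, Region

__all__ = [
    "MergeNode",
    "MergeGraph",
    "congruence_clusters",
    "containment_graph",
    "merge_concept_graph",
]


@dataclass
class MergeNode:
    """A node of a merge graph: a congruence cluster or an Euler region."""

    kind: str  # "cluster" | "euler_region"
    members: frozenset[str]  # concept qualified ids (empty for a pure region)
    provenance: str  # "T1_only" | "T2_only" | "both"
    labels: tuple[str, ...]  # display label first; extra region labels appended
    extension: frozenset[Region] = field(default_factory=frozenset)

    @property
    def label(self) -> str:
        return self.labels[0]

    def display(self) -> str:
        return " = ".join(self.labels)

    def __repr__(self) -> str:
        return f"MergeNode({self.display()!r}, {self.provenance})"


@dataclass
class MergeGraph:
    """Cluster/Euler-region graph with typed edges.

    ``inclusion_edges`` are directed (parent, child) node-index pairs and are
    transitively reduced; ``overlap_edges`` are undirected (sorted index
    pairs), present only in the containment style.
    """

    kind: str  # "containment" | "merge"
    nodes: list[MergeNode]
    inclusion_edges: set[tuple[int, int]]
    overlap_edges: set[tuple[int, int]]

    def node_by_label(self, label: str) -> MergeNode:
        for node in self.nodes:
            if label in node.labels:
                return node
        raise KeyError(label)

    def labels(self) -> set[str]:
        return {lab for node in self.nodes for lab in node.labels}


def congruence_clusters(world: PossibleWorld) -> list[frozenset[str]]:
    """Partition of all concepts into equivalence classes under congruence."""
    seen: set[str] = set()
    clusters: list[frozenset[str]] = []
    for c in world.concepts:
        if c in seen:
            continue
        cls = frozenset(
            d for d in world.concepts if d == c or world.relation(c, d) == BaseRelation.EQ
        )
        seen |= cls
        clusters.append(cls)
    return clusters


def _provenance(members: frozenset[str], taxonomy_ids: tuple[str, str]) -> str:
    t1, t2 = taxonomy_ids
    tids = {m.split(".", 1)[0] for m in members}
    if tids == {t1}:
        return "T1_only"
    if tids == {t2}:
        return "T2_only"
    return "both"


def _cluster_label(members: frozenset[str], taxonomy_ids: tuple[str, str]) -> str:
    """Member qualified ids concatenated, T2 members first (listing convention)."""
    t1, t2 = taxonomy_ids
    ordered = sorted(m for m in members if m.startswith(t2 + ".")) + sorted(
        m for m in members if not m.startswith(t2 + ".")
    )
    return " = ".join(ordered)


def _extension(members: frozenset[str], world: PossibleWorld) -> frozenset[Region]:
    rep = min(members)
    return frozenset(r for r in world.occupied_regions if rep in r)


def _cluster_nodes(world: PossibleWorld) -> list[MergeNode]:
    nodes = []
    for members in congruence_clusters(world):
        nodes.append(
            MergeNode(
                kind="cluster",
                members=members,
                provenance=_provenance(members, world.taxonomy_ids),
                labels=(_cluster_label(members, world.taxonomy_ids),),
                extension=_extension(members, world),
            )
        )
    nodes.sort(key=lambda n: n.label)
    return nodes


def _reduced_inclusion(nodes: list[MergeNode]) -> set[tuple[int, int]]:
    """Transitive reduction of strict extension containment between nodes."""
    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i != j and b.extension < a.extension:
                g.add_edge(i, j)
    reduced = nx.transitive_reduction(g)
    return set(reduced.edges())


def containment_graph(problem: AlignmentProblem, world: PossibleWorld) -> MergeGraph:
    """Congruence clusters with reduced inclusion edges and overlap edges."""
    nodes = _cluster_nodes(world)
    inclusion = _reduced_inclusion(nodes)
    overlap: set[tuple[int, int]] = set()
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            b = nodes[j]
            if world.relation(min(a.members), min(b.members)) == BaseRelation.OV:
                overlap.add((i, j))
    return MergeGraph("containment", nodes, inclusion, overlap)


def merge_concept_graph(problem: AlignmentProblem, world: PossibleWorld) -> MergeGraph:
    """Containment graph with every overlap resolved into Euler regions."""
    nodes = _cluster_nodes(world)
    ext_index: dict[frozenset[Region], int] = {n.extension: i for i, n in enumerate(nodes)}

    def add_region(extension: frozenset[Region], label: str, provenance: str) -> None:
        if not extension:
            return  # empty region in this world: not drawn
        if extension in ext_index:
            node = nodes[ext_index[extension]]
            if label not in node.labels:
                node.labels = node.labels + (label,)
            return
        ext_index[extension] = len(nodes)
        nodes.append(
            MergeNode(
                kind="euler_region",
                members=frozenset(),
                provenance=provenance,
                labels=(label,),
                extension=extension,
            )
        )

    cluster_count = len(nodes)
    for i in range(cluster_count):
        for j in range(i + 1, cluster_count):
            a, b = nodes[i], nodes[j]
            if world.relation(min(a.members), min(b.members)) != BaseRelation.OV:
                continue
            # operands in deterministic lexicographic order
            x, y = sorted((min(a.members), min(b.members)))
            ext_x, ext_y = (
                (a.extension, b.extension) if x == min(a.members) else (b.extension, a.extension)
            )
            prov_x, prov_y = (
                (a.provenance, b.provenance) if x == min(a.members) else (b.provenance, a.provenance)
            )
            add_region(ext_x & ext_y, f"{x}*{y}", "both")
            add_region(ext_x - ext_y, f"{x}\\{y}", prov_x)
            add_region(ext_y - ext_x, f"{y}\\{x}", prov_y)

    inclusion = _reduced_inclusion(nodes)
    return MergeGraph("merge", nodes, inclusion, set())
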