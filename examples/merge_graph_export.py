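"""Build merge graphs for a resolved alignment and export them as DOT.

Uses the 1936/1954 alignment under the intensional/ostensive reading, whose
single possible world has the two genera overlapping.  The containment graph
keeps the overlap as a lateral edge; the merge-concept graph resolves it into
Euler regions (shared region ``1936.ELL*1954.PER``, unique regions
``1936.ELL\\1954.PER`` and ``1954.PER\\1936.ELL``).
"""

from taxalign import (
    containment_graph,
    enumerate_worlds,
    merge_concept_graph,
    perelleschus,
    write_dot,
)

problem = perelleschus(1, "INT_OST")
world = enumerate_worlds(problem)[0]

contain = containment_graph(problem, world)
merged = merge_concept_graph(problem, world)

print(f"containment graph: {len(contain.nodes)} nodes, "
      f"{len(contain.inclusion_edges)} inclusion edges, "
      f"{len(contain.overlap_edges)} overlap edge(s)")
print(f"merge-concept graph: {len(merged.nodes)} nodes, no overlap edges\n")
print(write_dot(merged))
print("# Grey boxes are shared clusters, yellow octagons are unique to the")
print("# 1936 taxonomy, green rectangles unique to the 1954 taxonomy.")
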