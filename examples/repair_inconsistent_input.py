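"""Diagnose an inconsistent set of articulations and list minimal repairs.

Rebuilds the classic conflict pattern: an outgroup genus (2001.PHY) whose
only listed child is congruent with a species inside the other taxonomy's
genus (1986.Psubcin ⊂ 1986.PER), while the genera themselves are asserted to
overlap.  Coverage forces 2001.PHY == 2001.PHYsubcin ⊂ 1986.PER, which
contradicts the overlap — so no possible world exists.
"""

from taxalign import (
    AlignmentProblem,
    Articulation,
    BaseRelation,
    RelationSet,
    Taxonomy,
    is_consistent,
    repair_options,
)

t1 = Taxonomy("1986", "Wibmer & O'Brien 1986",
              edges={"PER": ["Pcarlud", "Prectir", "Psubcin"]})
t2 = Taxonomy("2001", "Franz & O'Brien 2001",
              edges={"DER": ["PER", "PHY"], "PER": ["Pcarlud", "Prectir"],
                     "PHY": ["PHYsubcin"]})


def art(left, rel, right):
    lt, _, ll = left.partition(".")
    rt, _, rl = right.partition(".")
    return Articulation(t2.concept(ll), t1.concept(rl), RelationSet.of(rel))


problem = AlignmentProblem(t1, t2, [
    art("2001.Pcarlud", BaseRelation.EQ, "1986.Pcarlud"),
    art("2001.Prectir", BaseRelation.EQ, "1986.Prectir"),
    art("2001.PHYsubcin", BaseRelation.EQ, "1986.Psubcin"),
    art("2001.PHY", BaseRelation.OV, "1986.PER"),
])

print("consistent:", bool(is_consistent(problem)))
for i, option in enumerate(repair_options(problem), start=1):
    print(f"repair option {i}: {option}")

print(
    "\nEach option is a minimal set of articulations whose removal restores\n"
    "consistency.  Removing the species congruence lets the overlap stand;\n"
    "removing the genus overlap resolves it to inclusion.  (The expert fix\n"
    "in practice is a third route: add an implied child to 2001.PHY.)"
)
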