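"""Built-in alignment problems and a seeded random-problem generator.

The embedded fixtures are the two fully printed *Perelleschus* alignments:

* alignment 1 — *Elleschus* sec. Günther (1936) vs. *Perelleschus* sec. Voss
  (1954), in its ostensive, intensional/ostensive and intensional readings,
  plus the two underspecified variants obtained by articulation removal;
* alignment 2 — *Perelleschus* sec. Voss (1954) vs. *Perelleschus* sec.
  Wibmer & O'Brien (1986), whose concepts are pairwise congruent.

Alignments 3-6 involve the larger 1986/2001/2006/2013 trees whose complete
articulation lists live only in external supplementary files; they can be
loaded from a converted problem file but are not embedded.

The random generator plants a ground-truth world first (random trees, random
leaf extensions over a shared point universe respecting disjointness and
coverage) and then emits a density-chosen subset of the true leaf
articulations, so the planted world is consistent with the emitted problem by
construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    AlignmentProblem,
    Articulation,
    ConstraintToggles,
    Taxonomy,
)
from .rcc5 import BaseRelation, RelationSet
from .reasoner import PossibleWorld, Region

__all__ = [
    "perelleschus",
    "random_problem",
    "GeneratorConfig",
    "FixtureUnavailableError",
    "PERELLESCHUS_READINGS",
]

PERELLESCHUS_READINGS = (
    "OST",
    "OST_ORIGINAL",
    "INT",
    "INT_OST",
    "underspec_L1",
    "underspec_L2",
)


class FixtureUnavailableError(LookupError):
    """Requested alignment needs an external problem file not shipped here."""


def _art(problem_t2: Taxonomy, problem_t1: Taxonomy, left: str, rel, right: str,
         tag: str | None = None) -> Articulation:
    relation = (
        RelationSet.of(*rel) if isinstance(rel, (tuple, list)) else RelationSet.of(rel)
    )
    return Articulation(
        left=problem_t2.concept(left),
        right=problem_t1.concept(right),
        relation=relation,
        reading_tag=tag,
    )


def _taxonomy_1936(with_implied_child: bool) -> Taxonomy:
    children = ["ELLcarlud"] + (["ELL_IC"] if with_implied_child else [])
    return Taxonomy(
        "1936",
        "Guenther 1936",
        edges={"ELL": children},
        implied_children=("ELL_IC",) if with_implied_child else (),
    )


def _taxonomy_1954() -> Taxonomy:
    return Taxonomy(
        "1954",
        "Voss 1954",
        edges={"PER": ["Pcarlud", "Prectir", "Psubcin"]},
    )


def _taxonomy_1986() -> Taxonomy:
    return Taxonomy(
        "1986",
        "Wibmer & O'Brien 1986",
        edges={"PER": ["Pcarlud", "Prectir", "Psubcin"]},
    )


def _alignment_1(reading: str) -> AlignmentProblem:
    implied = reading in ("INT", "INT_OST", "underspec_L1", "underspec_L2")
    t1 = _taxonomy_1936(with_implied_child=implied)
    t2 = _taxonomy_1954()
    EQ, PI, IPI, OV, DJ = (
        BaseRelation.EQ,
        BaseRelation.PI,
        BaseRelation.IPI,
        BaseRelation.OV,
        BaseRelation.DJ,
    )
    species = [
        _art(t2, t1, "Pcarlud", EQ, "ELLcarlud", "OST"),
        _art(t2, t1, "Prectir", DJ, "ELLcarlud", "OST"),
        _art(t2, t1, "Psubcin", DJ, "ELLcarlud", "OST"),
    ]
    if reading == "OST":
        arts = species
    elif reading == "OST_ORIGINAL":
        # the original, overspecified input: adds the disjunctive genus
        # articulation 1954.PER > or >< or < 1936.ELL
        arts = species + [_art(t2, t1, "PER", (PI, OV, IPI), "ELL")]
    elif reading == "INT_OST":
        arts = species + [
            _art(t2, t1, "PER", OV, "ELL", "INT/OST"),
            _art(t2, t1, "PER", DJ, "ELL_IC", "INT/OST"),
        ]
    elif reading == "underspec_L1":
        # INT/OST minus the exclusion articulation to the implied child
        arts = species + [_art(t2, t1, "PER", OV, "ELL", "INT/OST")]
    elif reading == "underspec_L2":
        # additionally minus the genus-level overlap articulation
        arts = species
    elif reading == "INT":
        arts = species + [_art(t2, t1, "PER", IPI, "ELL", "INT")]
    else:
        raise FixtureUnavailableError(f"unknown reading {reading!r} for alignment 1")
    return AlignmentProblem(t1, t2, arts)


def _alignment_2(reading: str) -> AlignmentProblem:
    if reading not in ("OST", "INT_OST", "OST_ORIGINAL"):
        raise FixtureUnavailableError(f"unknown reading {reading!r} for alignment 2")
    t1 = _taxonomy_1954()
    t2 = _taxonomy_1986()
    EQ = BaseRelation.EQ
    arts = [
        _art(t2, t1, "Pcarlud", EQ, "Pcarlud", "INT/OST"),
        _art(t2, t1, "Prectir", EQ, "Prectir", "INT/OST"),
        _art(t2, t1, "Psubcin", EQ, "Psubcin", "INT/OST"),
        # the logically redundant genus-level congruence of the original input
        _art(t2, t1, "PER", EQ, "PER", "INT/OST"),
    ]
    if reading == "OST":  # sufficient subset: species articulations only
        arts = arts[:3]
    return AlignmentProblem(t1, t2, arts)


def perelleschus(alignment_id: int, reading: str = "OST") -> AlignmentProblem:
    """One of the use case's alignment problems, by id (1-6) and reading.

    Alignments 1 and 2 are embedded; 3-6 require an externally converted
    problem file (load it with :func:`taxalign.formats.parse_input`) and raise
    FixtureUnavailableError here.
    """
    if alignment_id == 1:
        return _alignment_1(reading)
    if alignment_id == 2:
        return _alignment_2(reading)
    if alignment_id in (3, 4, 5, 6):
        raise FixtureUnavailableError(
            f"alignment {alignment_id} requires an external problem file "
            "(the full articulation list is not printed in the running text); "
            "convert the source file and load it with taxalign.formats.parse_input"
        )
    raise FixtureUnavailableError(f"unknown alignment id {alignment_id!r}")


# ---------------------------------------------------------------------------
# Random problems with a planted world
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for :func:`random_problem`.

    n1, n2 count the concepts per taxonomy (including the root);
    articulation_density is the fraction of cross-taxonomy leaf pairs whose
    true relation is emitted as an input articulation.
    """

    n1: int = 5
    n2: int = 5
    max_children: int = 3
    articulation_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("taxonomies need at least one concept")
        if not 0.0 <= self.articulation_density <= 1.0:
            raise ValueError("articulation_density must lie in [0, 1]")
        if self.max_children < 1:
            raise ValueError("max_children must be positive")


def _random_tree(rng: random.Random, taxonomy_id: str, n: int, max_children: int) -> Taxonomy:
    labels = [f"c{i}" for i in range(n)]
    edges: dict[str, list[str]] = {}
    child_count = {labels[0]: 0}
    for lab in labels[1:]:
        eligible = [p for p, k in child_count.items() if k < max_children]
        parent = rng.choice(sorted(eligible))
        edges.setdefault(parent, []).append(lab)
        child_count[parent] = child_count.get(parent, 0) + 1
        child_count[lab] = 0
    return Taxonomy(taxonomy_id, f"random {taxonomy_id}", edges=edges)


def _leaf_extensions(
    rng: random.Random, t: Taxonomy, points: list[int]
) -> dict[str, set[int]]:
    """Assign each point to exactly one leaf (≥1 point per leaf): leaves are
    disjoint, parents are the unions of their children (coverage holds)."""
    leaf_labels = sorted(lab for lab in t.labels if t.is_leaf(lab))
    ext: dict[str, set[int]] = {lab: set() for lab in t.labels}
    shuffled = points[:]
    rng.shuffle(shuffled)
    for i, lab in enumerate(leaf_labels):
        ext[lab].add(shuffled[i])
    for p in shuffled[len(leaf_labels):]:
        ext[rng.choice(leaf_labels)].add(p)
    # internal concepts: union of descendants
    def fill(lab: str) -> set[int]:
        if not t.is_leaf(lab):
            ext[lab] = set().union(*(fill(c) for c in t.children(lab)))
        return ext[lab]

    fill(t.root)
    return ext


def _relation_of(a: set[int], b: set[int]) -> BaseRelation:
    if a == b:
        return BaseRelation.EQ
    if a > b:
        return BaseRelation.PI
    if a < b:
        return BaseRelation.IPI
    if a & b:
        return BaseRelation.OV
    return BaseRelation.DJ


def random_problem(config: GeneratorConfig) -> tuple[AlignmentProblem, PossibleWorld]:
    """A random consistent problem plus the planted ground-truth world.

    Deterministic in the config (identical config => identical problem).  The
    planted world is always among the worlds of the emitted problem because
    its extensions satisfy every emitted articulation and every default
    constraint by construction.
    """
    rng = random.Random(("taxalign", config.seed, config.n1, config.n2,
                         config.max_children, config.articulation_density).__repr__())
    t1 = _random_tree(rng, "g1", config.n1, config.max_children)
    t2 = _random_tree(rng, "g2", config.n2, config.max_children)
    n_leaves = max(
        sum(t1.is_leaf(l) for l in t1.labels),
        sum(t2.is_leaf(l) for l in t2.labels),
    )
    points = list(range(n_leaves + rng.randint(0, 2)))
    ext1 = _leaf_extensions(rng, t1, points)
    ext2 = _leaf_extensions(rng, t2, points)
    ext = {f"{t1.taxonomy_id}.{lab}": s for lab, s in ext1.items()}
    ext.update({f"{t2.taxonomy_id}.{lab}": s for lab, s in ext2.items()})

    concepts = sorted(ext)
    relations = {
        (a, b): _relation_of(ext[a], ext[b])
        for ia, a in enumerate(concepts)
        for b in concepts[ia + 1:]
    }
    region_map: dict[frozenset[str], None] = {}
    for p in points:
        membership = frozenset(q for q, s in ext.items() if p in s)
        if membership:
            region_map[membership] = None
    planted = PossibleWorld(
        concepts,
        (t1.taxonomy_id, t2.taxonomy_id),
        relations,
        tuple(sorted(Region(m) for m in region_map)),
    )

    arts = []
    leaves1 = sorted(lab for lab in t1.labels if t1.is_leaf(lab))
    leaves2 = sorted(lab for lab in t2.labels if t2.is_leaf(lab))
    for l2 in leaves2:
        for l1 in leaves1:
            if rng.random() < config.articulation_density:
                rel = _relation_of(ext2[l2], ext1[l1])
                arts.append(
                    Articulation(
                        left=t2.concept(l2),
                        right=t1.concept(l1),
                        relation=RelationSet.of(rel),
                    )
                )
    problem = AlignmentProblem(t1, t2, arts, ConstraintToggles())
    return problem, planted
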