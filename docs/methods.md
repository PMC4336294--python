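# Methods

## Model

A taxonomy is a single-rooted tree of concepts; an edge means set inclusion
of the child's referential extension in the parent's (⊆, not necessarily
strict). An alignment problem is two such trees T₁ (earlier) and T₂ (later),
a list of expert articulations — RCC-5 relation sets between cross-taxonomy
concept pairs, T₂ concept listed first — and three global constraints:

* **non-emptiness** — every concept has at least one instance. Default on;
  the reasoner requires it, because RCC-5 relations are undefined between
  empty extensions. The toggle exists on the problem object for
  completeness and validation, but reasoning with it off raises an error.
* **sibling disjointness** — children of one parent are mutually exclusive.
  Default on; relaxable globally.
* **coverage** — a parent equals the union of its children. Default on;
  relaxable per parent (`nc`). A consequence worth noting: a covered
  monotypic parent is extensionally *congruent* to its single child, which
  is exactly what drives several of the package's fixture results.

Reading tags (`OST`, `INT`, `INT/OST`) on articulations record whether the
expert intended an ostensive (member-pointing) or intensional
(property-based) interpretation. They are metadata only: intensional
readings are expressed by editing the input (adding implied-child concepts
and the corresponding articulations), never by changing the logic.

## Semantics: regions and zones

All reasoning is grounded in *candidate regions*. A region is a set of
concepts that may jointly contain a point of the domain. Restricted to one
taxonomy, a region must be upward closed (a point in a child is in every
ancestor), must not contain two siblings while sibling disjointness holds,
and must extend through every covered parent into at least one child. With
sibling disjointness on, the per-taxonomy patterns are exactly the root
chains ending at a leaf or a non-covered parent; with it off, all non-empty
upward-closed sets whose covered members retain a child. A candidate region
pairs one such pattern (or the empty pattern) from each taxonomy.

A *possible world* is an assignment of one base relation to every concept
pair (within and across taxonomies) realized by some set of occupied
regions: the relation of a pair is read off the emptiness pattern of its
three Euler zones (A∖B, A∩B, B∖A), a zone being occupied iff some occupied
region lies in it. World identity is the relation mapping, not the
witnessing region set — two region sets inducing the same relations are the
same alignment, which is what makes the enumerated counts meaningful.

## Solver

`enumerate_worlds` searches atomic relation assignments pair by pair:

1. **Domains.** Each pair's domain starts from zone feasibility (a base
   relation is feasible only if every zone it requires occupied has at least
   one candidate region) intersected with any articulations on the pair.
   This bakes the tree structure in: ancestor pairs get `{==, >}`, siblings
   get `{|}`, a covered monotypic parent is forced to `==` with its child.
2. **Propagation.** Incremental path consistency with the RCC-5 composition
   table prunes the search. The 25-entry table is stored as a frozen
   constant and re-derived in the tests by brute force over all triples of
   non-empty subsets of a four-point universe (a four-point universe
   realizes every composition case).
3. **Realizability.** A full atomic assignment is accepted iff it passes an
   exact model check: collect every candidate region not forbidden by a
   required-empty zone (the *maximal witness*), then verify that every
   required-occupied zone is inhabited by it. This check is sound and
   complete for the region semantics — if the maximal witness fails, no
   witness exists — so no path-consistency incompleteness can leak into the
   results. Non-emptiness needs no separate clause: every relation forces
   each of its endpoints to inhabit some zone.

Worlds are produced in lexicographic order of the relation assignment over
the sorted pair list, so output is deterministic without seeds. Enumeration
stops at a configurable cap (default 1000) with an explicit overflow flag;
counts from a truncated run are never used for sufficiency or repair
decisions.

`oracle_worlds` is the independent cross-check: it enumerates every subset
of the candidate regions as the occupied set, filters by non-emptiness and
the articulation zone patterns, projects to relation mappings and
deduplicates. It refuses instances above 22 candidate regions. The test
suite asserts solver ≡ oracle on all embedded fixtures and on 100 seeded
random problems.

## MIR and provenance

The MIR assigns to each ordered cross-taxonomy pair (T₂ first) the union of
the base relations realized across all worlds; the pair universe is the full
|T₁|×|T₂| grid. Provenance is three-way:

* *input* — the pair was asserted with a singleton relation;
* *deduced* — algebraic closure of the input articulations plus the tree
  edges alone (edges contribute non-strict inclusion `{==, >}`; no coverage
  reasoning) already yields a singleton;
* *inferred* — everything else.

Input entries are trivially deducible, so "immediately deducible" counts
include them. The deduced/inferred boundary is a definitional choice — the
closure criterion here reproduces the 4/4 split of the embedded 1936/1954
ostensive alignment. It does not reproduce every historically reported
split (the 1954/1986 alignment classifies 15/1 here rather than 12/4); no
formal definition of the boundary exists to calibrate against, so the
closure criterion is fixed and documented rather than tuned per case.

## Sufficiency and questions

`sufficient_subset` performs greedy deletion in file order: an articulation
is dropped permanently whenever dropping it leaves the world set (by
relation mapping) unchanged. The result is *sufficient* (identical world
set) and *minimal under deletion*, not globally minimum. It can be smaller
than an expert's hand-picked sufficient set: in the 1936/1954 ostensive
alignment, sibling disjointness plus the congruence
`1954.Pcarlud == 1936.ELLcarlud` already entail both exclusion
articulations, so greedy deletion keeps only the congruence. Both are valid
sufficient sets; this package reports the smaller one its algorithm finds.

`next_question` picks, among the cross-taxonomy pairs, the one whose
realized relation set over the remaining worlds is largest (ties broken
lexicographically): asking the expert to resolve that pair partitions the
world set most finely, and the partition property (no world lost or
duplicated across the possible answers) is asserted in the tests.

## Repair

`repair_options` enumerates all minimal correction sets up to `max_size`
(default 3) by breadth-first subset search with consistency checks, skipping
supersets of found repairs. Only articulations are candidates for removal:
relaxing coverage or inserting implied children are expert input edits, not
automated repairs. Beyond a handful of simultaneously erroneous
articulations the subset search grows combinatorially, hence the explicit
size bound. The search is exhaustive within the bound; when the documented
single-repair narrative for a fixture conflicts with exhaustive search (a
second minimal repair exists), the package reports all of them.

## Merge graphs

Both graph products are built from one world. Congruence clusters are the
equivalence classes under `==`; each node carries an *extension* — the set
of occupied regions containing its concepts — and inclusion edges are the
transitive reduction (via networkx) of strict extension containment. The
containment graph adds undirected overlap edges between `><` clusters. The
merge-concept graph instead resolves each overlapping cluster pair (X, Y)
into its occupied Euler regions, labelled `X*Y`, `X\Y`, `Y\X` with operands
in lexicographic order; a region that coincides extensionally with an
existing node becomes an extra label on that node rather than a duplicate.
Region existence is semantic (read off the world's occupied regions), so
empty regions are never drawn. Overlaps among more than two clusters are
handled pairwise. DOT output encodes provenance as grey boxes (both
taxonomies), yellow octagons (T₁ only) and green rectangles (T₂ only).

## Random problem generator

`random_problem` emulates expert-curated inputs for property testing. It
plants the ground truth first: two random trees (concept counts n₁, n₂,
branching bound `max_children`), leaf extensions drawn by assigning each
point of a shared universe to exactly one leaf per taxonomy (so sibling
disjointness and coverage hold by construction, and every leaf is
non-empty), the full relation mapping derived from the extensions, and then
a fraction `articulation_density` of the true cross-leaf relations emitted
as singleton articulations. The planted world is therefore always among the
worlds of the emitted problem. Defaults (n₁ = n₂ = 5, density 1.0) give
problems the size of the smallest published use-case alignments, where full
enumeration and the brute-force oracle are both exact and fast; the tests
sweep 2–7 concepts and densities 0–1.

What the generator does **not** emulate: disjunctive (uncertain) expert
articulations, erroneous articulations (its problems are consistent by
construction — inconsistency handling is exercised by explicit conflict
fixtures instead), non-default constraint toggles, implied-child editing,
and the skewed shapes of real revisions (outgroups, undersampled exemplar
phylogenies). Passing tests therefore certify the logic on well-formed
inputs; behaviour on the messier published alignments is exercised by the
embedded fixtures.

## Fixtures and problem sizes

The embedded fixtures are the two alignments of the use case whose inputs
are fully printed in the running text: 1936/1954 in five readings (ostensive
with and without the original disjunctive genus articulation,
intensional/ostensive, intensional, and the two underspecified variants
obtained by articulation removal) and the pairwise congruent 1954/1986
alignment. The four larger alignments (1986/2001, 2001/2006, 2006/2013,
2001/2013) depend on external supplementary data files; the loader raises a
clear error for them and accepts converted files in this package's dialect.
All shipped computations run on 6–8 concept problems and finish in well
under a second; the acceptance script's generator self-check uses 8–12
concept random problems.

## Numerical and degenerate-input choices

* The empty relation set is representable (lattice bottom) but illegal as
  input; it is reserved as the closure's inconsistency signal.
* `algebraic_closure` intersects converse entries first, so converse clashes
  (A > B with B > A) surface as inconsistency rather than silent repair.
* Ties everywhere break lexicographically on qualified concept ids; all
  operations are deterministic with no unseeded randomness.
* One-concept taxonomies are declared by a bare `(concept)` line; forests
  (multiple roots) are rejected by validation.
* Duplicate articulations are tolerated on input; sufficiency analysis
  removes the copies.

## Known limitations

* Alignments are pairwise; merging more than two taxonomies requires
  sequential runs on merged outputs and is out of scope.
* The deduced/inferred boundary is definitional (see above).
* Enumeration is exponential in the truly ambiguous pairs; heavily
  underspecified inputs hit the world cap by design rather than running
  unbounded.
* Intensional readings are represented only through edited inputs; no
  character data is consulted.
* Merge-concept labelling for three-way mutual overlap is pairwise; a
  dedicated composite-label scheme for such cases is future work.
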