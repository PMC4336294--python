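# taxalign

Logic-based alignment of biological taxonomies with RCC-5 articulations.

## The problem

Classifications and phylogenies change: names are reused, circumscriptions
are widened or split, ranks and clades are reshuffled. A *taxonomic concept*
— a name individuated by its source circumscription, e.g. *Perelleschus*
sec. Voss (1954) — makes those changes representable: an expert asserts
RCC-5 *articulations* between concepts of two taxonomies, and a reasoner
checks them for consistency, fills in everything they entail, and builds a
merge of the two trees. The five RCC-5 base relations compare the
referential extensions of two concepts A and B:

| relation | glyph | keyword | meaning |
|---|---|---|---|
| congruence | `==` | `equals` | A = B |
| proper inclusion | `>` | `includes` | A ⊃ B |
| inverse proper inclusion | `<` | `is_included_in` | A ⊂ B |
| overlap | `><` | `overlaps` | A∩B, A∖B, B∖A all non-empty |
| exclusion | `\|` | `disjoint` | A∩B = ∅ |

Disjunctions of base relations express expert uncertainty; the 2⁵ subsets
form a 32-element articulation lattice. Three relaxable constraints shape
the models: **non-emptiness** (every concept has an instance), **sibling
disjointness** (children of one parent exclude each other), and **coverage**
(a parent is the union of its children; relaxable per parent with an `nc`
flag).

Given two taxonomy trees T₁, T₂, articulations A and constraints C, the
package

* decides **consistency** and enumerates all **possible worlds** — the
  distinct assignments of one base relation to every concept pair that some
  finite set model realizes;
* computes the **maximally informative relations (MIR)**: for every ordered
  cross-taxonomy pair, the tightest relation set entailed across all worlds,
  classified as expert *input*, *immediately deducible* (algebraic closure
  of input plus tree edges), or *inferred* (full model-based reasoning);
* finds **sufficient inputs** (a deletion-minimal subset of articulations
  with the identical world set) and proposes the most informative **next
  question** when several worlds remain;
* explains inconsistent inputs by enumerating all minimal
  **articulation-removal repairs**;
* builds two merge visualizations per world: the **containment-with-overlap
  graph** (congruence clusters, reduced inclusion edges, lateral overlap
  edges) and the **merge-concept graph**, which resolves each overlap into
  its occupied Euler regions (`A*B` shared, `A\B` and `B\A` unique).

The solver searches atomic relation assignments with composition-table
propagation, and accepts an assignment only if it passes an exact,
region-based realizability check; an independent brute-force oracle
(`oracle_worlds`) enumerates occupied-region subsets directly and is used in
the tests to certify the solver on every small instance.

## Worked example

The weevil use case embedded in `taxalign.fixtures`: *Elleschus* sec.
Günther (1936) — one named species — aligned with *Perelleschus* sec. Voss
(1954) — three species, one of them congruent with the 1936 species.

```python
from taxalign import enumerate_worlds, mir_table, perelleschus, write_mir

problem = perelleschus(1, "OST")       # the ostensive reading: 3 articulations
worlds = enumerate_worlds(problem)
print(len(worlds))                     # -> 1  (a single consistent alignment)
print(write_mir(mir_table(problem, worlds)))
```

prints

```
left,relation,right,provenance
1954.Pcarlud,equals,1936.ELLcarlud,input
1954.Prectir,disjoint,1936.ELLcarlud,input
1954.Psubcin,disjoint,1936.ELLcarlud,input
1954.PER,includes,1936.ELLcarlud,deduced
1954.PER,includes,1936.ELL,inferred
1954.Pcarlud,equals,1936.ELL,inferred
1954.Prectir,disjoint,1936.ELL,inferred
1954.Psubcin,disjoint,1936.ELL,inferred
```

Eight MIR rows for six concepts: the three expert inputs, one relation
already deducible by algebraic closure, and four resolved only by model
reasoning — including the genus-level `1954.PER > 1936.ELL`, which the
expert never asserted. Because coverage makes the monotypic 1936 genus
congruent with its single species, the merge collapses
`{1936.ELL, 1936.ELLcarlud, 1954.Pcarlud}` into one cluster.

Removing articulations shows how ambiguity grows: the intensional/ostensive
variant (genus overlap plus an implied child `1936.ELL_IC`) has one world;
dropping `1954.PER | 1936.ELL_IC` yields 8 worlds; also dropping
`1954.PER >< 1936.ELL` yields 17, of which 7 place the 1954 genus above the
1936 genus and exactly 1 below it. See `examples/` for runnable scripts
covering each capability (world enumeration, MIR, repair, merge graphs,
random problem generation).

## Command line

```
taxalign check problem.txt            # consistent? how many worlds?
taxalign mir problem.txt -o out/      # MIR table as CSV
taxalign worlds problem.txt -o out/   # one relation table per world
taxalign merge problem.txt -o out/    # merge-concept DOT graph per world
taxalign repair problem.txt           # minimal repairs for inconsistent input
taxalign question problem.txt         # most informative next question
```

The problem file dialect (two taxonomy blocks of `(parent child ... [nc])`
lines, one articulation block of `[tax.concept relation tax.concept]`
statements) is documented in `taxalign.formats`.

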