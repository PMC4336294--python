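"""Inconsistency diagnosis: minimal articulation-removal repairs.

When an alignment problem admits no possible world, the conflict must lie in
the expert's articulations (the taxonomies themselves are internally
consistent trees).  A *repair option* is a minimal set of input articulations
whose removal restores consistency: removing the set yields at least one
world, and no proper subset of it does.  Only articulations are removal
candidates — relaxing constraints (e.g. non-coverage flags) or inserting
implied children are expert edits of the input, not automated repairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

from .model import AlignmentProblem, Articulation
from .reasoner import DEFAULT_WORLD_CAP, enumerate_worlds, is_consistent

__all__ = ["RepairOption", "RepairSearch", "repair_options", "DEFAULT_MAX_REPAIR_SIZE"]

# Diagnosis degrades beyond a handful of simultaneously erroneous
# articulations; larger searches must be requested explicitly.
DEFAULT_MAX_REPAIR_SIZE = 3


@dataclass(frozen=True)
class RepairOption:
    """A minimal correction set: remove these articulations (given by their
    positions in the input order) to restore consistency."""

    remove_indices: tuple[int, ...]
    remove: tuple[Articulation, ...]
    resulting_world_count: int
    world_count_truncated: bool = False

    def __str__(self) -> str:
        arts = "; ".join(str(a) for a in self.remove)
        worlds = f"{self.resulting_world_count}"
        if self.world_count_truncated:
            worlds = f">= {worlds}"
        return f"remove {arts} -> {worlds} possible world(s)"


@dataclass
class RepairSearch:
    """All minimal repair options found up to max_size, ordered by size then
    input position; ``truncated`` flags that none was found within the bound
    (or that larger minimal sets may exist beyond it)."""

    options: list[RepairOption] = field(default_factory=list)
    max_size: int = DEFAULT_MAX_REPAIR_SIZE
    truncated: bool = False

    def __iter__(self) -> Iterator[RepairOption]:
        return iter(self.options)

    def __len__(self) -> int:
        return len(self.options)

    def __getitem__(self, i):
        return self.options[i]


def repair_options(
    problem: AlignmentProblem,
    max_size: int = DEFAULT_MAX_REPAIR_SIZE,
    world_cap: int = DEFAULT_WORLD_CAP,
) -> RepairSearch:
    """All minimal correction sets of size <= max_size for an inconsistent
    problem, by breadth-first subset search with consistency checks.

    Raises ValueError if the problem is already consistent.  Minimality is
    guaranteed by the breadth-first order: a candidate set is skipped when it
    contains an already-found (smaller) correction set.
    """
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    if is_consistent(problem):
        raise ValueError("problem is consistent; there is nothing to repair")
    n = len(problem.articulations)
    found: list[tuple[int, ...]] = []
    options: list[RepairOption] = []
    for size in range(1, min(max_size, n) + 1):
        for combo in itertools.combinations(range(n), size):
            combo_set = set(combo)
            if any(set(f) <= combo_set for f in found):
                continue  # a proper subset already repairs: not minimal
            reduced = problem.without_articulations(combo)
            ws = enumerate_worlds(reduced, cap=world_cap)
            if ws.worlds:
                found.append(combo)
                options.append(
                    RepairOption(
                        remove_indices=combo,
                        remove=tuple(problem.articulations[i] for i in combo),
                        resulting_world_count=len(ws),
                        world_count_truncated=ws.truncated,
                    )
                )
    return RepairSearch(
        options=options, max_size=max_size, truncated=not options
    )
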