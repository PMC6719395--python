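"""Single-cell and long-read constraints on the PPM solution space.

A long read covering two mutations proves they arose in the same cellular
lineage: the pair must be ancestrally comparable (lie on one root-to-leaf
path) in any admissible tree.  An error-free single cell exposes the full
mutation set of one clone, which in a perfect phylogeny is exactly the set
of mutations on the root-to-clone path.  Two readings of the single-cell
constraint are supported:

- ``root_path`` (default, strict): the cell's mutation set must equal the
  label set of the root-to-v path for some vertex v;
- ``chain`` (weaker): every pair of mutations in the cell must be
  ancestrally comparable.

``root_path`` implies ``chain``.  Constraints are applied as filters over
enumerated or sampled solution sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import CloneTree, Solution, ValidationError

__all__ = [
    "ConstraintSet",
    "is_comparable",
    "satisfies_long_reads",
    "satisfies_single_cell",
    "satisfies_constraints",
    "filter_solutions",
    "CELL_MODES",
]

CELL_MODES = ("root_path", "chain")


@dataclass(frozen=True)
class ConstraintSet:
    """Constraints from long-read pairs and single-cell mutation sets."""

    long_read_pairs: frozenset[frozenset[str]] = frozenset()
    single_cells: tuple[frozenset[str], ...] = ()
    single_cell_mode: str = "root_path"

    def __post_init__(self):
        if self.single_cell_mode not in CELL_MODES:
            raise ValidationError(
                f"unknown single-cell mode {self.single_cell_mode!r}; "
                f"choose from {CELL_MODES}"
            )
        for pair in self.long_read_pairs:
            if len(pair) != 2:
                raise ValidationError(f"long-read pair must have 2 mutations: {set(pair)}")
        for cell in self.single_cells:
            if not cell:
                raise ValidationError("single-cell mutation sets must be non-empty")

    @classmethod
    def build(
        cls,
        pairs: Iterable[tuple[str, str]] = (),
        cells: Iterable[Iterable[str]] = (),
        mode: str = "root_path",
    ) -> "ConstraintSet":
        return cls(
            long_read_pairs=frozenset(frozenset(map(str, p)) for p in pairs),
            single_cells=tuple(frozenset(map(str, c)) for c in cells),
            single_cell_mode=mode,
        )

    def is_empty(self) -> bool:
        return not self.long_read_pairs and not self.single_cells


def is_comparable(T: CloneTree, c: str, d: str) -> bool:
    """True iff c is an ancestor of d or d an ancestor of c in T."""
    if c not in T.vertices:
        raise ValidationError(f"unknown mutation {c!r}")
    if d not in T.vertices:
        raise ValidationError(f"unknown mutation {d!r}")
    if c == d:
        raise ValidationError("comparability requires two distinct mutations")
    return T.is_ancestor(c, d) or T.is_ancestor(d, c)


def satisfies_long_reads(
    T: CloneTree, pairs: Iterable
) -> tuple[bool, frozenset[str] | None]:
    """Check all long-read pairs; returns (ok, first violating pair or None)."""
    for pair in pairs:
        c, d = sorted(pair)
        if not is_comparable(T, c, d):
            return False, frozenset(pair)
    return True, None


def satisfies_single_cell(T: CloneTree, S: Iterable[str], mode: str = "root_path") -> bool:
    """Check one cell's mutation set against tree T.

    ``root_path``: S equals the root-to-v path label set for some vertex v
    (v is forced to be the deepest member of S, so the check is linear).
    ``chain``: all pairs of S are ancestrally comparable.
    """
    S = set(map(str, S))
    if not S:
        raise ValidationError("single-cell mutation set must be non-empty")
    for s in S:
        if s not in T.vertices:
            raise ValidationError(f"unknown mutation {s!r}")
    if mode == "root_path":
        deepest = max(S, key=lambda v: len(T.path_from_root(v)))
        return set(T.path_from_root(deepest)) == S
    if mode == "chain":
        members = sorted(S)
        return all(
            is_comparable(T, members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        )
    raise ValidationError(f"unknown single-cell mode {mode!r}")


def satisfies_constraints(T: CloneTree, C: ConstraintSet) -> bool:
    ok, _ = satisfies_long_reads(T, C.long_read_pairs)
    if not ok:
        return False
    return all(
        satisfies_single_cell(T, S, C.single_cell_mode) for S in C.single_cells
    )


def filter_solutions(solutions: Sequence[Solution], C: ConstraintSet) -> list[Solution]:
    """Solutions passing every constraint; order preserved, size monotone."""
    return [s for s in solutions if satisfies_constraints(s.tree, C)]
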