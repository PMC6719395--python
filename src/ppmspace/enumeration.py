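"""Exhaustive enumeration of spanning arborescences and PPM solutions.

Arborescences are enumerated by growing a partial tree from a candidate root
and branching on one admissible frontier edge at a time: the recursion first
explores all arborescences containing the edge, then all arborescences
avoiding it (with a reachability check pruning dead branches).  This
include/exclude scheme partitions the tree set, so every arborescence is
emitted exactly once, and with a fixed vertex ordering the stream is
deterministic.

Solution enumeration additionally maintains the per-vertex sum-condition
slack (frequency minus sum of children's frequencies, per sample) as an
invariant of the growing tree: slack only decreases as children are added,
so a partial tree with negative slack anywhere can be abandoned without
losing any solution.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterator

from .core import (
    AncestryGraph,
    CloneTree,
    FrequencyMatrix,
    Solution,
    ValidationError,
    as_fraction,
    build_ancestry_graph,
    validate_frequency_matrix,
    verify_solution,
)
from .counting import count_arborescences_rooted

__all__ = [
    "InstanceTooLargeError",
    "enumerate_arborescences",
    "enumerate_solutions",
    "count_solutions",
    "DEFAULT_MAX_N",
]

DEFAULT_MAX_N = 13  # guard for exact counting; enumeration is exponential


class InstanceTooLargeError(ValueError):
    """Raised when exact enumeration is requested above the size guard."""


def _enumerate_rooted(
    G: AncestryGraph,
    root: int,
    slack_init: list[list[Fraction]] | None,
    eps: Fraction,
) -> Iterator[dict[int, int]]:
    """Yield parent vectors of all spanning arborescences rooted at root.

    ``slack_init`` (samples x vertices), when given, switches on
    sum-condition pruning; ``slack_init[p][v]`` must be f[p][v].
    """
    n = G.n_vertices
    out_adj: list[list[int]] = [[] for _ in range(n)]
    for c, d in G.edges:
        out_adj[c].append(d)
    for adj in out_adj:
        adj.sort()

    parent: dict[int, int] = {}
    in_tree = [False] * n
    in_tree[root] = True
    excluded: set[tuple[int, int]] = set()
    prune = slack_init is not None
    slack = [row[:] for row in slack_init] if prune else None
    m = len(slack) if prune else 0

    def frontier_edge() -> tuple[int, int] | None:
        for u in range(n):
            if not in_tree[u]:
                continue
            for v in out_adj[u]:
                if not in_tree[v] and (u, v) not in excluded:
                    return (u, v)
        return None

    def extension_possible() -> bool:
        # all non-tree vertices must be reachable from the tree via
        # non-excluded edges whose head is outside the tree
        seen = [False] * n
        stack = [v for v in range(n) if in_tree[v]]
        for v in stack:
            seen[v] = True
        while stack:
            u = stack.pop()
            for w in out_adj[u]:
                if not seen[w] and not in_tree[w] and (u, w) not in excluded:
                    seen[w] = True
                    stack.append(w)
        return all(seen)

    def rec() -> Iterator[dict[int, int]]:
        if len(parent) == n - 1:
            yield dict(parent)
            return
        e = frontier_edge()
        if e is None:
            return
        u, v = e
        # branch 1: include (u, v)
        feasible = True
        if prune:
            for p in range(m):
                slack[p][u] -= slack_init[p][v]
                # slack_init[p][v] is f[p][v]; v enters with no children
            feasible = all(slack[p][u] >= -eps for p in range(m))
        if feasible:
            parent[v] = u
            in_tree[v] = True
            yield from rec()
            in_tree[v] = False
            del parent[v]
        if prune:
            for p in range(m):
                slack[p][u] += slack_init[p][v]
        # branch 2: exclude (u, v)
        excluded.add((u, v))
        if extension_possible():
            yield from rec()
        excluded.remove((u, v))

    if len(G.reachable_from(root)) == n:
        yield from rec()


def enumerate_arborescences(
    G: AncestryGraph, root: int | str = "all"
) -> Iterator[CloneTree]:
    """Emit every spanning arborescence of G exactly once.

    ``root`` may be a vertex index or ``"all"`` (union over all candidate
    roots; distinct roots give distinct trees so no dedup is needed).  The
    stream is deterministic given the graph's vertex ordering, and its
    length equals the matrix-tree count.
    """
    if root == "all":
        roots = list(G.candidate_roots())
    else:
        roots = [int(root)]
    labels = G.labels
    for r in roots:
        for pv in _enumerate_rooted(G, r, None, Fraction(0)):
            yield CloneTree(labels[r], {labels[v]: labels[u] for v, u in pv.items()})


def enumerate_solutions(
    F: FrequencyMatrix, tol=0, prune: bool = True
) -> list[Solution]:
    """All PPM solutions of F: spanning arborescences of the ancestry graph
    that satisfy the sum condition, each packaged with its (B, U) pair.

    With ``prune=True`` partial trees whose slack is already negative are
    abandoned early; the output is identical to filtering the full
    arborescence stream.  An empty list means F is infeasible.
    """
    F = validate_frequency_matrix(F)
    eps = as_fraction(tol)
    G = build_ancestry_graph(F, tol)
    labels = F.mutation_labels
    f_by_vertex = [
        [F.values[p][v] for v in range(F.n_mutations)]
        for p in range(F.n_samples)
    ]
    solutions: list[Solution] = []
    for r in G.candidate_roots():
        slack_init = [row[:] for row in f_by_vertex] if prune else None
        for pv in _enumerate_rooted(G, r, slack_init, eps):
            tree = CloneTree(
                labels[r], {labels[v]: labels[u] for v, u in pv.items()}
            )
            from .core import check_sum_condition

            ok, _ = check_sum_condition(F, tree, tol)
            if ok:
                solutions.append(verify_solution(F, tree, tol))
    return solutions


def count_solutions(F: FrequencyMatrix, tol=0, max_n: int = DEFAULT_MAX_N) -> int:
    """Exact number of PPM solutions of F (exponential-time enumeration).

    Guarded by ``max_n`` because solution counting is #P-complete; raise the
    guard explicitly to go beyond it.
    """
    F = validate_frequency_matrix(F)
    if F.n_mutations > max_n:
        raise InstanceTooLargeError(
            f"instance too large for exact counting: n={F.n_mutations} > "
            f"max_n={max_n} (raise max_n to force)"
        )
    return len(enumerate_solutions(F, tol))
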