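"""Exact counting of spanning arborescences of an ancestry graph.

The number of spanning arborescences of a digraph rooted at vertex i is the
determinant of the Laplacian with row and column i removed (Tutte's directed
matrix-tree theorem); summing over all roots gives the total.  For an
ancestry graph that is a DAG with a unique source — the generic case, which
holds whenever the frequency matrix has no repeated columns — the count
collapses to the product of the in-degrees of the non-source vertices,
because a topological ordering makes the reduced Laplacian triangular.

The arborescence count is a polynomial-time upper bound on the number of
PPM solutions (the solutions are the arborescences that additionally satisfy
the sum condition; exact solution counting is #P-complete).

Determinants are computed by fraction-free (Bareiss) elimination over Python
integers, so counts are exact at any size that is enumerable in practice.
"""

from __future__ import annotations

from .core import (
    AncestryGraph,
    FrequencyMatrix,
    ValidationError,
    build_ancestry_graph,
    validate_frequency_matrix,
)

__all__ = [
    "laplacian",
    "integer_determinant",
    "count_arborescences_rooted",
    "count_arborescences_by_root",
    "count_arborescences_total",
    "count_arborescences_dag",
    "upper_bound_solutions",
]


def laplacian(G: AncestryGraph) -> list[list[int]]:
    """In-degree Laplacian L: L[j][j] = in-degree(j), L[i][j] = -1 on edges."""
    n = G.n_vertices
    L = [[0] * n for _ in range(n)]
    for i, j in G.edges:
        L[i][j] -= 1
        L[j][j] += 1
    return L


def integer_determinant(M: list[list[int]]) -> int:
    """Exact determinant of an integer matrix by Bareiss elimination.

    Fraction-free: every intermediate value is an integer, and Python's
    arbitrary-precision integers make the result exact at any size.
    """
    a = [row[:] for row in M]
    n = len(a)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            for i in range(k + 1, n):
                if a[i][k] != 0:
                    a[k], a[i] = a[i], a[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
            a[i][k] = 0
        prev = a[k][k]
    return sign * a[n - 1][n - 1]


def count_arborescences_rooted(G: AncestryGraph, i: int) -> int:
    """Number of spanning arborescences of G rooted at vertex i.

    Computed as det of the Laplacian with row/column i deleted; 0 when no
    arborescence rooted at i exists.
    """
    L = laplacian(G)
    reduced = [
        [L[r][c] for c in range(G.n_vertices) if c != i]
        for r in range(G.n_vertices)
        if r != i
    ]
    return integer_determinant(reduced)


def count_arborescences_by_root(G: AncestryGraph) -> dict[int, int]:
    """Per-root arborescence counts (only roots with a nonzero count)."""
    out = {}
    for i in range(G.n_vertices):
        n_i = count_arborescences_rooted(G, i)
        if n_i:
            out[i] = n_i
    return out


def count_arborescences_total(G: AncestryGraph) -> int:
    """Total number of spanning arborescences over all roots."""
    return sum(count_arborescences_rooted(G, i) for i in range(G.n_vertices))


def count_arborescences_dag(G: AncestryGraph) -> int:
    """In-degree-product shortcut for single-source DAGs.

    Equals the matrix-tree count rooted at the unique source; raises a
    dispatch error for cyclic graphs or graphs without a unique source so
    callers fall back to the general counter.
    """
    sources = G.source_vertices
    if len(sources) != 1:
        raise ValidationError(
            f"in-degree product requires a unique source vertex; found "
            f"{len(sources)} — use the general matrix-tree counter"
        )
    if not G.is_dag():
        raise ValidationError(
            "in-degree product requires a DAG — use the general "
            "matrix-tree counter"
        )
    (r,) = sources
    prod = 1
    for c in range(G.n_vertices):
        if c != r:
            prod *= G.in_degree(c)
    return prod


def upper_bound_solutions(F: FrequencyMatrix, tol=0) -> int:
    """Arborescence count of the ancestry graph: an upper bound on the
    number of PPM solutions of F."""
    F = validate_frequency_matrix(F)
    G = build_ancestry_graph(F, tol)
    if not F.has_duplicate_columns() and len(G.source_vertices) == 1:
        return count_arborescences_dag(G)
    return count_arborescences_total(G)
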