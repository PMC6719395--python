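"""Core domain types for the perfect phylogeny mixture (PPM) problem.

A PPM instance is an m x n frequency matrix F whose entry ``f[p][c]`` is the
fraction of cells in bulk sample ``p`` that carry mutation ``c``.  A solution
is a factorization F = U B where B is the genotype matrix of a complete
perfect phylogeny tree T (row c = mutations on the root-to-c path) and U is a
matrix of per-sample clone proportions.  Solutions are exactly the spanning
arborescences of the ancestry graph of F that satisfy the sum condition: in
every sample, each mutation's frequency is at least the sum of its tree
children's frequencies.

All frequencies are held as :class:`fractions.Fraction` so that ties — the
one genuinely degenerate configuration for the ancestry relation — are
resolved exactly.  Instances are small (tens of mutations), so exact
arithmetic costs nothing that matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "NotASolutionError",
    "FrequencyMatrix",
    "AncestryGraph",
    "CloneTree",
    "PerfectPhylogenyMatrix",
    "MixtureMatrix",
    "Solution",
    "as_fraction",
    "validate_frequency_matrix",
    "build_ancestry_graph",
    "branching_coefficient",
    "tree_to_b_matrix",
    "b_matrix_to_tree",
    "compute_mixture",
    "check_sum_condition",
    "verify_solution",
]


class ValidationError(ValueError):
    """Raised when an input object violates its defining conditions."""


class NotASolutionError(ValueError):
    """Raised when a tree fails the sum condition on a frequency matrix.

    Attributes
    ----------
    sample, mutation : str
        Labels of the first violating coordinate.
    """

    def __init__(self, message: str, sample: str, mutation: str):
        super().__init__(message)
        self.sample = sample
        self.mutation = mutation


def as_fraction(x) -> Fraction:
    """Convert a number to an exact Fraction.

    Floats are interpreted through their shortest round-trip decimal
    representation (``repr``), so 0.1 becomes 1/10 rather than the binary
    float it is stored as; strings are parsed as exact decimals or ``p/q``
    fractions.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, (int, np.integer)):
        return Fraction(int(x))
    if isinstance(x, (float, np.floating)):
        return Fraction(repr(float(x)))
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as an exact number")


# ---------------------------------------------------------------------------
# Frequency matrix


@dataclass(frozen=True)
class FrequencyMatrix:
    """An m x n matrix of mutation frequencies, entries in [0, 1]."""

    values: tuple[tuple[Fraction, ...], ...]
    sample_labels: tuple[str, ...]
    mutation_labels: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_labels)

    def column(self, j: int) -> tuple[Fraction, ...]:
        return tuple(row[j] for row in self.values)

    def __getitem__(self, key: tuple[int, int]) -> Fraction:
        p, c = key
        return self.values[p][c]

    def duplicate_column_groups(self) -> list[tuple[str, ...]]:
        """Groups (size >= 2) of mutation labels with identical columns."""
        seen: dict[tuple[Fraction, ...], list[str]] = {}
        for j, lab in enumerate(self.mutation_labels):
            seen.setdefault(self.column(j), []).append(lab)
        return [tuple(g) for g in seen.values() if len(g) > 1]

    def has_duplicate_columns(self) -> bool:
        return bool(self.duplicate_column_groups())

    def to_numpy(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.values])


def validate_frequency_matrix(
    raw,
    sample_labels: Sequence[str] | None = None,
    mutation_labels: Sequence[str] | None = None,
) -> FrequencyMatrix:
    """Validate a rectangular grid of proportions into a FrequencyMatrix.

    Raises
    ------
    ValidationError
        If the grid is empty or ragged, an entry lies outside [0, 1]
        (the error names the offending sample and mutation), or labels
        are duplicated.
    """
    if isinstance(raw, FrequencyMatrix):
        return raw
    rows = [list(r) for r in raw]
    if not rows or not rows[0]:
        raise ValidationError("frequency matrix must be non-empty")
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise ValidationError("frequency matrix must be rectangular")
    m = len(rows)
    if sample_labels is None:
        sample_labels = [f"sample{p + 1}" for p in range(m)]
    if mutation_labels is None:
        mutation_labels = [f"mut{c + 1}" for c in range(n)]
    sample_labels = tuple(str(s) for s in sample_labels)
    mutation_labels = tuple(str(c) for c in mutation_labels)
    if len(sample_labels) != m or len(mutation_labels) != n:
        raise ValidationError("label lists must match matrix dimensions")
    if len(set(sample_labels)) != m:
        raise ValidationError("duplicate sample labels")
    if len(set(mutation_labels)) != n:
        raise ValidationError("duplicate mutation labels")
    values = []
    for p, row in enumerate(rows):
        frow = []
        for c, x in enumerate(row):
            f = as_fraction(x)
            if not (0 <= f <= 1):
                raise ValidationError(
                    f"entry out of [0,1] at sample {sample_labels[p]!r}, "
                    f"mutation {mutation_labels[c]!r}: {x}"
                )
            frow.append(f)
        values.append(tuple(frow))
    return FrequencyMatrix(tuple(values), sample_labels, mutation_labels)


# ---------------------------------------------------------------------------
# Ancestry graph


@dataclass(frozen=True)
class AncestryGraph:
    """Directed graph on mutations encoding all pairwise frequency orders.

    Edge (c, d) is present iff mutation c's frequency is >= mutation d's in
    every sample (within the comparison tolerance used at construction).
    Vertices are 0-based indices aligned with ``labels``.
    """

    n_vertices: int
    edges: frozenset[tuple[int, int]]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != self.n_vertices:
            raise ValidationError("label count must equal vertex count")

    @property
    def source_vertices(self) -> tuple[int, ...]:
        """Vertices with in-degree zero."""
        heads = {d for _, d in self.edges}
        return tuple(v for v in range(self.n_vertices) if v not in heads)

    def in_neighbors(self, v: int) -> tuple[int, ...]:
        return tuple(sorted(c for c, d in self.edges if d == v))

    def out_neighbors(self, v: int) -> tuple[int, ...]:
        return tuple(sorted(d for c, d in self.edges if c == v))

    def in_degree(self, v: int) -> int:
        return sum(1 for _, d in self.edges if d == v)

    def is_dag(self) -> bool:
        import networkx as nx

        return nx.is_directed_acyclic_graph(self.to_networkx())

    def reachable_from(self, v: int) -> set[int]:
        out: dict[int, list[int]] = {u: [] for u in range(self.n_vertices)}
        for c, d in self.edges:
            out[c].append(d)
        seen = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for w in out[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    def candidate_roots(self) -> tuple[int, ...]:
        """Vertices from which every vertex is reachable (possible roots)."""
        return tuple(
            v
            for v in range(self.n_vertices)
            if len(self.reachable_from(v)) == self.n_vertices
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g


def build_ancestry_graph(F: FrequencyMatrix, tol=0) -> AncestryGraph:
    """Construct the ancestry graph of a frequency matrix.

    Edge (c, d) present iff ``f[p][c] >= f[p][d] - tol`` for all samples p.
    With the default ``tol=0`` comparisons are exact (rational); equal
    columns therefore produce 2-cycles, which downstream code handles via
    the general (cyclic) counting and sampling paths.
    """
    F = validate_frequency_matrix(F)
    eps = as_fraction(tol)
    n = F.n_mutations
    cols = [F.column(j) for j in range(n)]
    edges = set()
    for c in range(n):
        for d in range(n):
            if c == d:
                continue
            if all(cols[c][p] >= cols[d][p] - eps for p in range(F.n_samples)):
                edges.add((c, d))
    return AncestryGraph(n, frozenset(edges), F.mutation_labels)


def branching_coefficient(G: AncestryGraph) -> Fraction:
    """Fraction of unordered mutation pairs with no ancestry edge either way.

    Measures how much the data reveals branching: 0 means every pair is
    ordered (always the case with a single sample), 1 means no pair is.
    """
    n = G.n_vertices
    if n < 2:
        raise ValidationError("branching coefficient undefined for n < 2")
    incomparable = 0
    for c in range(n):
        for d in range(c + 1, n):
            if (c, d) not in G.edges and (d, c) not in G.edges:
                incomparable += 1
    return Fraction(incomparable, n * (n - 1) // 2)


# ---------------------------------------------------------------------------
# Clone trees and perfect phylogeny matrices


class CloneTree:
    """A rooted tree on mutation labels; each vertex introduces one mutation.

    The root carries the founder mutation.  ``parent`` maps every non-root
    mutation to its parent mutation.
    """

    __slots__ = ("root", "parent", "children", "_canonical")

    def __init__(self, root: str, parent: Mapping[str, str]):
        root = str(root)
        parent = {str(c): str(p) for c, p in parent.items()}
        if root in parent:
            raise ValidationError("root must not have a parent")
        vertices = {root} | set(parent) | set(parent.values())
        if set(parent.values()) - set(parent) - {root}:
            missing = set(parent.values()) - set(parent) - {root}
            raise ValidationError(f"parents {sorted(missing)} are not vertices")
        # every non-root vertex must reach the root without revisiting
        for v in parent:
            seen = {v}
            u = v
            while u != root:
                u = parent.get(u)
                if u is None:
                    raise ValidationError(f"vertex {v!r} is disconnected from root")
                if u in seen:
                    raise ValidationError(f"cycle through vertex {v!r}")
                seen.add(u)
        self.root = root
        self.parent = dict(parent)
        children: dict[str, list[str]] = {v: [] for v in vertices}
        for c, p in parent.items():
            children[p].append(c)
        self.children = {v: tuple(sorted(ch)) for v, ch in children.items()}
        self._canonical = tuple(sorted(self.parent.items()))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "CloneTree":
        """Build from (parent, child) pairs; root inferred as the label
        never appearing as a child."""
        edges = [(str(p), str(c)) for p, c in edges]
        children = [c for _, c in edges]
        if len(set(children)) != len(children):
            dup = sorted({c for c in children if children.count(c) > 1})
            raise ValidationError(f"repeated child labels: {dup}")
        parent = {c: p for p, c in edges}
        roots = {p for p, _ in edges} - set(children)
        if len(roots) != 1:
            if not roots:
                raise ValidationError("no root: edges form a cycle")
            raise ValidationError(f"multiple roots: {sorted(roots)}")
        return cls(roots.pop(), parent)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self.children)

    @property
    def n(self) -> int:
        return len(self.children)

    def edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, p in self.parent.items()}

    def path_from_root(self, v: str) -> tuple[str, ...]:
        """Labels on the root-to-v path, root first, v last."""
        if v not in self.children:
            raise ValidationError(f"unknown mutation {v!r}")
        path = [v]
        while v != self.root:
            v = self.parent[v]
            path.append(v)
        return tuple(reversed(path))

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff a == b or a lies on the root-to-b path."""
        return a in self.path_from_root(b)

    def subtree(self, v: str) -> Iterator[str]:
        stack = [v]
        while stack:
            u = stack.pop()
            yield u
            stack.extend(self.children[u])

    def canonical(self) -> tuple[tuple[str, str], ...]:
        """Sorted (child, parent) pairs; the identity used for dedup and
        as dictionary keys in sampling reports."""
        return self._canonical

    def __eq__(self, other):
        return (
            isinstance(other, CloneTree)
            and self.root == other.root
            and self._canonical == other._canonical
        )

    def __hash__(self):
        return hash((self.root, self._canonical))

    def __repr__(self):
        return f"CloneTree(root={self.root!r}, edges={sorted(self.edges())})"

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class PerfectPhylogenyMatrix:
    """n x n binary genotype matrix B of a complete perfect phylogeny tree.

    Row c holds the genotype of the clone introducing mutation c: exactly
    the mutations on the root-to-c path.
    """

    bits: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_numpy(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.int8)


@dataclass(frozen=True)
class MixtureMatrix:
    """m x n matrix U of clone proportions per sample; rows sum to <= 1."""

    values: tuple[tuple[Fraction, ...], ...]
    sample_labels: tuple[str, ...]
    mutation_labels: tuple[str, ...]

    def __post_init__(self):
        for p, row in enumerate(self.values):
            if any(not (0 <= u <= 1) for u in row):
                raise ValidationError(
                    f"mixture entry outside [0,1] in sample {self.sample_labels[p]!r}"
                )
            if sum(row) > 1:
                raise ValidationError(
                    f"mixture row sums to more than 1 in sample "
                    f"{self.sample_labels[p]!r}"
                )

    def to_numpy(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.values])


@dataclass(frozen=True)
class Solution:
    """A verified PPM solution: the tree, its B matrix, and mixture U."""

    tree: CloneTree
    b_matrix: PerfectPhylogenyMatrix
    mixture: MixtureMatrix
    frequencies: FrequencyMatrix


def tree_to_b_matrix(
    T: CloneTree, labels: Sequence[str] | None = None
) -> PerfectPhylogenyMatrix:
    """Genotype matrix of T: b[c][d] = 1 iff d is on the root-to-c path."""
    if labels is None:
        labels = sorted(T.vertices)
    labels = tuple(str(x) for x in labels)
    if set(labels) != set(T.vertices):
        raise ValidationError("labels must be exactly the tree's vertices")
    idx = {lab: j for j, lab in enumerate(labels)}
    bits = []
    for c in labels:
        row = [0] * len(labels)
        for d in T.path_from_root(c):
            row[idx[d]] = 1
        bits.append(tuple(row))
    return PerfectPhylogenyMatrix(tuple(bits), labels)


def b_matrix_to_tree(B: PerfectPhylogenyMatrix) -> CloneTree:
    """Recover the clone tree from a genotype matrix.

    Validates the three defining conditions of a complete perfect phylogeny
    matrix (unique founder row of weight 1; every other row has a unique
    parent row one lighter and componentwise dominated; unit diagonal) and
    raises a :class:`ValidationError` naming the violated condition.
    """
    bits = B.bits
    labels = B.labels
    n = len(labels)
    for c in range(n):
        if bits[c][c] != 1:
            raise ValidationError(
                f"condition 3 violated: diagonal entry for {labels[c]!r} is 0"
            )
    sums = [sum(row) for row in bits]
    roots = [c for c in range(n) if sums[c] == 1]
    if len(roots) != 1:
        raise ValidationError(
            f"condition 1 violated: {len(roots)} rows of weight 1 (need exactly 1)"
        )
    r = roots[0]
    parent: dict[str, str] = {}
    for d in range(n):
        if d == r:
            continue
        cands = [
            c
            for c in range(n)
            if sums[d] - sums[c] == 1
            and all(bits[d][e] >= bits[c][e] for e in range(n))
        ]
        if len(cands) != 1:
            raise ValidationError(
                f"condition 2 violated: vertex {labels[d]!r} has "
                f"{len(cands)} candidate parent rows (need exactly 1)"
            )
        parent[labels[d]] = labels[cands[0]]
    tree = CloneTree(labels[r], parent)
    # condition 2 guarantees consistency, but cheap to confirm the round trip
    if tree_to_b_matrix(tree, labels).bits != bits:
        raise ValidationError("matrix is not the genotype matrix of any tree")
    return tree


# ---------------------------------------------------------------------------
# The factorization F = U B


def compute_mixture(
    F: FrequencyMatrix, T: CloneTree
) -> list[list[Fraction]]:
    """Candidate mixture: u[p][c] = f[p][c] - sum of children's f[p][d].

    The result satisfies F = U B(T) exactly by construction but may contain
    negative entries; callers check the sum condition before promoting it to
    a :class:`MixtureMatrix`.
    """
    F = validate_frequency_matrix(F)
    if set(T.vertices) != set(F.mutation_labels):
        raise ValidationError("tree must span exactly the matrix's mutations")
    idx = {lab: j for j, lab in enumerate(F.mutation_labels)}
    U = []
    for p in range(F.n_samples):
        row = []
        for c in F.mutation_labels:
            u = F.values[p][idx[c]] - sum(
                (F.values[p][idx[d]] for d in T.children[c]), Fraction(0)
            )
            row.append(u)
        U.append(row)
    return U


def check_sum_condition(
    F: FrequencyMatrix, T: CloneTree, tol=0
) -> tuple[bool, tuple[str, str] | None]:
    """Check f[p][c] >= sum of children's frequencies, for all p and c.

    Returns (True, None) if the condition holds everywhere, otherwise
    (False, (sample_label, mutation_label)) for the first violation in
    row-major order.
    """
    F = validate_frequency_matrix(F)
    eps = as_fraction(tol)
    U = compute_mixture(F, T)
    for p in range(F.n_samples):
        for j, c in enumerate(F.mutation_labels):
            if U[p][j] < -eps:
                return False, (F.sample_labels[p], c)
    return True, None


def verify_solution(F: FrequencyMatrix, T: CloneTree, tol=0) -> Solution:
    """Build and verify the full solution (B, U) for tree T on instance F.

    Raises :class:`NotASolutionError` at the first sum-condition violation;
    otherwise asserts F = U B exactly and returns the packaged solution.
    """
    F = validate_frequency_matrix(F)
    ok, violation = check_sum_condition(F, T, tol)
    if not ok:
        p, c = violation
        raise NotASolutionError(
            f"not a solution: sum condition fails at sample {p!r}, mutation {c!r}",
            sample=p,
            mutation=c,
        )
    B = tree_to_b_matrix(T, F.mutation_labels)
    U = compute_mixture(F, T)
    eps = as_fraction(tol)
    # reconstruction check: (U B)[p][c] == f[p][c]
    n = F.n_mutations
    for p in range(F.n_samples):
        for c in range(n):
            recon = sum(
                (U[p][k] for k in range(n) if B.bits[k][c]), Fraction(0)
            )
            if abs(recon - F.values[p][c]) > eps:
                raise NotASolutionError(
                    "factorization mismatch at sample "
                    f"{F.sample_labels[p]!r}, mutation {F.mutation_labels[c]!r}",
                    sample=F.sample_labels[p],
                    mutation=F.mutation_labels[c],
                )
    clamped = tuple(
        tuple(max(Fraction(0), u) if -eps <= u < 0 else u for u in row)
        for row in U
    )
    mixture = MixtureMatrix(clamped, F.sample_labels, F.mutation_labels)
    return Solution(tree=T, b_matrix=B, mixture=mixture, frequencies=F)
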