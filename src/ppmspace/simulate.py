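"""Ground-truthed PPM instance simulator and evaluation metrics.

The simulation protocol mirrors the study conditions used throughout the
package's experiments: draw a complete perfect phylogeny tree T* on n
mutations, assign each clone v a proportion f(v) >= 0 with sum 1, then
produce m bulk samples by partitioning the clones into m non-empty parts and
renormalizing proportions within each part.  The induced frequency matrix
F = U B(T*) is exact (rational arithmetic throughout), so T* is always a
solution of its own instance — the basic sanity contract every experiment
relies on.

Tree topologies are uniform over labeled rooted trees (Pruefer sequence plus
a uniform root); clone proportions are symmetric Dirichlet (flat on the
simplex by default), rationalized onto a fixed denominator so downstream
arithmetic stays exact.  Both distributions are deliberate, documented
choices: the protocol fixes the grid of n, m, and replicate counts, not the
topology law.

Also here: simulated single-cell and long-read constraint generators (drawn
from T*, so they never eliminate the truth), binomial-free read-count export
at a fixed sequencing depth, and the edge-recall metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .core import (
    CloneTree,
    FrequencyMatrix,
    MixtureMatrix,
    ValidationError,
    validate_frequency_matrix,
)

__all__ = [
    "SimulatedInstance",
    "ReadCounts",
    "simulate_tree",
    "simulate_proportions",
    "mix_bulk_samples",
    "simulate_instance",
    "simulate_batch",
    "simulate_single_cells",
    "simulate_long_read_pairs",
    "export_read_counts",
    "edge_recall",
    "DEFAULT_GRID_N",
    "DEFAULT_GRID_M",
    "DEFAULT_TREES_PER_CELL",
    "PROPORTION_DENOMINATOR",
]

DEFAULT_GRID_N = (3, 5, 7, 9, 11, 13)
DEFAULT_GRID_M = (1, 2, 5, 10)
DEFAULT_TREES_PER_CELL = 10
PROPORTION_DENOMINATOR = 10**6


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SimulatedInstance:
    """A PPM instance together with the ground truth that generated it."""

    truth_tree: CloneTree
    clone_proportions: dict[str, Fraction]
    sample_partition: dict[str, int]
    frequency_matrix: FrequencyMatrix
    truth_mixture: MixtureMatrix
    seed: int | None = None
    n_samples_requested: int | None = None

    @property
    def n(self) -> int:
        return self.truth_tree.n

    @property
    def m(self) -> int:
        return self.frequency_matrix.n_samples


@dataclass(frozen=True)
class ReadCounts:
    """Variant (a) and total (d) read counts per sample and mutation."""

    variant: np.ndarray
    total: np.ndarray
    sample_labels: tuple[str, ...]
    mutation_labels: tuple[str, ...]

    def __post_init__(self):
        if (self.variant < 0).any() or (self.variant > self.total).any():
            raise ValidationError("need 0 <= variant <= total read counts")


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"mut{i + 1:0{width}d}" for i in range(n)]


def simulate_tree(n: int, rng=None, labels: Sequence[str] | None = None) -> CloneTree:
    """Draw a complete perfect phylogeny tree on n labeled mutations,
    uniformly over all n^(n-1) labeled rooted trees.

    A uniform Pruefer sequence gives a uniform unrooted labeled tree
    (Cayley: n^(n-2) of them); a uniform root choice then orients it.
    """
    if n < 1:
        raise ValidationError("need at least one mutation")
    rng = _as_rng(rng)
    if labels is None:
        labels = _default_labels(n)
    labels = [str(x) for x in labels]
    if len(labels) != n or len(set(labels)) != n:
        raise ValidationError("need n unique labels")
    if n == 1:
        return CloneTree(labels[0], {})
    if n == 2:
        r = int(rng.integers(2))
        return CloneTree(labels[r], {labels[1 - r]: labels[r]})
    prufer = [int(x) for x in rng.integers(0, n, size=n - 2)]
    degree = [1] * n
    for x in prufer:
        degree[x] += 1
    edges: list[tuple[int, int]] = []
    # smallest leaf first, standard decode
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    root = int(rng.integers(n))
    # orient away from root
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent: dict[str, str] = {}
    stack = [root]
    seen = {root}
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if b not in seen:
                seen.add(b)
                parent[labels[b]] = labels[a]
                stack.append(b)
    return CloneTree(labels[root], parent)


def simulate_proportions(
    T: CloneTree,
    rng=None,
    concentration: float = 1.0,
    denominator: int = PROPORTION_DENOMINATOR,
) -> dict[str, Fraction]:
    """Clone proportions f(v) >= 0 summing to exactly 1.

    A symmetric Dirichlet(concentration) draw (flat on the simplex at the
    default concentration 1), rationalized onto a fixed denominator: every
    clone gets at least 1/denominator so no clone is empty, and the total is
    exactly 1 so downstream rational arithmetic is exact.
    """
    rng = _as_rng(rng)
    labels = sorted(T.vertices)
    n = len(labels)
    if denominator < n:
        raise ValidationError("denominator must be at least the number of clones")
    raw = rng.dirichlet([concentration] * n)
    counts = np.maximum(1, np.rint(raw * denominator).astype(np.int64))
    # repair the sum exactly, never dropping a clone below 1
    diff = denominator - int(counts.sum())
    order = np.argsort(-counts)
    i = 0
    while diff != 0:
        j = int(order[i % n])
        step = 1 if diff > 0 else -1
        if counts[j] + step >= 1:
            counts[j] += step
            diff -= step
        i += 1
    return {lab: Fraction(int(c), denominator) for lab, c in zip(labels, counts)}


def _random_partition(labels: Sequence[str], m: int, rng) -> dict[str, int]:
    """Uniform assignment of labels to m parts, rejected until no part is
    empty."""
    n = len(labels)
    while True:
        assign = rng.integers(0, m, size=n)
        if len(set(int(a) for a in assign)) == m:
            return {lab: int(a) for lab, a in zip(labels, assign)}


def mix_bulk_samples(
    T: CloneTree,
    proportions: dict[str, Fraction],
    m: int,
    rng=None,
    seed: int | None = None,
    n_samples_requested: int | None = None,
) -> SimulatedInstance:
    """Produce m bulk samples by partitioning clones and renormalizing.

    Clones are split uniformly into m non-empty parts; within sample p the
    mixture weight of clone v is f(v) normalized over its part, zero
    elsewhere, so each mixture row sums to exactly 1.  The frequency of
    mutation c in sample p is the total weight of the clones below (and
    including) c, which is exactly (U B)[p][c].
    """
    rng = _as_rng(rng)
    labels = sorted(T.vertices)
    n = len(labels)
    if m > n:
        raise ValidationError(f"m > n: cannot split {n} clones into {m} non-empty parts")
    if m < 1:
        raise ValidationError("need at least one sample")
    if set(proportions) != set(labels):
        raise ValidationError("proportions must cover exactly the tree's clones")
    partition = _random_partition(labels, m, rng)
    part_sums = [
        sum((proportions[v] for v in labels if partition[v] == p), Fraction(0))
        for p in range(m)
    ]
    U = []
    for p in range(m):
        row = [
            proportions[v] / part_sums[p] if partition[v] == p else Fraction(0)
            for v in labels
        ]
        U.append(tuple(row))
    idx = {lab: j for j, lab in enumerate(labels)}
    Fvals = []
    for p in range(m):
        row = [Fraction(0)] * n
        for c in labels:
            row[idx[c]] = sum((U[p][idx[v]] for v in T.subtree(c)), Fraction(0))
        Fvals.append(tuple(row))
    sample_labels = tuple(f"sample{p + 1}" for p in range(m))
    F = FrequencyMatrix(tuple(Fvals), sample_labels, tuple(labels))
    mixture = MixtureMatrix(tuple(U), sample_labels, tuple(labels))
    return SimulatedInstance(
        truth_tree=T,
        clone_proportions=dict(proportions),
        sample_partition=partition,
        frequency_matrix=F,
        truth_mixture=mixture,
        seed=seed,
        n_samples_requested=n_samples_requested,
    )


def simulate_instance(
    n: int,
    m: int,
    rng=None,
    seed: int | None = None,
    concentration: float = 1.0,
) -> SimulatedInstance:
    """Convenience: tree + proportions + bulk mixing in one call.

    When the requested number of samples exceeds the number of clones, the
    effective number of samples is capped at n (the finest possible
    partition, where every sample is a single clone); the requested m is
    recorded on the instance.
    """
    if rng is None and seed is not None:
        rng = seed
    rng = _as_rng(rng)
    T = simulate_tree(n, rng)
    props = simulate_proportions(T, rng, concentration)
    m_eff = min(m, n)
    return mix_bulk_samples(
        T, props, m_eff, rng, seed=seed, n_samples_requested=m
    )


def simulate_batch(
    ns: Sequence[int] = DEFAULT_GRID_N,
    ms: Sequence[int] = DEFAULT_GRID_M,
    trees_per_cell: int = DEFAULT_TREES_PER_CELL,
    seed: int | None = None,
) -> list[SimulatedInstance]:
    """The full simulation grid: trees_per_cell trees per n, each mixed into
    bulk samples for every m (default 10 x 6 x 4 = 240 instances).

    Each replicate reuses one tree and one proportion draw across all values
    of m, so the effect of the number of samples is measured on the same
    underlying tumor.
    """
    rng = _as_rng(seed)
    instances = []
    for n in ns:
        for _ in range(trees_per_cell):
            T = simulate_tree(n, rng)
            props = simulate_proportions(T, rng)
            for m in ms:
                m_eff = min(m, n)
                instances.append(
                    mix_bulk_samples(
                        T, props, m_eff, rng, seed=seed, n_samples_requested=m
                    )
                )
    return instances


def simulate_single_cells(
    inst: SimulatedInstance, k: int, rng=None
) -> list[frozenset[str]]:
    """Simulate k error-free single cells from the truth tree.

    Each cell draws a clone v with probability f(v) (exact integer-weight
    draw) and reports the mutation set of that clone: the labels on the
    root-to-v path of T*.  Every emitted set therefore satisfies both
    single-cell constraint modes on T*.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    rng = _as_rng(rng)
    labels = sorted(inst.truth_tree.vertices)
    weights = [inst.clone_proportions[v] for v in labels]
    denom = np.lcm.reduce([w.denominator for w in weights]) if labels else 1
    int_weights = [int(w * int(denom)) for w in weights]
    cum = np.cumsum(int_weights)
    total = int(cum[-1])
    cells = []
    for _ in range(k):
        t = int(rng.integers(0, total))
        v = labels[int(np.searchsorted(cum, t, side="right"))]
        cells.append(frozenset(inst.truth_tree.path_from_root(v)))
    return cells


def simulate_long_read_pairs(
    inst: SimulatedInstance, k: int, rng=None
) -> list[frozenset[str]]:
    """Draw k distinct mutation pairs co-observed on long reads.

    Pairs are sampled uniformly without replacement from the ancestrally
    comparable pairs of T*, so every pair is consistent with the truth.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    rng = _as_rng(rng)
    T = inst.truth_tree
    comparable = []
    labels = sorted(T.vertices)
    for i, c in enumerate(labels):
        for d in labels[i + 1 :]:
            if T.is_ancestor(c, d) or T.is_ancestor(d, c):
                comparable.append(frozenset((c, d)))
    if k > len(comparable):
        raise ValidationError(
            f"only {len(comparable)} comparable pairs exist in the truth tree, "
            f"cannot draw {k}"
        )
    chosen = rng.choice(len(comparable), size=k, replace=False)
    return [comparable[int(i)] for i in sorted(chosen)]


def export_read_counts(
    F: FrequencyMatrix, depth: int = 1_000_000
) -> ReadCounts:
    """Error-free read counts at a fixed sequencing depth.

    Total reads d[p][c] = depth for every entry; variant reads
    a[p][c] = round(f[p][c] * depth) with round-half-even.  This is the
    standard export for feeding frequency-based instances to read-count
    tools: at large depth the likelihood is maximized at the true F.
    """
    F = validate_frequency_matrix(F)
    if depth < 1:
        raise ValidationError("depth must be positive")
    a = np.array(
        [[int(round(v * depth)) for v in row] for row in F.values], dtype=np.int64
    )
    d = np.full_like(a, depth)
    return ReadCounts(a, d, F.sample_labels, F.mutation_labels)


def edge_recall(T: CloneTree, T_star: CloneTree) -> float:
    """Fraction of true-tree edges recovered: |E(T) ∩ E(T*)| / |E(T*)|.

    Directed labeled edges; equals 1 iff the trees are identical (same
    mutation set required, n >= 2 so the denominator n-1 is positive).
    """
    if T.vertices != T_star.vertices:
        raise ValidationError("trees must be on the same mutation set")
    if T_star.n < 2:
        raise ValidationError("edge recall undefined for a single mutation")
    shared = len(T.edges() & T_star.edges())
    return shared / (T_star.n - 1)
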