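"""Uniform sampling of arborescences and rejection sampling of solutions.

Two uniform arborescence samplers are provided.  For the generic case —
ancestry graph is a DAG with a unique source r — every non-root vertex
independently picks a parent uniformly from its in-neighborhood; any such
parent assignment is an arborescence, and all arborescences are equally
likely.  For cyclic ancestry graphs (repeated frequency columns) a root is
drawn proportional to its exact matrix-tree count and a uniform arborescence
with that root is produced by the cycle-popping / loop-erased random walk of
Propp and Wilson; the mixture is uniform over all arborescences over all
roots.

Rejection sampling draws arborescences uniformly and keeps those that
satisfy the sum condition, which yields exactly uniform samples from the PPM
solution set.  The expected acceptance rate is (#solutions)/(#arborescences)
— the quantity that collapses to ~1e-10 around 21 mutations and makes
rejection sampling a small-n tool.  A chi-square goodness-of-fit audit
against the uniform distribution over a known support is included; it is the
same audit one can apply to tree samples imported from any other tool.

Sum-condition checks on the hot path use floating point with an exact
rational fallback whenever a slack lands within 1e-9 of zero, so exact ties
are never misclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core import (
    AncestryGraph,
    CloneTree,
    FrequencyMatrix,
    Solution,
    ValidationError,
    build_ancestry_graph,
    check_sum_condition,
    validate_frequency_matrix,
    verify_solution,
)
from .counting import count_arborescences_by_root, upper_bound_solutions

__all__ = [
    "SamplingReport",
    "ChiSquareResult",
    "InfeasibleError",
    "sample_arborescence_dag",
    "sample_arborescence_general",
    "sample_arborescence",
    "rejection_sample",
    "estimate_solution_fraction",
    "uniformity_chi_square",
    "DEFAULT_TRIAL_BUDGET",
]

DEFAULT_TRIAL_BUDGET = 10_000_000
_TIE_BAND = 1e-9


class InfeasibleError(RuntimeError):
    """Trial budget exhausted without a single accepted solution."""


@dataclass
class SamplingReport:
    """Audit record of a rejection-sampling run."""

    observed: dict[tuple[tuple[str, str], ...], int]
    trials: int
    acceptances: int
    acceptance_rate: float
    chi_square_stat: float
    p_value: float
    seed: int | None

    def __post_init__(self):
        assert self.acceptances == sum(self.observed.values())


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float
    n_incorrect: int
    incorrect_counts: dict


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_arborescence_dag(G: AncestryGraph, rng=None) -> CloneTree:
    """Uniform spanning arborescence of a single-source DAG.

    Each non-root vertex picks its parent uniformly and independently from
    its in-neighbors; cost is linear in the number of edges.
    """
    rng = _as_rng(rng)
    sources = G.source_vertices
    if len(sources) != 1 or not G.is_dag():
        raise ValidationError(
            "DAG sampler requires an acyclic graph with a unique source; "
            "use the general sampler"
        )
    (r,) = sources
    labels = G.labels
    parent = {}
    for v in range(G.n_vertices):
        if v == r:
            continue
        nbrs = G.in_neighbors(v)
        if not nbrs:
            raise ValidationError(f"vertex {labels[v]!r} has no in-neighbors")
        parent[labels[v]] = labels[nbrs[int(rng.integers(len(nbrs)))]]
    return CloneTree(labels[r], parent)


def sample_arborescence_general(G: AncestryGraph, rng=None) -> CloneTree:
    """Uniform spanning arborescence of an arbitrary digraph.

    A root is drawn proportional to its exact arborescence count, then a
    uniform arborescence with that root is generated by loop-erased random
    walks (Wilson's cycle-popping algorithm) on the reversed graph.  The
    output is uniform over all arborescences over all roots, which covers
    ancestry graphs with 2-cycles from repeated frequency columns.
    """
    rng = _as_rng(rng)
    draw = _make_general_sampler(G)
    return _parent_vector_tree(G, draw(rng))


def sample_arborescence(G: AncestryGraph, rng=None) -> CloneTree:
    """Uniform arborescence via the fast DAG path when applicable."""
    if len(G.source_vertices) == 1 and G.is_dag():
        return sample_arborescence_dag(G, rng)
    return sample_arborescence_general(G, rng)


class _FastSumCondition:
    """Float sum-condition check with an exact fallback near ties."""

    def __init__(self, F: FrequencyMatrix, tol=0):
        self.F = F
        self.tol = tol
        self.f = F.to_numpy()
        self.idx = {lab: j for j, lab in enumerate(F.mutation_labels)}
        self.band = _TIE_BAND + float(tol)

    def __call__(self, T: CloneTree) -> bool:
        f = self.f
        idx = self.idx
        min_slack = np.inf
        for c, kids in T.children.items():
            if not kids:
                continue
            slack = f[:, idx[c]] - sum(f[:, idx[d]] for d in kids)
            s = slack.min()
            if s < min_slack:
                min_slack = s
        if min_slack > self.band:
            return True
        if min_slack < -self.band:
            return False
        ok, _ = check_sum_condition(self.F, T, self.tol)
        return ok


def _dag_structure(G: AncestryGraph):
    """(root, in-neighbor lists) if G is a single-source DAG, else None."""
    sources = G.source_vertices
    if len(sources) != 1 or not G.is_dag():
        return None
    (r,) = sources
    return r, [G.in_neighbors(v) for v in range(G.n_vertices)]


def _make_general_sampler(G: AncestryGraph):
    """Closure drawing uniform arborescences of an arbitrary digraph with
    the root distribution and adjacency precomputed once."""
    by_root = count_arborescences_by_root(G)
    if not by_root:
        raise ValidationError(
            "graph has no spanning arborescence (no vertex reaches all others)"
        )
    roots = sorted(by_root)
    total = sum(by_root.values())
    n = G.n_vertices
    in_nbrs = [G.in_neighbors(v) for v in range(n)]

    def draw(rng) -> dict[int, int]:
        ticket = (int(rng.integers(0, 2**62)) * total) >> 62
        r = roots[-1]
        acc = 0
        for cand in roots:
            acc += by_root[cand]
            if ticket < acc:
                r = cand
                break
        nxt: dict[int, int] = {}
        in_tree = [False] * n
        in_tree[r] = True
        for start in range(n):
            u = start
            while not in_tree[u]:
                nbrs = in_nbrs[u]
                nxt[u] = nbrs[int(rng.integers(len(nbrs)))]
                u = nxt[u]
            u = start
            while not in_tree[u]:
                in_tree[u] = True
                u = nxt[u]
        return nxt

    return draw


def _parent_vector_tree(G: AncestryGraph, pv: dict[int, int]) -> CloneTree:
    labels = G.labels
    roots = [v for v in range(G.n_vertices) if v not in pv]
    (r,) = roots
    return CloneTree(labels[r], {labels[v]: labels[u] for v, u in pv.items()})


def _dag_trial_stream(F: FrequencyMatrix, G: AncestryGraph, dag, rng, tol,
                      batch: int = 1024):
    """Endless stream of (passes_sum_condition, canonical_key) for uniform
    DAG arborescence draws, vectorized over batches of trials.

    Slacks are evaluated in floating point for the whole batch at once; any
    trial whose minimum slack falls in the tie band is re-checked exactly.
    """
    root, in_nbrs = dag
    n = G.n_vertices
    labels = G.labels
    nonroot = [v for v in range(n) if v != root]
    nbr_arrays = [np.asarray(in_nbrs[v], dtype=np.int64) for v in nonroot]
    f = F.to_numpy()
    band = _TIE_BAND + float(tol)
    bidx = np.arange(batch)[:, None]
    vidx = np.asarray(nonroot, dtype=np.int64)[None, :]
    while True:
        P = np.empty((batch, len(nonroot)), dtype=np.int64)
        for j, arr in enumerate(nbr_arrays):
            P[:, j] = arr[rng.integers(0, len(arr), size=batch)]
        one_hot = np.zeros((batch, n, n))
        one_hot[bidx, vidx, P] = 1.0
        slack = f[None, :, :] - np.einsum("pv,bvu->bpu", f, one_hot)
        mins = slack.min(axis=(1, 2))
        for b in range(batch):
            if mins[b] < -band:
                yield False, None
                continue
            key = tuple(
                sorted((labels[v], labels[P[b, j]]) for j, v in enumerate(nonroot))
            )
            if mins[b] > band:
                ok = True
            else:
                tree = CloneTree(labels[root], dict(key))
                ok, _ = check_sum_condition(F, tree, tol)
            yield ok, key


def rejection_sample(
    F: FrequencyMatrix,
    k: int,
    rng=None,
    tol=0,
    max_trials: int = DEFAULT_TRIAL_BUDGET,
    seed: int | None = None,
) -> tuple[list[Solution], SamplingReport]:
    """Sample k solutions of F uniformly at random by rejection.

    Arborescences of the ancestry graph are drawn uniformly; those passing
    the sum condition are kept.  Accepted trees are exactly uniform over the
    solution set.  Raises :class:`InfeasibleError` if the trial budget runs
    out with zero acceptances (the instance may be infeasible or the
    acceptance rate too low; the error reports the arborescence-count upper
    bound).
    """
    F = validate_frequency_matrix(F)
    if seed is not None and rng is None:
        rng = seed
    rng = _as_rng(rng)
    G = build_ancestry_graph(F, tol)
    dag = _dag_structure(G)
    if dag is not None:
        trial_iter = _dag_trial_stream(F, G, dag, rng, tol)
    else:
        general_draw = _make_general_sampler(G)
        sc_ok = _FastSumCondition(F, tol)

        def _general_stream():
            while True:
                T = _parent_vector_tree(G, general_draw(rng))
                yield sc_ok(T), T.canonical()

        trial_iter = _general_stream()
    observed: dict = {}
    trials = 0
    acceptances = 0
    while acceptances < k:
        if trials >= max_trials:
            if acceptances == 0:
                raise InfeasibleError(
                    f"no solution found in {trials} trials; instance may be "
                    f"infeasible or acceptance rate too low "
                    f"(arborescence upper bound: {upper_bound_solutions(F, tol)})"
                )
            break
        ok, key = next(trial_iter)
        trials += 1
        if ok:
            acceptances += 1
            observed[key] = observed.get(key, 0) + 1
    root_label = G.labels[dag[0]] if dag is not None else None
    solutions = []
    for key in sorted(observed):
        parent = dict(key)
        root = root_label
        if root is None:
            (root,) = set(p for _, p in key) - set(c for c, _ in key)
        solutions.append(verify_solution(F, CloneTree(root, parent), tol))
    if len(observed) >= 2:
        chi = uniformity_chi_square(observed, list(observed))
        stat, p = chi.statistic, chi.p_value
    else:
        stat, p = 0.0, 1.0
    report = SamplingReport(
        observed=observed,
        trials=trials,
        acceptances=acceptances,
        acceptance_rate=acceptances / trials if trials else 0.0,
        chi_square_stat=stat,
        p_value=p,
        seed=seed,
    )
    return solutions, report


def estimate_solution_fraction(F: FrequencyMatrix, trials: int, rng=None, tol=0) -> float:
    """Unbiased estimate of (#solutions)/(#arborescences) for F.

    The fraction of uniformly drawn arborescences that satisfy the sum
    condition; also the expected acceptance rate of rejection sampling.
    """
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    F = validate_frequency_matrix(F)
    rng = _as_rng(rng)
    G = build_ancestry_graph(F, tol)
    dag = _dag_structure(G)
    if dag is not None:
        stream = _dag_trial_stream(F, G, dag, rng, tol)
        hits = sum(1 for _ in range(trials) if next(stream)[0])
    else:
        draw = _make_general_sampler(G)
        sc_ok = _FastSumCondition(F, tol)
        hits = sum(
            1
            for _ in range(trials)
            if sc_ok(_parent_vector_tree(G, draw(rng)))
        )
    return hits / trials


def uniformity_chi_square(
    observed: Mapping, support: Iterable
) -> ChiSquareResult:
    """Pearson chi-square test of observed tree counts against uniformity.

    ``observed`` maps canonical tree keys to counts; ``support`` is the set
    of trees the uniform hypothesis ranges over (typically the enumerated
    solution set).  Support trees with zero observations contribute their
    expected count.  Observed keys outside the support are excluded from the
    test and returned separately as incorrect-solution counts.  A support of
    size < 2 yields p = 1 by convention (with a warning).
    """
    support = list(support)
    if not support:
        raise ValidationError("support must be non-empty")
    support_set = set(support)
    incorrect = {k: v for k, v in observed.items() if k not in support_set}
    counts = [observed.get(k, 0) for k in support]
    total = sum(counts)
    if len(support) < 2:
        warnings.warn("support has fewer than 2 trees; chi-square undefined, p=1")
        return ChiSquareResult(0.0, 1.0, sum(incorrect.values()), incorrect)
    if total == 0:
        raise ValidationError("no observations within the support")
    expected = total / len(support)
    if expected < 5:
        warnings.warn(
            f"expected count per tree is {expected:.2f} < 5; chi-square "
            "approximation may be poor — draw more samples"
        )
    stat, p = stats.chisquare(counts)
    return ChiSquareResult(float(stat), float(p), sum(incorrect.values()), incorrect)
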