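import itertools
from fractions import Fraction

import numpy as np
import pytest

import ppmspace as pp
from ppmspace.core import AncestryGraph, CloneTree


# ---------------------------------------------------------------------------
# Small worked instances used across modules


@pytest.fixture
def chain_instance():
    """Single-sample instance whose ancestry graph is a total order."""
    return pp.validate_frequency_matrix([[0.8, 0.5, 0.2]])


@pytest.fixture
def chain_tree():
    return CloneTree("mut1", {"mut2": "mut1", "mut3": "mut2"})


@pytest.fixture
def star_tree():
    return CloneTree("mut1", {"mut2": "mut1", "mut3": "mut1"})


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the library's algorithms)


def brute_force_arborescences(n_vertices, edges, root):
    """All spanning arborescences rooted at root, by exhausting parent
    assignments over in-neighbors and keeping the acyclic ones."""
    in_nbrs = {
        v: [c for c, d in edges if d == v] for v in range(n_vertices) if v != root
    }
    if any(not nb for nb in in_nbrs.values()):
        return []
    result = []
    non_roots = sorted(in_nbrs)
    for choice in itertools.product(*(in_nbrs[v] for v in non_roots)):
        parent = dict(zip(non_roots, choice))
        ok = True
        for v in non_roots:
            seen = {v}
            u = v
            while u != root:
                u = parent[u]
                if u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            result.append(parent)
    return result


def brute_force_solution_trees(F):
    """All solution trees of F: arborescences of the ancestry graph over all
    candidate roots, filtered by the sum condition (no pruning)."""
    G = pp.build_ancestry_graph(F)
    labels = F.mutation_labels
    trees = []
    for root in range(G.n_vertices):
        for pv in brute_force_arborescences(G.n_vertices, G.edges, root):
            tree = CloneTree(
                labels[root], {labels[v]: labels[u] for v, u in pv.items()}
            )
            ok, _ = pp.check_sum_condition(F, tree)
            if ok:
                trees.append(tree)
    return trees


def random_graph(rng, n, p=0.5):
    edges = frozenset(
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    )
    return AncestryGraph(n, edges, tuple(f"v{i}" for i in range(n)))


def random_single_source_dag(rng, n):
    """Random DAG on 0..n-1 with all edges i->j for i<j present with prob,
    vertex 0 forced to be the unique source with everything reachable."""
    edges = set((0, j) for j in range(1, n))
    for i in range(1, n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges.add((i, j))
    return AncestryGraph(n, frozenset(edges), tuple(f"v{i}" for i in range(n)))
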