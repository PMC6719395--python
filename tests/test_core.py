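from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppmspace as pp
from ppmspace.core import CloneTree, NotASolutionError, ValidationError


# ---------------------------------------------------------------------------
# Frequency matrix validation


class TestValidateFrequencyMatrix:
    def test_valid_matrix(self):
        F = pp.validate_frequency_matrix([[0.8, 0.5, 0.2]])
        assert (F.n_samples, F.n_mutations) == (1, 3)
        assert not F.has_duplicate_columns()

    def test_duplicate_columns_reported(self):
        F = pp.validate_frequency_matrix([[0.5, 0.5]])
        assert F.duplicate_column_groups() == [("mut1", "mut2")]

    @pytest.mark.parametrize("bad", [[[1.2]], [[-0.1]]])
    def test_entry_out_of_range(self, bad):
        with pytest.raises(ValidationError, match="out of \\[0,1\\]"):
            pp.validate_frequency_matrix(bad)

    def test_ragged_and_empty(self):
        with pytest.raises(ValidationError):
            pp.validate_frequency_matrix([[0.5, 0.5], [0.5]])
        with pytest.raises(ValidationError):
            pp.validate_frequency_matrix([])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            pp.validate_frequency_matrix([[0.5, 0.4]], mutation_labels=["a", "a"])

    def test_exact_decimal_parsing(self):
        F = pp.validate_frequency_matrix([["0.1", 0.2]])
        assert F.values[0][0] == Fraction(1, 10)
        assert F.values[0][1] == Fraction(1, 5)


# ---------------------------------------------------------------------------
# Ancestry graph


class TestAncestryGraph:
    def test_single_sample_total_order(self, chain_instance):
        G = pp.build_ancestry_graph(chain_instance)
        assert G.edges == {(0, 1), (0, 2), (1, 2)}

    def test_opposite_orders_give_incomparable_pair(self):
        F = pp.validate_frequency_matrix([[0.7, 0.4, 0.2], [0.7, 0.2, 0.4]])
        G = pp.build_ancestry_graph(F)
        assert G.edges == {(0, 1), (0, 2)}

    def test_equal_columns_give_two_cycle(self):
        G = pp.build_ancestry_graph(pp.validate_frequency_matrix([[0.5, 0.5]]))
        assert G.edges == {(0, 1), (1, 0)}
        assert not G.is_dag()

    def test_tolerance_adds_edges(self):
        F = pp.validate_frequency_matrix([[0.5, 0.45]])
        assert pp.build_ancestry_graph(F).edges == {(0, 1)}
        assert pp.build_ancestry_graph(F, tol=0.1).edges == {(0, 1), (1, 0)}


@st.composite
def frequency_grids(draw, max_m=3, max_n=6):
    m = draw(st.integers(1, max_m))
    n = draw(st.integers(2, max_n))
    # coarse grid of rationals so that ties actually happen
    cell = st.integers(0, 4).map(lambda k: Fraction(k, 4))
    return draw(
        st.lists(st.lists(cell, min_size=n, max_size=n), min_size=m, max_size=m)
    )


class TestAncestryGraphProperties:
    @settings(max_examples=150, derandomize=True)
    @given(frequency_grids())
    def test_reachability_implies_direct_edge(self, grid):
        """Transitivity: the ancestry graph equals its transitive closure."""
        import networkx as nx

        G = pp.build_ancestry_graph(pp.validate_frequency_matrix(grid))
        closure = nx.transitive_closure(G.to_networkx())
        closure_edges = {(u, v) for u, v in closure.edges() if u != v}
        assert closure_edges == set(G.edges)

    @settings(max_examples=150, derandomize=True)
    @given(frequency_grids())
    def test_incomparable_iff_oppositely_ordered_samples(self, grid):
        F = pp.validate_frequency_matrix(grid)
        G = pp.build_ancestry_graph(F)
        n = F.n_mutations
        for c in range(n):
            for d in range(c + 1, n):
                incomparable = (c, d) not in G.edges and (d, c) not in G.edges
                opposite = any(
                    F.values[p][c] > F.values[p][d] for p in range(F.n_samples)
                ) and any(
                    F.values[q][c] < F.values[q][d] for q in range(F.n_samples)
                )
                assert incomparable == opposite

    @settings(max_examples=150, derandomize=True)
    @given(frequency_grids())
    def test_acyclic_iff_no_repeated_columns(self, grid):
        F = pp.validate_frequency_matrix(grid)
        G = pp.build_ancestry_graph(F)
        assert G.is_dag() == (not F.has_duplicate_columns())

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10))
    def test_branching_coefficient_zero_for_single_sample(self, row):
        G = pp.build_ancestry_graph(pp.validate_frequency_matrix([row]))
        assert pp.branching_coefficient(G) == 0


class TestBranchingCoefficient:
    def test_one_incomparable_pair_of_three(self):
        F = pp.validate_frequency_matrix([[0.7, 0.4, 0.2], [0.7, 0.2, 0.4]])
        assert pp.branching_coefficient(pp.build_ancestry_graph(F)) == Fraction(1, 3)

    def test_undefined_below_two_vertices(self):
        G = pp.build_ancestry_graph(pp.validate_frequency_matrix([[0.5]]))
        with pytest.raises(ValidationError):
            pp.branching_coefficient(G)


# ---------------------------------------------------------------------------
# Trees and genotype matrices


class TestTreeBMatrix:
    def test_chain_paths(self, chain_tree):
        B = pp.tree_to_b_matrix(chain_tree, ["mut1", "mut2", "mut3"])
        assert B.bits == ((1, 0, 0), (1, 1, 0), (1, 1, 1))

    def test_star_paths(self, star_tree):
        B = pp.tree_to_b_matrix(star_tree, ["mut1", "mut2", "mut3"])
        assert B.bits == ((1, 0, 0), (1, 1, 0), (1, 0, 1))

    def test_single_vertex(self):
        B = pp.tree_to_b_matrix(CloneTree("m", {}))
        assert B.bits == ((1,),)

    @pytest.mark.parametrize(
        "bits",
        [((1, 0, 0), (1, 1, 0), (1, 1, 1)), ((1, 0, 0), (1, 1, 0), (1, 0, 1))],
    )
    def test_round_trip(self, bits):
        B = pp.PerfectPhylogenyMatrix(bits, ("mut1", "mut2", "mut3"))
        tree = pp.b_matrix_to_tree(B)
        assert pp.tree_to_b_matrix(tree, B.labels).bits == bits

    def test_orphan_row_rejected_with_named_condition(self):
        # row m2 = 010 has no parent row; this also duplicates the weight-1
        # row, so the first condition in definition order is reported
        B = pp.PerfectPhylogenyMatrix(
            ((1, 0, 0), (0, 1, 0), (1, 1, 1)), ("m1", "m2", "m3")
        )
        with pytest.raises(ValidationError, match="condition 1"):
            pp.b_matrix_to_tree(B)

    def test_missing_parent_row_names_condition_two(self):
        # m3's row has weight 3 but no row of weight 2 is dominated by it
        B = pp.PerfectPhylogenyMatrix(
            ((1, 0, 0, 0), (1, 1, 0, 0), (1, 0, 1, 1), (1, 1, 0, 1)),
            ("m1", "m2", "m3", "m4"),
        )
        with pytest.raises(ValidationError, match="condition 2"):
            pp.b_matrix_to_tree(B)

    def test_zero_diagonal_names_condition_three(self):
        with pytest.raises(ValidationError, match="condition 3"):
            pp.b_matrix_to_tree(pp.PerfectPhylogenyMatrix(((0, 1), (1, 1)), ("a", "b")))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 10))
    def test_round_trip_on_random_trees(self, seed, n):
        tree = pp.simulate_tree(n, np.random.default_rng(seed))
        B = pp.tree_to_b_matrix(tree)
        assert pp.b_matrix_to_tree(B) == tree


class TestCloneTreeValidation:
    def test_cycle_detected(self):
        with pytest.raises(ValidationError):
            CloneTree("r", {"a": "b", "b": "a"})

    def test_from_edges_infers_root(self):
        tree = CloneTree.from_edges([("1", "2"), ("2", "3")])
        assert tree.root == "1"
        assert tree.path_from_root("3") == ("1", "2", "3")

    def test_repeated_child_rejected(self):
        with pytest.raises(ValidationError, match="repeated child"):
            CloneTree.from_edges([("1", "3"), ("2", "3")])


# ---------------------------------------------------------------------------
# Mixture / sum condition / solution verification


class TestMixtureAndSumCondition:
    def test_chain_mixture(self, chain_instance, chain_tree):
        U = pp.compute_mixture(chain_instance, chain_tree)
        assert U == [[Fraction(3, 10), Fraction(3, 10), Fraction(1, 5)]]

    def test_star_mixture_can_go_negative(self, star_tree):
        F = pp.validate_frequency_matrix([[0.8, 0.5, 0.4]])
        U = pp.compute_mixture(F, star_tree)
        assert U[0][0] == Fraction(-1, 10)

    def test_single_vertex(self):
        F = pp.validate_frequency_matrix([[0.7]], mutation_labels=["m"])
        assert pp.compute_mixture(F, CloneTree("m", {})) == [[Fraction(7, 10)]]

    def test_sum_condition_pass(self, chain_instance, star_tree):
        ok, violation = pp.check_sum_condition(chain_instance, star_tree)
        assert ok and violation is None

    def test_sum_condition_violation_coordinates(self, star_tree):
        F = pp.validate_frequency_matrix([[0.8, 0.5, 0.4]])
        ok, violation = pp.check_sum_condition(F, star_tree)
        assert not ok
        assert violation == ("sample1", "mut1")

    def test_verify_solution_builds_mixture(self, chain_instance, chain_tree):
        sol = pp.verify_solution(chain_instance, chain_tree)
        assert sol.mixture.values[0] == (
            Fraction(3, 10),
            Fraction(3, 10),
            Fraction(1, 5),
        )

    def test_verify_solution_raises_with_coordinate(self, star_tree):
        F = pp.validate_frequency_matrix([[0.8, 0.5, 0.4]])
        with pytest.raises(NotASolutionError) as exc:
            pp.verify_solution(F, star_tree)
        assert (exc.value.sample, exc.value.mutation) == ("sample1", "mut1")

    def test_two_sample_star_solution(self, star_tree):
        F = pp.validate_frequency_matrix([[0.7, 0.4, 0.2], [0.7, 0.2, 0.4]])
        sol = pp.verify_solution(F, star_tree)
        expect = (
            (Fraction(1, 10), Fraction(2, 5), Fraction(1, 5)),
            (Fraction(1, 10), Fraction(1, 5), Fraction(2, 5)),
        )
        assert sol.mixture.values == expect

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 7), st.integers(1, 3))
    def test_factorization_reconstructs_f_exactly(self, seed, n, m):
        """U B(T) reproduces F entry for entry, in exact rationals."""
        rng = np.random.default_rng(seed)
        inst = pp.simulate_instance(n, min(m, n), rng)
        F = inst.frequency_matrix
        sol = pp.verify_solution(F, inst.truth_tree)
        B = sol.b_matrix.bits
        n_ = F.n_mutations
        for p in range(F.n_samples):
            for c in range(n_):
                recon = sum(
                    sol.mixture.values[p][k] for k in range(n_) if B[k][c]
                )
                assert recon == F.values[p][c]
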