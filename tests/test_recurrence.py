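"""The class recurrence: mixing step, combination kernel, tree traversal.

The decisive test is equivalence with the exact enumeration oracle, which
computes the accuracies straight from their definition.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fitchacc import (
    ClassPartition,
    DomainError,
    accuracies_from_classvector,
    branch_mixing,
    build_combination_kernel,
    combine_children,
    exact_enumeration_accuracy,
    leaf_class_vector,
    tree_accuracy,
)
from tests.conftest import build_from_shape, tree_shapes


class TestClassPartition:
    @pytest.mark.parametrize("N", [2, 3, 4, 7])
    def test_partition_counts_cover_all_nonempty_subsets(self, N):
        part = ClassPartition(N)
        assert part.n_classes == 2 * N - 1
        total = sum(part.cardinality(i, c) for i, c in part.classes())
        assert total == 2**N - 1

    def test_index_round_trip(self):
        part = ClassPartition(5)
        for k in range(part.n_classes):
            i, c = part.cls(k)
            assert part.index(i, c) == k
        with pytest.raises(ValueError):
            part.index(5, 0)  # the full set always contains the true state


class TestLeafVectorAndMixing:
    def test_leaf_vector(self):
        A = leaf_class_vector(4)
        assert A[0] == 1.0 and A.sum() == 1.0 and len(A) == 7

    def test_zero_branch_is_identity(self, rng):
        N = 4
        A = rng.dirichlet(np.ones(2 * N - 1))
        assert np.allclose(branch_mixing(A, 0.0, N), A)

    def test_leaf_vector_mixing_hand_values(self):
        # N=4, p=0.1: singleton keeps the parent state w.p. q=0.7
        M = branch_mixing(leaf_class_vector(4), 0.1, 4)
        part = ClassPartition(4)
        assert M[part.index(1, 1)] == pytest.approx(0.7)
        assert M[part.index(1, 0)] == pytest.approx(0.3)
        assert M.sum() == pytest.approx(1.0)

    def test_stationary_branch_randomizes_membership(self, rng):
        N = 4
        A = rng.dirichlet(np.ones(2 * N - 1))
        M = branch_mixing(A, 1.0 / N, N)
        part = ClassPartition(N)
        for i in range(1, N + 1):
            a0 = A[part.index(i, 0)] if i < N else 0.0
            assert M[part.index(i, 1)] == pytest.approx(
                (i / N) * (A[part.index(i, 1)] + a0)
            )

    @given(
        st.integers(min_value=2, max_value=6),
        st.floats(min_value=0.0, max_value=1.0),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mixing_preserves_size_marginal_and_total(self, N, frac, seed):
        p = frac / (N - 1)  # anywhere in the stochastic range q >= 0
        A = np.random.default_rng(seed).dirichlet(np.ones(2 * N - 1))
        M = branch_mixing(A, p, N)
        part = ClassPartition(N)
        assert M.sum() == pytest.approx(1.0, abs=1e-12)
        for i in range(1, N):
            assert M[part.index(i, 1)] + M[part.index(i, 0)] == pytest.approx(
                A[part.index(i, 1)] + A[part.index(i, 0)], abs=1e-12
            )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DomainError):
            branch_mixing(leaf_class_vector(4), 0.4, 4)


class TestCombinationKernel:
    @pytest.mark.parametrize("N", [2, 3, 4, 10])
    def test_rows_are_distributions_and_symmetric(self, N):
        K = build_combination_kernel(N).tensor
        assert np.allclose(K.sum(axis=2), 1.0, atol=1e-12)
        assert np.allclose(K, K.transpose(1, 0, 2))

    def test_matching_singletons(self):
        part = ClassPartition(4)
        K = build_combination_kernel(4).tensor
        row = K[part.index(1, 1), part.index(1, 1)]
        assert row[part.index(1, 1)] == 1.0

    def test_disjoint_singletons_union(self):
        part = ClassPartition(4)
        K = build_combination_kernel(4).tensor
        row = K[part.index(1, 1), part.index(1, 0)]
        assert row[part.index(2, 1)] == 1.0

    def test_pairs_of_two_subsets_enumerated(self):
        # N=4: two independent uniform 2-subsets of {2,3,4} intersect in one
        # element w.p. 2/3 (-> class (1,0)) and coincide w.p. 1/3 (-> (2,0))
        part = ClassPartition(4)
        K = build_combination_kernel(4).tensor
        row = K[part.index(2, 0), part.index(2, 0)]
        assert row[part.index(1, 0)] == pytest.approx(2 / 3)
        assert row[part.index(2, 0)] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("N", [2, 3, 4])
    def test_kernel_matches_explicit_subset_enumeration(self, N):
        """Exhaustively enumerate every pair of subsets per class pair and
        apply the Fitch rule; the hypergeometric kernel must agree exactly."""
        from itertools import combinations

        part = ClassPartition(N)
        states = range(1, N + 1)
        members = {}
        for i, c in part.classes():
            sets = [
                frozenset(s)
                for s in combinations(states, i)
                if (1 in s) == bool(c)
            ]
            members[(i, c)] = sets
        K = build_combination_kernel(N).tensor
        for ic in part.classes():
            for jc in part.classes():
                counts = np.zeros(part.n_classes)
                pairs = 0
                for BX in members[ic]:
                    for BY in members[jc]:
                        inter = BX & BY
                        B = inter if inter else BX | BY
                        counts[part.index(len(B), int(1 in B))] += 1
                        pairs += 1
                expected = counts / pairs
                assert np.allclose(
                    K[part.index(*ic), part.index(*jc)], expected, atol=1e-14
                )


class TestCombineAndTreeAccuracy:
    def test_leaf_vectors_combine_to_singleton(self):
        kern = build_combination_kernel(3)
        A = combine_children(leaf_class_vector(3), leaf_class_vector(3), kern)
        assert A[0] == 1.0

    def test_cherry_class_vector_hand_enumeration(self):
        # N=2, both branches p=0.1: mixed vectors (0.9, 0.1, 0)
        kern = build_combination_kernel(2)
        M = branch_mixing(leaf_class_vector(2), 0.1, 2)
        A = combine_children(M, M, kern)
        assert A == pytest.approx([0.81, 0.01, 0.18])

    def test_symmetric_in_arguments(self, rng):
        N = 4
        kern = build_combination_kernel(N)
        MX = rng.dirichlet(np.ones(2 * N - 1))
        MY = rng.dirichlet(np.ones(2 * N - 1))
        assert np.allclose(
            combine_children(MX, MY, kern), combine_children(MY, MX, kern)
        )

    def test_cherry_accuracy(self, cherry):
        res = tree_accuracy(cherry, 2)
        assert res.ua == pytest.approx(0.81, abs=1e-12)
        assert res.aa == pytest.approx(0.90, abs=1e-12)

    def test_zero_substitution_probability_gives_certainty(self, rng):
        t = build_from_shape(tree_shapes(5)[0], rng, 3)
        t.set_uniform_branch_p(0.0)
        res = tree_accuracy(t, 3)
        assert res.ua == pytest.approx(1.0) and res.aa == pytest.approx(1.0)

    def test_stationary_branches_randomize(self, rng):
        N = 3
        t = build_from_shape(tree_shapes(5)[1], rng, N)
        t.set_uniform_branch_p(1.0 / N)
        assert tree_accuracy(t, N).aa == pytest.approx(1.0 / N, abs=1e-12)

    def test_invariant_under_child_swap(self, rng):
        N = 3
        t = build_from_shape(tree_shapes(5)[2], rng, N)
        before = tree_accuracy(t, N)
        for node in t.preorder():
            if not node.is_leaf:
                node.children.reverse()
        after = tree_accuracy(t, N)
        assert before.ua == pytest.approx(after.ua, abs=1e-14)
        assert before.aa == pytest.approx(after.aa, abs=1e-14)

    @pytest.mark.parametrize("N", [2, 3, 4])
    def test_matches_enumeration_oracle(self, N, rng):
        """Spot check of the central oracle identity (the exhaustive battery
        runs in the acceptance tests)."""
        for n_leaves in (2, 3, 4, 5):
            for shape in tree_shapes(n_leaves):
                t = build_from_shape(shape, rng, N)
                a = tree_accuracy(t, N)
                b = exact_enumeration_accuracy(t, N)
                assert a.ua == pytest.approx(b.ua, abs=1e-10)
                assert a.aa == pytest.approx(b.aa, abs=1e-10)


class TestAccuraciesFromClassVector:
    def test_leaf_vector_is_certain(self):
        res = accuracies_from_classvector(leaf_class_vector(4), 4)
        assert res.ua == 1.0 and res.aa == 1.0

    def test_arithmetic_examples(self):
        res = accuracies_from_classvector(np.array([1 / 3, 1 / 3, 1 / 3]), 2)
        assert res.ua == pytest.approx(1 / 3)
        assert res.aa == pytest.approx(1 / 2)
        part = ClassPartition(4)
        A = np.zeros(7)
        A[part.index(1, 1)] = 0.5
        A[part.index(2, 1)] = 0.3
        A[part.index(4, 1)] = 0.2
        res = accuracies_from_classvector(A, 4)
        assert res.ua == pytest.approx(0.5)
        assert res.aa == pytest.approx(0.70)

    def test_unnormalized_vector_rejected(self):
        with pytest.raises(ValueError):
            accuracies_from_classvector(np.array([0.5, 0.1, 0.1]), 2)

    def test_aa_never_below_ua(self, rng):
        for _ in range(20):
            N = int(rng.integers(2, 7))
            A = rng.dirichlet(np.ones(2 * N - 1))
            res = accuracies_from_classvector(A, N)
            assert res.aa >= res.ua - 1e-15
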