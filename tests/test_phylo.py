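import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from conftest import random_binary_tree
from phagecompare.align import MultipleAlignment
from phagecompare.errors import FormatError, TreeError
from phagecompare.phylo import (
    fitch_score,
    hierarchical_tree,
    is_monophyletic,
    neighbor_joining,
    p_distance_matrix,
    permutation_test,
    read_newick,
    unifrac_statistic,
    write_newick,
)


class TestNewick:
    def test_four_tip_tree(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C", "D"]
        total = sum(
            n.length for n in tree.traverse(include_self=False) if n.length
        )
        assert total == pytest.approx(6.0)

    def test_missing_lengths_default_to_zero(self):
        tree = read_newick("(A,B);")
        assert [t.length for t in tree.tips()] == [0.0, 0.0]

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(FormatError):
            read_newick("((A:1,B:1):1;")

    def test_round_trip_of_random_trees(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            tree = random_binary_tree(rng, int(rng.integers(3, 10)))
            back = read_newick(write_newick(tree))
            orig = {
                frozenset(t.name for t in n.tips()): n.length
                for n in tree.traverse(include_self=False)
                if not n.is_tip()
            }
            again = {
                frozenset(t.name for t in n.tips()): n.length
                for n in back.traverse(include_self=False)
                if not n.is_tip()
            }
            assert set(orig) == set(again)
            for key in orig:
                assert again[key] == pytest.approx(orig[key], rel=1e-9)


class TestHierarchical:
    def test_two_items_join_at_their_distance(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["A", "B"])
        tree = hierarchical_tree(dm)
        a, b = tree.children
        assert a.length + b.length == pytest.approx(0.4)

    def test_hand_agglomeration(self):
        dm = DistanceMatrix(
            [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]], ids=["A", "B", "C"]
        )
        tree = hierarchical_tree(dm, linkage="complete")
        assert is_monophyletic(tree, {"A": "x", "B": "x", "C": "y"}, "x")
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(0.1)
        assert tree.find("A").distance(tree.find("C")) == pytest.approx(0.9)

    def test_average_linkage_reproduces_ultrametric_input(self):
        # clock tree: (A,B) join at 0.2, +C at 0.5, (D,E) at 0.3, all at 0.8
        ids = list("ABCDE")
        h = {
            frozenset("AB"): 0.2,
            frozenset("AC"): 0.5,
            frozenset("BC"): 0.5,
            frozenset("DE"): 0.3,
        }
        data = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            data[i, j] = data[j, i] = h.get(frozenset(ids[i] + ids[j]), 0.8)
        tree = hierarchical_tree(DistanceMatrix(data, ids=ids), linkage="average")
        for i, j in itertools.combinations(range(5), 2):
            assert tree.find(ids[i]).distance(tree.find(ids[j])) == pytest.approx(
                data[i, j]
            )

    def test_nan_distance_is_an_error(self):
        class Fake:
            ids = ["A", "B"]
            data = np.array([[0, np.nan], [np.nan, 0]])

        with pytest.raises(TreeError):
            hierarchical_tree(Fake())


class TestPDistance:
    def _msa(self, rows):
        return MultipleAlignment(ids=[f"s{i}" for i in range(len(rows))], rows=rows)

    def test_identical_sequences(self):
        d = p_distance_matrix(self._msa(["AAAA", "AAAA"]))
        assert d["s0", "s1"] == 0.0

    def test_one_in_four(self):
        d = p_distance_matrix(self._msa(["AAAA", "AAAT"]))
        assert d["s0", "s1"] == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        d = p_distance_matrix(self._msa(["AA-A", "AATA"]))
        assert d["s0", "s1"] == 0.0

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(TreeError):
            p_distance_matrix(self._msa(["A-", "-A"]))

    def test_symmetric_zero_diagonal_on_random_sequences(self):
        rng = np.random.default_rng(8)
        seqs = [
            (f"s{i}", "".join(rng.choice(list("ACDEFG"), size=12)))
            for i in range(5)
        ]
        d = p_distance_matrix(seqs)
        assert np.allclose(d.data, d.data.T)
        assert np.allclose(np.diag(d.data), 0.0)


class TestNeighborJoining:
    def test_additive_four_taxon_example(self):
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ids=list("ABCD"),
        )
        tree = neighbor_joining(dm)
        tip_lengths = {t.name: t.length for t in tree.tips()}
        assert tip_lengths == {
            "A": pytest.approx(1.0),
            "B": pytest.approx(2.0),
            "C": pytest.approx(3.0),
            "D": pytest.approx(4.0),
        }
        internals = [
            n.length
            for n in tree.traverse(include_self=False)
            if not n.is_tip()
        ]
        assert internals == [pytest.approx(1.0)]
        for a, b in itertools.combinations("ABCD", 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                dm[a, b]
            )

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(21)
        for n in (5, 6, 8):
            source = random_binary_tree(rng, n)
            dm = source.tip_tip_distances()
            tree = neighbor_joining(dm)
            for a, b in itertools.combinations([f"t{i+1}" for i in range(n)], 2):
                assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                    dm[a, b], rel=1e-9
                )

    def test_star_matrix_has_zero_internal_branches(self):
        n = 4
        data = np.full((n, n), 2.0)
        np.fill_diagonal(data, 0.0)
        tree = neighbor_joining(DistanceMatrix(data, ids=list("ABCD")))
        internals = [
            n_.length
            for n_ in tree.traverse(include_self=False)
            if not n_.is_tip()
        ]
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in internals)

    def test_asymmetric_matrix_rejected(self):
        class Fake:
            ids = ["a", "b", "c"]
            data = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]])

        with pytest.raises(TreeError):
            neighbor_joining(Fake())


def brute_force_fitch(tree, labels, states):
    """Exhaustive minimum over all internal label assignments."""
    internals = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    best = np.inf
    for assignment in itertools.product(states, repeat=len(internals)):
        lab = {id(n): s for n, s in zip(internals, assignment)}
        changes = 0
        for node in tree.traverse(include_self=False):
            child = labels[node.name] if node.is_tip() else lab[id(node)]
            if child != lab[id(node.parent)]:
                changes += 1
        best = min(best, changes)
    return int(best)


class TestFitch:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ({"A": "x", "B": "x", "C": "y", "D": "y"}, 1),
            ({"A": "x", "B": "y", "C": "x", "D": "y"}, 2),
            ({"A": "x", "B": "x", "C": "x", "D": "x"}, 0),
        ],
    )
    def test_four_tip_examples(self, labels, expected):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fitch_score(tree, labels) == expected

    def test_matches_exhaustive_internal_labelings(self):
        rng = np.random.default_rng(41)
        states = ["x", "y", "z"]
        for _ in range(6):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree(rng, n)
            labels = {f"t{i+1}": states[rng.integers(0, 3)] for i in range(n)}
            assert fitch_score(tree, labels) == brute_force_fitch(
                tree, labels, states
            )

    def test_unlabeled_tip_is_an_error(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(TreeError):
            fitch_score(tree, {"A": "x", "B": "x", "C": "y"})

    def test_multifurcation_is_resolved(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        assert fitch_score(tree, {"A": "x", "B": "x", "C": "y", "D": "y"}) == 1


class TestUnifrac:
    def test_perfect_separation(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        labels = {"A": "h1", "B": "h1", "C": "h2", "D": "h2"}
        assert unifrac_statistic(tree, labels) == pytest.approx(1.0)

    def test_interleaved_labels(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        labels = {"A": "h1", "B": "h2", "C": "h1", "D": "h2"}
        assert unifrac_statistic(tree, labels) == pytest.approx(4 / 6)

    def test_two_tips(self):
        tree = read_newick("(A:1,B:1);")
        assert unifrac_statistic(tree, {"A": "h1", "B": "h2"}) == pytest.approx(1.0)

    def test_invariant_under_branch_rescaling(self):
        rng = np.random.default_rng(3)
        tree = random_binary_tree(rng, 8)
        labels = {f"t{i+1}": ("a" if i % 2 else "b") for i in range(8)}
        before = unifrac_statistic(tree, labels)
        for node in tree.traverse(include_self=False):
            node.length *= 7.5
        assert unifrac_statistic(tree, labels) == pytest.approx(before)

    def test_single_label_is_an_error(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(TreeError):
            unifrac_statistic(tree, {"A": "h1", "B": "h1"})


class TestPermutationTest:
    def test_exhaustive_four_tip_unifrac(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        labels = {"A": "h1", "B": "h1", "C": "h2", "D": "h2"}
        res = permutation_test(tree, labels, mode="exhaustive")
        assert res.p_value == pytest.approx(2 / 6)
        assert res.n_perm == 6

    def test_sampled_p_is_reproducible_bit_for_bit(self):
        rng = np.random.default_rng(9)
        tree = random_binary_tree(rng, 12)
        labels = {f"t{i+1}": ("a" if i < 6 else "b") for i in range(12)}
        r1 = permutation_test(tree, labels, n_perm=500, seed=123)
        r2 = permutation_test(tree, labels, n_perm=500, seed=123)
        assert r1.p_value == r2.p_value
        assert r1.null_samples == r2.null_samples

    def test_sampled_p_never_zero(self):
        rng = np.random.default_rng(10)
        tree = random_binary_tree(rng, 10)
        labels = {f"t{i+1}": ("a" if i < 5 else "b") for i in range(10)}
        res = permutation_test(tree, labels, n_perm=99, seed=4)
        assert 0 < res.p_value <= 1

    def test_fitch_statistic_small_is_extreme(self):
        # perfectly separated labels: observed score 1 is minimal, p small
        rng = np.random.default_rng(12)
        tree = random_binary_tree(rng, 4)
        # group tips by clade membership of the root's first child
        left = {t.name for t in tree.children[0].tips()} or {tree.children[0].name}
        labels = {f"t{i+1}": ("L" if f"t{i+1}" in left else "R") for i in range(4)}
        res = permutation_test(tree, labels, statistic="fitch", mode="exhaustive")
        assert res.observed == 1.0
        assert res.p_value <= 0.5

    def test_single_distinct_label_is_an_error(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(TreeError):
            permutation_test(tree, {"A": "h", "B": "h"})
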