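from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phagecompare.align import global_align, identity_over_shorter
from phagecompare.clustering import (
    FamilyVariabilityProfile,
    PresenceAbsenceMatrix,
    classify_core,
    family_variability,
    greedy_cluster,
    jaccard_distance,
    pangenome_partition,
    presence_absence,
    proteome_tree,
)
from phagecompare.errors import AlignmentError, FormatError
from phagecompare.phylo import is_monophyletic
from phagecompare.seqio import SequenceRecord


def _rec(gid, seq):
    return SequenceRecord(gid, seq, alphabet="protein")


def _random_proteins(rng, n, lo=8, hi=25):
    return [
        _rec(f"p{i:02d}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                             size=rng.integers(lo, hi))))
        for i in range(n)
    ]


class TestGreedyCluster:
    def test_identical_pair_separates_from_unrelated(self):
        recs = [
            _rec("P1", "MKTAYIAKQR"),
            _rec("P2", "MKTAYIAKQR"),
            _rec("P3", "GGGGGGGGGG"),
        ]
        cs = greedy_cluster(recs, threshold=0.40)
        member_sets = sorted(sorted(c.members) for c in cs.clusters)
        assert member_sets == [["P1", "P2"], ["P3"]]

    @pytest.mark.parametrize("threshold", [0.1, 0.5, 1.0])
    def test_identical_sequences_always_co_cluster(self, threshold):
        recs = [_rec(f"p{i}", "MKTAYIAK") for i in range(4)]
        cs = greedy_cluster(recs, threshold=threshold)
        assert len(cs) == 1

    def test_representative_is_longest_member(self):
        recs = [_rec("short", "MKTAYI"), _rec("long", "MKTAYIAKQR")]
        cs = greedy_cluster(recs, threshold=0.4)
        assert cs.clusters[0].representative == "long"

    def test_matches_first_qualifying_representative_oracle(self):
        rng = np.random.default_rng(31)
        recs = _random_proteins(rng, 20)
        threshold = 0.40
        # independent restatement of the contract
        ordered = sorted(recs, key=lambda r: (-len(r.residues), r.id))
        oracle: list[list[str]] = []
        reps: list[str] = []
        for rec in ordered:
            for k, rep in enumerate(reps):
                pct = identity_over_shorter(global_align(rep, rec.residues))
                if pct >= 100 * threshold:
                    oracle[k].append(rec.id)
                    break
            else:
                oracle.append([rec.id])
                reps.append(rec.residues)
        cs = greedy_cluster(recs, threshold=threshold)
        assert [c.members for c in cs.clusters] == oracle

    def test_input_order_does_not_matter(self):
        rng = np.random.default_rng(13)
        recs = _random_proteins(rng, 12)
        a = greedy_cluster(recs)
        b = greedy_cluster(recs[::-1])
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]

    def test_empty_input_is_an_error(self):
        with pytest.raises(FormatError):
            greedy_cluster([])


class TestPresenceAbsence:
    def test_missing_genome_row_is_false(self):
        recs = [_rec("a", "MKTAYIAK"), _rec("b", "MKTAYIAK")]
        cs = greedy_cluster(recs)
        pa = presence_absence(cs, {"a": "g1", "b": "g2", "c": "g3"})
        assert set(pa.genomes) == {"g1", "g2"}
        assert pa.table.loc["g1"].any() and pa.table.loc["g2"].any()

    def test_unmapped_gene_is_named(self):
        cs = greedy_cluster([_rec("orphan", "MKTAYIAK")])
        with pytest.raises(FormatError, match="orphan"):
            presence_absence(cs, {})

    def test_matrix_shape_from_generated_community(
        self, default_community, default_clusters
    ):
        pa = presence_absence(default_clusters, default_community.gene_to_genome)
        assert pa.table.shape == (len(default_community.genomes), len(default_clusters))
        assert pa.table.any(axis=0).all()  # every cluster present somewhere


class TestJaccard:
    def _pa(self, data, genomes, clusters):
        return PresenceAbsenceMatrix(
            table=pd.DataFrame(data, index=genomes, columns=clusters, dtype=bool)
        )

    def test_worked_example(self):
        pa = self._pa(
            [[1, 1, 1, 0], [0, 1, 1, 1]], ["A", "B"], ["c1", "c2", "c3", "c4"]
        )
        assert jaccard_distance(pa, "A", "B") == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        pa = self._pa([[1, 1, 0], [1, 1, 0], [0, 0, 1]], list("ABC"), ["x", "y", "z"])
        assert jaccard_distance(pa, "A", "B") == 0.0
        assert jaccard_distance(pa, "A", "C") == 1.0

    def test_both_empty_is_an_error(self):
        pa = self._pa([[0, 0], [0, 0], [1, 1]], list("ABC"), ["x", "y"])
        with pytest.raises(FormatError):
            jaccard_distance(pa, "A", "B")

    def test_metric_axioms_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            data = rng.random((5, 9)) < 0.6
            data[:, 0] = True  # no empty genomes
            pa = self._pa(data, [f"g{i}" for i in range(5)], [f"c{j}" for j in range(9)])
            g = pa.genomes
            for a, b in combinations(g, 2):
                assert jaccard_distance(pa, a, b) == jaccard_distance(pa, b, a)
                assert jaccard_distance(pa, a, a) == 0.0
            for a, b, c in combinations(g, 3):
                assert (
                    jaccard_distance(pa, a, c)
                    <= jaccard_distance(pa, a, b) + jaccard_distance(pa, b, c) + 1e-12
                )

    def test_proteome_tree_groups_similar_genomes(self):
        data = [
            [1, 1, 1, 1, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [0, 0, 1, 0, 1, 1],
        ]
        pa = self._pa(data, ["g1", "g2", "g3"], [f"c{j}" for j in range(6)])
        tree = proteome_tree(pa)
        assert is_monophyletic(tree, {"g1": "i", "g2": "i", "g3": "o"}, "i")


class TestPangenome:
    def test_core_and_unique_cells(self):
        part = pangenome_partition(
            {"f1": {"g1", "g2"}, "f2": {"g1"}, "f3": {"g1", "g2"}}
        )
        assert part.core == ["f1", "f3"]
        assert part.cells[frozenset({"g1"})] == ["f2"]

    def test_triple_intersection(self):
        part = pangenome_partition(
            {
                "shared": {"a", "b", "c"},
                "ab": {"a", "b"},
                "only_c": {"c"},
            },
            ids=["a", "b", "c"],
        )
        assert part.core == ["shared"]
        assert part.counts()["a+b+c"] == 1

    def test_cells_partition_the_universe(self):
        rng = np.random.default_rng(5)
        genomes = ["g1", "g2", "g3", "g4"]
        universe = {
            f"f{i}": {g for g in genomes if rng.random() < 0.5} | {"g1"}
            for i in range(30)
        }
        part = pangenome_partition(universe, ids=genomes)
        assert sum(len(v) for v in part.cells.values()) == 30


class TestFamilyVariability:
    def test_identical_members_are_100_percent(self):
        members = [(f"m{i}", f"g{i}", "MKTAYIAKQRQISFVK") for i in range(4)]
        profile = family_variability("holin", members)
        assert profile.min_identity_pct == 100.0
        assert all(v == 100.0 for v in profile.pairwise_identity_pct)

    def test_single_substitution_in_100_sites(self):
        base = "ADEFGHIKLM" * 10
        mutated = "P" + base[1:]
        profile = family_variability(
            "f", [("a", "g1", base), ("b", "g2", mutated)]
        )
        assert profile.min_identity_pct == pytest.approx(99.0)

    def test_pair_count(self):
        members = [(f"m{i}", f"g{i}", "MKTAYIAK") for i in range(5)]
        assert len(family_variability("f", members).pairwise_identity_pct) == 10

    def test_fewer_than_two_members_is_an_error(self):
        with pytest.raises(AlignmentError):
            family_variability("f", [("a", "g1", "MKT")])


class TestClassifyCore:
    def _profile(self, min_pct, genomes):
        return FamilyVariabilityProfile(
            family_id="f",
            gene_ids=["a", "b"],
            genomes=set(genomes),
            pairwise_identity_pct=[min_pct],
            min_identity_pct=min_pct,
        )

    def test_conserved_at_the_8_percent_difference_boundary(self):
        (p,) = classify_core([self._profile(92.0, {"g1", "g2"})], genome_count=2)
        assert p.cls == "conserved_core"

    def test_just_below_the_boundary_is_variable(self):
        (p,) = classify_core([self._profile(91.9, {"g1", "g2"})], genome_count=2)
        assert p.cls == "variable_core"

    def test_family_absent_from_a_genome_is_never_core(self):
        (p,) = classify_core([self._profile(100.0, {"g1"})], genome_count=2)
        assert p.cls == "accessory"
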