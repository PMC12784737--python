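"""Jaccard distances, NJ trees, bootstrap support, duplicates, ROC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrfp import (
    DissimilarityMatrix,
    LocusDefinition,
    SimulationConfig,
    bootstrap_support,
    duplicate_precision_recall,
    find_duplicates,
    jaccard_matrix,
    nj_tree,
    node_support,
    parse_newick,
    simulate_dataset,
    threshold_roc,
    to_newick,
    verify_profiles,
)

from .conftest import make_matrix

TWO_LOCI = [
    LocusDefinition("LA", tuple(range(100, 124, 2))),
    LocusDefinition("LB", tuple(range(200, 218, 2))),
]


class TestJaccard:
    LOCI = [LocusDefinition("L", (100, 102, 104))]

    def test_identical_rows_zero(self):
        m = make_matrix([[1, 1, 0], [1, 1, 0]], self.LOCI)
        assert jaccard_matrix(m).d[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        m = make_matrix([[1, 0, 0], [0, 1, 1]], self.LOCI)
        assert jaccard_matrix(m).d[0, 1] == 1.0

    def test_hand_count_one_extra_band(self):
        # 20 shared presences, 1 extra in one sample -> 1 - 20/21
        row_a = [1] * 20 + [0]
        row_b = [1] * 21
        m = make_matrix([row_a, row_b], [LocusDefinition("L", tuple(range(100, 142, 2)))])
        assert jaccard_matrix(m).d[0, 1] == pytest.approx(1 - 20 / 21)

    def test_missing_locus_masked_per_pair(self):
        m = make_matrix(
            [[1, 0, 0, 1, 1], [1, 0, 0, 9, 9], [0, 1, 0, 1, 1]],
            [LocusDefinition("LA", (100, 102, 104)), LocusDefinition("LB", (200, 202))],
        )
        D = jaccard_matrix(m)
        assert D.d[0, 1] == 0.0  # LB masked out for this pair
        assert D.d[0, 2] == pytest.approx(1 - 2 / 4)

    def test_no_coscored_locus_flagged_undefined(self):
        m = make_matrix(
            [[1, 0, 9, 9], [9, 9, 1, 0]],
            [LocusDefinition("LA", (100, 102)), LocusDefinition("LB", (200, 202))],
        )
        D = jaccard_matrix(m)
        assert math.isnan(D.d[0, 1])
        assert D.undefined_pairs == [("S1", "S2")]

    @given(st.integers(0, 10_000))
    def test_triangle_inequality_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(3, 12))
        rows[:, 0] = 1  # avoid empty profiles
        m = make_matrix(rows, [LocusDefinition("L", tuple(range(100, 124, 2)))])
        d = jaccard_matrix(m).d
        for i, j, k in itertools.permutations(range(3), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNjTree:
    def test_three_taxon_closed_form(self):
        D = DissimilarityMatrix(
            ["A", "B", "C"], np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        )
        tree = nj_tree(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.3)
        assert lengths["C"] == pytest.approx(0.5)

    def test_additive_four_taxon_distances_recovered(self):
        # tree ((A:1,B:2):0.5,C:0.7,D:0.3) -> additive distance matrix
        names = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 3.0, 2.2, 1.8],
                [3.0, 0.0, 3.2, 2.8],
                [2.2, 3.2, 0.0, 1.0],
                [1.8, 2.8, 1.0, 0.0],
            ]
        )
        tree = nj_tree(DissimilarityMatrix(names, d))
        got = tree.tip_tip_distances()
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert got[a, b] == pytest.approx(d[i, j], abs=1e-9)

    def test_identical_samples_sister_at_zero_branches(self):
        m = make_matrix(
            [[1, 1, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]],
            [LocusDefinition("L", (100, 102, 104))],
        )
        tree = nj_tree(jaccard_matrix(m))
        s1 = tree.find("S1")
        s2 = tree.find("S2")
        assert s1.parent is s2.parent
        assert s1.length == pytest.approx(0.0, abs=1e-12)
        assert s2.length == pytest.approx(0.0, abs=1e-12)

    def test_undefined_entries_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        D = DissimilarityMatrix(list("ABC"), d, [("A", "B")])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(D)


class TestNewick:
    def test_round_trip_topology_lengths_supports(self, clean_clone_dataset):
        matrix, _ = clean_clone_dataset
        sub_ids = matrix.sample_ids[:12]
        from ssrfp import subset

        tree = bootstrap_support(subset(matrix, sub_ids), n_reps=10, seed=3)
        text = to_newick(tree)
        back = parse_newick(text)
        assert {t.name for t in back.tips()} == set(sub_ids)
        orig = {
            frozenset(t.name for t in n.tips()): (n.length, node_support(n))
            for n in tree.non_tips(include_self=False)
        }
        for node in back.non_tips(include_self=False):
            key = frozenset(t.name for t in node.tips())
            if key in orig:
                length, sup = orig[key]
                assert node.length == pytest.approx(length)
                if sup is not None:
                    assert node_support(node) == pytest.approx(sup)

    def test_awkward_labels_escaped_and_round_trip(self):
        # spaces are underscore-escaped and literal underscores quoted,
        # per the Newick convention; both must survive a round trip
        m = make_matrix(
            [[1, 1, 0], [1, 0, 1], [0, 1, 1]],
            [LocusDefinition("L", (100, 102, 104))],
        )
        rec = type(m.samples[0])
        m.samples[0] = rec("sample one")
        m.samples[1] = rec("acc_01")
        text = to_newick(nj_tree(jaccard_matrix(m)))
        assert "sample one" not in text  # raw space never emitted bare
        assert "'acc_01'" in text  # quoting protects the literal underscore
        assert {t.name for t in parse_newick(text).tips()} == {
            "sample one", "acc_01", "S3",
        }


class TestBootstrap:
    def test_duplicated_signal_gives_full_support(self):
        # one informative split repeated across every locus: no resampling
        # variance, every internal edge supported in 100% of replicates
        base = [[1, 0], [1, 0], [0, 1], [0, 1]]
        loci = [LocusDefinition(f"L{i}", (100 + 4 * i, 102 + 4 * i)) for i in range(8)]
        rows = [list(np.tile(r, 8)) for r in base]
        m = make_matrix(rows, loci)
        tree = bootstrap_support(m, n_reps=25, seed=0)
        supports = [
            node_support(n) for n in tree.non_tips(include_self=False)
            if node_support(n) is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_fixed_seed_reproducible_and_in_range(self, clone_dataset):
        matrix, _ = clone_dataset
        from ssrfp import subset

        sub = subset(matrix, matrix.sample_ids[:15])
        t1 = bootstrap_support(sub, n_reps=30, seed=9)
        t2 = bootstrap_support(sub, n_reps=30, seed=9)
        assert to_newick(t1) == to_newick(t2)
        sups = [
            node_support(n) for n in t1.non_tips(include_self=False)
            if node_support(n) is not None
        ]
        assert sups and all(0.0 <= s <= 100.0 for s in sups)

    def test_clone_group_splits_strongly_supported(self, clean_clone_dataset):
        matrix, truth = clean_clone_dataset
        from ssrfp import subset

        # three well-separated clone families
        fams = ["F001", "F002", "F003"]
        ids = [s for s in matrix.sample_ids if truth.clone_group[s] in fams]
        tree = bootstrap_support(subset(matrix, ids), n_reps=50, seed=5)
        by_fam = {
            f: frozenset(s for s in ids if truth.clone_group[s] == f) for f in fams
        }
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if side in by_fam.values():
                assert node_support(node) > 90.0


class TestDuplicates:
    def test_strict_threshold_boundary(self):
        ids = ["A", "B", "C"]
        d = np.array(
            [[0.0, 1 - 20 / 21, 0.05], [1 - 20 / 21, 0.0, 0.5], [0.05, 0.5, 0.0]]
        )
        rep = find_duplicates(DissimilarityMatrix(ids, d), threshold=0.05)
        flagged = {(p.sample_a, p.sample_b) for p in rep.pairs}
        assert flagged == {("A", "B")}  # 0.04762 < 0.05, but 0.05 is excluded

    def test_identical_rows_grouped_at_zero(self):
        m = make_matrix([[1, 1, 0]] * 3 + [[0, 1, 1]],
                        [LocusDefinition("L", (100, 102, 104))])
        rep = find_duplicates(jaccard_matrix(m), matrix=m)
        assert rep.groups == [["S1", "S2", "S3"]]
        assert all(p.d == 0.0 and p.mismatch_count == 0 for p in rep.pairs)

    def test_all_distant_matrix_empty_report(self):
        m = make_matrix([[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                        [LocusDefinition("L", (100, 102, 104))])
        rep = find_duplicates(jaccard_matrix(m))
        assert rep.pairs == [] and rep.groups == []

    def test_single_linkage_chains_groups(self):
        ids = ["A", "B", "C"]
        d = np.array([[0.0, 0.01, 0.06], [0.01, 0.0, 0.01], [0.06, 0.01, 0.0]])
        rep = find_duplicates(DissimilarityMatrix(ids, d))
        assert rep.groups == [["A", "B", "C"]]  # A-C linked through B

    def test_zero_noise_clone_recovery_is_exact(self, clean_clone_dataset):
        matrix, truth = clean_clone_dataset
        rep = find_duplicates(jaccard_matrix(matrix), matrix=matrix)
        p, r = duplicate_precision_recall(rep, truth.clone_group, matrix.sample_ids)
        assert p == 1.0 and r == 1.0


class TestVerifyProfiles:
    LOCI = [LocusDefinition("LA", (100, 102)), LocusDefinition("LB", (200, 202))]

    def test_identical_samples_all_match(self):
        m = make_matrix([[1, 0, 1, 1], [1, 0, 1, 1]], self.LOCI)
        cmp = verify_profiles(m, ("S1", "S2"))
        assert cmp.mismatch_count == 0
        assert all(c.match for c in cmp.loci)

    def test_single_flip_names_locus_and_allele(self):
        m = make_matrix([[1, 0, 1, 1], [1, 1, 1, 1]], self.LOCI)
        cmp = verify_profiles(m, ("S1", "S2"))
        assert cmp.mismatching_loci == ["LA"]
        (bad,) = [c for c in cmp.loci if not c.match and c.comparable]
        assert bad.differing_alleles == (102,)

    def test_missing_locus_not_comparable(self):
        m = make_matrix([[1, 0, 9, 9], [1, 0, 1, 1]], self.LOCI)
        cmp = verify_profiles(m, ("S1", "S2"))
        assert cmp.mismatch_count == 0
        assert [c.comparable for c in cmp.loci] == [True, False]

    def test_unknown_sample_rejected(self, two_locus_matrix):
        with pytest.raises(KeyError):
            verify_profiles(two_locus_matrix, ("S1", "nope"))


class TestRoc:
    def test_perfect_separation_auc_one(self, clean_clone_dataset):
        matrix, truth = clean_clone_dataset
        roc = threshold_roc(jaccard_matrix(matrix), truth.clone_group)
        assert roc.auc == pytest.approx(1.0)

    def test_specificity_monotone_in_threshold(self, clone_dataset):
        matrix, truth = clone_dataset
        roc = threshold_roc(jaccard_matrix(matrix), truth.clone_group)
        specs = [p.specificity for p in roc.points]
        assert all(b <= a + 1e-12 for a, b in zip(specs, specs[1:]))

    def test_agrees_with_sklearn_auc_oracle(self, clone_dataset):
        from sklearn.metrics import roc_auc_score

        matrix, truth = clone_dataset
        D = jaccard_matrix(matrix)
        roc = threshold_roc(D, truth.clone_group)
        y, score = [], []
        ids = matrix.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                y.append(truth.clone_group[ids[i]] == truth.clone_group[ids[j]])
                score.append(-D.d[i, j])
        assert roc.auc == pytest.approx(roc_auc_score(y, score), abs=1e-6)

    def test_random_labels_auc_near_half(self):
        cfg = SimulationConfig(seed=37, n_founders=40, min_clones=1, max_clones=1)
        matrix, _ = simulate_dataset(cfg)
        rng = np.random.default_rng(4)
        labels = {s: f"g{rng.integers(20)}" for s in matrix.sample_ids}
        roc = threshold_roc(jaccard_matrix(matrix), labels)
        n_pos = sum(
            labels[a] == labels[b]
            for a, b in itertools.combinations(matrix.sample_ids, 2)
        )
        se = math.sqrt(1 / 12 / n_pos)  # rough permutation SE envelope
        assert abs(roc.auc - 0.5) < 3 * se + 0.05

    def test_degenerate_single_group_flagged(self):
        m = make_matrix([[1, 1, 0], [1, 0, 1], [0, 1, 1]],
                        [LocusDefinition("L", (100, 102, 104))])
        roc = threshold_roc(jaccard_matrix(m), {s: "g" for s in m.sample_ids})
        assert math.isnan(roc.auc)
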