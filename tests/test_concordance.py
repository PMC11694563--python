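import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

from trainfate import (
    ClusterAssignment,
    DescriptorTable,
    descriptor_tests_by_cluster,
    kmeans_descriptors,
    kruskal_wallis,
    overlap_count,
    zscore_columns,
)
from trainfate.core import DESCRIPTOR_COLUMNS
from tests._oracles import brute_force_matched_count


class TestZscore:
    def test_standardizes_columns(self):
        Z = zscore_columns(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]]))
        assert np.allclose(Z.mean(axis=0), 0.0)
        assert np.allclose(Z.std(axis=0), 1.0)

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            Z = zscore_columns(np.array([[1.0, 5.0], [2.0, 5.0]]))
        assert np.allclose(Z[:, 1], 0.0)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        Z = zscore_columns(rng.normal(size=(50, 3)))
        assert np.allclose(zscore_columns(Z), Z)


class TestKMeansDescriptors:
    def test_recovers_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (30, 7)), rng.normal(20, 1, (30, 7))])
        df = pd.DataFrame(X, columns=list(DESCRIPTOR_COLUMNS),
                          index=[f"c{i}" for i in range(60)])
        res = kmeans_descriptors(df, k=2, seed=0)
        labels = np.array([res.labels[f"c{i}"] for i in range(60)])
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_seed_fixes_labels(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 7)),
                          columns=list(DESCRIPTOR_COLUMNS),
                          index=[f"c{i}" for i in range(40)])
        assert kmeans_descriptors(df, 3, seed=5).labels == \
            kmeans_descriptors(df, 3, seed=5).labels

    def test_k_exceeding_n_rejected(self):
        df = pd.DataFrame(np.ones((2, 7)), columns=list(DESCRIPTOR_COLUMNS))
        with pytest.raises(ValueError):
            kmeans_descriptors(df, k=5, seed=0)


def assignments_from(labels_a, labels_b):
    ids = [f"c{i}" for i in range(len(labels_a))]
    return (
        ClusterAssignment("C1", dict(zip(ids, labels_a))),
        ClusterAssignment("property", dict(zip(ids, labels_b))),
    )


class TestOverlap:
    def test_identical_labelings_full_overlap(self):
        a, b = assignments_from([0, 0, 1, 1, 2] * 2, [0, 0, 1, 1, 2] * 2)
        res = overlap_count(a, b)
        assert res.matched_count == 10 and res.matched_percent == 100.0

    def test_label_permutation_absorbed(self):
        lab = [0, 1, 2, 0, 1, 2, 0]
        perm = {0: "x", 1: "y", 2: "z"}
        a, b = assignments_from(lab, [perm[v] for v in lab])
        assert overlap_count(a, b).matched_count == len(lab)

    def test_small_contingency_example(self):
        # contingency [[3,1],[2,4]] -> rows map to cols identically, 7 matched
        labels_a = [0] * 4 + [1] * 6
        labels_b = [0] * 3 + [1] + [0] * 2 + [1] * 4
        res = overlap_count(*assignments_from(labels_a, labels_b))
        assert res.contingency.to_numpy().tolist() == [[3, 1], [2, 4]]
        assert res.matched_count == 7
        assert res.mapping == {0: 0, 1: 1}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            kr, kc = rng.integers(2, 5, size=2)
            labels_a = rng.integers(0, kr, size=40)
            labels_b = rng.integers(0, kc, size=40)
            res = overlap_count(*assignments_from(labels_a, labels_b))
            assert res.matched_count == brute_force_matched_count(
                res.contingency.to_numpy().tolist())

    def test_transposed_roles_same_count(self):
        rng = np.random.default_rng(4)
        labels_a = rng.integers(0, 3, size=30)
        labels_b = rng.integers(0, 3, size=30)
        a, b = assignments_from(labels_a, labels_b)
        assert overlap_count(a, b).matched_count == \
            overlap_count(b, a).matched_count

    def test_mismatched_compound_sets(self):
        a = ClusterAssignment("C1", {"c1": 0, "c2": 1})
        b = ClusterAssignment("property", {"c1": 0, "c3": 1})
        with pytest.raises(ValueError, match="c2.*c3|c3.*c2"):
            overlap_count(a, b)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        H, p = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                              [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert H == pytest.approx(7.2)

    def test_equal_rank_groups_give_zero(self):
        H, _ = kruskal_wallis([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert H == pytest.approx(0.0)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(9, 40))
            vals = rng.normal(size=n)
            if rng.random() < 0.5:
                vals = np.round(vals)  # force ties
            groups = rng.integers(0, 3, size=n)
            if len(np.unique(groups)) < 2 or any(
                    (groups == g).sum() == 0 for g in np.unique(groups)):
                continue
            H, p = kruskal_wallis(vals, groups)
            ref_H, ref_p = kruskal(*[vals[groups == g] for g in np.unique(groups)])
            assert H == pytest.approx(ref_H, abs=1e-9)
            assert p == pytest.approx(ref_p, abs=1e-9)

    def test_all_identical_degenerates(self):
        H, p = kruskal_wallis([5.0] * 6, [0, 0, 1, 1, 2, 2])
        assert (H, p) == (0.0, 1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=30)
        groups = rng.integers(0, 3, size=30)
        H1, _ = kruskal_wallis(vals, groups)
        H2, _ = kruskal_wallis(np.exp(vals), groups)
        assert H1 == pytest.approx(H2, abs=1e-12)


class TestDescriptorTests:
    def _table(self, shift_feature=None, shift=0.0, n_per=50, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(1.0, 1.0, size=(3 * n_per, 7))
        labels = np.repeat([0, 1, 2], n_per)
        if shift_feature is not None:
            j = DESCRIPTOR_COLUMNS.index(shift_feature)
            X[:, j] += labels * shift
        df = pd.DataFrame(np.abs(X) + 0.01, columns=list(DESCRIPTOR_COLUMNS),
                          index=[f"c{i}" for i in range(3 * n_per)])
        if shift_feature is not None:
            df[shift_feature] = X[:, DESCRIPTOR_COLUMNS.index(shift_feature)]
        desc = DescriptorTable(data=df)
        assignment = ClusterAssignment(
            "C1", {f"c{i}": int(l) for i, l in enumerate(labels)})
        return desc, assignment

    def test_planted_shift_detected_only_in_shifted_feature(self):
        desc, assignment = self._table(shift_feature="A", shift=3.0)
        table = descriptor_tests_by_cluster(desc, assignment)
        by_feature = table.set_index("feature")["significant"]
        assert bool(by_feature["A"])
        assert int(table["significant"].sum()) <= 2  # A plus at most one false hit

    def test_seven_rows_and_bonferroni_column(self):
        desc, assignment = self._table()
        table = descriptor_tests_by_cluster(desc, assignment)
        assert len(table) == 7
        assert (table["p_bonferroni"] >= table["p"]).all()

    def test_singleton_cluster_warns(self):
        desc, assignment = self._table(n_per=2)
        assignment.labels["c0"] = 99
        with pytest.warns(UserWarning, match="single compound"):
            descriptor_tests_by_cluster(desc, assignment)
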