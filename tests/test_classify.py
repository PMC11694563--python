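import numpy as np
import pandas as pd
import pytest

from trainfate import (
    ClusterAssignment,
    DescriptorTable,
    build_feature_matrix,
    crossval_classify,
    generate_study,
    make_folds,
    preset,
    rf_feature_importance,
)
from trainfate.core import DESCRIPTOR_COLUMNS


def descriptor_table(n, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.normal(1.0, 0.3, size=(n, 7)),
        columns=list(DESCRIPTOR_COLUMNS),
        index=[f"c{i:03d}" for i in range(n)],
    )
    data["V"] = data["V"].abs() + 0.1
    return DescriptorTable(data=data)


class TestFeatureMatrix:
    def test_alignment_and_dropping(self):
        desc = descriptor_table(9)
        labels = {f"c{i:03d}": "x" if i < 5 else "y" for i in range(10)}
        X, y, ids, dropped = build_feature_matrix(
            desc, ClusterAssignment("C1", labels))
        assert X.shape == (9, 7)
        assert dropped == ("c009",)
        assert ids == sorted(ids)

    def test_logkow_is_last_column(self):
        desc = descriptor_table(4)
        desc.data.loc[:, "logKow"] = [9, 9, 9, 9]
        labels = {c: i % 2 for i, c in enumerate(desc.compounds)}
        X, _, _, _ = build_feature_matrix(desc, ClusterAssignment("C1", labels))
        assert np.allclose(X[:, 6], 9)

    def test_single_label_rejected(self):
        desc = descriptor_table(4)
        labels = {c: "only" for c in desc.compounds}
        with pytest.raises(ValueError, match="2 distinct"):
            build_feature_matrix(desc, ClusterAssignment("C1", labels))


class TestMakeFolds:
    @pytest.mark.parametrize("n,k,sizes", [(10, 5, [2] * 5),
                                           (11, 5, [3, 2, 2, 2, 2])])
    def test_sizes(self, n, k, sizes):
        folds = make_folds(n, k, seed=1)
        assert sorted(len(f) for f in folds) == sorted(sizes)
        assert sorted(np.concatenate(folds)) == list(range(n))

    def test_seed_reproducible(self):
        a = make_folds(20, 5, seed=7)
        b = make_folds(20, 5, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_n_smaller_than_k(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)


def separated_classes(n_per=40, delta=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(i * delta, 1.0, size=(n_per, 7)) for i in range(2)])
    y = np.repeat(["lo", "hi"], n_per)
    return X, y


class TestCrossvalClassify:
    @pytest.mark.parametrize("model", ["SVM", "RF", "LR"])
    def test_separable_classes_near_perfect(self, model):
        X, y = separated_classes()
        rep = crossval_classify(X, y, model=model, seed=0)
        assert rep.mean_accuracy >= 0.95

    def test_every_sample_tested_once_and_bounds(self):
        X, y = separated_classes(n_per=23)
        rep = crossval_classify(X, y, model="LR", seed=3)
        tested = np.concatenate(rep.fold_indices)
        assert sorted(tested) == list(range(len(y)))
        assert all(0.0 <= a <= 1.0 for a in rep.per_fold_accuracy)
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.per_fold_accuracy))

    def test_seed_fixes_report(self):
        X, y = separated_classes(n_per=15, delta=1.0)
        a = crossval_classify(X, y, model="RF", seed=5)
        b = crossval_classify(X, y, model="RF", seed=5)
        assert a.per_fold_accuracy == b.per_fold_accuracy

    def test_rf_invariant_to_duplicated_single_feature(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=120)
        y = np.where(f > 0, "a", "b")
        X7 = np.tile(f[:, None], (1, 7))
        X1 = f[:, None]
        a = crossval_classify(X7, y, model="RF", seed=2)
        b = crossval_classify(X1, y, model="RF", seed=2)
        assert a.per_fold_accuracy == b.per_fold_accuracy

    def test_rare_class_warns_but_kept(self):
        X, y = separated_classes(n_per=10)
        y = y.copy()
        y[0] = "rare"
        with pytest.warns(UserWarning, match="single member"):
            rep = crossval_classify(X, y, model="LR", seed=0)
        assert rep.mean_accuracy > 0

    def test_single_class_rejected(self):
        X = np.zeros((10, 7))
        with pytest.raises(ValueError):
            crossval_classify(X, np.repeat("a", 10), model="LR", seed=0)

    def test_stratified_folds_balance_classes(self):
        X, y = separated_classes(n_per=25, delta=0.0)
        rep = crossval_classify(X, y, model="LR", seed=0, stratify=True)
        for f in rep.fold_indices:
            _, counts = np.unique(y[f], return_counts=True)
            assert max(counts) - min(counts) <= 1


class TestAccuracyMonotoneInSeparation:
    def test_accuracy_grows_with_effect_size(self):
        """Descriptor separability Δ drives accuracy up (chance at Δ=0)."""
        accs = []
        for delta in (0.0, 1.0, 3.0):
            cfg = preset("potable", seed=8, effect_size=delta, n_compounds=120)
            st = generate_study(cfg)
            X = st.descriptors.data.to_numpy()
            y = st.truth["archetype"].to_numpy()
            accs.append(crossval_classify(X, y, model="RF", seed=1).mean_accuracy)
        assert accs[0] <= accs[1] + 0.1
        assert accs[1] <= accs[2] + 0.1
        assert accs[2] > accs[0]


class TestFeatureImportance:
    def test_planted_logkow_signal_ranked_first(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 7))
        y = np.where(X[:, 6] > 0, "high", "low")  # logKow threshold
        rep = rf_feature_importance(X, y, seed=0)
        assert rep.top_feature == "logKow"

    def test_weights_sum_to_one_and_cover_features(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 7))
        y = rng.choice(["a", "b"], size=60)
        rep = rf_feature_importance(X, y, seed=1)
        assert sum(rep.weights.values()) == pytest.approx(1.0)
        assert set(rep.weights) == set(DESCRIPTOR_COLUMNS)

    def test_null_features_share_importance(self):
        """With pure-noise features no single descriptor dominates."""
        rng = np.random.default_rng(9)
        for seed in range(5):
            X = rng.normal(size=(80, 7))
            y = rng.choice(["a", "b"], size=80)
            rep = rf_feature_importance(X, y, seed=seed)
            assert max(rep.weights.values()) < 0.5
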