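"""Comparison assembly, differential filter, classifier training,
evaluation and quality gating."""

import numpy as np
import pandas as pd
import pytest

from geroscreen.classify import (
    AgeClassifierModel,
    ModelQualityGate,
    assemble_comparison,
    default_mtry_grid,
    differential_filter,
    evaluate_classifier,
    load_model,
    save_model,
    select_models,
    train_classifier,
)
from geroscreen.matrix import ExpressionMatrix

from conftest import make_separable_dataset


def _partition_from(young_vals, old_vals, genes, tissue="Lung", gender="f"):
    young = pd.DataFrame(young_vals, index=genes,
                         columns=[f"y{i}" for i in range(np.shape(young_vals)[1])])
    old = pd.DataFrame(old_vals, index=genes,
                       columns=[f"o{i}" for i in range(np.shape(old_vals)[1])])
    return {
        (tissue, gender, "30-39"): ExpressionMatrix(young, stage="log2"),
        (tissue, gender, "60-69"): ExpressionMatrix(old, stage="log2"),
    }


class TestDifferentialFilter:
    def test_constant_gene_dropped(self):
        young = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"])
        old = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"])
        survivors, p = differential_filter(young, old, alpha=0.01)
        assert len(survivors) == 0
        assert p["g"] == 1.0

    def test_strong_shift_retained(self):
        young = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], index=["g"])
        old = pd.DataFrame([[5.0, 5.0, 5.0, 5.1]], index=["g"])
        survivors, p = differential_filter(young, old, alpha=0.01)
        # pooled-variance t by hand: sp^2 = 3*0.0025/6 = 0.00125,
        # t = 5.025 / sqrt(0.00125 * 0.5) = 201, p << 0.01
        assert list(survivors) == ["g"]
        assert p["g"] < 1e-10

    def test_alpha_one_keeps_all_testable(self):
        rng = np.random.default_rng(0)
        young = pd.DataFrame(rng.normal(size=(10, 4)))
        old = pd.DataFrame(rng.normal(size=(10, 4)))
        survivors, _ = differential_filter(young, old, alpha=1.0)
        assert len(survivors) == 10

    def test_too_few_samples_rejected(self):
        one = pd.DataFrame([[1.0]], index=["g"])
        with pytest.raises(ValueError):
            differential_filter(one, one, alpha=0.05)


class TestAssembleComparison:
    def test_small_side_gives_skip_signal(self):
        rng = np.random.default_rng(0)
        parts = _partition_from(rng.normal(5, 1, (6, 9)), rng.normal(5, 1, (6, 12)),
                                [f"g{i}" for i in range(6)])
        ds = assemble_comparison(parts, "Lung", "f", "30-39", universe=[f"g{i}" for i in range(6)])
        assert ds is None

    def test_universe_intersection(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(6)]
        parts = _partition_from(rng.normal(5, 1, (6, 12)), rng.normal(5, 1, (6, 12)), genes)
        ds = assemble_comparison(parts, "Lung", "f", "30-39", universe=genes[:3],
                                 abundance_drop=0.0, de_alpha=1.0)
        assert list(ds.genes) == genes[:3]

    def test_abundance_drop_removes_lowest_mean_genes(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:02d}" for i in range(20)]
        young = rng.normal(8, 0.1, (20, 12))
        old = rng.normal(8, 0.1, (20, 12))
        young[3], old[3] = 1.0, 1.0  # clearly lowest means
        young[17], old[17] = 1.5, 1.5
        parts = _partition_from(young, old, genes)
        ds = assemble_comparison(parts, "Lung", "f", "30-39", universe=genes, de_alpha=1.0)
        assert len(ds.genes) == 18  # floor(0.10 * 20) = 2 dropped
        assert "g03" not in ds.genes and "g17" not in ds.genes

    def test_same_bins_rejected(self):
        with pytest.raises(ValueError):
            assemble_comparison({}, "Lung", "f", "60-69", universe=[], old_bin="60-69")


class TestTrainClassifier:
    def test_majority_class_downsampled(self):
        ds = make_separable_dataset(n_per_side=25, seed=1)
        ds.young = ds.young.iloc[:, :15]  # 15 young vs 25 old
        model = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25,
                                 n_trees=50, seed=0)
        # 15 per class -> 30 total -> 21 train / 9 test
        assert len(model.holdout_y) == 9
        assert model.forest.n_features_in_ == 50

    def test_deterministic_given_seed(self):
        ds = make_separable_dataset(n_per_side=20, seed=2)
        m1 = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25, n_trees=50, seed=7)
        m2 = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25, n_trees=50, seed=7)
        assert m1.mtry == m2.mtry
        assert np.array_equal(
            m1.predict_proba_young(m1.holdout_X), m2.predict_proba_young(m2.holdout_X)
        )

    def test_separable_data_accuracy(self):
        # mean held-out accuracy over seeds on clearly separable data
        accs = []
        for seed in range(10):
            ds = make_separable_dataset(n_per_side=30, seed=seed)
            model = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25,
                                     n_trees=100, seed=seed)
            _, acc = evaluate_classifier(model)
            accs.append(acc)
        assert np.mean(accs) >= 0.9

    def test_too_few_samples_for_folds_rejected(self):
        ds = make_separable_dataset(n_per_side=8, seed=0)
        with pytest.raises(ValueError, match="cv_folds"):
            train_classifier(ds, cv_folds=10, seed=0)

    def test_scaling_constants_from_training_split_only(self):
        ds = make_separable_dataset(n_per_side=20, seed=3)
        model = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25, n_trees=50, seed=1)
        train_samples = (
            set(ds.young.columns) | set(ds.old.columns)
        ) - set(model.holdout_X.index)
        X_all = pd.concat([ds.young.T, ds.old.T])
        X_tr = X_all.loc[sorted(train_samples & set(X_all.index))]
        assert np.allclose(model.center, X_tr.mean(axis=0).to_numpy())
        assert np.allclose(model.scale, X_tr.std(axis=0, ddof=1).to_numpy())

    def test_holdout_values_do_not_influence_tuning(self):
        # the 30% split never leaks into mtry selection
        ds = make_separable_dataset(n_per_side=20, seed=4)
        base = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25, n_trees=50, seed=5)
        perturbed = make_separable_dataset(n_per_side=20, seed=4)
        rng = np.random.default_rng(0)
        for col in base.holdout_X.index:
            if col in perturbed.young.columns:
                perturbed.young[col] += rng.normal(0, 5, size=len(perturbed.young))
            else:
                perturbed.old[col] += rng.normal(0, 5, size=len(perturbed.old))
        again = train_classifier(perturbed, cv_folds=5, cv_repeats=1, cv_n_trees=25,
                                 n_trees=50, seed=5)
        assert again.mtry == base.mtry


class TestEvaluate:
    def test_perfect_separation(self):
        ds = make_separable_dataset(n_per_side=20, n_informative=10, shift_sd=6.0, seed=5)
        model = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25, n_trees=100, seed=2)
        auc, acc = evaluate_classifier(model)
        assert auc == 1.0 and acc == 1.0

    def test_label_randomized_auc_near_half(self):
        # permutation oracle: destroy the labels, AUC ~ 0.5
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(5):
            ds = make_separable_dataset(n_per_side=30, n_informative=0, seed=seed)
            model = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25,
                                     n_trees=100, seed=seed)
            auc, _ = evaluate_classifier(model)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_single_class_holdout_rejected(self):
        ds = make_separable_dataset(n_per_side=20, seed=6)
        model = train_classifier(ds, cv_folds=5, cv_repeats=1, cv_n_trees=25, n_trees=50, seed=3)
        X = model.holdout_X
        with pytest.raises(ValueError, match="single class"):
            evaluate_classifier(model, X, np.array(["young"] * len(X)))


def _dummy_model(**metrics) -> AgeClassifierModel:
    defaults = dict(cv_roc_auc=0.9, cv_sensitivity=0.9, cv_specificity=0.9,
                    test_roc_auc=0.9, test_accuracy=0.9)
    defaults.update(metrics)
    return AgeClassifierModel(
        tissue="T", gender="f", young_bin="30-39", old_bin="60-69", genes=["g"],
        center=np.zeros(1), scale=np.ones(1), forest=None, mtry=1, seed=0, **defaults,
    )


class TestGate:
    def test_all_metrics_above_cutoff_retained(self):
        models = [_dummy_model(cv_roc_auc=0.80)]
        assert select_models(models) == models

    def test_one_failing_metric_drops_model(self):
        models = [_dummy_model(test_accuracy=0.70)]
        assert select_models(models) == []

    def test_exactly_at_cutoff_fails_strict_gate(self):
        models = [_dummy_model(cv_sensitivity=0.75)]
        assert select_models(models) == []

    def test_empty_input(self):
        assert select_models([]) == []

    def test_incomplete_metrics_rejected(self):
        with pytest.raises(ValueError):
            select_models([_dummy_model(test_roc_auc=None)])


def test_default_mtry_grid_clipped_and_unique():
    assert default_mtry_grid(110) == [5, 10, 20, 36]
    assert default_mtry_grid(4) == [1, 2, 4]
    assert all(1 <= m <= 9 for m in default_mtry_grid(9))


def test_model_persistence_round_trip(tmp_path):
    ds = make_separable_dataset(n_per_side=15, n_genes=20, seed=7)
    model = train_classifier(ds, cv_folds=3, cv_repeats=1, cv_n_trees=25, n_trees=50, seed=4)
    evaluate_classifier(model)
    save_model(model, tmp_path / "bundle")
    loaded = load_model(tmp_path / "bundle")
    assert loaded.genes == model.genes
    assert loaded.metrics() == model.metrics()
    X = model.holdout_X
    assert np.array_equal(loaded.predict_proba_young(X), model.predict_proba_young(X))
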