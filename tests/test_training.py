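import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import omicnet as on
from omicnet.training import SplitIndices, binary_auc


def mannwhitney_auc(y_true, scores):
    """AUC via the rank-sum (Mann-Whitney U) formulation — the oracle."""
    y_true = np.asarray(y_true)
    ranks = rankdata(scores)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestSplitDataset:
    def test_hundred_samples_give_60_20_20(self, tiny_sim_config):
        cfg = on.SimConfig(n_samples=100, n_features=10, planted={}, interactions=[], seed=0)
        mats, _, truth = on.generate_cohort(cfg)
        enc = [on.encode_modality(mats[m]) for m in cfg.modalities]
        bundle = on.merge_modalities(enc, on.phenotype_from_truth(truth))
        split = on.split_dataset(bundle, seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (60, 20, 20)

    def test_remainder_goes_to_train_first(self, tiny_bundle):
        sub = tiny_bundle.subset(tiny_bundle.sample_ids[:10])
        split = on.split_dataset(sub, stratify=False, seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    def test_same_seed_identical_partitions(self, tiny_bundle):
        a = on.split_dataset(tiny_bundle, seed=5)
        b = on.split_dataset(tiny_bundle, seed=5)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test

    def test_partitions_are_exact(self, tiny_bundle):
        split = on.split_dataset(tiny_bundle, seed=2)
        all_ids = set(split.train) | set(split.validation) | set(split.test)
        assert all_ids == set(tiny_bundle.sample_ids)
        assert len(split.train) + len(split.validation) + len(split.test) == len(all_ids)

    def test_stratification_preserves_class_shares(self, tiny_bundle):
        split = on.split_dataset(tiny_bundle, stratify=True, seed=3)
        labels = tiny_bundle.phenotype.labels
        for cls in labels.unique():
            n_cls = (labels == cls).sum()
            for part, frac in zip((split.train, split.validation, split.test), (0.6, 0.2, 0.2)):
                got = sum(labels.loc[s] == cls for s in part)
                assert abs(got - n_cls * frac) <= 1.0

    def test_small_class_under_stratification_rejected(self):
        from omicnet.omics_io import PhenotypeTable, get_modality

        enc = on.EncodedModality(
            get_modality("gene_expression"),
            [f"s{i}" for i in range(10)],
            ["f1"],
            np.zeros((10, 1, 1)),
        )
        labels = pd.Series(["a"] * 8 + ["b"] * 2, index=[f"s{i}" for i in range(10)])
        bundle = on.merge_modalities(
            [enc], PhenotypeTable(labels=labels, task="classification")
        )
        with pytest.raises(ValueError, match="stratified"):
            on.split_dataset(bundle, stratify=True, seed=0)

    def test_bad_fractions_rejected(self, tiny_bundle):
        with pytest.raises(ValueError, match="fractions"):
            on.split_dataset(tiny_bundle, fractions=(0.5, 0.2, 0.2))


class TestMakeFolds:
    def test_five_equal_folds_of_twenty(self):
        cfg = on.SimConfig(n_samples=100, n_features=10, planted={}, interactions=[], seed=0)
        mats, _, truth = on.generate_cohort(cfg)
        enc = [on.encode_modality(mats[m]) for m in cfg.modalities]
        bundle = on.merge_modalities(enc, on.phenotype_from_truth(truth))
        folds = on.make_folds(bundle, k=5, seed=0)
        assert folds.sizes() == [20] * 5

    def test_balanced_remainder(self, tiny_bundle):
        sub = tiny_bundle.subset(tiny_bundle.sample_ids[:7])
        folds = on.make_folds(sub, k=5, stratify=False, seed=0)
        assert sorted(folds.sizes(), reverse=True) == [2, 2, 1, 1, 1]

    def test_folds_partition_all_samples(self, tiny_bundle):
        folds = on.make_folds(tiny_bundle, k=5, seed=1)
        assert set(folds.fold_of) == set(tiny_bundle.sample_ids)
        assert sum(folds.sizes()) == tiny_bundle.n_samples

    def test_more_folds_than_samples_rejected(self, tiny_bundle):
        labels = tiny_bundle.phenotype.labels
        mixed = [labels[labels == c].index[0] for c in labels.unique()]
        sub = tiny_bundle.subset(mixed + [labels.index[10]])
        with pytest.raises(ValueError, match="folds"):
            on.make_folds(sub, k=5, stratify=False)


class TestTrainModel:
    def test_learnable_signal_reduces_loss(self, tiny_bundle):
        spec = on.ModelSpec(epochs=8, seed=0, dropout=0.0)
        handle = on.build_multi_cnn(spec, tiny_bundle.input_shapes())
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, curve = on.train_model(handle, tiny_bundle, split)
        assert curve.train_loss[-1] < curve.train_loss[0]
        assert handle.fitted

    def test_single_epoch_single_point_curve(self, tiny_bundle):
        spec = on.ModelSpec(epochs=1, seed=0)
        handle = on.build_multi_cnn(spec, tiny_bundle.input_shapes())
        split = on.split_dataset(tiny_bundle, seed=0)
        _, curve = on.train_model(handle, tiny_bundle, split)
        assert len(curve) == 1

    def test_loss_contract_per_task(self, tiny_bundle):
        clf = on.build_multi_cnn(on.ModelSpec(task="classification"), tiny_bundle.input_shapes())
        assert clf.metadata["loss"] == "cross_entropy"
        reg_handle = on.build_baseline("random_forest", task="regression")
        assert reg_handle.metadata["loss"] == "mean_squared_error"

    def test_refitting_requires_clone(self, tiny_bundle):
        handle = on.build_baseline("decision_tree")
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, _ = on.train_model(handle, tiny_bundle, split)
        with pytest.raises(ValueError, match="clone"):
            on.train_model(handle, tiny_bundle, split)


class TestEvaluateModel:
    def test_perfect_scores_auc_one(self):
        y = np.array([0, 1, 0, 1, 1])
        assert binary_auc(y, y.astype(float)) == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(123)
        y = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        assert abs(binary_auc(y, scores) - 0.5) < 0.05

    def test_trapezoid_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = rng.integers(10, 200)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            assert abs(binary_auc(y, scores) - mannwhitney_auc(y, scores)) < 1e-12

    def test_regression_identity_predictions(self, tiny_bundle):
        from omicnet.omics_io import PhenotypeTable

        reg = on.build_baseline("decision_tree", task="regression")
        labels = pd.Series(
            np.arange(tiny_bundle.n_samples, dtype=float), index=tiny_bundle.sample_ids
        )
        bundle = on.DatasetBundle(
            modalities=tiny_bundle.modalities,
            phenotype=PhenotypeTable(labels=labels, task="regression"),
        )
        split = SplitIndices(bundle.sample_ids, [], [], (1, 0, 0), 0)
        reg, _ = on.train_model(reg, bundle, split)
        # an unpruned tree interpolates its training data exactly
        report = on.evaluate_model(reg, bundle)
        assert report.pcc == pytest.approx(1.0) and report.r2 == pytest.approx(1.0)

    def test_single_class_truth_rejected(self, tiny_bundle):
        labels = tiny_bundle.phenotype.labels
        one_class = labels[labels == labels.iloc[0]].index[:5]
        handle = on.build_baseline("decision_tree")
        split = on.split_dataset(tiny_bundle, seed=0)
        handle, _ = on.train_model(handle, tiny_bundle, split)
        with pytest.raises(ValueError, match="single-class"):
            on.evaluate_model(handle, tiny_bundle, indices=list(one_class))

    def test_fold_mode_reports_per_fold_and_mean(self, tiny_bundle):
        handle = on.build_baseline("logistic_l2")
        folds = on.make_folds(tiny_bundle, k=3, seed=0)
        report = on.evaluate_model(handle, tiny_bundle, folds=folds)
        assert len(report.per_fold) == 3
        assert report.auc == pytest.approx(np.mean([f["auc"] for f in report.per_fold]))


class TestTuneHyperparameters:
    def test_bayesian_finds_quadratic_minimum(self):
        result = on.tune_hyperparameters(
            {"x": (0.0, 5.0)},
            lambda a: (a["x"] - 2.0) ** 2,
            n_trials=40,
            seed=0,
            mode="bayesian",
        )
        assert abs(result.best_params["x"] - 2.0) < 0.25

    def test_trace_is_monotone_for_minimization(self):
        result = on.tune_hyperparameters(
            {"x": (-1.0, 1.0)}, lambda a: a["x"] ** 2, n_trials=25, seed=1
        )
        trace = result.trace
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_same_seed_identical_trial_sequence(self):
        args = dict(n_trials=15, seed=4, mode="bayesian")
        a = on.tune_hyperparameters({"x": (0.0, 1.0)}, lambda p: p["x"], **args)
        b = on.tune_hyperparameters({"x": (0.0, 1.0)}, lambda p: p["x"], **args)
        assert [t[0]["x"] for t in a.trials] == [t[0]["x"] for t in b.trials]

    def test_bayesian_beats_random_on_smooth_objectives(self):
        def objective(a):
            return (a["x"] - 1.2) ** 2 + (a["y"] + 0.7) ** 2

        space = {"x": (-3.0, 3.0), "y": (-3.0, 3.0)}
        gaps = {"bayesian": [], "random": []}
        for seed in range(20):
            for mode in gaps:
                res = on.tune_hyperparameters(
                    space, objective, n_trials=40, seed=seed, mode=mode
                )
                gaps[mode].append(res.best_value)
        assert np.median(gaps["bayesian"]) < np.median(gaps["random"])

    def test_integer_and_categorical_domains(self):
        space = {"n": ("int", 1, 8), "kind": ["a", "b"]}
        res = on.tune_hyperparameters(
            space,
            lambda p: abs(p["n"] - 6) + (0.0 if p["kind"] == "b" else 0.5),
            n_trials=30,
            seed=2,
        )
        assert abs(res.best_params["n"] - 6) <= 1 and res.best_params["kind"] == "b"
        assert all(isinstance(t[0]["n"], int) for t in res.trials)

    def test_all_failing_objective_raises_after_exhaustion(self):
        def broken(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="all 5 trials"):
            on.tune_hyperparameters({"x": (0, 1)}, broken, n_trials=5, seed=0)
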