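"""CV splitting, metrics, the subset sweep, and error-rate accounting."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from omifuse.evaluation import (
    FoldProbabilities,
    compute_metrics,
    enumerate_subsets,
    error_rate_reduction,
    evaluate_subset_fold,
    stratified_patientwise_kfold,
    subset_sweep,
    summarize_reports,
)
from omifuse.exceptions import DegenerateClassError, InvalidSpecError
from omifuse.fusion import FusionTrainConfig
from omifuse.types import DEFAULT_CLASSES


def patient_series(n_per_class, classes=DEFAULT_CLASSES):
    labels = np.repeat(list(classes), n_per_class)
    return pd.Series(labels, index=[f"P{i}" for i in range(len(labels))])


class TestKFold:
    def test_balanced_cohort_one_patient_per_class_per_fold(self):
        splits = stratified_patientwise_kfold(patient_series(10), k=10, seed=0)
        labels = patient_series(10)
        assert len(splits) == 10
        for sp in splits:
            assert len(sp.test_patients) == 3
            assert sorted(labels.loc[sp.test_patients]) == sorted(DEFAULT_CLASSES)

    def test_patients_never_split_and_folds_cover_everyone(self):
        labels = patient_series(13)
        splits = stratified_patientwise_kfold(labels, k=4, seed=1)
        seen = []
        for sp in splits:
            assert not set(sp.train_patients) & set(sp.test_patients)
            assert set(sp.train_patients) | set(sp.test_patients) == set(labels.index)
            seen.extend(sp.test_patients)
        assert sorted(seen) == sorted(labels.index)

    def test_multi_sample_patient_stays_on_one_side(self):
        # samples resolve membership through their patient id, so a patient
        # with 2 slides and 1 RNA sample lands entirely in train or test
        labels = patient_series(6)
        splits = stratified_patientwise_kfold(labels, k=3, seed=2)
        samples = {"P0": ["P0_slideA", "P0_slideB", "P0_rna"]}
        for sp in splits:
            in_train = "P0" in set(sp.train_patients)
            side = sp.train_patients if in_train else sp.test_patients
            assert all(pid in set(side) for pid in ["P0"] * len(samples["P0"]))

    def test_k1_and_oversized_k_error(self):
        with pytest.raises(InvalidSpecError):
            stratified_patientwise_kfold(patient_series(5), k=1)
        with pytest.raises(DegenerateClassError):
            stratified_patientwise_kfold(patient_series(5), k=6)

    def test_deterministic_under_seed(self):
        a = stratified_patientwise_kfold(patient_series(8), k=4, seed=5)
        b = stratified_patientwise_kfold(patient_series(8), k=4, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.test_patients, y.test_patients)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(list(DEFAULT_CLASSES) * 5)
        scores = np.array([[1.0 if c == t else 0.0 for c in DEFAULT_CLASSES] for t in y])
        rep = compute_metrics(y, scores, DEFAULT_CLASSES)
        assert rep.accuracy == 1.0 and rep.f1_weighted == 1.0
        assert rep.auc_macro == 1.0 and rep.auprc_macro == 1.0
        assert np.trace(rep.confusion.values) == len(y)

    def test_half_wrong_balanced_binary_toy(self):
        y = np.array(["LUAD"] * 10 + ["LUSC"] * 10)
        pred_class = ["LUAD"] * 5 + ["LUSC"] * 5 + ["LUSC"] * 5 + ["LUAD"] * 5
        scores = np.array([[0.9 if c == p else 0.05 for c in DEFAULT_CLASSES]
                           for p in pred_class])
        rep = compute_metrics(y, scores, DEFAULT_CLASSES)
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.confusion.loc["LUAD"].sum() == 10  # row sums = class counts

    def test_random_scores_auc_near_half(self, rng):
        n = 4000
        y = rng.choice(DEFAULT_CLASSES, size=n)
        scores = rng.dirichlet(np.ones(3), size=n)
        rep = compute_metrics(y, scores, DEFAULT_CLASSES)
        assert rep.auc_macro == pytest.approx(0.5, abs=0.03)

    def test_absent_class_reported_missing_with_warning(self, caplog):
        y = np.array(["LUAD", "LUSC", "LUAD", "LUSC"])
        scores = np.tile([0.4, 0.3, 0.3], (4, 1))
        with caplog.at_level("WARNING"):
            rep = compute_metrics(y, scores, DEFAULT_CLASSES)
        assert np.isnan(rep.auc_per_class["control"])
        assert np.isfinite(rep.auc_macro)

    def test_roc_pr_curves_cover_present_classes(self, rng):
        from omifuse.evaluation import roc_pr_curves

        y = rng.choice(["LUAD", "LUSC"], size=50)
        scores = rng.dirichlet(np.ones(3), size=50)
        df = roc_pr_curves(y, scores, DEFAULT_CLASSES)
        assert set(df["class"]) == {"LUAD", "LUSC"}  # absent class skipped
        roc = df[(df["class"] == "LUAD") & (df["curve"] == "roc")]
        assert roc["x"].is_monotonic_increasing
        assert roc["y"].between(0, 1).all()

    def test_fold_aggregation_uses_sample_std(self):
        y = np.array(["LUAD", "LUSC"])
        perfect = np.array([[1, 0, 0], [0, 0, 1.0]])
        wrong = perfect[::-1]
        reps = [compute_metrics(y, perfect, DEFAULT_CLASSES),
                compute_metrics(y, wrong, DEFAULT_CLASSES)]
        s = summarize_reports(reps)
        assert s.loc["accuracy", "mean"] == pytest.approx(0.5)
        assert s.loc["accuracy", "std"] == pytest.approx(np.std([1.0, 0.0], ddof=1))


class TestErrorRateReduction:
    def test_reference_cohort_counts(self):
        assert error_rate_reduction((1636, 220), (1796, 60), 1856) == 8.6
        assert error_rate_reduction((913, 67), (929, 51), 980) == 1.6

    def test_identical_models_zero(self):
        assert error_rate_reduction((90, 10), (90, 10), 100) == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidSpecError):
            error_rate_reduction((90, 5), (90, 10), 100)
        with pytest.raises(InvalidSpecError):
            error_rate_reduction((90, 10), (90, 10), 0)


def toy_fold(rng, n=60, quality=(0.95, 0.7)):
    """One synthetic fold with two modalities of configurable reliability."""
    classes = DEFAULT_CLASSES
    y = rng.choice(classes, size=2 * n)

    def probs_for(acc):
        out = np.zeros((2 * n, 3))
        for i, t in enumerate(y):
            true = classes.index(t)
            pick = true if rng.random() < acc else rng.integers(0, 3)
            out[i] = 0.1
            out[i, pick] = 0.8
        return out

    tensors = np.stack([probs_for(a) for a in quality], axis=1)
    tensors /= tensors.sum(axis=2, keepdims=True)
    table = make_table(tensors, modalities=("A", "B"))
    return FoldProbabilities(
        fold=0,
        train=table.select_samples(np.arange(n)),
        test=table.select_samples(np.arange(n, 2 * n)),
        train_labels=y[:n],
        test_labels=y[n:],
    )


class TestSubsetSweep:
    def test_five_modalities_enumerate_31_subsets(self):
        subsets = enumerate_subsets(["a", "b", "c", "d", "e"])
        assert len(subsets) == 31
        assert len(set(subsets)) == 31

    def test_singleton_subset_reproduces_single_modality_metrics(self, rng):
        fold = toy_fold(rng)
        out = evaluate_subset_fold(fold, ("A",), FusionTrainConfig(epochs=2, seed=0))
        assert out is not None
        report, weights = out
        # M=1: softmax collapses to weight 1, so fused scores == the modality's probs
        assert weights.projected == pytest.approx(np.ones((3, 1)))
        direct = compute_metrics(fold.test_labels, fold.test.probs[:, 0, :],
                                 DEFAULT_CLASSES)
        assert report.accuracy == direct.accuracy
        assert report.f1_weighted == direct.f1_weighted

    def test_sweep_table_covers_requested_subsets(self, rng):
        fold = toy_fold(rng)
        table = subset_sweep([fold], [("A",), ("B",), ("A", "B")],
                             FusionTrainConfig(epochs=2, seed=0))
        assert list(table.index) == ["A", "B", "A+B"]
        assert (table["folds"] == 1).all()

    def test_common_regime_restricts_to_joint_samples(self, rng):
        fold = toy_fold(rng)
        fold.test.mask[:10, 1] = False
        fold.test.probs[:10, 1, :] = 0.0
        out_common = evaluate_subset_fold(fold, ("A", "B"),
                                          FusionTrainConfig(epochs=2, seed=0), "common")
        out_all = evaluate_subset_fold(fold, ("A", "B"),
                                       FusionTrainConfig(epochs=2, seed=0), "all")
        assert out_common[0].n == fold.test.n_samples - 10
        assert out_all[0].n == fold.test.n_samples

    def test_label_permutation_does_not_change_trained_weights(self, rng):
        # no leakage: test labels play no role in fusion-weight training
        fold = toy_fold(rng)
        _, w1 = evaluate_subset_fold(fold, ("A", "B"), FusionTrainConfig(epochs=2, seed=3))
        fold.test_labels = rng.permutation(fold.test_labels)
        _, w2 = evaluate_subset_fold(fold, ("A", "B"), FusionTrainConfig(epochs=2, seed=3))
        assert np.array_equal(w1.raw, w2.raw)
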