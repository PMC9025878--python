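"""Stratified patient-wise cross-validation, metrics, the modality-subset
fusion sweep, and misclassification-reduction accounting.

All model-dependent steps — feature screening, mRMR ranking, scaling, SVM
grid search, tile-classifier fitting and fusion-weight optimization — run
inside each training fold only, so no information leaks from test patients
into any trained artifact.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .exceptions import DegenerateClassError, InvalidSpecError, OrderMismatchError
from .features import TTestSelectionConfig, mrmr_rank, ttest_screen
from .fusion import FusionTrainConfig, fuse, optimize_weights
from .models import SVMConfig, fit_svm_modality, predict_proba
from .types import FusionWeights, LabeledCohort, ModalityMatrix, ProbabilityTable
from .wsi import MeanColorTileClassifier, SlideTileSet, TilePredictionSet, slide_probabilities

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cross-validation splitting
# ---------------------------------------------------------------------------
@dataclass
class CVSplit:
    """One fold: disjoint train/test patient id sets."""

    fold: int
    train_patients: np.ndarray
    test_patients: np.ndarray


def stratified_patientwise_kfold(cohort_or_labels, k: int, seed: int = 0) -> list[CVSplit]:
    """Stratified k-fold over *patients*, never splitting a patient.

    Accepts a :class:`LabeledCohort` or a Series of patient labels indexed by
    patient id.  Stratification keeps each fold's per-class patient count
    within one of the even split.
    """
    if isinstance(cohort_or_labels, LabeledCohort):
        labels = cohort_or_labels.patients["label"]
    else:
        labels = pd.Series(cohort_or_labels)
    if k < 2:
        raise InvalidSpecError("k must be >= 2 (k=1 leaves no training data)")
    counts = labels.value_counts()
    if k > counts.min():
        raise DegenerateClassError(
            f"k={k} exceeds smallest class size {counts.min()} ({counts.idxmin()!r})"
        )
    patients = labels.index.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        CVSplit(fold=i, train_patients=patients[tr], test_patients=patients[te])
        for i, (tr, te) in enumerate(skf.split(patients, labels.to_numpy()))
    ]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
@dataclass
class MetricsReport:
    """Classification metrics for one evaluation set."""

    n: int
    accuracy: float
    f1_weighted: float
    f1_macro: float
    auc_per_class: dict[str, float]
    auprc_per_class: dict[str, float]
    auc_macro: float
    auprc_macro: float
    confusion: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "f1_weighted": self.f1_weighted,
            "f1_macro": self.f1_macro,
            "auc_macro": self.auc_macro,
            "auprc_macro": self.auprc_macro,
        }


def compute_metrics(y_true, scores: np.ndarray, classes: Sequence[str]) -> MetricsReport:
    """Accuracy, F1 (weighted and macro), one-vs-rest AUC/average precision.

    ``scores`` holds one column per class (probabilities or fused scores).
    A class absent from ``y_true`` has undefined AUC; it is reported as NaN
    and excluded from the macro averages with a warning.
    """
    classes = tuple(classes)
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise InvalidSpecError("need at least one sample")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(y_true), len(classes)):
        raise OrderMismatchError(
            f"scores shape {scores.shape} != ({len(y_true)}, {len(classes)})"
        )
    y_pred = np.asarray([classes[i] for i in scores.argmax(axis=1)])
    acc = float(np.mean(y_pred == y_true))
    f1w = float(f1_score(y_true, y_pred, labels=list(classes), average="weighted", zero_division=0))
    f1m = float(f1_score(y_true, y_pred, labels=list(classes), average="macro", zero_division=0))

    auc, ap = {}, {}
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            logger.warning("class %r absent (or alone) in y_true; AUC/AUPRC undefined", c)
            auc[c] = np.nan
            ap[c] = np.nan
            continue
        auc[c] = float(roc_auc_score(pos, scores[:, i]))
        ap[c] = float(average_precision_score(pos, scores[:, i]))
    auc_vals = [v for v in auc.values() if np.isfinite(v)]
    ap_vals = [v for v in ap.values() if np.isfinite(v)]
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    return MetricsReport(
        n=len(y_true),
        accuracy=acc,
        f1_weighted=f1w,
        f1_macro=f1m,
        auc_per_class=auc,
        auprc_per_class=ap,
        auc_macro=float(np.mean(auc_vals)) if auc_vals else np.nan,
        auprc_macro=float(np.mean(ap_vals)) if ap_vals else np.nan,
        confusion=pd.DataFrame(cm, index=list(classes), columns=list(classes)),
    )


def roc_pr_curves(y_true, scores: np.ndarray, classes: Sequence[str]) -> pd.DataFrame:
    """Per-class one-vs-rest ROC and precision-recall curve points, long format.

    Columns: class, curve ("roc"/"pr"), x (FPR or recall), y (TPR or
    precision), threshold.  Ready to write as TSV for plotting elsewhere.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    y_true = np.asarray(y_true)
    rows = []
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        fpr, tpr, thr = roc_curve(pos, scores[:, i])
        rows.extend({"class": c, "curve": "roc", "x": a, "y": b, "threshold": t}
                    for a, b, t in zip(fpr, tpr, thr))
        prec, rec, thr = precision_recall_curve(pos, scores[:, i])
        rows.extend({"class": c, "curve": "pr", "x": r, "y": p, "threshold": t}
                    for p, r, t in zip(prec[:-1], rec[:-1], thr))
    return pd.DataFrame(rows, columns=["class", "curve", "x", "y", "threshold"])


def summarize_reports(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Across-fold mean and sample (n-1) standard deviation of each metric."""
    rows = [r.as_dict() for r in reports]
    df = pd.DataFrame(rows).drop(columns="n")
    return pd.DataFrame({"mean": df.mean(), "std": df.std(ddof=1)})


def error_rate_reduction(
    single_counts: tuple[int, int], fusion_counts: tuple[int, int], total: int
) -> float:
    """Percentage-point drop in the misclassification rate from fusion.

    ``single_counts`` and ``fusion_counts`` are (correct, misclassified)
    pairs over the same ``total`` samples; the result is
    ``100 * (mis_single - mis_fusion) / total`` rounded to one decimal.
    """
    if total <= 0:
        raise InvalidSpecError("total must be positive")
    for name, (correct, mis) in (("single", single_counts), ("fusion", fusion_counts)):
        if correct < 0 or mis < 0 or correct + mis != total:
            raise InvalidSpecError(
                f"{name} counts ({correct} + {mis}) inconsistent with total {total}"
            )
    return round(100.0 * (single_counts[1] - fusion_counts[1]) / total, 1)


# ---------------------------------------------------------------------------
# per-fold probability generation (the full per-modality pipeline)
# ---------------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """End-to-end settings for the cross-validated fusion experiment."""

    n_select: int = 10  # mRMR prefix length fed to each SVM
    screen: TTestSelectionConfig = field(
        default_factory=lambda: TTestSelectionConfig(
            required_comparisons=2, mean_diff_threshold=0.4
        )
    )
    svm: SVMConfig = field(default_factory=SVMConfig)
    fusion: FusionTrainConfig = field(default_factory=FusionTrainConfig)
    k_folds: int = 10
    seed: int = 0
    tile_classifier_factory: Callable[[], object] = MeanColorTileClassifier


@dataclass
class FoldProbabilities:
    """Per-modality probability tables for one fold's train and test patients."""

    fold: int
    train: ProbabilityTable
    test: ProbabilityTable
    train_labels: np.ndarray
    test_labels: np.ndarray


def assemble_probability_table(
    sample_ids: Sequence[str],
    classes: Sequence[str],
    modalities: Sequence[str],
    blocks: Mapping[str, pd.DataFrame],
) -> ProbabilityTable:
    """Stack per-modality probability frames (index: sample id, columns: classes)
    into a dense tensor, zero-filling missing (sample, modality) pairs."""
    sample_ids = list(sample_ids)
    classes = tuple(classes)
    modalities = tuple(modalities)
    probs = np.zeros((len(sample_ids), len(modalities), len(classes)))
    mask = np.zeros((len(sample_ids), len(modalities)), dtype=bool)
    pos = {s: i for i, s in enumerate(sample_ids)}
    for j, mod in enumerate(modalities):
        blk = blocks.get(mod)
        if blk is None:
            continue
        for sid, row in zip(blk.index, blk.loc[:, list(classes)].to_numpy()):
            i = pos.get(sid)
            if i is not None:
                probs[i, j, :] = row
                mask[i, j] = True
    return ProbabilityTable(
        sample_ids=sample_ids, classes=classes, modalities=modalities, probs=probs, mask=mask
    )


def _molecular_fold_probs(
    mm: ModalityMatrix,
    train_patients: np.ndarray,
    test_patients: np.ndarray,
    config: PipelineConfig,
    fold_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen + rank features, fit the SVM and emit train/test probabilities."""
    mm_train = mm.with_samples(train_patients)
    mm_test = mm.with_samples(test_patients)
    selected = ttest_screen(mm_train, config.screen)
    if not selected:
        logger.warning("%s: t-test screen kept nothing; ranking all features", mm.modality)
        selected = mm_train.feature_names
    ranking = mrmr_rank(mm_train.with_features(selected), k=min(config.n_select, len(selected)))
    feats = ranking.feature_names
    svm_cfg = SVMConfig(
        C_grid=config.svm.C_grid,
        gamma_grid=config.svm.gamma_grid,
        inner_cv_folds=config.svm.inner_cv_folds,
        seed=fold_seed,
    )
    model = fit_svm_modality(mm_train.with_features(feats), svm_cfg)

    def frame(sub: ModalityMatrix) -> pd.DataFrame:
        probs = predict_proba(model, sub.with_features(feats))
        return pd.DataFrame(probs, index=sub.values.index, columns=list(model.classes))

    return frame(mm_train), frame(mm_test)


def _wsi_fold_probs(
    tile_sets: Mapping[str, SlideTileSet],
    train_patients: np.ndarray,
    test_patients: np.ndarray,
    classes: tuple[str, ...],
    factory: Callable[[], object],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the tile classifier on training tiles; emit tile-fraction probabilities."""
    train_tiles, train_tile_labels = [], []
    for pid in train_patients:
        ts = tile_sets.get(pid)
        if ts is not None and ts.n_tiles:
            train_tiles.extend(ts.tiles)
            train_tile_labels.extend([ts.label] * ts.n_tiles)
    clf = factory().fit(train_tiles, train_tile_labels)

    def frame(patients: np.ndarray) -> pd.DataFrame:
        rows, idx = [], []
        for pid in patients:
            ts = tile_sets.get(pid)
            if ts is None or not ts.n_tiles:
                continue
            preds = TilePredictionSet(
                slide_id=ts.slide_id, predictions=clf.predict(ts.tiles), classes=classes
            )
            rows.append(slide_probabilities(preds))
            idx.append(pid)
        return pd.DataFrame(rows, index=idx, columns=list(classes))

    return frame(train_patients), frame(test_patients)


def cross_validated_probabilities(
    cohort: LabeledCohort,
    config: PipelineConfig | None = None,
    tile_sets: Mapping[str, SlideTileSet] | None = None,
) -> list[FoldProbabilities]:
    """Run the whole per-modality pipeline inside each CV fold.

    Returns, per fold, probability tables over the fold's train and test
    patients for every modality (the slide modality ``"WSI"`` first when
    ``tile_sets`` is given), with missing (patient, modality) pairs zero-filled.
    """
    config = config or PipelineConfig()
    classes = tuple(cohort.classes)
    modalities = tuple(cohort.modality_names)
    if tile_sets is not None:
        modalities = ("WSI",) + modalities
    splits = stratified_patientwise_kfold(cohort, config.k_folds, seed=config.seed)
    label_of = cohort.patients["label"]

    folds: list[FoldProbabilities] = []
    for split in splits:
        fold_seed = config.seed + split.fold
        blocks_train: dict[str, pd.DataFrame] = {}
        blocks_test: dict[str, pd.DataFrame] = {}
        if tile_sets is not None:
            blocks_train["WSI"], blocks_test["WSI"] = _wsi_fold_probs(
                tile_sets, split.train_patients, split.test_patients, classes,
                config.tile_classifier_factory,
            )
        for mod in cohort.modality_names:
            blocks_train[mod], blocks_test[mod] = _molecular_fold_probs(
                cohort.modalities[mod], split.train_patients, split.test_patients,
                config, fold_seed,
            )
        folds.append(
            FoldProbabilities(
                fold=split.fold,
                train=assemble_probability_table(
                    split.train_patients, classes, modalities, blocks_train
                ),
                test=assemble_probability_table(
                    split.test_patients, classes, modalities, blocks_test
                ),
                train_labels=label_of.loc[split.train_patients].to_numpy(),
                test_labels=label_of.loc[split.test_patients].to_numpy(),
            )
        )
        logger.info("fold %d: probability tables ready", split.fold)
    return folds


# ---------------------------------------------------------------------------
# subset sweep and the full experiment
# ---------------------------------------------------------------------------
def enumerate_subsets(modalities: Sequence[str]) -> list[tuple[str, ...]]:
    """All nonempty modality subsets, smallest first (2^M - 1 of them)."""
    mods = list(modalities)
    return [
        tuple(c)
        for size in range(1, len(mods) + 1)
        for c in itertools.combinations(mods, size)
    ]


def _subset_rows(table: ProbabilityTable, subset: tuple[str, ...], regime: str) -> np.ndarray:
    cols = [table.modalities.index(m) for m in subset]
    sub_mask = table.mask[:, cols]
    if regime == "common":
        return np.flatnonzero(sub_mask.all(axis=1))
    if regime == "all":
        return np.flatnonzero(sub_mask.any(axis=1))
    raise InvalidSpecError(f"unknown regime {regime!r} (use 'common' or 'all')")


def evaluate_subset_fold(
    fold: FoldProbabilities,
    subset: tuple[str, ...],
    fusion_config: FusionTrainConfig,
    regime: str = "common",
) -> tuple[MetricsReport, FusionWeights] | None:
    """Train fusion weights on one fold's training probabilities restricted to
    ``subset`` and score the fold's test samples; None when the subset has no
    usable train or test samples in this fold."""
    tr = fold.train.select_modalities(subset)
    te = fold.test.select_modalities(subset)
    tr_rows = _subset_rows(tr, subset, regime)
    te_rows = _subset_rows(te, subset, regime)
    if len(tr_rows) == 0 or len(te_rows) == 0:
        logger.warning("fold %d, subset %s: no %s samples; skipped",
                       fold.fold, subset, regime)
        return None
    tr_sub = tr.select_samples(tr_rows)
    te_sub = te.select_samples(te_rows)
    weights = optimize_weights(tr_sub, fold.train_labels[tr_rows], fusion_config)
    scores = fuse(te_sub, weights)
    report = compute_metrics(fold.test_labels[te_rows], scores, tr.classes)
    return report, weights


def subset_sweep(
    folds: Sequence[FoldProbabilities],
    subsets: Sequence[tuple[str, ...]],
    fusion_config: FusionTrainConfig | None = None,
    regime: str = "common",
) -> pd.DataFrame:
    """Fusion metrics (across-fold mean and std) for each modality subset."""
    if not subsets:
        raise InvalidSpecError("need at least one subset")
    fusion_config = fusion_config or FusionTrainConfig()
    rows = []
    for subset in subsets:
        reports = []
        for fold in folds:
            out = evaluate_subset_fold(fold, tuple(subset), fusion_config, regime)
            if out is not None:
                reports.append(out[0])
        if not reports:
            logger.warning("subset %s: skipped in every fold", subset)
            continue
        summary = summarize_reports(reports)
        rows.append(
            {
                "subset": "+".join(subset),
                "n_modalities": len(subset),
                "folds": len(reports),
                **{
                    f"{metric}_{stat}": summary.loc[metric, stat]
                    for metric in summary.index
                    for stat in ("mean", "std")
                },
            }
        )
    return pd.DataFrame(rows).set_index("subset")


@dataclass
class ExperimentResult:
    """Per-modality and full-fusion fold reports plus learned weights."""

    per_modality: dict[str, list[MetricsReport]]
    fused: list[MetricsReport]
    weights: list[FusionWeights]

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, reports in self.per_modality.items():
            s = summarize_reports(reports)
            rows[name] = {
                f"{m}_{st}": s.loc[m, st] for m in s.index for st in ("mean", "std")
            }
        s = summarize_reports(self.fused)
        rows["fusion(all)"] = {
            f"{m}_{st}": s.loc[m, st] for m in s.index for st in ("mean", "std")
        }
        return pd.DataFrame(rows).T


def run_fusion_experiment(
    cohort: LabeledCohort,
    config: PipelineConfig | None = None,
    tile_sets: Mapping[str, SlideTileSet] | None = None,
    regime: str = "all",
) -> ExperimentResult:
    """Cross-validated single-modality baselines plus all-modality fusion.

    Single-modality metrics use each modality's own available test samples;
    the fused model is scored under ``regime`` ("all": every test sample with
    at least one modality, zero-filling the rest; "common": only samples with
    every modality present).
    """
    config = config or PipelineConfig()
    folds = cross_validated_probabilities(cohort, config, tile_sets)
    modalities = folds[0].train.modalities

    per_modality: dict[str, list[MetricsReport]] = {m: [] for m in modalities}
    fused_reports: list[MetricsReport] = []
    weights_per_fold: list[FusionWeights] = []
    for fold in folds:
        for j, mod in enumerate(modalities):
            rows = np.flatnonzero(fold.test.mask[:, j])
            if len(rows) == 0:
                continue
            per_modality[mod].append(
                compute_metrics(
                    fold.test_labels[rows], fold.test.probs[rows, j, :], fold.test.classes
                )
            )
        out = evaluate_subset_fold(fold, tuple(modalities), config.fusion, regime)
        if out is not None:
            fused_reports.append(out[0])
            weights_per_fold.append(out[1])
    return ExperimentResult(
        per_modality=per_modality, fused=fused_reports, weights=weights_per_fold
    )
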