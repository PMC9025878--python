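"""Molecular feature selection: missing-value removal, differential-expression
thresholds, pairwise t-test screening with Bonferroni control, and mRMR ranking.

All operations are pure: the input :class:`~omifuse.types.ModalityMatrix` is
never modified; selections are returned as feature-name lists or a
:class:`FeatureRanking`.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .exceptions import DegenerateClassError, DomainError, EmptyMatrixError
from .types import ModalityMatrix

logger = logging.getLogger(__name__)


@dataclass
class TTestSelectionConfig:
    """Settings for pairwise two-tailed t-test screening.

    A feature passes when its (optionally Bonferroni-adjusted) p-value is at
    or below ``alpha`` in at least ``required_comparisons`` of the pairwise
    class comparisons, and every one of those significant comparisons also
    shows an absolute mean difference of at least ``mean_diff_threshold``.
    The conventions for copy-number data are all three comparisons with a
    0.1 mean-difference floor; for methylation beta values, two of three
    with a 0.4 floor.
    """

    alpha: float = 0.001
    bonferroni: bool = True
    required_comparisons: int = 3
    mean_diff_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.required_comparisons not in (1, 2, 3):
            raise ValueError("required_comparisons must be 1, 2 or 3")
        if self.mean_diff_threshold < 0:
            raise ValueError("mean_diff_threshold must be >= 0")


@dataclass
class DEGFilterConfig:
    """Differential-expression thresholds: |log2 fold change| >= ``lfc_threshold``,
    omnibus p-value <= ``p_threshold``, coefficient of variation <= ``cov_threshold``."""

    lfc_threshold: float = 2.0
    p_threshold: float = 0.05
    cov_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.p_threshold <= 0 or self.cov_threshold <= 0:
            raise ValueError("all thresholds must be > 0")


@dataclass
class FeatureRanking:
    """Ordered feature names with the greedy mRMR score at selection time."""

    feature_names: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.scores):
            raise ValueError("names and scores differ in length")
        if not all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def drop_missing_features(matrix: ModalityMatrix) -> ModalityMatrix:
    """Remove every feature column containing at least one missing value."""
    keep = matrix.values.columns[matrix.values.notna().all(axis=0)]
    if len(keep) == 0:
        raise EmptyMatrixError(f"{matrix.modality}: all features contain missing values")
    dropped = matrix.n_features - len(keep)
    if dropped:
        logger.info(
            "%s: dropped %d/%d features with missing values", matrix.modality, dropped,
            matrix.n_features,
        )
    return matrix.with_features(list(keep))


def _class_groups(matrix: ModalityMatrix, min_per_class: int = 2):
    order = matrix.class_order
    groups = {}
    for cls in order:
        rows = matrix.values.values[np.asarray(matrix.labels == cls)]
        if rows.shape[0] < min_per_class:
            raise DegenerateClassError(
                f"{matrix.modality}: class {cls!r} has {rows.shape[0]} samples "
                f"(needs >= {min_per_class})"
            )
        groups[cls] = rows
    return order, groups


def ttest_screen(matrix: ModalityMatrix, config: TTestSelectionConfig) -> list[str]:
    """Screen features by pairwise Welch t-tests with a mean-difference floor.

    The Bonferroni family is (number of features) x (number of pairwise class
    comparisons), the most conservative reading of a family-wise correction
    over the whole screen.
    """
    order, groups = _class_groups(matrix)
    pairs = list(itertools.combinations(order, 2))
    n_tests = matrix.n_features * len(pairs)

    sig = np.zeros((len(pairs), matrix.n_features), dtype=bool)
    big_diff = np.zeros_like(sig)
    for k, (a, b) in enumerate(pairs):
        res = stats.ttest_ind(groups[a], groups[b], axis=0, equal_var=False)
        p = res.pvalue
        if config.bonferroni:
            p = np.minimum(p * n_tests, 1.0)
        sig[k] = p <= config.alpha
        big_diff[k] = (
            np.abs(groups[a].mean(axis=0) - groups[b].mean(axis=0))
            >= config.mean_diff_threshold
        )

    n_sig = sig.sum(axis=0)
    # the mean-difference floor applies to every comparison that came out
    # significant, not just to the first `required` of them
    diff_ok = np.logical_or(~sig, big_diff).all(axis=0)
    selected_mask = (n_sig >= config.required_comparisons) & diff_ok
    selected = [f for f, s in zip(matrix.feature_names, selected_mask) if s]
    logger.info(
        "%s: t-test screen kept %d/%d features (alpha=%g, bonferroni=%s, "
        "required=%d, mean-diff>=%g)",
        matrix.modality, len(selected), matrix.n_features, config.alpha,
        config.bonferroni, config.required_comparisons, config.mean_diff_threshold,
    )
    return selected


def deg_filter(matrix: ModalityMatrix, config: DEGFilterConfig) -> list[str]:
    """Select differentially expressed features on a positive expression scale.

    A feature passes when its largest pairwise |log2 fold change| between
    class means reaches ``lfc_threshold``, a one-way ANOVA across classes has
    p <= ``p_threshold``, and its coefficient of variation over all samples
    is at most ``cov_threshold``.
    """
    X = matrix.values.values
    if (X <= 0).any():
        raise DomainError(
            "expression values must be strictly positive for the log2 fold change; "
            "add a pseudocount (e.g. +1) before filtering"
        )
    order, groups = _class_groups(matrix)
    means = np.stack([groups[c].mean(axis=0) for c in order])  # (C, F)
    log_means = np.log2(means)
    lfc = np.zeros(matrix.n_features)
    for a, b in itertools.combinations(range(len(order)), 2):
        lfc = np.maximum(lfc, np.abs(log_means[a] - log_means[b]))

    pvals = stats.f_oneway(*[groups[c] for c in order], axis=0).pvalue
    grand_mean = X.mean(axis=0)
    cov = X.std(axis=0, ddof=1) / np.abs(grand_mean)

    mask = (lfc >= config.lfc_threshold) & (pvals <= config.p_threshold) & (
        cov <= config.cov_threshold
    )
    selected = [f for f, s in zip(matrix.feature_names, mask) if s]
    logger.info(
        "%s: DEG filter kept %d/%d features (LFC>=%g, p<=%g, COV<=%g)",
        matrix.modality, len(selected), matrix.n_features,
        config.lfc_threshold, config.p_threshold, config.cov_threshold,
    )
    return selected


def _discretize(column: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning; a constant column collapses to a single bin."""
    lo, hi = column.min(), column.max()
    if hi <= lo:
        return np.zeros(len(column), dtype=np.int64)
    edges = np.linspace(lo, hi, bins + 1)[1:-1]
    return np.searchsorted(edges, column, side="right")


def mrmr_rank(matrix: ModalityMatrix, k: int, bins: int = 3) -> FeatureRanking:
    """Greedy minimum-redundancy maximum-relevance ranking (MID criterion).

    Features are discretized into ``bins`` equal-width bins; relevance is the
    mutual information with the class label and redundancy the mean mutual
    information with already-selected features.  The first-ranked feature is
    the relevance argmax; ties break by input column order.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > matrix.n_features:
        raise ValueError(f"k={k} exceeds {matrix.n_features} features")
    if k == 0:
        return FeatureRanking(feature_names=[], scores=[])

    X = matrix.values.values
    disc = np.column_stack([_discretize(X[:, j], bins) for j in range(X.shape[1])])
    y = pd.Categorical(matrix.labels, categories=matrix.class_order).codes

    relevance = np.array([mutual_info_score(y, disc[:, j]) for j in range(X.shape[1])])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(X.shape[1])
    available = np.ones(X.shape[1], dtype=bool)
    for _ in range(k):
        if selected:
            crit = relevance - redundancy_sum / len(selected)
        else:
            crit = relevance.copy()
        crit[~available] = -np.inf
        j = int(np.argmax(crit))  # first max wins ties (input order)
        selected.append(j)
        scores.append(float(crit[j]))
        available[j] = False
        mi_j = np.array(
            [mutual_info_score(disc[:, j], disc[:, i]) if available[i] else 0.0
             for i in range(X.shape[1])]
        )
        redundancy_sum += mi_j
    return FeatureRanking(
        feature_names=[matrix.feature_names[j] for j in selected], scores=scores
    )
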