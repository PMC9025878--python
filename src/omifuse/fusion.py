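r"""Gradient-optimized late fusion of per-modality class probabilities.

The fused score for class :math:`c_i` of a sample is the weighted sum

.. math:: P_{\mathrm{fusion}}(c_i) = \sum_j w_{i,j}\, P_j(c_i)

where :math:`P_j(c_i)` is modality :math:`j`'s probability for class
:math:`c_i` (exactly zero when the modality is missing for that sample) and
the weight matrix :math:`w` (classes x modalities) is constrained row-wise to
the probability simplex by a softmax.  The raw parameters behind :math:`w`
are trained by minibatch Adam on the cross-entropy of the fused scores
against the training labels, with a stratified validation split monitoring
accuracy across epochs.

Fused scores are a convex combination per class but are *not* renormalized
across classes before the argmax or the loss; the loss takes
``log(max(score, 1e-12))`` of the true-class fused score directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.model_selection import train_test_split

from .exceptions import (
    DegenerateClassError,
    InvalidSpecError,
    NoInformationError,
    OrderMismatchError,
)
from .types import FusionWeights, ProbabilityTable

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FusionTrainConfig:
    """Optimizer settings for the fusion weights.

    ``projection="forward"`` keeps the softmax inside the forward pass (the
    raw parameters are the optimized variables and gradients flow through the
    softmax); ``"post_step"`` reads the projection literally as overwriting
    the raw parameters with their softmax after each Adam step.
    """

    epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 32
    validation_fraction: float = 0.10
    seed: int = 0
    projection: str = "forward"
    select_best_epoch: bool = True
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidSpecError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise InvalidSpecError("validation_fraction must be in (0, 0.5]")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidSpecError("batch_size and learning_rate must be positive")
        if self.projection not in ("forward", "post_step"):
            raise InvalidSpecError("projection must be 'forward' or 'post_step'")


def project_weights(raw: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a raw weight matrix (rows sum to one)."""
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise InvalidSpecError("raw weights must be finite")
    return softmax(raw, axis=-1)


def _check_orders(probs: ProbabilityTable, weights: FusionWeights) -> None:
    if tuple(probs.classes) != tuple(weights.classes):
        raise OrderMismatchError(
            f"class order mismatch: {probs.classes} vs {weights.classes}"
        )
    if tuple(probs.modalities) != tuple(weights.modalities):
        raise OrderMismatchError(
            f"modality order mismatch: {probs.modalities} vs {weights.modalities}"
        )


def fuse_tensor(P: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Weighted-sum fusion on a raw (n, M, C) tensor with projected (C, M) weights."""
    return np.einsum("nmc,cm->nc", P, V)


def fuse(probs: ProbabilityTable, weights: FusionWeights) -> np.ndarray:
    """Fused per-class scores, shape (n_samples, n_classes).

    Missing modalities hold all-zero probability rows, so they contribute
    exactly nothing to the sum — fusing with a zeroed modality is bit-identical
    to dropping its term.
    """
    _check_orders(probs, weights)
    return fuse_tensor(probs.probs, weights.projected)


def loss_and_grad(
    raw: np.ndarray, P: np.ndarray, y_idx: np.ndarray, projection: str = "forward"
) -> tuple[float, np.ndarray]:
    """Cross-entropy of fused scores and its gradient w.r.t. the raw weights.

    With ``projection="forward"`` the forward pass uses ``softmax(raw)`` and
    the gradient includes the softmax Jacobian; with ``"post_step"`` the
    forward pass uses ``raw`` as the (already projected) weights and the
    gradient is taken w.r.t. those directly.
    """
    n = P.shape[0]
    V = project_weights(raw) if projection == "forward" else np.asarray(raw, dtype=float)
    s = fuse_tensor(P, V)
    p_true = s[np.arange(n), y_idx]
    clamped = np.maximum(p_true, _EPS)
    loss = float(-np.mean(np.log(clamped)))
    # dL/ds is nonzero only at the true class entries (clamped entries get 0)
    G = np.zeros_like(s)
    G[np.arange(n), y_idx] = np.where(p_true >= _EPS, -1.0 / (n * clamped), 0.0)
    dV = np.einsum("ni,nji->ij", G, P)  # (C, M)
    if projection == "forward":
        inner = (dV * V).sum(axis=1, keepdims=True)
        d_raw = V * (dV - inner)  # softmax Jacobian, row-wise
    else:
        d_raw = dV
    return loss, d_raw


class _Adam:
    """Minimal Adam optimizer over a single parameter matrix."""

    def __init__(self, shape, lr: float, betas: tuple[float, float], eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        m_hat = self.m / (1 - self.b1**self.t)
        v_hat = self.v / (1 - self.b2**self.t)
        return params - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _labels_to_idx(labels, classes: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lut[l] for l in labels])
    except KeyError as exc:
        raise OrderMismatchError(f"label {exc} not in class order {classes}") from exc


def optimize_weights(
    train_probs: ProbabilityTable, train_labels, config: FusionTrainConfig | None = None
) -> FusionWeights:
    """Learn the fusion weight matrix on training probabilities.

    Raw weights start from a standard-normal draw (their projection already
    satisfies the row-sum-to-one constraint); minibatch Adam minimizes the
    cross-entropy of the fused scores, and a stratified validation split
    (``validation_fraction``) monitors accuracy each epoch.  By default the
    weights from the best-validation epoch are returned.

    A modality with no available training sample leaves its column untouched
    by the data; its raw parameters are reset to the row mean of the observed
    columns (a neutral weight) with a warning.
    """
    config = config or FusionTrainConfig()
    train_probs.validate()
    y = _labels_to_idx(train_labels, train_probs.classes)
    if len(np.unique(y)) < 2:
        raise DegenerateClassError("need at least 2 classes to optimize fusion weights")
    n, M, C = train_probs.probs.shape
    if len(y) != n:
        raise OrderMismatchError("labels length differs from probability table")

    dead_cols = np.flatnonzero(~train_probs.mask.any(axis=0))
    if dead_cols.size:
        logger.warning(
            "modalities %s have no available training samples; their weights are "
            "unconstrained and will fall back to a neutral value",
            [train_probs.modalities[j] for j in dead_cols],
        )

    rng = np.random.default_rng(config.seed)
    raw = rng.standard_normal((C, M))
    if config.projection == "post_step":
        raw = project_weights(raw)

    idx = np.arange(n)
    try:
        tr_idx, val_idx = train_test_split(
            idx,
            test_size=config.validation_fraction,
            stratify=y,
            random_state=config.seed,
        )
    except ValueError:
        logger.warning("too few samples for a stratified validation split; "
                       "monitoring on the full training set")
        tr_idx, val_idx = idx, idx

    P, Pv, yv = train_probs.probs, train_probs.probs[val_idx], y[val_idx]
    adam = _Adam(raw.shape, config.learning_rate, config.adam_betas, config.adam_eps)

    def val_accuracy(raw_now: np.ndarray) -> float:
        V = project_weights(raw_now) if config.projection == "forward" else raw_now
        return float(np.mean(fuse_tensor(Pv, V).argmax(axis=1) == yv))

    best_raw, best_acc, best_epoch = raw.copy(), -np.inf, 0
    for epoch in range(config.epochs):
        order = rng.permutation(tr_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            _, grad = loss_and_grad(raw, P[batch], y[batch], config.projection)
            raw = adam.step(raw, grad)
            if config.projection == "post_step":
                raw = project_weights(raw)
        acc = val_accuracy(raw)
        logger.debug("fusion epoch %d: validation accuracy %.4f", epoch + 1, acc)
        # ties go to the later epoch: the accuracy monitor is coarse (it
        # saturates quickly on easy validation sets) and the better-converged
        # weights are preferable among equally accurate epochs
        if acc >= best_acc:
            best_raw, best_acc, best_epoch = raw.copy(), acc, epoch + 1
    if not config.select_best_epoch:
        best_raw = raw
    else:
        logger.info("fusion: best validation accuracy %.4f at epoch %d", best_acc, best_epoch)

    if dead_cols.size and M > dead_cols.size:
        alive = np.setdiff1d(np.arange(M), dead_cols)
        best_raw = best_raw.copy()
        best_raw[:, dead_cols] = best_raw[:, alive].mean(axis=1, keepdims=True)

    if config.projection == "post_step":
        # best_raw is already row-stochastic; keep it as the projected matrix
        return FusionWeights(
            raw=best_raw,
            projected=best_raw.copy(),
            classes=train_probs.classes,
            modalities=train_probs.modalities,
        )
    return FusionWeights.from_raw(
        best_raw, classes=train_probs.classes, modalities=train_probs.modalities
    )


def predict_fused(probs: ProbabilityTable, weights: FusionWeights) -> np.ndarray:
    """Predicted class per sample: argmax of the fused scores.

    Samples with every modality missing carry no information and raise
    :class:`NoInformationError`.  Ties break toward the earlier class in
    order, with a warning.
    """
    _check_orders(probs, weights)
    no_info = ~probs.mask.any(axis=1)
    if no_info.any():
        bad = [probs.sample_ids[i] for i in np.flatnonzero(no_info)]
        raise NoInformationError(f"all modalities missing for samples: {bad[:5]}")
    s = fuse(probs, weights)
    top = s.argmax(axis=1)
    ties = (s == s[np.arange(len(top)), top][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "%d sample(s) with tied fused scores; keeping first class in order",
            int(ties.sum()),
        )
    return np.asarray([probs.classes[i] for i in top])
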