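"""Per-modality probabilistic classifiers.

The reference model is an RBF-kernel SVM whose ``C`` and ``gamma`` are chosen
by grid search with inner stratified cross-validation on the training split,
after min-max scaling of every feature into [-1, 1] (scaling parameters come
from the training data only; test values outside the training range map
outside [-1, 1] and are deliberately not clipped).  Class probabilities are
the SVM's pairwise-coupling estimates.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .exceptions import DegenerateClassError, DomainError
from .types import ModalityMatrix

logger = logging.getLogger(__name__)

#: Powers-of-two search grid used for both C and gamma.
DEFAULT_GRID: tuple[float, ...] = (2**-7, 2**-5, 2**-2, 2.0, 2**4, 2**7)

_SERIAL_VERSION = 1


@dataclass
class SVMConfig:
    C_grid: tuple[float, ...] = DEFAULT_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GRID
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be nonempty")
        if min(self.C_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("grid values must be positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass
class MinMaxScale:
    """Per-feature affine map of the training range onto [-1, 1].

    Constant features (zero training range) map to 0 with a warning.
    """

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScale":
        lo, hi = X.min(axis=0), X.max(axis=0)
        n_const = int((hi <= lo).sum())
        if n_const:
            warnings.warn(f"{n_const} constant feature(s) scaled to 0", stacklevel=2)
        return cls(lo=lo, hi=hi)

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        out = np.zeros_like(X, dtype=float)
        ok = span > 0
        out[:, ok] = -1.0 + 2.0 * (X[:, ok] - self.lo[ok]) / span[ok]
        return out


@dataclass
class FittedModalityModel:
    modality: str
    scaler: MinMaxScale
    C: float
    gamma: float
    classes: tuple[str, ...]
    svc: SVC = field(repr=False)
    feature_names: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        joblib.dump(
            {
                "format": "omifuse-modality-model",
                "version": _SERIAL_VERSION,
                "modality": self.modality,
                "scaling": {"lo": self.scaler.lo, "hi": self.scaler.hi},
                "C": self.C,
                "gamma": self.gamma,
                "classes": list(self.classes),
                "feature_names": list(self.feature_names),
                "svc": self.svc,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "FittedModalityModel":
        blob = joblib.load(path)
        if blob.get("format") != "omifuse-modality-model":
            raise DomainError(f"{path}: not an omifuse modality model")
        return cls(
            modality=blob["modality"],
            scaler=MinMaxScale(lo=blob["scaling"]["lo"], hi=blob["scaling"]["hi"]),
            C=blob["C"],
            gamma=blob["gamma"],
            classes=tuple(blob["classes"]),
            svc=blob["svc"],
            feature_names=list(blob["feature_names"]),
        )


def fit_svm_modality(matrix: ModalityMatrix, config: SVMConfig | None = None) -> FittedModalityModel:
    """Fit the reference RBF SVM for one modality on a training matrix.

    Grid search scores training-split accuracy with ``inner_cv_folds``
    stratified folds; the winning (C, gamma) pair is refit on the full
    training split with pairwise-coupling probability estimates enabled.
    """
    config = config or SVMConfig()
    y = np.asarray(matrix.labels)
    present, counts = np.unique(y, return_counts=True)
    if len(present) < 2:
        raise DegenerateClassError(f"{matrix.modality}: training labels are all {present[0]!r}")
    if counts.min() < config.inner_cv_folds:
        raise DegenerateClassError(
            f"{matrix.modality}: smallest class has {counts.min()} samples, "
            f"fewer than inner_cv_folds={config.inner_cv_folds}"
        )
    scaler = MinMaxScale.fit(matrix.values.values)
    Xs = scaler.transform(matrix.values.values)

    cv = StratifiedKFold(n_splits=config.inner_cv_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.C_grid), "gamma": list(config.gamma_grid)},
        scoring="accuracy",
        cv=cv,
        refit=False,
    )
    search.fit(Xs, y)
    C, gamma = search.best_params_["C"], search.best_params_["gamma"]
    svc = SVC(kernel="rbf", C=C, gamma=gamma, probability=True, random_state=config.seed)
    with warnings.catch_warnings():
        # pairwise-coupling probability estimates are the point here; sklearn
        # deprecates the flag in favor of a different (Platt-only) calibration
        warnings.filterwarnings("ignore", category=FutureWarning)
        svc.fit(Xs, y)
    logger.info(
        "%s: grid search chose C=%g gamma=%g (inner-CV acc %.3f)",
        matrix.modality, C, gamma, search.best_score_,
    )
    return FittedModalityModel(
        modality=matrix.modality,
        scaler=scaler,
        C=C,
        gamma=gamma,
        classes=matrix.class_order,
        svc=svc,
        feature_names=matrix.feature_names,
    )


def predict_proba(model: FittedModalityModel, samples) -> np.ndarray:
    """Class probabilities in the model's recorded class order.

    ``samples`` may be a ModalityMatrix, a DataFrame or a 2-D array whose
    columns match the training features.  Rows sum to one (pairwise-coupling
    estimates).  Empty input returns an empty (0, n_classes) array.
    """
    if isinstance(samples, ModalityMatrix):
        X = samples.values.loc[:, model.feature_names].values
    elif isinstance(samples, pd.DataFrame):
        X = samples.loc[:, model.feature_names].values
    else:
        X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.scaler.lo):
        raise DomainError(
            f"{model.modality}: expected {len(model.scaler.lo)} features, "
            f"got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return np.empty((0, len(model.classes)))
    raw = model.svc.predict_proba(model.scaler.transform(X))
    # reorder sklearn's sorted class columns into the recorded class order
    col = {c: i for i, c in enumerate(model.svc.classes_)}
    return raw[:, [col[c] for c in model.classes]]
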