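"""Core data containers shared across the pipeline.

The containers mirror the stages of a late-fusion experiment: a cohort of
patients with per-modality feature tables (:class:`LabeledCohort`,
:class:`ModalityMatrix`), per-sample per-modality class probabilities
(:class:`ProbabilityTable`, where an all-zero row encodes a missing
modality), and the class-by-modality fusion weight matrix
(:class:`FusionWeights`, whose rows live on the probability simplex via a
row-wise softmax).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from .exceptions import InvalidSpecError, OrderMismatchError

#: Default class order: the two non-small-cell lung cancer subtypes around
#: the control group.  Row i of the fusion weight matrix corresponds to
#: CLASSES[i].
DEFAULT_CLASSES: tuple[str, ...] = ("LUAD", "control", "LUSC")

#: Default modality (column) order of the fusion weight matrix.
DEFAULT_MODALITIES: tuple[str, ...] = ("WSI", "RNA-Seq", "miRNA-Seq", "CNV", "metDNA")


@dataclass
class ModalityMatrix:
    """One modality's samples-by-features table with labels and patient links.

    Parameters
    ----------
    modality:
        Name of the data modality (e.g. ``"RNA-Seq"``).
    values:
        DataFrame of shape (n_samples, n_features); index holds sample ids,
        columns hold unique feature names.
    labels:
        Class label per sample, indexed like ``values``.
    patient_ids:
        Patient id per sample, indexed like ``values``.  Several samples may
        share a patient (e.g. multiple slides).
    classes:
        Optional explicit class order; defaults to order of first appearance
        in ``labels``.
    """

    modality: str
    values: pd.DataFrame
    labels: pd.Series
    patient_ids: pd.Series
    classes: tuple[str, ...] | None = None
    #: Ground-truth map feature -> shifted class for synthetic cohorts.
    informative_features: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise InvalidSpecError(f"{self.modality}: duplicated feature names")
        if not self.values.index.equals(self.labels.index) or not self.values.index.equals(
            self.patient_ids.index
        ):
            raise InvalidSpecError(f"{self.modality}: labels/patients misaligned with values")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_order(self) -> tuple[str, ...]:
        if self.classes is not None:
            return tuple(self.classes)
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def with_features(self, features: list[str]) -> "ModalityMatrix":
        """Return a copy restricted to ``features`` (order preserved)."""
        return dataclasses.replace(
            self,
            values=self.values.loc[:, list(features)].copy(),
            informative_features={
                k: v for k, v in self.informative_features.items() if k in set(features)
            },
        )

    def with_samples(self, sample_ids) -> "ModalityMatrix":
        """Return a copy restricted to ``sample_ids`` present in the matrix."""
        idx = self.values.index.intersection(pd.Index(sample_ids))
        return dataclasses.replace(
            self,
            values=self.values.loc[idx].copy(),
            labels=self.labels.loc[idx].copy(),
            patient_ids=self.patient_ids.loc[idx].copy(),
        )


@dataclass
class LabeledCohort:
    """Patients with class labels and the per-modality matrices observed for them."""

    classes: tuple[str, ...]
    patients: pd.DataFrame  # index: patient_id; column "label"
    modalities: dict[str, ModalityMatrix]

    @property
    def modality_names(self) -> tuple[str, ...]:
        return tuple(self.modalities)

    @property
    def availability(self) -> pd.DataFrame:
        """Boolean patients x modalities table of which modality each patient has."""
        avail = pd.DataFrame(
            False, index=self.patients.index, columns=list(self.modalities), dtype=bool
        )
        for name, mm in self.modalities.items():
            avail.loc[avail.index.isin(mm.patient_ids.values), name] = True
        return avail


@dataclass
class ProbabilityTable:
    """Per-sample, per-modality class probabilities; all-zero rows mean missing.

    ``probs`` has shape (n_samples, n_modalities, n_classes).  For an
    available (sample, modality) pair the class vector sums to one; a missing
    pair is exactly all-zero so it contributes nothing to the weighted sum.
    """

    sample_ids: list[str]
    classes: tuple[str, ...]
    modalities: tuple[str, ...]
    probs: np.ndarray
    mask: np.ndarray  # (n_samples, n_modalities) bool: True = available

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, m, c = len(self.sample_ids), len(self.modalities), len(self.classes)
        if self.probs.shape != (n, m, c):
            raise InvalidSpecError(
                f"probs shape {self.probs.shape} != ({n}, {m}, {c})"
            )
        if self.mask.shape != (n, m):
            raise InvalidSpecError(f"mask shape {self.mask.shape} != ({n}, {m})")

    def validate(self, atol: float = 1e-6) -> None:
        """Check the simplex/missingness invariants, raising on violation."""
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums[self.mask], 1.0, atol=atol):
            raise InvalidSpecError("available probability rows must sum to 1")
        if self.probs[~self.mask].any():
            raise InvalidSpecError("missing (sample, modality) rows must be all-zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_modalities(self, names) -> "ProbabilityTable":
        names = tuple(names)
        missing = [n for n in names if n not in self.modalities]
        if missing:
            raise OrderMismatchError(f"unknown modalities: {missing}")
        cols = [self.modalities.index(n) for n in names]
        return ProbabilityTable(
            sample_ids=list(self.sample_ids),
            classes=self.classes,
            modalities=names,
            probs=self.probs[:, cols, :].copy(),
            mask=self.mask[:, cols].copy(),
        )

    def select_samples(self, rows) -> "ProbabilityTable":
        rows = np.asarray(rows)
        return ProbabilityTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            classes=self.classes,
            modalities=self.modalities,
            probs=self.probs[rows].copy(),
            mask=self.mask[rows].copy(),
        )


@dataclass
class FusionWeights:
    """Class-by-modality fusion weights: raw parameters and their softmax projection."""

    raw: np.ndarray  # (n_classes, n_modalities)
    projected: np.ndarray  # row-stochastic
    classes: tuple[str, ...] = DEFAULT_CLASSES
    modalities: tuple[str, ...] = DEFAULT_MODALITIES

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        classes: tuple[str, ...] = DEFAULT_CLASSES,
        modalities: tuple[str, ...] = DEFAULT_MODALITIES,
    ) -> "FusionWeights":
        raw = np.asarray(raw, dtype=float)
        if not np.isfinite(raw).all():
            raise InvalidSpecError("raw weights must be finite")
        return cls(raw=raw, projected=softmax(raw, axis=1), classes=classes, modalities=modalities)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.projected = np.asarray(self.projected, dtype=float)
        if self.raw.shape != (len(self.classes), len(self.modalities)):
            raise InvalidSpecError(
                f"weights shape {self.raw.shape} != ({len(self.classes)}, {len(self.modalities)})"
            )
        if self.projected.shape != self.raw.shape:
            raise InvalidSpecError("projected shape differs from raw shape")
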