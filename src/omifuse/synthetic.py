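"""Synthetic multi-modal cohorts and tiled slides.

The generator emulates the statistical structure the late-fusion method
assumes, without pretending to be real data:

* **Molecular modalities** are independent Gaussian features.  A configurable
  fraction of features is *informative*: each informative feature shifts the
  mean of exactly one class by ``effect_size`` within-class standard
  deviations, giving t-test screening, mRMR and the SVMs a planted ground
  truth to recover.  Per-modality missingness is missing-completely-at-random
  over patients, emulating the uneven per-modality sample counts of public
  tumor cohorts.
* **Slides** are square grids of RGB tiles.  A configurable fraction of grid
  cells is near-white background (all channel means above the background
  threshold of 220); the remaining tissue tiles are colored around a
  class-dependent mean with per-tile color jitter (stain/region variability)
  plus per-pixel noise.

Everything is driven by ``numpy.random.default_rng``; identical seeds give
bit-identical cohorts and slides.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError
from .types import DEFAULT_CLASSES, LabeledCohort, ModalityMatrix

#: Tissue color means chosen so the three classes are separated but, with the
#: default tile jitter, not trivially so at the single-tile level.
DEFAULT_CLASS_COLORS: dict[str, tuple[float, float, float]] = {
    "LUAD": (168.0, 118.0, 170.0),
    "control": (160.0, 160.0, 160.0),
    "LUSC": (118.0, 130.0, 178.0),
}

_BACKGROUND_THRESHOLD = 220.0


def _per_modality(value, modalities, name: str) -> dict[str, float]:
    """Broadcast a scalar or validate a mapping over modality names."""
    if isinstance(value, Mapping):
        missing = set(modalities) - set(value)
        if missing:
            raise InvalidSpecError(f"{name} missing entries for {sorted(missing)}")
        return {m: value[m] for m in modalities}
    return {m: value for m in modalities}


@dataclass
class CohortSpec:
    """Configuration of a synthetic patient cohort.

    ``n_features``, ``effect_size`` and ``missing_rate`` may be scalars
    (shared by all modalities) or per-modality mappings.  ``effect_size`` is
    the between-class mean shift in units of the within-class standard
    deviation; ``informative_fraction`` of the features carry it, the rest
    are pure noise.
    """

    n_patients_per_class: int = 100
    classes: tuple[str, ...] = DEFAULT_CLASSES
    modalities: tuple[str, ...] = ("RNA-Seq", "miRNA-Seq", "CNV", "metDNA")
    n_features: int | Mapping[str, int] = 100
    effect_size: float | Mapping[str, float] = 1.0
    missing_rate: float | Mapping[str, float] = 0.0
    informative_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise InvalidSpecError("need at least 2 classes")
        if len(self.modalities) < 1:
            raise InvalidSpecError("need at least 1 modality")
        if self.n_patients_per_class < 1:
            raise InvalidSpecError("n_patients_per_class must be >= 1")
        for m, f in _per_modality(self.n_features, self.modalities, "n_features").items():
            if f < 1:
                raise InvalidSpecError(f"{m}: n_features must be >= 1")
        for m, e in _per_modality(self.effect_size, self.modalities, "effect_size").items():
            if e < 0:
                raise InvalidSpecError(f"{m}: effect_size must be >= 0")
        for m, r in _per_modality(self.missing_rate, self.modalities, "missing_rate").items():
            if not 0.0 <= r <= 1.0:
                raise InvalidSpecError(f"{m}: missing_rate must be in [0, 1]")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise InvalidSpecError("informative_fraction must be in [0, 1]")


def generate_cohort(spec: CohortSpec) -> LabeledCohort:
    """Generate a patient-linked multi-modal cohort per ``spec``.

    Each patient contributes at most one sample per modality; a patient is
    dropped from a modality's matrix with probability ``missing_rate`` for
    that modality, independently across (patient, modality) pairs.
    """
    rng = np.random.default_rng(spec.seed)
    n_feat = _per_modality(spec.n_features, spec.modalities, "n_features")
    effect = _per_modality(spec.effect_size, spec.modalities, "effect_size")
    miss = _per_modality(spec.missing_rate, spec.modalities, "missing_rate")

    patient_ids = [
        f"P{ci}_{j:04d}"
        for ci, _ in enumerate(spec.classes)
        for j in range(spec.n_patients_per_class)
    ]
    labels = np.repeat(list(spec.classes), spec.n_patients_per_class)
    patients = pd.DataFrame({"label": labels}, index=pd.Index(patient_ids, name="patient_id"))

    modalities: dict[str, ModalityMatrix] = {}
    for mod in spec.modalities:
        f = int(n_feat[mod])
        n_info = int(round(spec.informative_fraction * f))
        values = rng.standard_normal((len(patient_ids), f))
        feature_names = [f"{mod}_f{j:04d}" for j in range(f)]
        informative: dict[str, str] = {}
        for j in range(n_info):
            target = spec.classes[j % len(spec.classes)]
            values[labels == target, j] += effect[mod]
            informative[feature_names[j]] = target
        keep = rng.random(len(patient_ids)) >= miss[mod]
        idx = pd.Index(np.asarray(patient_ids)[keep], name="sample_id")
        modalities[mod] = ModalityMatrix(
            modality=mod,
            values=pd.DataFrame(values[keep], index=idx, columns=feature_names),
            labels=pd.Series(labels[keep], index=idx, name="label"),
            patient_ids=pd.Series(np.asarray(patient_ids)[keep], index=idx, name="patient_id"),
            classes=spec.classes,
            informative_features=informative,
        )
    return LabeledCohort(classes=spec.classes, patients=patients, modalities=modalities)


@dataclass
class SlideSpec:
    """Configuration of a synthetic tiled slide.

    ``background_fraction`` of the ``grid x grid`` cells are near-white
    (every channel mean > 220, so the tile filter discards them); the rest
    are tissue colored around ``class_color_means[label]`` with per-tile
    color jitter ``tile_color_sd`` and per-pixel noise ``noise_sd``.
    """

    grid: int = 8
    tile_px: int = 512
    background_fraction: float = 0.3
    class_color_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COLORS)
    )
    tile_color_sd: float = 25.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid < 1:
            raise InvalidSpecError("grid must be >= 1")
        if self.tile_px < 1:
            raise InvalidSpecError("tile_px must be >= 1")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise InvalidSpecError("background_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.tile_color_sd < 0:
            raise InvalidSpecError("noise sds must be >= 0")
        for cls, rgb in self.class_color_means.items():
            if len(rgb) != 3:
                raise InvalidSpecError(f"{cls}: color mean must have 3 channels")


def generate_slide(
    spec: SlideSpec, class_label: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one synthetic slide for ``class_label`` as a uint8 RGB array.

    The output is a ``(grid*tile_px, grid*tile_px, 3)`` image.  Exactly
    ``round(background_fraction * grid**2)`` grid cells are background; their
    pixels are clipped to [235, 255] so every channel mean exceeds the 220
    filter threshold.  Tissue tiles clamp their darkest channel to at most
    210 so at least one channel mean stays at or below 220.
    """
    if class_label not in spec.class_color_means:
        raise InvalidSpecError(f"no color mean configured for class {class_label!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g, t = spec.grid, spec.tile_px
    n_cells = g * g
    n_bg = int(round(spec.background_fraction * n_cells))
    bg_cells = set(rng.choice(n_cells, size=n_bg, replace=False).tolist())

    base = np.asarray(spec.class_color_means[class_label], dtype=float)
    dark = int(np.argmin(base))
    img = np.empty((g * t, g * t, 3), dtype=np.uint8)
    for cell in range(n_cells):
        r, c = divmod(cell, g)
        if cell in bg_cells:
            tile = 245.0 + rng.normal(0.0, spec.noise_sd, size=(t, t, 3))
            tile = np.clip(tile, 235.0, 255.0)
        else:
            color = base + rng.normal(0.0, spec.tile_color_sd, size=3)
            tile = color + rng.normal(0.0, spec.noise_sd, size=(t, t, 3))
            tile = np.clip(tile, 0.0, 255.0)
            # keep the darkest channel's mean safely below the 220 filter cut
            tile[:, :, dark] = np.minimum(tile[:, :, dark], 210.0)
        img[r * t : (r + 1) * t, c * t : (c + 1) * t, :] = np.round(tile).astype(np.uint8)
    return img


def generate_slides(
    spec: SlideSpec, labels: Mapping[str, str], seed: int | None = None
):
    """Yield ``(slide_id, label, image)`` for each ``slide_id -> label`` entry.

    A single generator seeded once drives all slides, so the whole collection
    is reproducible from ``seed`` (default: ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    for slide_id, label in labels.items():
        yield slide_id, label, generate_slide(spec, label, rng=rng)


def write_cohort_tsv(cohort: LabeledCohort, outdir) -> list[str]:
    """Write one TSV per modality (sample_id, patient_id, label, features)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mm in cohort.modalities.items():
        df = pd.concat([mm.patient_ids, mm.labels, mm.values], axis=1)
        path = outdir / f"{name.replace('/', '_')}.tsv"
        df.to_csv(path, sep="\t", index_label="sample_id")
        written.append(str(path))
    return written


def spec_to_dict(spec) -> dict:
    """Serialize a CohortSpec/SlideSpec to a plain dict (YAML/JSON-ready)."""
    return dataclasses.asdict(spec)
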