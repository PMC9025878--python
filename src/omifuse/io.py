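"""Plain-text I/O: TSV matrices and probability tables, weight exports, PNG tiles."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .exceptions import InvalidSpecError
from .types import FusionWeights, ModalityMatrix, ProbabilityTable


def write_modality_matrix(matrix: ModalityMatrix, path) -> None:
    """TSV with columns sample_id, patient_id, label, then one per feature."""
    df = pd.concat([matrix.patient_ids, matrix.labels, matrix.values], axis=1)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_modality_matrix(path, modality: str | None = None,
                         classes: tuple[str, ...] | None = None) -> ModalityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("patient_id", "label"):
        if col not in df.columns:
            raise InvalidSpecError(f"{path}: missing required column {col!r}")
    return ModalityMatrix(
        modality=modality or Path(path).stem,
        values=df.drop(columns=["patient_id", "label"]),
        labels=df["label"],
        patient_ids=df["patient_id"],
        classes=classes,
    )


def write_probability_table(table: ProbabilityTable, path) -> None:
    """Long TSV: sample_id, modality, one column per class; missing pairs omitted."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        for j, mod in enumerate(table.modalities):
            if table.mask[i, j]:
                rows.append([sid, mod, *table.probs[i, j, :]])
    pd.DataFrame(rows, columns=["sample_id", "modality", *table.classes]).to_csv(
        path, sep="\t", index=False
    )


def read_probability_table(
    path,
    classes: tuple[str, ...],
    modalities: tuple[str, ...],
    sample_ids: list[str] | None = None,
) -> ProbabilityTable:
    df = pd.read_csv(path, sep="\t")
    if sample_ids is None:
        sample_ids = list(dict.fromkeys(df["sample_id"]))
    probs = np.zeros((len(sample_ids), len(modalities), len(classes)))
    mask = np.zeros((len(sample_ids), len(modalities)), dtype=bool)
    pos = {s: i for i, s in enumerate(sample_ids)}
    mpos = {m: j for j, m in enumerate(modalities)}
    for _, row in df.iterrows():
        i, j = pos.get(row["sample_id"]), mpos.get(row["modality"])
        if i is None or j is None:
            raise InvalidSpecError(
                f"{path}: unexpected sample/modality {row['sample_id']}/{row['modality']}"
            )
        probs[i, j, :] = [row[c] for c in classes]
        mask[i, j] = True
    return ProbabilityTable(
        sample_ids=sample_ids, classes=tuple(classes), modalities=tuple(modalities),
        probs=probs, mask=mask,
    )


def write_weights(weights: FusionWeights, path) -> None:
    """Projected weight matrix as TSV with class rows and modality columns."""
    pd.DataFrame(
        weights.projected, index=list(weights.classes), columns=list(weights.modalities)
    ).to_csv(path, sep="\t", index_label="class")


def read_weights(path) -> FusionWeights:
    df = pd.read_csv(path, sep="\t", index_col="class")
    projected = df.to_numpy(dtype=float)
    return FusionWeights(
        raw=np.log(np.clip(projected, 1e-300, None)),
        projected=projected,
        classes=tuple(df.index),
        modalities=tuple(df.columns),
    )


def write_feature_list(features: list[str], path) -> None:
    Path(path).write_text("\n".join(features) + ("\n" if features else ""))


def read_feature_list(path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line.strip()]


def write_slide_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_slide_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise InvalidSpecError(f"{path}: config must be a mapping")
    return out
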