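"""Whole-slide image pipeline: tiling with a background filter, a pluggable
tile-classifier contract, and tile-to-slide aggregation.

A slide is cut into non-overlapping ``tile_px`` x ``tile_px`` tiles in
row-major grid order; a tile is discarded iff the mean of *all three* color
channels exceeds the background threshold (default 220), the standard
near-white test for H&E slides.  Slide-level class probabilities are tile
fractions: P(class c) = (#tiles predicted c) / (#tiles), and the slide label
is the majority vote over tiles (equivalently the argmax of those fractions).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .exceptions import DomainError, InvalidSpecError

logger = logging.getLogger(__name__)

BACKGROUND_THRESHOLD = 220.0
DEFAULT_TILE_PX = 512


@dataclass
class SlideTileSet:
    """Tissue tiles retained from one slide, in row-major grid order."""

    slide_id: str
    patient_id: str
    tiles: list[np.ndarray]
    label: str | None = None

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise InvalidSpecError(f"{self.slide_id}: tiles have mixed shapes {shapes}")

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


@dataclass
class TilePredictionSet:
    """Per-tile predicted classes for one slide."""

    slide_id: str
    predictions: list[str]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.predictions) - set(self.classes)
        if bad:
            raise InvalidSpecError(f"{self.slide_id}: predictions outside class set: {bad}")


class TileClassifier(Protocol):
    """Behavioral contract for tile-level classifiers.

    Any model that can fit on a list of RGB tile arrays with class labels and
    predict a class per tile satisfies the contract; the reference default is
    a multinomial logistic regression on per-tile channel means, which keeps
    the tile-to-slide aggregation fully testable without a GPU stage.  A
    convolutional backend can be plugged in behind the same two methods.
    """

    def fit(self, tiles: Sequence[np.ndarray], labels: Sequence[str]) -> "TileClassifier": ...

    def predict(self, tiles: Sequence[np.ndarray]) -> list[str]: ...


def _channel_means(tiles: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(t, dtype=float).mean(axis=(0, 1)) for t in tiles])


@dataclass
class MeanColorTileClassifier:
    """Multinomial logistic regression on per-tile RGB channel means."""

    C: float = 1.0
    max_iter: int = 1000
    _model: LogisticRegression = field(init=False, repr=False, default=None)

    def fit(self, tiles: Sequence[np.ndarray], labels: Sequence[str]) -> "MeanColorTileClassifier":
        self._model = LogisticRegression(C=self.C, max_iter=self.max_iter)
        self._model.fit(_channel_means(tiles), np.asarray(labels))
        return self

    def predict(self, tiles: Sequence[np.ndarray]) -> list[str]:
        if self._model is None:
            raise DomainError("classifier must be fit before predict")
        return list(self._model.predict(_channel_means(tiles)))


def is_background(tile: np.ndarray, threshold: float = BACKGROUND_THRESHOLD) -> bool:
    """True iff the mean of every color channel exceeds ``threshold``."""
    means = np.asarray(tile, dtype=float).mean(axis=(0, 1))
    return bool((means > threshold).all())


def extract_tiles(
    slide_image: np.ndarray,
    tile_px: int = DEFAULT_TILE_PX,
    background_threshold: float = BACKGROUND_THRESHOLD,
    slide_id: str = "slide",
    patient_id: str | None = None,
    label: str | None = None,
) -> SlideTileSet:
    """Cut a slide into non-overlapping grid tiles, discarding background.

    Partial tiles at the right/bottom edge are dropped.  The returned tile
    set may be empty (an all-background slide); callers decide how to treat
    that.
    """
    img = np.asarray(slide_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidSpecError("slide image must be HxWx3 RGB")
    h, w = img.shape[:2]
    if h < tile_px or w < tile_px:
        raise InvalidSpecError(
            f"slide {h}x{w} smaller than one {tile_px}px tile"
        )
    tiles = []
    for r in range(h // tile_px):
        for c in range(w // tile_px):
            tile = img[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px]
            if not is_background(tile, background_threshold):
                tiles.append(tile)
    if not tiles:
        logger.warning("%s: no tissue tiles retained (all background)", slide_id)
    return SlideTileSet(
        slide_id=slide_id,
        patient_id=patient_id if patient_id is not None else slide_id,
        tiles=tiles,
        label=label,
    )


def slide_probabilities(preds: TilePredictionSet) -> np.ndarray:
    """Tile-fraction class probabilities for a slide.

    P(c_i) = #tiles predicted c_i / #tiles; the vector sums to one.
    """
    if not preds.predictions:
        raise DomainError(f"{preds.slide_id}: empty prediction set")
    arr = np.asarray(preds.predictions)
    counts = np.array([(arr == c).sum() for c in preds.classes], dtype=float)
    return counts / counts.sum()


def slide_predict_majority(preds: TilePredictionSet) -> str:
    """Majority-vote slide label; ties break toward the earlier class in order."""
    probs = slide_probabilities(preds)
    top = int(np.argmax(probs))
    if (probs == probs[top]).sum() > 1:
        logger.warning(
            "%s: majority-vote tie, keeping first class in order (%s)",
            preds.slide_id, preds.classes[top],
        )
    return preds.classes[top]
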