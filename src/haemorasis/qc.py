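"""Tile quality control: keep only informative, monolayer-like tile regions.

Tiles with too few cells, too many overlapping cells, or out-of-focus blur
are rejected before any detection runs. The default backend scores each
tile with three engineered statistics — cell-scale blob count from a
Laplacian-of-Gaussian response, foreground fraction from Otsu thresholding,
and variance-of-Laplacian sharpness — fed to a logistic classifier. The
backend is pluggable so a convolutional classifier can substitute under
the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .io_core import Tile
from .morphometry import _gray

GOOD, POOR = "good", "poor"

#: Cell-scale sigma (px at 40x) for blob detection.
BLOB_SIGMA = 8.0

FEATURE_NAMES = ("blob_count", "foreground_fraction", "laplacian_variance",
                 "gray_std", "gray_mean")


class TrainingError(ValueError):
    pass


class ShapeError(ValueError):
    pass


def qc_features(tile: Tile) -> np.ndarray:
    """Engineered quality statistics for one tile."""
    gray = _gray(tile.pixels)
    # blob count: maxima of the inverted LoG response at cell scale
    log = -ndi.gaussian_laplace(gray, BLOB_SIGMA) * BLOB_SIGMA**2
    peaks = peak_local_max(log, min_distance=int(BLOB_SIGMA),
                           threshold_abs=10.0, exclude_border=False)
    blob_count = float(len(peaks))
    # foreground fraction: pixels darker than Otsu (cells are darker than
    # the smear background); degenerate on constant tiles
    if gray.std() < 1.0:
        fg_fraction = 0.0
    else:
        fg_fraction = float((gray < threshold_otsu(gray)).mean())
    lap_var = float(ndi.laplace(gray).var())
    return np.array([blob_count, fg_fraction, lap_var,
                     float(gray.std()), float(gray.mean())])


@dataclass
class QCModel:
    """Trained tile-quality classifier with a probability threshold."""

    scaler: StandardScaler
    classifier: LogisticRegression
    threshold: float = 0.5
    backend: str = "engineered"
    tile_size: int = 512
    heldout_accuracy_: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


def train_qc(
    tiles: Sequence[Tile],
    labels: Sequence[str],
    backend: str = "engineered",
    seed: int = 0,
    threshold: float = 0.5,
    holdout: float = 0.25,
) -> QCModel:
    """Fit the tile-quality classifier on labeled tiles.

    ``labels`` are "good" / "poor". A stratified holdout split reports
    accuracy on unseen tiles (``heldout_accuracy_``). Deterministic given
    ``seed``.
    """
    if backend != "engineered":
        raise ValueError(f"unknown QC backend {backend!r}")
    labels = list(labels)
    if len(set(labels)) < 2:
        raise TrainingError("QC training needs both good and poor tiles")
    X = np.stack([qc_features(t) for t in tiles])
    y = np.array([1 if lab == GOOD else 0 for lab in labels])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=seed
    )
    scaler = StandardScaler().fit(X_tr)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(scaler.transform(X_tr), y_tr)
    acc = float((clf.predict(scaler.transform(X_te)) == y_te).mean())
    return QCModel(scaler=scaler, classifier=clf, threshold=threshold,
                   backend=backend, tile_size=tiles[0].pixels.shape[0],
                   heldout_accuracy_=acc)


def classify_tile(model: QCModel, tile: Tile) -> tuple[str, float]:
    """Score one tile; verdict is "good" iff score >= model.threshold."""
    if tile.pixels.shape[0] != model.tile_size or tile.pixels.shape[1] != model.tile_size:
        raise ShapeError(
            f"tile shape {tile.pixels.shape[:2]} does not match model input "
            f"size {model.tile_size}"
        )
    x = model.scaler.transform(qc_features(tile)[None, :])
    score = float(model.classifier.predict_proba(x)[0, 1])
    return (GOOD if score >= model.threshold else POOR), score


def qc_fraction(verdicts: Sequence[str]) -> float:
    """Fraction of good tiles on a slide."""
    verdicts = list(verdicts)
    if not verdicts:
        raise ValueError("qc_fraction needs at least one verdict")
    return sum(v == GOOD for v in verdicts) / len(verdicts)
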