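"""White-cell segmentation: pixel-probability model, test-time augmentation,
rule-based post-processing, and nuclear segmentation by intensity clustering.

The segmenter contract is a model that maps an RGB tile to a per-pixel
white-cell probability map of the same height and width. The default
backend is a logistic pixel classifier over multi-scale color/intensity
features trained by full-batch gradient descent; any encoder–decoder
network satisfying the same contract can be plugged in.

Nuclei are segmented inside each cell mask by 2-cluster k-means on
grayscale intensity: the darker cluster is taken as the nucleus. This
deliberately fails (returns the darker cytoplasm) on inverted-contrast
cells — the documented low-contrast failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.cluster import KMeans

from .io_core import Tile
from .morphometry import _gray


class ShapeError(ValueError):
    pass


class DegenerateCellError(ValueError):
    """Cell has (nearly) constant intensity; nucleus cannot be resolved."""


# ---------------------------------------------------------------------------
# Pixel features
# ---------------------------------------------------------------------------

_FEATURE_SIGMAS = (2.0, 4.0)


def pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (H, W, F): RGB, luma, smoothed luma, local contrast."""
    p = pixels.astype(float)
    gray = _gray(pixels)
    feats = [p[..., 0], p[..., 1], p[..., 2], gray]
    for sigma in _FEATURE_SIGMAS:
        sm = ndi.gaussian_filter(gray, sigma)
        feats.append(sm)
        # local standard deviation: sqrt(E[g^2] - E[g]^2)
        sq = ndi.gaussian_filter(gray**2, sigma)
        feats.append(np.sqrt(np.clip(sq - sm**2, 0.0, None)))
    return np.stack(feats, axis=-1)


N_PIXEL_FEATURES = 4 + 2 * len(_FEATURE_SIGMAS)


@dataclass
class SegmenterModel:
    """Logistic pixel classifier: p(WBC) = sigmoid(features . w + b)."""

    weights: np.ndarray = field(default_factory=lambda: np.zeros(N_PIXEL_FEATURES))
    bias: float = 0.0
    feat_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_PIXEL_FEATURES))
    feat_scale: np.ndarray = field(default_factory=lambda: np.ones(N_PIXEL_FEATURES))
    input_size: int | None = None
    backend: str = "pixel-logistic"
    loss_history_: list[float] = field(default_factory=list)

    def predict_proba_map(self, pixels: np.ndarray) -> np.ndarray:
        f = (pixel_features(pixels) - self.feat_mean) / self.feat_scale
        z = f @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Random image alterations applied to each training tile per epoch."""

    flips: bool = True
    rotations: bool = True
    intensity_jitter: float = 10.0  # additive, gray levels
    blur_sigma_max: float = 1.0


def _augment(pixels, mask, rng, cfg: AugmentConfig):
    img = pixels.astype(float)
    if cfg.rotations:
        k = int(rng.integers(4))
        img = np.rot90(img, k)
        mask = np.rot90(mask, k)
    if cfg.flips and rng.random() < 0.5:
        img = img[:, ::-1]
        mask = mask[:, ::-1]
    if cfg.intensity_jitter > 0:
        img = img + rng.uniform(-cfg.intensity_jitter, cfg.intensity_jitter)
    if cfg.blur_sigma_max > 0:
        sigma = rng.uniform(0, cfg.blur_sigma_max)
        if sigma > 0.1:
            for c in range(3):
                img[:, :, c] = ndi.gaussian_filter(img[:, :, c], sigma)
    return np.clip(img, 0, 255).astype(np.uint8), np.ascontiguousarray(mask)


def train_segmenter(
    tiles: Sequence[Tile],
    masks: Sequence[np.ndarray],
    epochs: int = 20,
    seed: int = 0,
    augment: AugmentConfig | None = None,
    pixels_per_tile: int = 2000,
    learning_rate: float = 0.5,
) -> SegmenterModel:
    """Train the pixel classifier on annotated tiles.

    Each epoch re-applies random augmentations, subsamples pixels
    (balanced between classes where possible) and takes one full-batch
    logistic-regression gradient step. The per-epoch cross-entropy on a
    fixed unaugmented reference sample is recorded in ``loss_history_``.
    With ``epochs=0`` the returned model equals the zero initialization.
    """
    if not tiles:
        raise ValueError("train_segmenter needs at least one annotated tile")
    if augment is None:
        augment = AugmentConfig()
    rng = np.random.default_rng(seed)

    # standardization statistics from the raw tiles
    ref_X, ref_y = [], []
    for tile, mask in zip(tiles, masks):
        f = pixel_features(tile.pixels).reshape(-1, N_PIXEL_FEATURES)
        m = np.asarray(mask, dtype=bool).reshape(-1)
        idx = rng.choice(len(m), size=min(pixels_per_tile, len(m)), replace=False)
        ref_X.append(f[idx])
        ref_y.append(m[idx])
    ref_X = np.concatenate(ref_X)
    ref_y = np.concatenate(ref_y).astype(float)
    mean = ref_X.mean(axis=0)
    scale = ref_X.std(axis=0)
    scale[scale < 1e-9] = 1.0

    model = SegmenterModel(feat_mean=mean, feat_scale=scale,
                           input_size=tiles[0].pixels.shape[0])
    w = model.weights.copy()
    b = model.bias
    ref_Xs = (ref_X - mean) / scale

    order = np.arange(len(tiles))
    for _ in range(epochs):
        rng.shuffle(order)
        for ti in order:
            tile, mask = tiles[ti], masks[ti]
            img, m = _augment(tile.pixels, np.asarray(mask, dtype=bool), rng, augment)
            f = pixel_features(img).reshape(-1, N_PIXEL_FEATURES)
            mflat = m.reshape(-1)
            pos = np.flatnonzero(mflat)
            neg = np.flatnonzero(~mflat)
            n_half = pixels_per_tile // 2
            take_pos = rng.choice(pos, size=min(n_half, len(pos)), replace=False) \
                if len(pos) else np.empty(0, dtype=int)
            take_neg = rng.choice(neg, size=min(n_half, len(neg)), replace=False) \
                if len(neg) else np.empty(0, dtype=int)
            idx = np.concatenate([take_pos, take_neg])
            if len(idx) == 0:
                continue
            X = (f[idx] - mean) / scale
            y = mflat[idx].astype(float)
            p = 1.0 / (1.0 + np.exp(-(X @ w + b)))
            w -= learning_rate * (X.T @ (p - y) / len(y))
            b -= learning_rate * float((p - y).mean())
        p_ref = 1.0 / (1.0 + np.exp(-(ref_Xs @ w + b)))
        eps = 1e-12
        loss = float(-np.mean(ref_y * np.log(p_ref + eps)
                              + (1 - ref_y) * np.log(1 - p_ref + eps)))
        model.loss_history_.append(loss)

    model.weights = w
    model.bias = b
    return model


# ---------------------------------------------------------------------------
# Inference with test-time augmentation
# ---------------------------------------------------------------------------

def _dihedral_transforms():
    """The 8 symmetries of the square as (forward, inverse) array maps."""
    out = []
    for k in range(4):
        out.append((lambda a, k=k: np.rot90(a, k),
                    lambda a, k=k: np.rot90(a, -k)))
        out.append((lambda a, k=k: np.rot90(a[:, ::-1], k),
                    lambda a, k=k: np.rot90(a, -k)[:, ::-1]))
    return out


DIHEDRAL = _dihedral_transforms()
IDENTITY_ONLY = [(lambda a: a, lambda a: a)]


def segment_probabilities(
    model, tile: Tile, tta: bool = False, transforms=None
) -> np.ndarray:
    """Per-pixel white-cell probability map, optionally averaged over the
    8-element dihedral group of rotations and flips (TTA)."""
    size = getattr(model, "input_size", None)
    if size is not None and (tile.pixels.shape[0] != size or tile.pixels.shape[1] != size):
        raise ShapeError(f"tile shape {tile.pixels.shape[:2]} != model input {size}")
    if not tta:
        return model.predict_proba_map(tile.pixels)
    if transforms is None:
        transforms = DIHEDRAL
    acc = None
    for fwd, inv in transforms:
        pred = model.predict_proba_map(np.ascontiguousarray(fwd(tile.pixels)))
        pred = inv(pred)
        acc = pred if acc is None else acc + pred
    return acc / len(transforms)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

@dataclass
class PostprocessParams:
    """Rules turning a probability map into instance masks.

    Area gates default to [300, 15000] px^2 at 40x (0.25 um/px), bracketing
    leukocyte diameters of roughly 10–70 um.
    """

    prob_threshold: float = 0.5
    min_area: int = 300
    max_area: int = 15000
    hole_fill: bool = True
    split_touching: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")


def postprocess(prob_map: np.ndarray, params: PostprocessParams | None = None
                ) -> list[np.ndarray]:
    """Threshold, clean and split a probability map into disjoint instances."""
    if params is None:
        params = PostprocessParams()
    binary = np.asarray(prob_map) >= params.prob_threshold
    if params.hole_fill:
        binary = ndi.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    if params.split_touching and labels.max() > 0:
        dist = ndi.distance_transform_edt(binary)
        min_dist = max(3, int(np.sqrt(params.min_area / np.pi)))
        peaks = peak_local_max(dist, min_distance=min_dist, labels=labels,
                               exclude_border=False)
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() > 0:
            labels = watershed(-dist, markers, mask=binary)
    instances = []
    for region in measure.regionprops(labels):
        if params.min_area <= region.area <= params.max_area:
            instances.append(labels == region.label)
    return instances


# ---------------------------------------------------------------------------
# Nucleus segmentation
# ---------------------------------------------------------------------------

def segment_nucleus(pixels: np.ndarray, cell_mask: np.ndarray, seed: int = 0,
                    min_component_fraction: float = 0.15) -> np.ndarray:
    """Segment the nucleus within a cell mask by 2-cluster intensity k-means.

    The lower-mean-intensity cluster is taken as the nucleus (nuclei stain
    darker than cytoplasm); connected components smaller than
    ``min_component_fraction`` of the largest are dropped, keeping
    multi-lobed nuclei intact. The result is always a subset of the cell
    mask. Raises :class:`DegenerateCellError` on constant-intensity cells.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    gray = _gray(pixels)
    vals = gray[cell_mask]
    if vals.size < 2 or float(vals.max() - vals.min()) < 1e-9:
        raise DegenerateCellError("cell has constant intensity; cannot split nucleus")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(vals.reshape(-1, 1))
    dark_cluster = int(np.argmin(km.cluster_centers_.ravel()))
    nucleus = np.zeros_like(cell_mask)
    nucleus[cell_mask] = assign == dark_cluster
    # keep the dominant connected component(s): lobes are comparable in size
    lab = measure.label(nucleus, connectivity=2)
    if lab.max() > 1:
        areas = np.bincount(lab.ravel())[1:]
        keep = np.flatnonzero(areas >= min_component_fraction * areas.max()) + 1
        nucleus = np.isin(lab, keep)
    return nucleus
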