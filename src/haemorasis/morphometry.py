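"""Fixed morphometric feature vectors: 42 cellular features per cell and 11
additional nuclear features per white cell (53 total).

The cellular block is 12 shape + 18 color + 12 texture features:

* shape — area (px^2), perimeter (px, Crofton), circularity 4*pi*A/P^2,
  eccentricity, solidity, convexity (convex-hull perimeter / perimeter),
  major/minor axis lengths, aspect ratio, and mean / standard deviation /
  max-min ratio of the centroid distance function (CDF);
* color — mean, standard deviation, skewness and the 0.05/0.5/0.95
  quantiles of each of R, G, B over in-mask pixels only;
* texture — gray-level co-occurrence contrast, dissimilarity, homogeneity,
  energy, correlation and ASM at pixel distances 1 and 3, angle-averaged,
  on 32 gray levels.

The nuclear block repeats the core shape statistics for the nucleus and
adds the nucleus:cell area ratio and nucleus/cytoplasm intensity contrast.
The schema is versioned so alternative feature lists can be plugged in.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sstats
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure
from skimage.feature import graycomatrix, graycoprops

from .io_core import GeometryError

SCHEMA_VERSION = "1.0"

_SHAPE_NAMES = (
    "area", "perimeter", "circularity", "eccentricity", "solidity",
    "convexity", "major_axis", "minor_axis", "aspect_ratio",
    "cdf_mean", "cdf_std", "cdf_maxmin_ratio",
)
_COLOR_STATS = ("mean", "std", "skew", "q05", "q50", "q95")
_COLOR_NAMES = tuple(f"{c}_{s}" for c in ("r", "g", "b") for s in _COLOR_STATS)
_TEXTURE_PROPS = ("contrast", "dissimilarity", "homogeneity", "energy",
                  "correlation", "ASM")
_TEXTURE_NAMES = tuple(f"glcm_{p.lower()}_d{d}" for d in (1, 3) for p in _TEXTURE_PROPS)
_NUCLEAR_NAMES = (
    "nuc_area", "nuc_perimeter", "nuc_circularity", "nuc_eccentricity",
    "nuc_solidity", "nuc_convexity", "nuc_cell_area_ratio", "nuc_cdf_std",
    "nuc_mean_intensity", "nuc_intensity_std", "nuc_cyto_intensity_ratio",
)

GLCM_LEVELS = 32
CDF_SAMPLES = 128


class FeatureSchema(NamedTuple):
    """Ordered, versioned feature name lists."""

    shape: tuple[str, ...]
    color: tuple[str, ...]
    texture: tuple[str, ...]
    nuclear: tuple[str, ...]
    version: str

    @property
    def cellular(self) -> tuple[str, ...]:
        return self.shape + self.color + self.texture

    @property
    def wbc(self) -> tuple[str, ...]:
        return self.cellular + self.nuclear


SCHEMA = FeatureSchema(_SHAPE_NAMES, _COLOR_NAMES, _TEXTURE_NAMES,
                       _NUCLEAR_NAMES, SCHEMA_VERSION)

assert len(SCHEMA.cellular) == 42
assert len(SCHEMA.wbc) == 53


def cell_feature_names() -> list[str]:
    """The 42 cellular feature names (shape, color, texture), in order."""
    return list(SCHEMA.cellular)


def wbc_feature_names() -> list[str]:
    """The 53 white-cell feature names (42 cellular + 11 nuclear), in order."""
    return list(SCHEMA.wbc)


# ---------------------------------------------------------------------------
# Centroid distance function
# ---------------------------------------------------------------------------

def centroid_distance_function(boundary: np.ndarray, n_samples: int = CDF_SAMPLES
                               ) -> np.ndarray:
    """Distances from ``n_samples`` equal-arc-length boundary points to the centroid.

    The standard deviation of this vector is the shape-irregularity
    statistic used for red cells; its max/min ratio captures elongation.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    boundary = np.asarray(boundary, dtype=float)
    poly = ShapelyPolygon(boundary)
    if poly.area <= 0 or not poly.exterior:
        raise GeometryError("degenerate polygon: zero area")
    ring = poly.exterior
    centroid = np.asarray(poly.centroid.coords[0])
    length = ring.length
    pts = np.array(
        [ring.interpolate(length * i / n_samples).coords[0] for i in range(n_samples)]
    )
    return np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])


def _cdf_stats(boundary: np.ndarray, n_samples: int = CDF_SAMPLES):
    d = centroid_distance_function(boundary, n_samples)
    return float(d.mean()), float(d.std()), float(d.max() / max(d.min(), 1e-12))


def mask_to_boundary(mask: np.ndarray) -> np.ndarray:
    """Longest iso-contour of a binary mask as an (n, 2) (x, y) polygon."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise GeometryError("mask has no boundary contour")
    contour = max(contours, key=len)
    return contour[:, ::-1]  # (row, col) -> (x, y)


def touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _gray(pixels: np.ndarray) -> np.ndarray:
    """Luma on [0, 255] floats."""
    p = pixels.astype(float)
    return 0.2125 * p[..., 0] + 0.7154 * p[..., 1] + 0.0721 * p[..., 2]


def _single_region(mask: np.ndarray):
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    if not props:
        raise ValueError("empty mask")
    return max(props, key=lambda r: r.area)


def _shape_features(mask: np.ndarray) -> np.ndarray:
    region = _single_region(mask)
    area = float(region.area)
    perimeter = float(region.perimeter_crofton)
    circularity = 4 * np.pi * area / max(perimeter, 1e-12) ** 2
    hull = region.image_convex.astype(np.uint8)
    hull_perimeter = float(measure.regionprops(hull)[0].perimeter_crofton)
    convexity = hull_perimeter / max(perimeter, 1e-12)
    major = float(region.axis_major_length)
    minor = float(region.axis_minor_length)
    aspect = major / max(minor, 1e-12)
    cdf_mean, cdf_std, cdf_ratio = _cdf_stats(mask_to_boundary(mask))
    return np.array([
        area, perimeter, circularity, float(region.eccentricity),
        float(region.solidity), convexity, major, minor, aspect,
        cdf_mean, cdf_std, cdf_ratio,
    ])


def _color_features(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = pixels[mask].astype(float)  # (n, 3), in-mask pixels only
    out = []
    for c in range(3):
        v = vals[:, c]
        sd = float(v.std())
        skew = float(sstats.skew(v)) if sd > 1e-12 else 0.0
        q05, q50, q95 = np.quantile(v, (0.05, 0.5, 0.95))
        out.extend([float(v.mean()), sd, skew, float(q05), float(q50), float(q95)])
    return np.array(out)


def _texture_features(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    gray = _gray(pixels)
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    crop = gray[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    crop_mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    # out-of-mask pixels take the in-mask mean so that co-occurrence pairs
    # crossing the boundary do not import background structure
    filled = crop.copy()
    filled[~crop_mask] = crop[crop_mask].mean()
    q = np.clip((filled / 256.0 * GLCM_LEVELS).astype(int), 0, GLCM_LEVELS - 1)
    glcm = graycomatrix(
        q.astype(np.uint8), distances=(1, 3),
        angles=(0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
        levels=GLCM_LEVELS, symmetric=True, normed=True,
    )
    out = []
    for d_idx in range(2):
        for prop in _TEXTURE_PROPS:
            vals = graycoprops(glcm, prop)  # (n_dist, n_angle)
            out.append(float(vals[d_idx].mean()))
    return np.array(out)


def extract_cell_features(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Compute the 42-long cellular feature vector for one cell mask.

    ``pixels`` is the RGB tile, ``mask`` a boolean array of the same H x W.
    Cells touching the tile border are still measured; use
    :func:`touches_border` to flag them.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    feats = np.concatenate([
        _shape_features(mask),
        _color_features(pixels, mask),
        _texture_features(pixels, mask),
    ])
    assert feats.shape == (42,)
    return feats


def extract_nuclear_features(
    pixels: np.ndarray, cell_mask: np.ndarray, nucleus_mask: np.ndarray
) -> np.ndarray:
    """Compute the 11 nuclear features for a white cell.

    Raises ``ValueError`` on an empty nucleus; the caller should mark the
    nuclear block missing and set a quality flag in that case.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    if (nucleus_mask & ~cell_mask).any():
        raise ValueError("nucleus mask must lie within the cell mask")

    shape = _shape_features(nucleus_mask)
    area_ratio = float(nucleus_mask.sum() / cell_mask.sum())
    _, nuc_cdf_std, _ = _cdf_stats(mask_to_boundary(nucleus_mask))
    gray = _gray(pixels)
    nuc_vals = gray[nucleus_mask]
    cyto_mask = cell_mask & ~nucleus_mask
    nuc_mean = float(nuc_vals.mean())
    if cyto_mask.any():
        ratio = nuc_mean / max(float(gray[cyto_mask].mean()), 1e-12)
    else:
        ratio = 1.0  # nucleus fills the cell: no cytoplasm to contrast with
    feats = np.array([
        shape[0], shape[1], shape[2], shape[3], shape[4], shape[5],
        area_ratio, nuc_cdf_std, nuc_mean, float(nuc_vals.std()), ratio,
    ])
    assert feats.shape == (11,)
    return feats


def extract_wbc_features(
    pixels: np.ndarray, cell_mask: np.ndarray, nucleus_mask: np.ndarray | None
) -> tuple[np.ndarray, bool]:
    """53-long white-cell vector; returns (features, nucleus_ok).

    When the nucleus is missing or degenerate the nuclear block is NaN and
    ``nucleus_ok`` is False.
    """
    cellular = extract_cell_features(pixels, cell_mask)
    if nucleus_mask is None or not np.asarray(nucleus_mask).any():
        return np.concatenate([cellular, np.full(11, np.nan)]), False
    nuclear = extract_nuclear_features(pixels, cell_mask, nucleus_mask)
    return np.concatenate([cellular, nuclear]), True
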