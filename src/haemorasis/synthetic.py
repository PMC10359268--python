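"""Synthetic blood-smear tiles and per-cell feature bags with known ground truth.

Two generators make every downstream stage testable without slide data:

* :func:`render_tile` draws a simplified peripheral-blood-smear tile —
  pale-centered red-cell discs, larger white cells with a darker multi-lobed
  nucleus, small platelet dots, optional clumps and Gaussian blur — and
  returns per-object ground-truth masks.
* :func:`simulate_bags` draws per-cell feature bags from planted morphotype
  mixtures whose slide-level mixing proportions depend on the clinical
  condition, together with condition-dependent blood counts and task labels.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io_core import SlideBag, Tile

#: The five leaf clinical conditions used throughout.
CONDITIONS = ("control", "ida", "ma", "mds_sf3b1_mut", "mds_sf3b1_wt")

# Object classes in ground-truth maps
CLASS_BACKGROUND, CLASS_RBC, CLASS_WBC, CLASS_PLATELET = 0, 1, 2, 3

# Default smear palette (RGB, uint8): Romanowsky-like tones.
BACKGROUND_COLOR = (236, 230, 232)
RBC_COLOR = (196, 116, 108)
RBC_PALLOR_COLOR = (224, 168, 158)
WBC_CYTOPLASM_COLOR = (176, 158, 210)
WBC_NUCLEUS_COLOR = (90, 58, 128)
PLATELET_COLOR = (130, 96, 160)


class SceneError(ValueError):
    """Invalid tile scene specification."""


class DesignError(ValueError):
    """Invalid bag-simulation design."""


@dataclass
class RBCSpec:
    center: tuple[float, float]  # (x, y)
    radii: tuple[float, float] = (14.0, 13.0)
    rotation: float = 0.0  # radians
    central_pallor: bool = True


@dataclass
class WBCSpec:
    center: tuple[float, float]
    radius: float = 28.0
    n_lobes: int = 2
    nucleus_offset: tuple[float, float] = (0.0, 0.0)


@dataclass
class PlateletSpec:
    center: tuple[float, float]
    radius: float = 3.0


@dataclass
class TileScene:
    """Declarative description of one synthetic tile."""

    shape: tuple[int, int] = (512, 512)
    rbc_specs: list[RBCSpec] = field(default_factory=list)
    wbc_specs: list[WBCSpec] = field(default_factory=list)
    platelet_specs: list[PlateletSpec] = field(default_factory=list)
    blur_sigma: float = 0.0
    noise_sigma: float = 2.0
    background_color: tuple[int, int, int] = BACKGROUND_COLOR

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise SceneError("blur_sigma must be >= 0")
        for spec in self.rbc_specs:
            if min(spec.radii) <= 1:
                raise SceneError("RBC radius must exceed 1 px")
        for spec in self.wbc_specs:
            if spec.radius <= 1:
                raise SceneError("WBC radius must exceed 1 px")
        for spec in self.platelet_specs:
            if spec.radius <= 1:
                raise SceneError("platelet radius must exceed 1 px")


@dataclass
class TileGroundTruth:
    """Instance label image plus per-object class codes and WBC nucleus map."""

    labels: np.ndarray  # int instance map, 0 = background
    object_classes: list[int]  # class code per instance id (1-based ids)
    nucleus_mask: np.ndarray  # bool, union of WBC nucleus regions

    def masks_of(self, class_code: int) -> list[np.ndarray]:
        return [
            self.labels == i + 1
            for i, c in enumerate(self.object_classes)
            if c == class_code
        ]


def _ellipse_mask(shape, center, radii, rotation=0.0):
    """Boolean ellipse mask, rasterized on a local bounding box for speed."""
    H, W = shape
    r = max(radii) + 2
    x0, x1 = max(int(center[0] - r), 0), min(int(center[0] + r) + 1, W)
    y0, y1 = max(int(center[1] - r), 0), min(int(center[1] + r) + 1, H)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - center[0], yy - center[1]
    c, s = np.cos(rotation), np.sin(rotation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mask[y0:y1, x0:x1] = (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0
    return mask


def render_tile(scene: TileScene, seed: int = 0) -> tuple[Tile, TileGroundTruth]:
    """Rasterize a scene into an RGB tile and its ground truth.

    Red cells are ellipses with a paler central region (biconcave pallor);
    white cells are larger discs whose multi-lobed nucleus is strictly
    darker than the cytoplasm; platelets are small dark dots. Gaussian blur
    and additive noise are applied last. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    H, W = scene.shape
    img = np.empty((H, W, 3), dtype=float)
    img[:] = scene.background_color

    labels = np.zeros((H, W), dtype=np.int32)
    object_classes: list[int] = []
    nucleus_total = np.zeros((H, W), dtype=bool)

    def _paint(mask, color):
        img[mask] = color

    next_id = 1
    for spec in scene.rbc_specs:
        mask = _ellipse_mask((H, W), spec.center, spec.radii, spec.rotation)
        _paint(mask, RBC_COLOR)
        if spec.central_pallor:
            inner = _ellipse_mask(
                (H, W), spec.center,
                (spec.radii[0] * 0.55, spec.radii[1] * 0.55), spec.rotation,
            )
            _paint(inner, RBC_PALLOR_COLOR)
        labels[mask] = next_id
        object_classes.append(CLASS_RBC)
        next_id += 1

    for spec in scene.wbc_specs:
        mask = _ellipse_mask((H, W), spec.center, (spec.radius, spec.radius))
        _paint(mask, WBC_CYTOPLASM_COLOR)
        # nucleus: n_lobes overlapping discs around an offset sub-center
        nuc_center = (
            spec.center[0] + spec.nucleus_offset[0],
            spec.center[1] + spec.nucleus_offset[1],
        )
        lobe_r = spec.radius * 0.38
        nucleus = np.zeros((H, W), dtype=bool)
        for k in range(max(1, spec.n_lobes)):
            angle = 2 * np.pi * k / max(1, spec.n_lobes)
            lc = (
                nuc_center[0] + 0.55 * lobe_r * np.cos(angle),
                nuc_center[1] + 0.55 * lobe_r * np.sin(angle),
            )
            nucleus |= _ellipse_mask((H, W), lc, (lobe_r, lobe_r))
        nucleus &= mask
        _paint(nucleus, WBC_NUCLEUS_COLOR)
        labels[mask] = next_id
        object_classes.append(CLASS_WBC)
        nucleus_total |= nucleus
        next_id += 1

    for spec in scene.platelet_specs:
        mask = _ellipse_mask((H, W), spec.center, (spec.radius, spec.radius))
        _paint(mask, PLATELET_COLOR)
        labels[mask] = next_id
        object_classes.append(CLASS_PLATELET)
        next_id += 1

    if scene.blur_sigma > 0:
        for c in range(3):
            img[:, :, c] = ndi.gaussian_filter(img[:, :, c], scene.blur_sigma)
    if scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    tile = Tile(pixels=img)
    return tile, TileGroundTruth(labels, object_classes, nucleus_total)


def _sample_positions(rng, n, shape, margin, min_dist, max_tries=8000):
    """Rejection-sample non-overlapping object centers inside the tile."""
    H, W = shape
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        x = rng.uniform(margin, W - margin)
        y = rng.uniform(margin, H - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in pts):
            pts.append((x, y))
    return pts


def random_scene(
    seed: int,
    shape: tuple[int, int] = (512, 512),
    n_rbc: int = 30,
    n_wbc: int = 1,
    n_platelet: int = 4,
    blur_sigma: float = 0.0,
    rbc_radius: float = 14.0,
    wbc_radius: float = 28.0,
    overlap: bool = False,
) -> TileScene:
    """Sample a scene at realistic sizes (40x scale).

    With ``overlap=False`` cells are placed with rejection sampling so no
    two touch; ``overlap=True`` drops the spacing constraint to emulate
    over-dense smear regions.
    """
    rng = np.random.default_rng(seed)
    margin = max(rbc_radius, wbc_radius) + 4
    n_total = n_rbc + n_wbc + n_platelet
    if overlap:
        pts = [(rng.uniform(margin, shape[1] - margin),
                rng.uniform(margin, shape[0] - margin)) for _ in range(n_total)]
    else:
        spacing = 2 * max(rbc_radius, wbc_radius if n_wbc else rbc_radius) + 4
        pts = _sample_positions(rng, n_total, shape, margin, spacing)
    wbc = [WBCSpec(center=p, radius=wbc_radius * rng.uniform(0.9, 1.1),
                   n_lobes=int(rng.integers(1, 5)))
           for p in pts[:n_wbc]]
    rbc = []
    for p in pts[n_wbc : n_wbc + n_rbc]:
        r = rbc_radius * rng.uniform(0.85, 1.15)
        rbc.append(RBCSpec(center=p, radii=(r, r * rng.uniform(0.85, 1.0)),
                           rotation=rng.uniform(0, np.pi)))
    plate = [PlateletSpec(center=p, radius=rng.uniform(2.5, 4.0))
             for p in pts[n_wbc + n_rbc :]]
    return TileScene(shape=shape, rbc_specs=rbc, wbc_specs=wbc,
                     platelet_specs=plate, blur_sigma=blur_sigma)


def qc_benchmark(seed: int = 3, n_good: int = 100, n_poor: int = 100
                 ) -> tuple[list, list[str]]:
    """Labeled tile set for quality-control training.

    Good tiles are mid-density and sharp; poor tiles split evenly between
    blank, over-dense (overlapping cells) and blurred. Returns (tiles,
    labels).
    """
    from .io_core import Tile  # noqa: F401  (tiles are Tile instances)

    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    for i in range(n_good):
        sc = random_scene(seed=seed * 10000 + i,
                          n_rbc=int(rng.integers(20, 40)), n_wbc=1)
        tiles.append(render_tile(sc, seed=seed * 10000 + i)[0])
        labels.append("good")
    kinds = ["blank", "dense", "blurred"]
    for i in range(n_poor):
        kind = kinds[i % 3]
        s = seed * 10000 + 5000 + i
        if kind == "blank":
            sc = TileScene()
        elif kind == "dense":
            sc = random_scene(seed=s, n_rbc=150, n_wbc=2, overlap=True)
        else:
            sc = random_scene(seed=s, n_rbc=int(rng.integers(20, 40)),
                              blur_sigma=6.0)
        tiles.append(render_tile(sc, seed=s)[0])
        labels.append("poor")
    return tiles, labels


def clumped_scene(
    seed: int,
    shape: tuple[int, int] = (512, 512),
    n_rbc: int = 30,
    n_rbc_clumps: int = 5,
    n_platelet_clumps: int = 5,
    blur_sigma: float = 0.0,
    rbc_radius: float = 14.0,
) -> TileScene:
    """Scene mixing single red cells with fused-doublet and platelet clumps.

    Clumps are the principal false-positive sources for edge-based red-cell
    detection: a doublet is two overlapping discs (larger area, lower
    solidity than a single cell), a platelet clump a tight rosette of dark
    dots. Groups are mutually non-overlapping.
    """
    rng = np.random.default_rng(seed)
    margin = 3 * rbc_radius
    n_groups = n_rbc + n_rbc_clumps + n_platelet_clumps
    pts = _sample_positions(rng, n_groups, shape, margin, 4.6 * rbc_radius)
    rbc, plate = [], []
    for p in pts[:n_rbc]:
        r = rbc_radius * rng.uniform(0.85, 1.15)
        rbc.append(RBCSpec(center=p, radii=(r, r * rng.uniform(0.85, 1.0)),
                           rotation=rng.uniform(0, np.pi)))
    for p in pts[n_rbc : n_rbc + n_rbc_clumps]:
        r = rbc_radius * rng.uniform(0.9, 1.1)
        angle = rng.uniform(0, np.pi)
        off = 0.65 * r
        for sgn in (-1, 1):
            c = (p[0] + sgn * off * np.cos(angle), p[1] + sgn * off * np.sin(angle))
            rbc.append(RBCSpec(center=c, radii=(r, r * 0.95),
                               rotation=rng.uniform(0, np.pi)))
    for p in pts[n_rbc + n_rbc_clumps :]:
        for j in range(5):
            a = 2 * np.pi * j / 5 + rng.uniform(-0.3, 0.3)
            rad = rng.uniform(2.5, 4.0)
            c = (p[0] + 4.5 * np.cos(a), p[1] + 4.5 * np.sin(a))
            plate.append(PlateletSpec(center=c, radius=rad))
    return TileScene(shape=shape, rbc_specs=rbc, platelet_specs=plate,
                     blur_sigma=blur_sigma)


# ---------------------------------------------------------------------------
# Feature-bag simulation
# ---------------------------------------------------------------------------

@dataclass
class CellPopulation:
    """Planted morphotype mixture for one cell type.

    ``centroids`` is (K_true, d) in feature space; each condition's
    ``mixing`` vector gives its slide-level morphotype proportions and must
    sum to 1; ``within_scatter`` is the isotropic within-morphotype s.d.
    """

    centroids: np.ndarray
    within_scatter: float
    mixing: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.within_scatter <= 0:
            raise DesignError("within_scatter must be > 0")
        K = self.centroids.shape[0]
        for cond, w in self.mixing.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (K,):
                raise DesignError(f"mixing vector for {cond} must have length {K}")
            if not np.isclose(w.sum(), 1.0):
                raise DesignError(f"mixing vector for {cond} must sum to 1")
            self.mixing[cond] = w

    @property
    def k_true(self) -> int:
        return self.centroids.shape[0]


@dataclass
class BagDesign:
    """Full design of a synthetic cohort of slide bags."""

    wbc: CellPopulation
    rbc: CellPopulation
    n_slides: dict[str, int]
    cells_per_slide: tuple[int, int] = (150, 250)
    blood_count_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BLOOD_COUNT_MEANS)
    )
    blood_count_scales: tuple[float, float, float] = (1500.0, 1.0, 50000.0)
    seed: int = 0


#: Typical complete-blood-count means (WBCC cells/uL, Hb g/dL, Plt /uL) per condition.
DEFAULT_BLOOD_COUNT_MEANS = {
    "control": (7000.0, 14.0, 250000.0),
    "ida": (7500.0, 9.5, 300000.0),
    "ma": (5500.0, 9.0, 180000.0),
    "mds_sf3b1_mut": (4500.0, 9.5, 220000.0),
    "mds_sf3b1_wt": (3500.0, 10.0, 120000.0),
}


def condition_labels(condition: str) -> dict[str, int | None]:
    """Map a leaf condition to the four binary task labels.

    disease_detection: control (0) vs any disease (1), defined for all.
    disease_classification: anemia (0) vs MDS (1), diseased slides only.
    mds_subtyping: SF3B1-wildtype (0) vs SF3B1-mutant (1), MDS only.
    anemia_classification: IDA (0) vs MA (1), anemia only.
    """
    is_mds = condition.startswith("mds")
    is_anemia = condition in ("ida", "ma")
    return {
        "disease_detection": 0 if condition == "control" else 1,
        "disease_classification": (1 if is_mds else 0) if (is_mds or is_anemia) else None,
        "mds_subtyping": (1 if condition == "mds_sf3b1_mut" else 0) if is_mds else None,
        "anemia_classification": (1 if condition == "ma" else 0) if is_anemia else None,
    }


def _orthogonal_centroids(rng: np.random.Generator, k: int, d: int,
                          separation: float) -> np.ndarray:
    """K centroids with exact pairwise Euclidean distance ``separation``."""
    if k > d:
        raise DesignError("need k <= d for orthogonal centroid construction")
    raw = rng.normal(size=(d, k))
    q, _ = np.linalg.qr(raw)
    return (separation / np.sqrt(2.0)) * q[:, :k].T


def default_mixing(k_true: int = 4) -> dict[str, np.ndarray]:
    """Condition-specific mixing with one dominant morphotype per condition group."""
    if k_true < 4:
        raise DesignError("default mixing needs k_true >= 4")

    def dom(i, w=0.55):
        v = np.full(k_true, (1 - w) / (k_true - 1))
        v[i] = w
        return v

    # SF3B1-wildtype: signal split over morphotypes 0 and 3, so it differs
    # from both the mutant profile and the anemias
    wt = np.full(k_true, 0.30 / (k_true - 2))
    wt[0], wt[3] = 0.40, 0.30
    wt = wt / wt.sum()
    return {
        "control": dom(0),
        "ida": dom(1),
        "ma": dom(2),
        "mds_sf3b1_mut": dom(3),
        "mds_sf3b1_wt": wt,
    }


def default_bag_design(
    d: int = 10,
    k_true: int = 4,
    separation: float = 6.0,
    within_scatter: float = 1.0,
    n_slides_per_condition: int = 12,
    cells_per_slide: tuple[int, int] = (150, 250),
    seed: int = 0,
) -> BagDesign:
    """Well-separated planted design: centroid separation = 6x within-scatter."""
    rng = np.random.default_rng(seed)
    mixing = default_mixing(k_true)
    wbc = CellPopulation(
        centroids=_orthogonal_centroids(rng, k_true, d, separation * within_scatter),
        within_scatter=within_scatter,
        mixing={c: v.copy() for c, v in mixing.items()},
    )
    rbc = CellPopulation(
        centroids=_orthogonal_centroids(rng, k_true, d, separation * within_scatter),
        within_scatter=within_scatter,
        mixing={c: v.copy() for c, v in mixing.items()},
    )
    return BagDesign(
        wbc=wbc,
        rbc=rbc,
        n_slides={c: n_slides_per_condition for c in CONDITIONS},
        cells_per_slide=cells_per_slide,
        seed=seed,
    )


def simulate_bags(design: BagDesign) -> tuple[list[SlideBag], pd.DataFrame]:
    """Draw a cohort of slide bags from a planted morphotype design.

    Per slide the cell count is uniform over ``cells_per_slide``; each
    cell's morphotype is drawn from the slide condition's mixing vector and
    its features from an isotropic Gaussian at the morphotype centroid.
    Returns the bags and a table of planted per-cell assignments
    (slide_id, cell_type, cell_index, morphotype, condition).
    """
    rng = np.random.default_rng(design.seed)
    bags: list[SlideBag] = []
    records = []
    slide_no = 0
    for cond in sorted(design.n_slides):
        n_slides = design.n_slides[cond]
        labels = condition_labels(cond) if cond in CONDITIONS else {}
        for _ in range(n_slides):
            slide_id = f"s{slide_no:04d}"
            slide_no += 1
            feats = {}
            for ct, pop in (("wbc", design.wbc), ("rbc", design.rbc)):
                if cond not in pop.mixing:
                    raise DesignError(f"no mixing vector for condition {cond!r}")
                n_cells = int(rng.integers(design.cells_per_slide[0],
                                           design.cells_per_slide[1] + 1))
                z = rng.choice(pop.k_true, size=n_cells, p=pop.mixing[cond])
                x = pop.centroids[z] + rng.normal(
                    0.0, pop.within_scatter, size=(n_cells, pop.centroids.shape[1])
                )
                feats[ct] = x
                for i, zi in enumerate(z):
                    records.append(
                        (slide_id, ct, i, int(zi), cond)
                    )
            means = design.blood_count_means[cond]
            scales = design.blood_count_scales
            counts = {
                "wbcc": max(float(rng.normal(means[0], scales[0])), 100.0),
                "hb": max(float(rng.normal(means[1], scales[1])), 2.0),
                "plt": max(float(rng.normal(means[2], scales[2])), 5000.0),
            }
            bags.append(
                SlideBag(
                    slide_id=slide_id,
                    wbc_features=feats["wbc"],
                    rbc_features=feats["rbc"],
                    blood_counts=counts,
                    labels=labels,
                    condition=cond,
                )
            )
    assignments = pd.DataFrame(
        records, columns=["slide_id", "cell_type", "cell_index", "morphotype", "condition"]
    )
    return bags, assignments


def simulate_annotations(
    planted: Sequence[int], confusion: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Draw an "expert" annotation per cell from its planted morphotype.

    ``confusion`` is row-stochastic: row i gives the distribution of expert
    labels for planted morphotype i.
    """
    confusion = np.atleast_2d(np.asarray(confusion, dtype=float))
    if np.any(confusion < 0) or not np.allclose(confusion.sum(axis=1), 1.0):
        raise DesignError("confusion matrix rows must be non-negative and sum to 1")
    planted = np.asarray(planted, dtype=int)
    if planted.size and (planted.min() < 0 or planted.max() >= confusion.shape[0]):
        raise DesignError("planted label out of range for confusion matrix")
    rng = np.random.default_rng(seed)
    out = np.empty(planted.shape, dtype=int)
    for i, z in enumerate(planted):
        out[i] = rng.choice(confusion.shape[1], p=confusion[z])
    return out
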