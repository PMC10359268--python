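"""Core domain types and I/O for slide tiles, cells and feature tables.

Coordinates are 0-based pixels in the slide frame, origin at the top-left
corner, x rightward and y downward. Cell boundaries are closed polygon
rings in that frame; signed area follows the shoelace convention.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon

#: The four slide-level diagnostic tasks.
TASKS = (
    "disease_detection",
    "disease_classification",
    "mds_subtyping",
    "anemia_classification",
)

DEFAULT_TILE_SIZE = 512

logger = logging.getLogger("haemorasis")


class InputError(ValueError):
    """Unreadable or malformed input file."""


class FormatError(ValueError):
    """Input exists but is not in the expected format (e.g. non-RGB raster)."""


class GeometryError(ValueError):
    """Invalid cell geometry (degenerate or self-intersecting polygon)."""


class SchemaError(ValueError):
    """Feature-table columns do not match the expected schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Tile:
    """An RGB image region cut from a digitized slide.

    Parameters
    ----------
    pixels : uint8 array of shape (H, W, 3)
    slide_id : identifier of the parent slide
    origin : (x, y) pixel offset of the tile's top-left corner in the slide
    """

    pixels: np.ndarray
    slide_id: str = "slide"
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"tile pixels must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("tile must have positive height and width")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise FormatError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("tile origin must be non-negative")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class CellRecord:
    """A single detected cell with its geometry and feature vector."""

    cell_id: str
    slide_id: str
    cell_type: str  # "WBC" or "RBC"
    boundary: np.ndarray  # (n, 2) array of (x, y) vertices, implicitly closed
    nucleus_boundary: np.ndarray | None = None
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_type not in ("WBC", "RBC"):
            raise ValueError(f"cell_type must be WBC or RBC, got {self.cell_type!r}")
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[0] < 3:
            raise GeometryError(f"cell {self.cell_id}: boundary needs >= 3 vertices")
        if abs(shoelace_area(self.boundary)) <= 0:
            raise GeometryError(f"cell {self.cell_id}: boundary has zero area")


@dataclass
class SlideBag:
    """All cell features for one slide plus blood counts and task labels.

    ``wbc_features`` / ``rbc_features`` are (n_cells, d) float matrices;
    either may be empty. ``blood_counts`` holds (WBCC cells/uL, Hb g/dL,
    Plt platelets/uL) with ``None`` for missing values. ``labels`` maps each
    task to 0, 1 or ``None`` (slide not eligible for that task).
    """

    slide_id: str
    wbc_features: np.ndarray
    rbc_features: np.ndarray
    blood_counts: dict[str, float | None] = field(
        default_factory=lambda: {"wbcc": None, "hb": None, "plt": None}
    )
    labels: dict[str, int | None] = field(default_factory=dict)
    condition: str | None = None

    def __post_init__(self) -> None:
        self.wbc_features = np.atleast_2d(np.asarray(self.wbc_features, dtype=float))
        self.rbc_features = np.atleast_2d(np.asarray(self.rbc_features, dtype=float))
        for name, mat in (("wbc", self.wbc_features), ("rbc", self.rbc_features)):
            if mat.size and not np.all(np.isfinite(mat)):
                raise ValueError(f"{name} feature matrix contains non-finite values")
        for task in self.labels:
            if task not in TASKS:
                raise ValueError(f"unknown task label {task!r}")

    def n_cells(self, cell_type: str) -> int:
        mat = self.wbc_features if cell_type == "wbc" else self.rbc_features
        return 0 if mat.size == 0 else mat.shape[0]


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area by the shoelace formula (positive = CCW in x-right/y-down frame)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# Tile reading
# ---------------------------------------------------------------------------

class RasterReader:
    """Plain-raster backend of the whole-slide reader contract.

    The contract is three methods — ``dimensions``, ``read_region`` and
    ``close`` — so that pyramidal whole-slide backends can be plugged in
    without touching the tiling logic.
    """

    def __init__(self, path: str | pathlib.Path):
        path = pathlib.Path(path)
        try:
            arr = iio.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"cannot read raster {path}: {exc}") from exc
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(f"{path} is not an RGB raster (shape {arr.shape})")
        self._arr = np.ascontiguousarray(arr[:, :, :3]).astype(np.uint8)
        self.slide_id = path.stem

    @property
    def dimensions(self) -> tuple[int, int]:
        """(H, W) of the full raster."""
        return self._arr.shape[0], self._arr.shape[1]

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        return self._arr[y : y + h, x : x + w]

    def close(self) -> None:
        pass


def iter_tiles_from_array(
    pixels: np.ndarray,
    slide_id: str = "slide",
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
) -> Iterator[Tile]:
    """Tile an in-memory RGB array in row-major order, dropping partial edge tiles."""
    if stride is None:
        stride = tile_size
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise FormatError(f"expected RGB array, got shape {pixels.shape}")
    H, W = pixels.shape[:2]
    if H < tile_size or W < tile_size:
        return
    for y in range(0, H - tile_size + 1, stride):
        for x in range(0, W - tile_size + 1, stride):
            yield Tile(
                pixels=pixels[y : y + tile_size, x : x + tile_size],
                slide_id=slide_id,
                origin=(x, y),
            )


def read_tiles(
    source: str | pathlib.Path,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
) -> Iterator[Tile]:
    """Stream fixed-size tiles from a raster file or a directory of rasters.

    Tiles cover each raster in row-major order with the given stride; edge
    remainders smaller than ``tile_size`` are dropped. Tile origins are
    recorded in the slide pixel frame.
    """
    source = pathlib.Path(source)
    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
        )
        if not paths:
            raise InputError(f"no raster files in directory {source}")
    elif source.exists():
        paths = [source]
    else:
        raise InputError(f"no such file or directory: {source}")
    for path in paths:
        reader = RasterReader(path)
        yield from iter_tiles_from_array(
            reader._arr, slide_id=reader.slide_id, tile_size=tile_size, stride=stride
        )
        reader.close()


# ---------------------------------------------------------------------------
# QuPath-compatible GeoJSON export
# ---------------------------------------------------------------------------

def export_qupath_geojson(cells: Sequence[CellRecord], path: str | pathlib.Path) -> None:
    """Write cells as a GeoJSON FeatureCollection readable by QuPath.

    Each cell becomes a Polygon feature with ``cell_type`` and ``cell_id``
    properties; coordinates stay in the slide pixel frame and rings are
    explicitly closed (first coordinate repeated last).
    """
    features = []
    for cell in cells:
        ring = np.asarray(cell.boundary, dtype=float)
        poly = _ShapelyPolygon(ring)
        if not poly.is_valid:
            raise GeometryError(f"cell {cell.cell_id}: invalid (self-intersecting?) polygon")
        coords = ring.tolist()
        if coords[0] != coords[-1]:
            coords.append(coords[0])
        props = {"cell_type": cell.cell_type, "cell_id": cell.cell_id,
                 "slide_id": cell.slide_id}
        geometry = {"type": "Polygon", "coordinates": [coords]}
        if cell.nucleus_boundary is not None:
            nucleus = np.asarray(cell.nucleus_boundary, dtype=float).tolist()
            if nucleus[0] != nucleus[-1]:
                nucleus.append(nucleus[0])
            props["nucleus"] = nucleus
        features.append({"type": "Feature", "geometry": geometry, "properties": props})
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_qupath_geojson(path: str | pathlib.Path) -> list[CellRecord]:
    """Read back a FeatureCollection written by :func:`export_qupath_geojson`."""
    with open(path) as fh:
        collection = json.load(fh)
    cells = []
    for feat in collection.get("features", []):
        props = feat.get("properties", {})
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]  # drop closing duplicate: internal storage is open
        nucleus = props.get("nucleus")
        if nucleus is not None:
            nucleus = np.asarray(nucleus, dtype=float)
            if len(nucleus) > 1 and np.allclose(nucleus[0], nucleus[-1]):
                nucleus = nucleus[:-1]
        cells.append(
            CellRecord(
                cell_id=props.get("cell_id", "cell"),
                slide_id=props.get("slide_id", "slide"),
                cell_type=props.get("cell_type", "RBC"),
                boundary=ring,
                nucleus_boundary=nucleus,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = ("cell_id", "slide_id", "cell_type")


def cells_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """Flatten cell records (metadata + features) into a table."""
    rows = []
    for cell in cells:
        row = {"cell_id": cell.cell_id, "slide_id": cell.slide_id,
               "cell_type": cell.cell_type}
        row.update(cell.features)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=list(MANDATORY_COLUMNS))
    return frame


def write_feature_table(frame: pd.DataFrame, path: str | pathlib.Path) -> None:
    """Write a feature table as CSV or Parquet depending on the suffix."""
    path = pathlib.Path(path)
    _check_schema(frame)
    if path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_feature_table(path: str | pathlib.Path) -> pd.DataFrame:
    path = pathlib.Path(path)
    if path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path)
    _check_schema(frame)
    return frame


def _check_schema(frame: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature table missing mandatory columns: {missing}")


def split_by_cell_type(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a mixed table into per-cell-type tables, dropping all-NaN columns.

    WBC rows keep their 53 feature columns and RBC rows their 42; columns
    that are entirely missing within a cell type (e.g. nuclear features on
    RBC rows) are removed from that partition.
    """
    _check_schema(frame)
    out = {}
    for cell_type, sub in frame.groupby("cell_type"):
        sub = sub.dropna(axis=1, how="all")
        out[str(cell_type)] = sub.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Configuration and logging
# ---------------------------------------------------------------------------

def load_config(path: str | pathlib.Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def get_logger(stage: str) -> logging.LoggerAdapter:
    """Structured logger carrying the pipeline stage name."""
    base = logging.getLogger(f"haemorasis.{stage}")
    if not logging.getLogger("haemorasis").handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logging.getLogger("haemorasis").addHandler(handler)
        logging.getLogger("haemorasis").setLevel(logging.INFO)
    return logging.LoggerAdapter(base, {})
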