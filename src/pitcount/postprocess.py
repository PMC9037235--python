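"""Macro-style object analysis of three-class label maps.

Mirrors the classic ImageJ treatment of a background/cell/pit
segmentation: split the channels, fill holes in the cell mask, separate
adjoining cells with a distance-transform watershed, measure each cell
(area, solidity, pits), then flag cells that fail the RBC size gate, touch
the image edge, or have low solidity.  Low solidity — area over convex
area — is the workhorse filter against platelet aggregates and
debris-attached cells; excluded records are flagged, never deleted, so
every decision is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .types import BACKGROUND, CELL, PIT, LabelMap

__all__ = [
    "PostprocessConfig",
    "CellRecord",
    "ObjectTable",
    "split_channels",
    "fill_holes",
    "separate_cells",
    "measure_cells",
    "apply_filters",
    "run_macro",
    "pixel_solidity",
]

STATUS_INCLUDED = "included"
STATUS_SIZE = "excluded_size"
STATUS_EDGE = "excluded_edge"
STATUS_SOLIDITY = "excluded_solidity"
STATUSES = (STATUS_INCLUDED, STATUS_SIZE, STATUS_EDGE, STATUS_SOLIDITY)

_HULL_TOL = 1e-9


@dataclass(frozen=True)
class PostprocessConfig:
    """Filter gates and instance-separation settings.

    The RBC size gate 20–80 µm² brackets a 6–8 µm-diameter disc
    (≈28–50 µm²); solidity below 0.90 flags aggregates and
    debris-attached cells.  Cells touching the image edge are always
    discarded.  ``watershed_h`` is the merge depth for suppressing minor
    distance-map peaks before seeding the watershed.
    """

    min_cell_area_um2: float = 20.0
    max_cell_area_um2: float = 80.0
    min_solidity: float = 0.90
    min_pit_area_px: int = 4
    watershed_h: float = 3.0
    exclude_edge: bool = True
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.min_cell_area_um2 < self.max_cell_area_um2:
            raise ValueError("cell area gate must satisfy min < max")
        if not 0.0 < self.min_solidity <= 1.0:
            raise ValueError("min_solidity must lie in (0, 1]")
        if self.min_pit_area_px < 1:
            raise ValueError("min_pit_area_px must be >= 1")
        if self.watershed_h < 0:
            raise ValueError("watershed_h must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _structure(self) -> np.ndarray:
        return (
            np.ones((3, 3), dtype=bool)
            if self.connectivity == 8
            else ndimage.generate_binary_structure(2, 1)
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class CellRecord:
    """Per-cell measurements plus the inclusion decision."""

    cell_id: int
    area_um2: float
    solidity: float
    centroid: tuple[float, float]  # (row, col) px
    touches_edge: bool
    pit_count: int
    pit_areas_um2: list[float]
    status: str = STATUS_INCLUDED

    @property
    def pit_area_sum_um2(self) -> float:
        return float(sum(self.pit_areas_um2))

    @property
    def included(self) -> bool:
        return self.status == STATUS_INCLUDED

    @property
    def pitted(self) -> bool:
        return self.pit_count >= 1


@dataclass
class ObjectTable:
    """Ordered per-cell records with provenance."""

    records: list[CellRecord]
    source_image_id: str = ""
    config_hash: str = ""
    pixel_size_um: float = float("nan")

    def __len__(self) -> int:
        return len(self.records)

    def included(self) -> list[CellRecord]:
        return [r for r in self.records if r.included]

    def exclusion_tally(self) -> dict[str, int]:
        tally = {s: 0 for s in STATUSES[1:]}
        for r in self.records:
            if not r.included:
                tally[r.status] += 1
        return tally


# ---------------------------------------------------------------------------

def split_channels(labels: LabelMap) -> tuple[np.ndarray, np.ndarray]:
    """Split the three-class map into (cell_mask, pit_mask).

    Pits are part of their cell, so the cell mask is the union of the
    cell and pit codes; pits never read as holes downstream.
    """
    codes = labels.codes  # LabelMap construction already validated codes
    pit_mask = codes == PIT
    cell_mask = (codes == CELL) | pit_mask
    return cell_mask, pit_mask


def fill_holes(cell_mask: np.ndarray) -> np.ndarray:
    """Set every background component not connected to the border to
    foreground; border-connected background is untouched."""
    return ndimage.binary_fill_holes(np.asarray(cell_mask, dtype=bool))


def separate_cells(cell_mask: np.ndarray, config: PostprocessConfig | None = None) -> np.ndarray:
    """Distance-transform watershed instance separation.

    Peaks of the Euclidean distance map survive ``watershed_h`` depth
    suppression and seed a watershed of the inverted distance map
    restricted to the mask; any connected component left without a
    surviving peak is seeded at its distance-map argmax so every
    foreground pixel receives exactly one instance label.  Output labels
    are deterministic (raster order of seeds).
    """
    if config is None:
        config = PostprocessConfig()
    mask = np.asarray(cell_mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    dist = ndimage.distance_transform_edt(mask)
    if config.watershed_h > 0:
        peaks = h_maxima(dist, config.watershed_h, footprint=config._structure)
    else:
        peaks = dist == ndimage.maximum_filter(dist, footprint=config._structure)
        peaks &= mask
    markers, n_markers = ndimage.label(peaks, structure=config._structure)
    # rescue components whose peaks were all suppressed
    comp, n_comp = ndimage.label(mask, structure=config._structure)
    seeded = np.unique(comp[markers > 0])
    for c in range(1, n_comp + 1):
        if c not in seeded:
            flat = np.flatnonzero((comp == c).ravel())
            best = flat[np.argmax(dist.ravel()[flat])]
            n_markers += 1
            markers.ravel()[best] = n_markers
    conn = 2 if config.connectivity == 8 else 1
    return watershed(-dist, markers, mask=mask, connectivity=conn).astype(np.int32)


def pixel_solidity(rows: np.ndarray, cols: np.ndarray) -> float:
    """Solidity on the digital grid: pixel count over the number of pixel
    centres inside (or on, within 1e-9) the convex hull of the region's
    pixel centres.  Degenerate (collinear) regions have solidity 1.
    """
    pts = np.column_stack([rows, cols]).astype(np.float64)
    n = pts.shape[0]
    if n < 3:
        return 1.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 1.0  # collinear pixels: the hull is the region itself
    rlo, rhi = int(rows.min()), int(rows.max())
    clo, chi = int(cols.min()), int(cols.max())
    rr, cc = np.mgrid[rlo : rhi + 1, clo : chi + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    # inside iff every hull facet half-plane is satisfied within tolerance
    a = hull.equations[:, :2]
    b = hull.equations[:, 2]
    inside = np.all(grid @ a.T + b <= _HULL_TOL, axis=1)
    hull_px = int(inside.sum())
    return float(n / hull_px)


def measure_cells(
    cell_labels: np.ndarray,
    pit_mask: np.ndarray,
    pixel_size_um: float,
    config: PostprocessConfig | None = None,
    source_image_id: str = "",
) -> ObjectTable:
    """Measure every instance: area (µm²), solidity, centroid, edge
    contact, and its pits (connected pit components of at least
    ``min_pit_area_px`` pixels lying inside the instance)."""
    if config is None:
        config = PostprocessConfig()
    cell_labels = np.asarray(cell_labels)
    pit_mask = np.asarray(pit_mask, dtype=bool)
    if cell_labels.shape != pit_mask.shape:
        raise ValueError(
            f"geometry mismatch: labels {cell_labels.shape} vs pit mask {pit_mask.shape}"
        )
    h, w = cell_labels.shape
    px_area = pixel_size_um**2
    records: list[CellRecord] = []
    for lab in np.unique(cell_labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(cell_labels == lab)
        area_um2 = rows.size * px_area
        centroid = (float(rows.mean()), float(cols.mean()))
        touches = bool(
            (rows == 0).any() or (rows == h - 1).any() or (cols == 0).any() or (cols == w - 1).any()
        )
        solidity = pixel_solidity(rows, cols)
        # pits restricted to this instance, component-counted
        rlo, rhi = rows.min(), rows.max() + 1
        clo, chi = cols.min(), cols.max() + 1
        sub = pit_mask[rlo:rhi, clo:chi] & (cell_labels[rlo:rhi, clo:chi] == lab)
        pit_lab, n_pits = ndimage.label(sub, structure=config._structure)
        pit_areas = []
        if n_pits:
            sizes = ndimage.sum_labels(np.ones_like(pit_lab), pit_lab, index=range(1, n_pits + 1))
            pit_areas = [float(s * px_area) for s in sizes if s >= config.min_pit_area_px]
        records.append(
            CellRecord(
                cell_id=0,
                area_um2=float(area_um2),
                solidity=solidity,
                centroid=centroid,
                touches_edge=touches,
                pit_count=len(pit_areas),
                pit_areas_um2=pit_areas,
            )
        )
    records.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, r in enumerate(records, start=1):
        r.cell_id = i
    return ObjectTable(records, source_image_id, config.hash(), pixel_size_um)


def apply_filters(table: ObjectTable, config: PostprocessConfig | None = None) -> ObjectTable:
    """Assign inclusion statuses with precedence size → edge → solidity.

    The first failing gate is recorded; records are flagged, never
    removed, and measurements are retained on excluded records.
    """
    if config is None:
        config = PostprocessConfig()
    new_records = []
    for r in table.records:
        if not (config.min_cell_area_um2 <= r.area_um2 <= config.max_cell_area_um2):
            status = STATUS_SIZE
        elif config.exclude_edge and r.touches_edge:
            status = STATUS_EDGE
        elif r.solidity < config.min_solidity:
            status = STATUS_SOLIDITY
        else:
            status = STATUS_INCLUDED
        new_records.append(dataclasses.replace(r, status=status))
    return ObjectTable(new_records, table.source_image_id, config.hash(), table.pixel_size_um)


def run_macro(
    labels: LabelMap,
    pixel_size_um: float,
    config: PostprocessConfig | None = None,
    source_image_id: str = "",
) -> ObjectTable:
    """The full macro: split → fill holes → separate → measure → filter."""
    if config is None:
        config = PostprocessConfig()
    cell_mask, pit_mask = split_channels(labels)
    cell_mask = fill_holes(cell_mask)
    instances = separate_cells(cell_mask, config)
    table = measure_cells(instances, pit_mask, pixel_size_um, config, source_image_id)
    return apply_filters(table, config)
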