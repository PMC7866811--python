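"""Per-slide histology scores: nerve fiber density, tumor cellularity and
dominant immunophenotype.

Nerve fiber density (NFD) is the number of nerve fascicles with diameter
strictly below 100 μm counted over 20 contiguous microscope fields at ×200
magnification.  A ×200 field is modelled as a 1.1 mm square (the field of
view of a standard 20× objective); "20 continuous fields" is formalized as a
contiguous 20-tile window over the ROI's tile grid, and the maximum-count
(hotspot) window is reported so the score is deterministic.  Counts are
binned negative (0) / weak (1–10) / high (>10).

Tumor cellularity (TC) follows the area bookkeeping
``stroma = total − (normal + atrophic + tumor)`` and
``tc = tumor / (tumor + stroma)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor
from typing import Literal, Sequence

import numpy as np

from .core import CellRecord, Point2D, RegionAnnotation, Slide, polygon_area
from .errors import (
    ConfigurationError,
    InvalidAnnotationError,
    MissingAnnotationError,
    UndefinedCellularityError,
    ValidationError,
)

__all__ = [
    "FieldGridConfig",
    "NFDResult",
    "CellularityResult",
    "ImmunophenotypeResult",
    "FASCICLE_DIAMETER_CUTOFF_UM",
    "nfd_category",
    "score_nfd",
    "tumor_cellularity",
    "dominant_immunophenotype",
]

#: Fascicles with diameter >= this value are never counted (strict cut-off;
#: large nerve trunks are excluded from the density score).
FASCICLE_DIAMETER_CUTOFF_UM = 100.0


@dataclass(frozen=True)
class FieldGridConfig:
    """Geometry of the microscope-field grid used for NFD counting.

    ``window_mode='raster'`` slides a run of ``n_fields`` tiles along the
    row-major tile sequence; ``'block'`` scans contiguous rectangular blocks
    whose tile count equals ``n_fields`` (every factor pair that fits).
    """

    field_side_um: float = 1100.0
    n_fields: int = 20
    window_mode: Literal["raster", "block"] = "raster"

    def __post_init__(self) -> None:
        if self.field_side_um <= 0:
            raise ConfigurationError("field_side_um must be > 0")
        if self.n_fields < 1:
            raise ConfigurationError("n_fields must be >= 1")
        if self.window_mode not in ("raster", "block"):
            raise ConfigurationError("window_mode must be 'raster' or 'block'")


@dataclass(frozen=True)
class NFDResult:
    fascicle_count: int
    category: Literal["negative", "weak", "high"]
    binary_high: bool
    window_origin: Point2D


def nfd_category(count: int) -> str:
    """Three-bin nerve fiber density category from a fascicle count."""
    if count < 0:
        raise ValidationError("fascicle count cannot be negative")
    if count == 0:
        return "negative"
    if count <= 10:
        return "weak"
    return "high"


def _tile_counts(slide: Slide, grid: FieldGridConfig) -> tuple[np.ndarray, float, float]:
    roi = slide.roi()
    if roi is None:
        raise MissingAnnotationError(f"slide {slide.slide_id} has no roi annotation")
    xmin, ymin, xmax, ymax = roi.polygon.bounds
    side = grid.field_side_um
    if xmax - xmin < side or ymax - ymin < side:
        raise ConfigurationError(
            f"ROI ({xmax - xmin:.0f} x {ymax - ymin:.0f} um) is smaller than one "
            f"{side:.0f} um field"
        )
    nx = ceil((xmax - xmin) / side)
    ny = ceil((ymax - ymin) / side)
    counts = np.zeros((ny, nx), dtype=int)
    for fasc in slide.fascicles:
        if not fasc.diameter_um < FASCICLE_DIAMETER_CUTOFF_UM:
            continue
        ix = min(floor((fasc.position.x_um - xmin) / side), nx - 1)
        iy = min(floor((fasc.position.y_um - ymin) / side), ny - 1)
        if 0 <= ix < nx and 0 <= iy < ny:
            counts[iy, ix] += 1
    return counts, xmin, ymin


def score_nfd(slide: Slide, grid: FieldGridConfig = FieldGridConfig()) -> NFDResult:
    """Hotspot nerve fiber density of a slide.

    The ROI bounding box is tiled into ``field_side_um`` squares in raster
    order; every contiguous window of ``n_fields`` tiles is scored by the
    number of qualifying fascicles (diameter strictly < 100 μm) it contains,
    and the maximum-count window is reported.  Ties are broken by the first
    window in raster order.  If the grid holds fewer than ``n_fields`` tiles,
    the single all-tile window is used.
    """
    counts, xmin, ymin = _tile_counts(slide, grid)
    ny, nx = counts.shape
    side = grid.field_side_um

    if grid.window_mode == "raster" or counts.size <= grid.n_fields:
        flat = counts.ravel()  # row-major
        win = min(grid.n_fields, flat.size)
        sums = np.convolve(flat, np.ones(win, dtype=int), mode="valid")
        best = int(np.argmax(sums))  # first max in raster order
        count = int(sums[best])
        origin = Point2D(xmin + (best % nx) * side, ymin + (best // nx) * side)
        return NFDResult(count, nfd_category(count), nfd_category(count) == "high", origin)

    best_count, best_origin = -1, (0, 0)
    for rows in range(1, grid.n_fields + 1):
        if grid.n_fields % rows:
            continue
        cols = grid.n_fields // rows
        if rows > ny or cols > nx:
            continue
        # 2D sliding-window sums via cumulative sums
        c = np.cumsum(np.cumsum(counts, axis=0), axis=1)
        c = np.pad(c, ((1, 0), (1, 0)))
        sums = c[rows:, cols:] - c[:-rows, cols:] - c[rows:, :-cols] + c[:-rows, :-cols]
        iy, ix = np.unravel_index(int(np.argmax(sums)), sums.shape)
        if sums[iy, ix] > best_count:
            best_count = int(sums[iy, ix])
            best_origin = (ix, iy)
    if best_count < 0:
        raise ConfigurationError("no n_fields rectangular block fits the ROI grid")
    origin = Point2D(xmin + best_origin[0] * side, ymin + best_origin[1] * side)
    return NFDResult(
        best_count, nfd_category(best_count), nfd_category(best_count) == "high", origin
    )


@dataclass(frozen=True)
class CellularityResult:
    a_total: float
    a_normal: float
    a_atrophic: float
    a_tumor: float
    a_stroma: float
    tc: float


def tumor_cellularity(annotations: Sequence[RegionAnnotation]) -> CellularityResult:
    """Tumor cellularity from region annotations.

    ``stroma = total − (normal + atrophic + tumor)`` and
    ``tc = tumor / (tumor + stroma)``; component areas are sums of
    per-polygon areas (annotations are assumed non-overlapping within a
    label and mutually exclusive across tissue subtypes).
    """
    totals = [a for a in annotations if a.label == "total_tissue"]
    if len(totals) != 1:
        raise MissingAnnotationError(
            f"expected exactly one total_tissue annotation, found {len(totals)}"
        )
    area = {label: 0.0 for label in ("normal_pancreas", "atrophic_pancreas", "tumor_gland")}
    for a in annotations:
        if a.label in area:
            area[a.label] += polygon_area(a.polygon)
    a_total = polygon_area(totals[0].polygon)
    a_normal = area["normal_pancreas"]
    a_atrophic = area["atrophic_pancreas"]
    a_tumor = area["tumor_gland"]
    a_stroma = a_total - (a_normal + a_atrophic + a_tumor)
    if a_stroma < -1e-6 * max(a_total, 1.0):
        raise InvalidAnnotationError(
            f"component areas ({a_normal + a_atrophic + a_tumor:.1f} um2) exceed "
            f"total tissue ({a_total:.1f} um2); annotations overlap or are inconsistent"
        )
    a_stroma = max(a_stroma, 0.0)
    denom = a_tumor + a_stroma
    if denom == 0:
        raise UndefinedCellularityError("tumor + stroma area is zero; tc undefined")
    return CellularityResult(a_total, a_normal, a_atrophic, a_tumor, a_stroma,
                             tc=a_tumor / denom)


@dataclass(frozen=True)
class ImmunophenotypeResult:
    category: Literal["lymphocyte_predominant", "neutrophil_predominant", "no_immune_cells"]
    n_lymphocytes: int
    n_neutrophils: int


def dominant_immunophenotype(cells: Sequence[CellRecord]) -> ImmunophenotypeResult:
    """Dominant immune-cell type among the slide's immune cells.

    Ties are broken in favour of ``lymphocyte_predominant`` (a documented
    arbitrary convention; a tie has no biological reading).
    """
    n_lym = sum(1 for c in cells if c.immune_subtype == "lymphocyte")
    n_neu = sum(1 for c in cells if c.immune_subtype == "neutrophil")
    if n_lym == 0 and n_neu == 0:
        category = "no_immune_cells"
    elif n_neu > n_lym:
        category = "neutrophil_predominant"
    else:
        category = "lymphocyte_predominant"
    return ImmunophenotypeResult(category, n_lym, n_neu)
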