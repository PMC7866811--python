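"""Domain types shared by every pipeline stage.

All coordinates are physical micrometres in the image convention used by
slide scanners: the origin is the top-left corner of the scanned area and y
increases downward.  Every threshold in the pipeline (the 100 μm fascicle
diameter cut-off, field sizes, KDE bandwidths) is physical, so nothing here
knows about pixels.

The analysis unit is a :class:`Slide`: one set of region annotations
(total tissue, normal/atrophic pancreas, duodenum, tumor glands, ROI), one
table of cell centroids with morphometric features, and one table of nerve
fascicles with diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InvalidGeometryError, ValidationError

__all__ = [
    "REGION_LABELS",
    "CELL_CLASSES",
    "IMMUNE_SUBTYPES",
    "Point2D",
    "Polygon2D",
    "RegionAnnotation",
    "CellRecord",
    "NerveFascicle",
    "Slide",
    "polygon_area",
    "positions_of",
]

#: Allowed region-annotation labels.
REGION_LABELS = frozenset(
    {"total_tissue", "normal_pancreas", "atrophic_pancreas", "normal_duodenum",
     "tumor_gland", "roi"}
)

CELL_CLASSES = frozenset({"immune", "fibroblast", "tumor", "unknown"})
IMMUNE_SUBTYPES = frozenset({"lymphocyte", "neutrophil", "none"})


@dataclass(frozen=True)
class Point2D:
    """A planar position in micrometres (origin top-left, y down)."""

    x_um: float
    y_um: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise ValidationError(f"non-finite coordinates ({self.x_um}, {self.y_um})")


@dataclass(frozen=True)
class Polygon2D:
    """A simple (non-self-intersecting) closed ring of vertices.

    The ring is stored open (the first vertex is not repeated at the end);
    closure is implicit.  Holes are out of scope: annotations are simple rings.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        # drop an explicitly closed ring's repeated last vertex
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise InvalidGeometryError(
                f"polygon needs >=3 distinct vertices, got {len(verts)}"
            )
        for x, y in verts:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InvalidGeometryError("polygon vertex has non-finite coordinate")
        object.__setattr__(self, "vertices", verts)
        shp = _ShapelyPolygon(verts)
        if not shp.is_valid:
            raise InvalidGeometryError(
                f"polygon is not simple: {shapely.is_valid_reason(shp)}"
            )
        object.__setattr__(self, "_shp", shp)

    def to_shapely(self) -> _ShapelyPolygon:
        return self._shp  # type: ignore[attr-defined]

    @property
    def area_um2(self) -> float:
        """Enclosed planar area (shoelace magnitude), in μm²."""
        return float(self.to_shapely().area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the ring, in μm."""
        return tuple(self.to_shapely().bounds)  # type: ignore[return-value]

    @classmethod
    def from_xy(cls, xs: Iterable[float], ys: Iterable[float]) -> "Polygon2D":
        return cls(tuple(zip(xs, ys)))

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "Polygon2D":
        return cls(((xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)))


def polygon_area(p: Polygon2D) -> float:
    """Area of a simple polygon in μm², independent of vertex orientation."""
    if not isinstance(p, Polygon2D):
        p = Polygon2D(tuple(p))
    return p.area_um2


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled region polygon, as exported from manual slide annotation."""

    label: str
    polygon: Polygon2D

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValidationError(
                f"unknown region label {self.label!r}; expected one of "
                f"{sorted(REGION_LABELS)}"
            )


@dataclass(frozen=True)
class CellRecord:
    """A detected cell: centroid, class label and morphometric features.

    ``immune_subtype`` may differ from ``'none'`` only for immune cells.
    ``true_class`` is the planted (or curated) label; predicted labels live
    outside this record so that truth is never silently overwritten.
    """

    cell_id: str
    position: Point2D
    true_class: str = "unknown"
    immune_subtype: str = "none"
    nucleus_area_um2: float = 30.0
    circularity: float = 0.8
    stain_intensity: float = 0.5

    def __post_init__(self) -> None:
        if self.true_class not in CELL_CLASSES:
            raise ValidationError(f"unknown cell class {self.true_class!r}")
        if self.immune_subtype not in IMMUNE_SUBTYPES:
            raise ValidationError(f"unknown immune subtype {self.immune_subtype!r}")
        if self.immune_subtype != "none" and self.true_class != "immune":
            raise ValidationError(
                f"cell {self.cell_id}: immune_subtype={self.immune_subtype!r} "
                f"requires true_class='immune', got {self.true_class!r}"
            )
        if not self.nucleus_area_um2 > 0:
            raise ValidationError(f"cell {self.cell_id}: nucleus_area_um2 must be > 0")
        if not (0 < self.circularity <= 1):
            raise ValidationError(f"cell {self.cell_id}: circularity must be in (0, 1]")
        if self.stain_intensity < 0:
            raise ValidationError(f"cell {self.cell_id}: stain_intensity must be >= 0")


@dataclass(frozen=True)
class NerveFascicle:
    """A nerve fascicle cross-section: position and diameter in μm."""

    fascicle_id: str
    position: Point2D
    diameter_um: float

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValidationError(
                f"fascicle {self.fascicle_id}: diameter_um must be > 0"
            )


@dataclass
class Slide:
    """One patient's tumor slide: annotations, cells and nerve fascicles.

    Invariants enforced on construction: exactly one ``total_tissue``
    annotation, at most one ``roi``; all cells and fascicles lie within total
    tissue; tissue-subtype regions lie within total tissue.
    """

    slide_id: str
    annotations: list[RegionAnnotation] = field(default_factory=list)
    cells: list[CellRecord] = field(default_factory=list)
    fascicles: list[NerveFascicle] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_total = sum(a.label == "total_tissue" for a in self.annotations)
        if n_total != 1:
            raise ValidationError(
                f"slide {self.slide_id}: expected exactly one total_tissue "
                f"annotation, found {n_total}"
            )
        n_roi = sum(a.label == "roi" for a in self.annotations)
        if n_roi > 1:
            raise ValidationError(
                f"slide {self.slide_id}: at most one roi annotation allowed, "
                f"found {n_roi}"
            )
        total = self.total_tissue().polygon.to_shapely().buffer(1e-6)
        for a in self.annotations:
            if a.label in {"tumor_gland", "normal_pancreas", "atrophic_pancreas"}:
                if not total.covers(a.polygon.to_shapely()):
                    raise ValidationError(
                        f"slide {self.slide_id}: {a.label} annotation extends "
                        "outside total_tissue"
                    )
        for name, items in (("cell", self.cells), ("fascicle", self.fascicles)):
            if items:
                xs = np.array([it.position.x_um for it in items])
                ys = np.array([it.position.y_um for it in items])
                inside = shapely.contains_xy(total, xs, ys)
                if not inside.all():
                    bad = int(np.argmin(inside))
                    raise ValidationError(
                        f"slide {self.slide_id}: {name} at index {bad} lies "
                        "outside total_tissue"
                    )

    # -- annotation lookups -------------------------------------------------
    def regions(self, label: str) -> list[RegionAnnotation]:
        return [a for a in self.annotations if a.label == label]

    def total_tissue(self) -> RegionAnnotation:
        return next(a for a in self.annotations if a.label == "total_tissue")

    def roi(self) -> RegionAnnotation | None:
        rois = self.regions("roi")
        return rois[0] if rois else None

    def gland_polygons(self) -> list[Polygon2D]:
        return [a.polygon for a in self.regions("tumor_gland")]

    def immune_cells(self) -> list[CellRecord]:
        return [c for c in self.cells if c.true_class == "immune"]


def positions_of(items: Sequence) -> np.ndarray:
    """(n, 2) float array of positions from cells/fascicles or raw pairs."""
    if isinstance(items, np.ndarray):
        arr = np.asarray(items, dtype=float)
        return arr.reshape(-1, 2)
    out = []
    for it in items:
        pos = getattr(it, "position", it)
        if isinstance(pos, Point2D):
            out.append((pos.x_um, pos.y_um))
        else:
            x, y = pos
            out.append((float(x), float(y)))
    return np.array(out, dtype=float).reshape(-1, 2)
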