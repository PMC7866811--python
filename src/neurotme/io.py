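"""Readers and writers for the pipeline's on-disk formats.

Annotations travel as RFC 7946 GeoJSON FeatureCollections (one polygon
feature per region, region class in the ``label`` property — the convention
used by digital-pathology annotation exports).  Cells and fascicles travel
as plain CSV with fixed columns:

* ``cells.csv``: cell_id,x_um,y_um,true_class,immune_subtype,nucleus_area_um2,circularity,stain_intensity
* ``fascicles.csv``: fascicle_id,x_um,y_um,diameter_um

All readers validate records against the domain-type invariants and raise
:class:`~neurotme.errors.FormatError` / ``ValidationError`` on malformed
input; valid files round-trip losslessly (coordinates to better than
1e-6 μm).
"""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    CellRecord,
    NerveFascicle,
    Point2D,
    Polygon2D,
    RegionAnnotation,
    Slide,
)
from .errors import FormatError, ValidationError

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_cells_csv",
    "write_cells_csv",
    "read_fascicles_csv",
    "write_fascicles_csv",
    "load_slide",
    "save_slide",
]

CELL_COLUMNS = [
    "cell_id", "x_um", "y_um", "true_class", "immune_subtype",
    "nucleus_area_um2", "circularity", "stain_intensity",
]
FASCICLE_COLUMNS = ["fascicle_id", "x_um", "y_um", "diameter_um"]


# ---------------------------------------------------------------------------
# GeoJSON annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | PathLike) -> list[RegionAnnotation]:
    """Read region annotations from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    annotations = []
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        label = props.get("label")
        if label is None:
            raise FormatError(f"{path}: feature {i} has no 'label' property")
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(
                f"{path}: feature {i} has geometry type "
                f"{geom.get('type')!r}; only Polygon is supported"
            )
        rings = geom.get("coordinates") or []
        if len(rings) != 1:
            raise FormatError(
                f"{path}: feature {i} has {len(rings)} rings; polygons with "
                "holes are not supported"
            )
        try:
            ann = RegionAnnotation(label=label, polygon=Polygon2D(tuple(map(tuple, rings[0]))))
        except ValidationError as exc:
            raise FormatError(f"{path}: feature {i}: {exc}") from exc
        annotations.append(ann)
    return annotations


def write_annotations(annotations: Sequence[RegionAnnotation], path: str | PathLike) -> None:
    """Write region annotations as a GeoJSON FeatureCollection."""
    features = []
    for ann in annotations:
        ring = [list(v) for v in ann.polygon.vertices]
        ring.append(ring[0])  # GeoJSON rings are explicitly closed
        features.append(
            {
                "type": "Feature",
                "properties": {"label": ann.label},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_cells_csv(path: str | PathLike) -> list[CellRecord]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    _require_columns(df, CELL_COLUMNS, path)
    return [
        CellRecord(
            cell_id=row.cell_id,
            position=Point2D(float(row.x_um), float(row.y_um)),
            true_class=str(row.true_class),
            immune_subtype=str(row.immune_subtype),
            nucleus_area_um2=float(row.nucleus_area_um2),
            circularity=float(row.circularity),
            stain_intensity=float(row.stain_intensity),
        )
        for row in df.itertuples(index=False)
    ]


def write_cells_csv(cells: Sequence[CellRecord], path: str | PathLike) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "x_um": [repr(c.position.x_um) for c in cells],
            "y_um": [repr(c.position.y_um) for c in cells],
            "true_class": [c.true_class for c in cells],
            "immune_subtype": [c.immune_subtype for c in cells],
            "nucleus_area_um2": [repr(c.nucleus_area_um2) for c in cells],
            "circularity": [repr(c.circularity) for c in cells],
            "stain_intensity": [repr(c.stain_intensity) for c in cells],
        },
        columns=CELL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_fascicles_csv(path: str | PathLike) -> list[NerveFascicle]:
    df = pd.read_csv(path, dtype={"fascicle_id": str})
    _require_columns(df, FASCICLE_COLUMNS, path)
    return [
        NerveFascicle(
            fascicle_id=row.fascicle_id,
            position=Point2D(float(row.x_um), float(row.y_um)),
            diameter_um=float(row.diameter_um),
        )
        for row in df.itertuples(index=False)
    ]


def write_fascicles_csv(fascicles: Sequence[NerveFascicle], path: str | PathLike) -> None:
    df = pd.DataFrame(
        {
            "fascicle_id": [f.fascicle_id for f in fascicles],
            "x_um": [repr(f.position.x_um) for f in fascicles],
            "y_um": [repr(f.position.y_um) for f in fascicles],
            "diameter_um": [repr(f.diameter_um) for f in fascicles],
        },
        columns=FASCICLE_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Slide directories
# ---------------------------------------------------------------------------

def load_slide(slide_dir: str | PathLike, slide_id: str | None = None) -> Slide:
    """Load a slide from a directory with annotations.geojson / cells.csv / fascicles.csv.

    ``fascicles.csv`` is optional at load time (the NFD stage then fails
    cleanly downstream); annotations and cells are required.
    """
    slide_dir = Path(slide_dir)
    ann_path = slide_dir / "annotations.geojson"
    cells_path = slide_dir / "cells.csv"
    if not ann_path.exists():
        raise FormatError(f"{slide_dir}: missing annotations.geojson")
    if not cells_path.exists():
        raise FormatError(f"{slide_dir}: missing cells.csv")
    fasc_path = slide_dir / "fascicles.csv"
    fascicles = read_fascicles_csv(fasc_path) if fasc_path.exists() else []
    return Slide(
        slide_id=slide_id or slide_dir.name,
        annotations=read_annotations(ann_path),
        cells=read_cells_csv(cells_path),
        fascicles=fascicles,
    )


def save_slide(slide: Slide, slide_dir: str | PathLike) -> None:
    slide_dir = Path(slide_dir)
    slide_dir.mkdir(parents=True, exist_ok=True)
    write_annotations(slide.annotations, slide_dir / "annotations.geojson")
    write_cells_csv(slide.cells, slide_dir / "cells.csv")
    write_fascicles_csv(slide.fascicles, slide_dir / "fascicles.csv")
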