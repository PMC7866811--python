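import numpy as np
import pytest

from neurotme.core import (
    CellRecord,
    NerveFascicle,
    Point2D,
    Polygon2D,
    RegionAnnotation,
    Slide,
)


@pytest.fixture
def unit_square():
    return Polygon2D(((0, 0), (1, 0), (1, 1), (0, 1)))


def make_cell(cid, x, y, true_class="immune", subtype=None, **features):
    if subtype is None:
        subtype = "lymphocyte" if true_class == "immune" else "none"
    return CellRecord(
        cell_id=cid, position=Point2D(x, y), true_class=true_class,
        immune_subtype=subtype, **features,
    )


def make_slide(width=5000.0, height=5000.0, cells=(), fascicles=(), glands=(),
               with_roi=True, slide_id="s1"):
    """A rectangular slide whose total tissue (and ROI) is the full extent."""
    rect = Polygon2D.rectangle(0, 0, width, height)
    annotations = [RegionAnnotation("total_tissue", rect)]
    if with_roi:
        annotations.append(RegionAnnotation("roi", rect))
    annotations += [RegionAnnotation("tumor_gland", g) for g in glands]
    return Slide(slide_id=slide_id, annotations=annotations,
                 cells=list(cells), fascicles=list(fascicles))


def make_fascicle(fid, x, y, diameter=40.0):
    return NerveFascicle(fascicle_id=fid, position=Point2D(x, y),
                         diameter_um=diameter)


def star_polygon(rng, n_vertices=12, center=(0.0, 0.0), radius=1.0):
    """A random star-shaped (hence simple) polygon."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.4, 1.0, n_vertices) * radius
    xs = center[0] + radii * np.cos(angles)
    ys = center[1] + radii * np.sin(angles)
    return Polygon2D(tuple(zip(xs, ys)))
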