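"""Synthetic slides and patient cohorts with planted ground truth.

The slide generator emulates the spatial structure the analysis assumes:

* lymphoid aggregates as a Thomas cluster process — ``k`` parent centers
  placed uniformly in the ROI subject to a minimum mutual separation, each
  with Poisson(``mean_cells_per_aggregate``) immune-cell offspring scattered
  isotropically with Gaussian sd ``cluster_sd_um``;
* a sparse homogeneous Poisson background of additional immune cells and a
  denser Poisson background of fibroblasts;
* tumor glands as non-overlapping randomly perturbed ellipses;
* nerve fascicles preferentially co-localized with aggregate edges — a
  fraction is placed uniformly inside a disc of radius ``coloc_radius_um``
  around a random aggregate center, the rest uniformly in the ROI; diameters
  are log-normal.

The cohort generator draws covariates from the configured marginals and
survival times from an exponential-baseline proportional-hazards model by
inverse-CDF sampling, with independent uniform censoring, so a correctly
specified Cox fit recovers the planted log hazard ratios.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

from .core import (
    CellRecord,
    NerveFascicle,
    Point2D,
    Polygon2D,
    RegionAnnotation,
    Slide,
)
from .errors import ConfigurationError

__all__ = [
    "SlideSimConfig",
    "SlideTruth",
    "CohortSimConfig",
    "generate_slide",
    "generate_cohort",
    "write_truth_json",
    "read_truth_json",
]


def _default_feature_params() -> dict:
    # class-conditional (mean, sd) for nucleus area / circularity / stain
    # intensity; immune nuclei are small, round and strongly stained,
    # fibroblast nuclei large, elongated and weakly stained.
    return {
        "immune": {
            "nucleus_area_um2": (25.0, 5.0),
            "circularity": (0.85, 0.05),
            "stain_intensity": (0.8, 0.1),
        },
        "fibroblast": {
            "nucleus_area_um2": (60.0, 15.0),
            "circularity": (0.45, 0.1),
            "stain_intensity": (0.3, 0.1),
        },
    }


@dataclass
class SlideSimConfig:
    """Parameters of one synthetic slide.

    Spatial intensities are per μm²; with the defaults a 5 × 5 mm ROI holds
    about 100 background immune cells, 500 fibroblasts and ``k_aggregates``
    clusters of ~150 immune cells each.
    """

    roi_width_um: float = 5000.0
    roi_height_um: float = 5000.0
    n_glands: int = 8
    gland_radius_range_um: tuple[float, float] = (150.0, 400.0)
    k_aggregates: int = 4
    cluster_sd_um: float = 50.0
    mean_cells_per_aggregate: float = 150.0
    background_immune_intensity: float = 4e-6
    fibroblast_intensity: float = 2e-5
    n_fascicles: int = 20
    fascicle_coloc_fraction: float = 0.7
    coloc_radius_um: float = 150.0
    fascicle_diameter_lognorm: tuple[float, float] = (math.log(40.0), 0.5)
    p_background_lymphocyte: float = 0.6
    min_center_sep_factor: float = 8.0
    feature_params: dict = field(default_factory=_default_feature_params)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.roi_width_um <= 0 or self.roi_height_um <= 0:
            raise ConfigurationError("ROI dimensions must be positive")
        if self.k_aggregates < 0:
            raise ConfigurationError("k_aggregates must be >= 0")
        if self.background_immune_intensity < 0 or self.fibroblast_intensity < 0:
            raise ConfigurationError("intensities must be >= 0")
        if not 0 <= self.fascicle_coloc_fraction <= 1:
            raise ConfigurationError("fascicle_coloc_fraction must be in [0, 1]")
        if self.cluster_sd_um <= 0:
            raise ConfigurationError("cluster_sd_um must be > 0")


@dataclass
class SlideTruth:
    """Planted ground truth for a synthetic slide (the acceptance oracle)."""

    aggregate_centers: list[Point2D]
    cell_parent: dict[str, int]          # cell_id -> aggregate index, -1 = background
    fascicle_coloc: dict[str, bool]      # fascicle_id -> planted near an aggregate
    true_k: int

    def __post_init__(self) -> None:
        if self.true_k != len(self.aggregate_centers):
            raise ConfigurationError("true_k must equal len(aggregate_centers)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _place_separated_centers(
    k: int, width: float, height: float, min_sep: float,
    rng: np.random.Generator, exclusion=None, exclusion_margin: float = 0.0,
) -> np.ndarray:
    """Uniform centers with pairwise separation >= min_sep (rejection sampling).

    Candidates closer than ``exclusion_margin`` to any geometry in
    ``exclusion`` are rejected: aggregates are stromal structures and are not
    planted inside tumor glands.
    """
    if k == 0:
        return np.empty((0, 2))
    # crude feasibility guard: each center excludes a disc of radius min_sep/2
    if k * math.pi * (min_sep / 2) ** 2 > 2.0 * width * height:
        raise ConfigurationError(
            f"ROI too small to place {k} aggregate centers separated by {min_sep} um"
        )
    centers: list[np.ndarray] = []
    for _ in range(20000):
        c = rng.uniform((0, 0), (width, height))
        if any(np.hypot(*(c - o)) < min_sep for o in centers):
            continue
        if exclusion is not None and any(
            g.distance(_ShapelyPoint(c)) < exclusion_margin for g in exclusion
        ):
            continue
        centers.append(c)
        if len(centers) == k:
            return np.array(centers)
    raise ConfigurationError(
        f"could not place {k} aggregate centers with separation {min_sep} um"
    )


def _perturbed_ellipse(
    center: np.ndarray, a: float, b: float, theta: float, rng: np.random.Generator,
    n_vertices: int = 24,
) -> _ShapelyPolygon:
    """A gland outline: ellipse with smooth radial perturbation."""
    phi = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    wobble = 1.0 + 0.12 * np.sin(3 * phi + rng.uniform(0, 2 * math.pi)) \
                 + 0.06 * np.sin(5 * phi + rng.uniform(0, 2 * math.pi))
    x = a * wobble * np.cos(phi)
    y = b * wobble * np.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    xr = center[0] + ct * x - st * y
    yr = center[1] + st * x + ct * y
    return _ShapelyPolygon(np.column_stack([xr, yr]))


def _place_glands(config: SlideSimConfig, rng: np.random.Generator) -> list[Polygon2D]:
    lo, hi = config.gland_radius_range_um
    glands: list[_ShapelyPolygon] = []
    w, h = config.roi_width_um, config.roi_height_um
    attempts = 0
    while len(glands) < config.n_glands and attempts < 200 * max(config.n_glands, 1):
        attempts += 1
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        margin = 1.2 * max(a, b)
        if 2 * margin >= min(w, h):
            continue
        center = rng.uniform((margin, margin), (w - margin, h - margin))
        cand = _perturbed_ellipse(center, a, b, rng.uniform(0, math.pi), rng)
        if any(cand.intersects(g) for g in glands):
            continue
        glands.append(cand)
    if len(glands) < config.n_glands:
        raise ConfigurationError(
            f"could not place {config.n_glands} non-overlapping glands in the ROI"
        )
    return [Polygon2D(tuple(g.exterior.coords)) for g in glands]


def _draw_features(
    cls: str, n: int, params: Mapping, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out = {}
    for name, (mu, sd) in params[cls].items():
        vals = rng.normal(mu, sd, n)
        if name == "nucleus_area_um2":
            vals = np.clip(vals, 1.0, None)
        elif name == "circularity":
            vals = np.clip(vals, 1e-3, 1.0)
        elif name == "stain_intensity":
            vals = np.clip(vals, 0.0, None)
        out[name] = vals
    return out


def generate_slide(config: SlideSimConfig, seed=None) -> tuple[Slide, SlideTruth]:
    """Generate one synthetic slide plus its planted ground truth."""
    rng = _rng(config.seed if seed is None else seed)
    w, h = config.roi_width_um, config.roi_height_um
    area = w * h

    glands = _place_glands(config, rng)
    min_sep = config.min_center_sep_factor * config.cluster_sd_um
    centers = _place_separated_centers(
        config.k_aggregates, w, h, min_sep, rng,
        exclusion=[g.to_shapely() for g in glands],
        exclusion_margin=2.0 * config.cluster_sd_um,
    )

    # immune cells: Poisson background + Thomas-cluster offspring
    positions: list[np.ndarray] = []
    parents: list[np.ndarray] = []
    n_bg = rng.poisson(config.background_immune_intensity * area)
    positions.append(rng.uniform((0, 0), (w, h), (n_bg, 2)))
    parents.append(np.full(n_bg, -1))
    for j, c in enumerate(centers):
        m = rng.poisson(config.mean_cells_per_aggregate)
        offs = rng.normal(c, config.cluster_sd_um, (m, 2))
        keep = (offs[:, 0] >= 0) & (offs[:, 0] <= w) & (offs[:, 1] >= 0) & (offs[:, 1] <= h)
        positions.append(offs[keep])
        parents.append(np.full(int(keep.sum()), j))
    immune_xy = np.vstack(positions)
    immune_parent = np.concatenate(parents).astype(int)

    n_fib = rng.poisson(config.fibroblast_intensity * area)
    fib_xy = rng.uniform((0, 0), (w, h), (n_fib, 2))

    # immune subtypes: aggregate members are lymphocytes; the background is a
    # lymphocyte/neutrophil mixture
    n_imm = len(immune_xy)
    subtype = np.where(
        immune_parent >= 0,
        "lymphocyte",
        np.where(rng.uniform(size=n_imm) < config.p_background_lymphocyte,
                 "lymphocyte", "neutrophil"),
    )

    imm_feats = _draw_features("immune", n_imm, config.feature_params, rng)
    fib_feats = _draw_features("fibroblast", n_fib, config.feature_params, rng)

    cells: list[CellRecord] = []
    cell_parent: dict[str, int] = {}
    for i in range(n_imm):
        cid = f"c{i:05d}"
        cells.append(
            CellRecord(
                cell_id=cid,
                position=Point2D(float(immune_xy[i, 0]), float(immune_xy[i, 1])),
                true_class="immune",
                immune_subtype=str(subtype[i]),
                nucleus_area_um2=float(imm_feats["nucleus_area_um2"][i]),
                circularity=float(imm_feats["circularity"][i]),
                stain_intensity=float(imm_feats["stain_intensity"][i]),
            )
        )
        cell_parent[cid] = int(immune_parent[i])
    for i in range(n_fib):
        cid = f"c{n_imm + i:05d}"
        cells.append(
            CellRecord(
                cell_id=cid,
                position=Point2D(float(fib_xy[i, 0]), float(fib_xy[i, 1])),
                true_class="fibroblast",
                nucleus_area_um2=float(fib_feats["nucleus_area_um2"][i]),
                circularity=float(fib_feats["circularity"][i]),
                stain_intensity=float(fib_feats["stain_intensity"][i]),
            )
        )
        cell_parent[cid] = -1

    # nerve fascicles: a planted fraction near aggregate edges, rest uniform
    n_coloc = int(round(config.fascicle_coloc_fraction * config.n_fascicles)) \
        if len(centers) else 0
    mu, sigma = config.fascicle_diameter_lognorm
    fascicles: list[NerveFascicle] = []
    fascicle_coloc: dict[str, bool] = {}
    for i in range(config.n_fascicles):
        fid = f"f{i:04d}"
        coloc = i < n_coloc
        if coloc:
            c = centers[rng.integers(len(centers))]
            r = config.coloc_radius_um * math.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * math.pi)
            pos = np.clip(c + r * np.array([math.cos(phi), math.sin(phi)]),
                          (0, 0), (w, h))
        else:
            pos = rng.uniform((0, 0), (w, h))
        fascicles.append(
            NerveFascicle(
                fascicle_id=fid,
                position=Point2D(float(pos[0]), float(pos[1])),
                diameter_um=float(rng.lognormal(mu, sigma)),
            )
        )
        fascicle_coloc[fid] = coloc

    rect = Polygon2D.rectangle(0, 0, w, h)
    annotations = [
        RegionAnnotation("total_tissue", rect),
        RegionAnnotation("roi", rect),
        *[RegionAnnotation("tumor_gland", g) for g in glands],
    ]
    slide = Slide(
        slide_id="synthetic",
        annotations=annotations,
        cells=cells,
        fascicles=fascicles,
    )
    truth = SlideTruth(
        aggregate_centers=[Point2D(float(c[0]), float(c[1])) for c in centers],
        cell_parent=cell_parent,
        fascicle_coloc=fascicle_coloc,
        true_k=len(centers),
    )
    return slide, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Marginals and planted effects of a synthetic patient cohort.

    Covariate marginals default to the study-cohort summary statistics:
    age ~ N(66, 10) years, BMI ~ N(25.7, 4.3) kg/m², 48.19% female, high
    nerve fiber density in 72/166 patients, >=5 lymphoid aggregates in
    71/166, tumor cellularity ~ N(0.36, 0.20) truncated to [0, 1].
    Covariates are drawn independently (only marginals are known).

    ``true_log_hr`` maps column names to planted log hazard ratios; a key
    ``"a:b"`` denotes the product of columns ``a`` and ``b``.  The derived
    column ``nfd_low = 1 - nfd_high`` is always available so effects can be
    planted in either direction.  ``fixed_binary_counts`` pins the exact
    number of ones of a binary column (shuffled positions) instead of
    Bernoulli sampling.
    """

    n_patients: int = 166
    age_dist: tuple[float, float] = (66.0, 10.0)
    bmi_dist: tuple[float, float] = (25.7, 4.3)
    p_female: float = 0.4819
    p_nfd_high: float = 72 / 166
    p_la_ge5: float = 71 / 166
    tc_dist: tuple[float, float] = (0.36, 0.20)
    true_log_hr: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = math.log(2) / 20.0   # events per month; median OS 20 months
    censor_max: float = 64.0                    # months of administrative follow-up
    fixed_binary_counts: dict[str, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, p in (("p_female", self.p_female), ("p_nfd_high", self.p_nfd_high),
                        ("p_la_ge5", self.p_la_ge5)):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be > 0")
        if self.censor_max < 0:
            raise ConfigurationError("censor_max must be >= 0")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")


def _binary(
    name: str, p: float, n: int, rng: np.random.Generator,
    fixed: dict[str, int] | None,
) -> np.ndarray:
    if fixed and name in fixed:
        k = int(fixed[name])
        if not 0 <= k <= n:
            raise ConfigurationError(f"fixed count for {name} out of range")
        vals = np.zeros(n, dtype=int)
        vals[:k] = 1
        rng.shuffle(vals)
        return vals
    return rng.binomial(1, p, n)


def linear_predictor(table: pd.DataFrame, log_hr: Mapping[str, float]) -> np.ndarray:
    """βᵀx per patient; ``"a:b"`` keys are products of columns a and b."""
    eta = np.zeros(len(table))
    for key, beta in log_hr.items():
        if ":" in key:
            a, b = key.split(":")
            eta += beta * table[a].to_numpy() * table[b].to_numpy()
        else:
            eta += beta * table[key].to_numpy()
    return eta


def generate_cohort(config: CohortSimConfig, seed=None) -> pd.DataFrame:
    """Simulate a patient table under an exponential-baseline Cox model.

    Survival time per patient: T = −log(U) / (baseline_rate · exp(βᵀx)),
    U ~ Uniform(0, 1); censoring C ~ Uniform(0, censor_max); observed time
    min(T, C) and event = [T <= C].
    """
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_patients
    a, b = (0.0 - config.tc_dist[0]) / config.tc_dist[1], \
           (1.0 - config.tc_dist[0]) / config.tc_dist[1]
    table = pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(n)],
            "age": rng.normal(*config.age_dist, n),
            "gender01": _binary("gender01", config.p_female, n, rng,
                                config.fixed_binary_counts),
            "bmi": rng.normal(*config.bmi_dist, n),
            "nfd_high": _binary("nfd_high", config.p_nfd_high, n, rng,
                                config.fixed_binary_counts),
            "la_ge5": _binary("la_ge5", config.p_la_ge5, n, rng,
                              config.fixed_binary_counts),
            "tc": stats.truncnorm.rvs(a, b, loc=config.tc_dist[0],
                                      scale=config.tc_dist[1], size=n,
                                      random_state=rng),
        }
    )
    table["nfd_low"] = 1 - table["nfd_high"]

    eta = linear_predictor(table, config.true_log_hr)
    u = rng.uniform(size=n)
    t_event = -np.log(u) / (config.baseline_rate * np.exp(eta))
    if config.censor_max > 0:
        c = rng.uniform(0, config.censor_max, n)
    else:
        c = np.full(n, np.finfo(float).tiny)
    table["time"] = np.minimum(t_event, c)
    table["event"] = (t_event <= c).astype(int)
    # guard the time > 0 invariant (U == 1.0 cannot occur with default_rng's
    # half-open uniform, but censor_max -> 0 yields times at the float floor)
    table["time"] = np.maximum(table["time"], np.finfo(float).tiny)
    return table


# ---------------------------------------------------------------------------
# Truth sidecar JSON
# ---------------------------------------------------------------------------

def write_truth_json(truth: SlideTruth, path: str | PathLike) -> None:
    doc = {
        "aggregate_centers": [[p.x_um, p.y_um] for p in truth.aggregate_centers],
        "cell_parent": truth.cell_parent,
        "fascicle_coloc": truth.fascicle_coloc,
        "true_k": truth.true_k,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_truth_json(path: str | PathLike) -> SlideTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return SlideTruth(
        aggregate_centers=[Point2D(x, y) for x, y in doc["aggregate_centers"]],
        cell_parent={k: int(v) for k, v in doc["cell_parent"].items()},
        fascicle_coloc={k: bool(v) for k, v in doc["fascicle_coloc"].items()},
        true_k=int(doc["true_k"]),
    )
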