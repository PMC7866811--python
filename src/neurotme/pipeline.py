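"""End-to-end orchestration: per-slide analysis, cohort modelling and
simulate-and-recover harnesses.

``run_slide`` chains classification → gland distances → density estimation →
aggregate detection → nerve fiber density → tumor cellularity → dominant
immunophenotype for one slide, recording per-stage errors instead of
crashing (a report with errors is marked partial).  ``run_cohort`` joins
per-slide measures to clinical records and runs the survival protocol.
``simulate_and_recover`` wraps generator → analysis → truth comparison over
replicates.

All randomness flows from a single seed, split deterministically per slide
or replicate with ``numpy.random.SeedSequence`` so any single unit can be
regenerated in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import spatial, survival
from .core import Slide
from .errors import JoinError, NeurotmeError
from .io import load_slide
from .scores import (
    FieldGridConfig,
    dominant_immunophenotype,
    score_nfd,
    tumor_cellularity,
)
from .synth import CohortSimConfig, SlideSimConfig, generate_cohort, generate_slide

__all__ = [
    "DetectorParams",
    "PipelineConfig",
    "SlideReport",
    "run_slide",
    "slide_reports_to_frame",
    "run_cohort",
    "simulate_and_recover",
]

log = logging.getLogger("neurotme")


@dataclass(frozen=True)
class DetectorParams:
    rel_threshold: float = 0.25
    min_member_cells: int = 20
    connectivity: int = 4
    bandwidth_um: float | None = spatial.DEFAULT_DETECTION_BANDWIDTH_UM


@dataclass
class PipelineConfig:
    field_grid: FieldGridConfig = field(default_factory=FieldGridConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    distance_bin_um: float = 50.0
    classifier_model_path: str | None = None
    seed: int = 0


@dataclass
class SlideReport:
    """Per-slide summary row; ``errors`` maps failed stage name to message."""

    slide_id: str
    nfd_count: int | None = None
    nfd_category: str | None = None
    nfd_high: bool | None = None
    tc: float | None = None
    phenotype: str | None = None
    la_count: int | None = None
    la_ge5: bool | None = None
    mean_distance_um: float | None = None
    n_cells_classified: int | None = None
    n_immune_predicted: int | None = None
    classifier_accuracy: float | None = None
    errors: dict = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.errors)


def run_slide(slide: Slide | str | PathLike, config: PipelineConfig | None = None) -> SlideReport:
    """Run the full per-slide analysis; stage failures are recorded, not raised."""
    config = config or PipelineConfig()
    if not isinstance(slide, Slide):
        slide = load_slide(slide)
    report = SlideReport(slide_id=slide.slide_id)
    log.info("slide %s: %d cells, %d fascicles, %d annotations",
             slide.slide_id, len(slide.cells), len(slide.fascicles),
             len(slide.annotations))

    roi_ann = slide.roi() or slide.total_tissue()
    roi = roi_ann.polygon
    glands = slide.gland_polygons()

    # -- classification ----------------------------------------------------
    immune_pred = []
    try:
        if config.classifier_model_path:
            model = clf.ClassifierModel.from_json(config.classifier_model_path)
        else:
            # emulate interactive training: fit on the slide's curated labels
            model = clf.train(clf.TrainingSet.from_cells(slide.cells))
        predicted = clf.predict(model, slide.cells, roi, glands)
        report.n_cells_classified = len(predicted)
        by_id = {c.cell_id: c for c in slide.cells}
        immune_pred = [
            by_id[cid]
            for cid, lab in zip(predicted["cell_id"], predicted["predicted_class"])
            if lab == "immune"
        ]
        report.n_immune_predicted = len(immune_pred)
        if any(c.true_class in ("immune", "fibroblast") for c in slide.cells):
            report.classifier_accuracy = clf.evaluate(predicted, slide.cells).accuracy
    except NeurotmeError as exc:
        report.errors["classify"] = str(exc)
        immune_pred = slide.immune_cells()

    # -- distances to tumor glands -----------------------------------------
    try:
        if immune_pred:
            dres = spatial.distance_to_glands(immune_pred, glands,
                                              bin_width_um=config.distance_bin_um)
            report.mean_distance_um = dres.mean_um
    except NeurotmeError as exc:
        report.errors["distances"] = str(exc)

    # -- density + aggregates ----------------------------------------------
    try:
        det = config.detector
        aggs, _ = spatial.count_lymphoid_aggregates(
            immune_pred, roi.bounds,
            bandwidth_um=det.bandwidth_um,
            rel_threshold=det.rel_threshold,
            min_member_cells=det.min_member_cells,
            connectivity=det.connectivity,
        )
        report.la_count = aggs.la_count
        report.la_ge5 = spatial.la_dichotomize(aggs.la_count) == "ge5"
    except NeurotmeError as exc:
        report.errors["aggregates"] = str(exc)

    # -- nerve fiber density ------------------------------------------------
    try:
        if not slide.fascicles:
            raise NeurotmeError("no fascicle records on slide")
        nfd = score_nfd(slide, config.field_grid)
        report.nfd_count = nfd.fascicle_count
        report.nfd_category = nfd.category
        report.nfd_high = nfd.binary_high
    except NeurotmeError as exc:
        report.errors["nfd"] = str(exc)

    # -- tumor cellularity ---------------------------------------------------
    try:
        report.tc = tumor_cellularity(slide.annotations).tc
    except NeurotmeError as exc:
        report.errors["cellularity"] = str(exc)

    # -- immunophenotype -----------------------------------------------------
    try:
        report.phenotype = dominant_immunophenotype(immune_pred).category
    except NeurotmeError as exc:
        report.errors["phenotype"] = str(exc)

    if report.errors:
        log.warning("slide %s: partial report, failed stages %s",
                    slide.slide_id, sorted(report.errors))
    return report


def slide_reports_to_frame(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "slide_id": r.slide_id, "nfd_count": r.nfd_count,
                "nfd_category": r.nfd_category, "nfd_high": r.nfd_high,
                "tc": r.tc, "phenotype": r.phenotype, "la_count": r.la_count,
                "la_ge5": r.la_ge5, "mean_distance_um": r.mean_distance_um,
                "n_immune_predicted": r.n_immune_predicted,
                "classifier_accuracy": r.classifier_accuracy,
                "partial": r.partial,
                "errors": ";".join(sorted(r.errors)) if r.errors else "",
            }
        )
    return pd.DataFrame(rows)


DEFAULT_CANDIDATES = ("nfd_low", "la_ge5", "tc")


def run_cohort(
    slide_reports: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | PathLike | None = None,
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
) -> dict:
    """Join slide measures to clinical data and run the survival protocol.

    ``slide_reports`` must have one row per slide_id; ``clinical`` must carry
    ``patient_id`` matching slide ids plus age, gender01, bmi, time, event.
    Returns a dict with the screen table, selection result, interaction
    model and Kaplan–Meier output; writes CSV/JSON/PNG artifacts when
    ``out_dir`` is given.
    """
    config = config or PipelineConfig()
    missing = set(clinical["patient_id"]) - set(slide_reports["slide_id"])
    extra = set(slide_reports["slide_id"]) - set(clinical["patient_id"])
    if missing or extra:
        raise JoinError(
            f"unmatched ids: {sorted(missing)[:5]} lack slides, "
            f"{sorted(extra)[:5]} lack clinical rows"
        )
    # slide-derived measures win over any same-named clinical columns
    slide_cols = set(slide_reports.columns) - {"slide_id"}
    clin = clinical.drop(columns=[c for c in clinical.columns
                                  if c in slide_cols or c == "nfd_low"])
    merged = clin.merge(
        slide_reports, left_on="patient_id", right_on="slide_id", how="inner"
    )
    table = merged.copy()
    table["nfd_high"] = table["nfd_high"].astype(float)
    table["nfd_low"] = 1.0 - table["nfd_high"]
    table["la_ge5"] = table["la_ge5"].astype(float)

    errors: dict[str, str] = {}
    screen = survival.univariate_screen(table, [c for c in candidates
                                                if c in table.columns])
    selection = None
    try:
        inter_terms = survival.pairwise_interaction_screen(table, screen.relevant)
        if screen.relevant:
            spec = survival.ModelSpec(tuple(screen.relevant) + tuple(inter_terms))
            selection = survival.backward_select(table, spec)
    except NeurotmeError as exc:
        errors["selection"] = str(exc)
    inter = None
    try:
        inter = survival.interaction_model(table)
    except NeurotmeError as exc:
        errors["interaction"] = str(exc)
    km = None
    try:
        table["km_group"] = np.where(table["la_ge5"] > 0, "LA>=5", "LA<5") + \
            np.where(table["nfd_high"] > 0, ", NFD high", ", NFD low")
        km = survival.km_curves(table, "km_group")
    except NeurotmeError as exc:
        errors["km"] = str(exc)
    if errors:
        log.warning("cohort analysis: failed stages %s", sorted(errors))

    out = {
        "table": table,
        "screen": screen,
        "selection": selection,
        "interaction": inter,
        "km": km,
        "errors": errors,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        screen.table.to_csv(out_dir / "table1.csv", index=False)
        if selection is not None:
            selection.final.summary.to_csv(out_dir / "final_model.csv")
        if inter is not None:
            with open(out_dir / "interaction_model.json", "w") as fh:
                json.dump(
                    {
                        "la_tc_dropped": inter.la_tc_dropped,
                        "la_nfd_p": inter.la_nfd_p,
                        "terms": {
                            t: {"hr": inter.cox.hr(t), "p": inter.cox.p(t)}
                            for t in inter.cox.terms
                        },
                        "subgroups": inter.subgroups.to_dict(orient="records"),
                        "note": "proportional-hazards diagnostics are not run "
                                "here; check the PH assumption externally "
                                "before reporting",
                    },
                    fh, indent=2,
                )
        if km is not None:
            km.plot(out_dir / "km_groups.png")
    return out


def simulate_and_recover(
    slide_config: SlideSimConfig | None = None,
    cohort_config: CohortSimConfig | None = None,
    n_slides: int = 20,
    n_replicates: int = 20,
    seed: int = 0,
    pipeline_config: PipelineConfig | None = None,
) -> dict:
    """Generate → analyze → compare-to-truth over replicates.

    Reports aggregate-count recovery (exact rate, MAE), classifier accuracy
    over slides, and bias/RMSE of the cohort hazard-ratio estimates under
    the planted ``true_log_hr``.
    """
    slide_config = slide_config or SlideSimConfig()
    cohort_config = cohort_config or CohortSimConfig()
    pipeline_config = pipeline_config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    slide_seeds, cohort_seeds = ss.spawn(2)

    la_exact, la_err, accs = [], [], []
    for child in slide_seeds.spawn(n_slides):
        rng = np.random.default_rng(child)
        k = int(rng.integers(0, 9))
        slide, truth = generate_slide(replace(slide_config, k_aggregates=k), rng)
        report = run_slide(slide, pipeline_config)
        la_exact.append(report.la_count == truth.true_k)
        la_err.append(abs((report.la_count or 0) - truth.true_k))
        if report.classifier_accuracy is not None:
            accs.append(report.classifier_accuracy)

    betas = {k: [] for k in cohort_config.true_log_hr}
    fit_terms = tuple(survival.ALWAYS_KEEP) + tuple(
        t for t in cohort_config.true_log_hr if t not in survival.ALWAYS_KEEP
    )
    for child in cohort_seeds.spawn(n_replicates):
        cohort = generate_cohort(cohort_config, np.random.default_rng(child))
        try:
            res = survival.fit_cox(cohort, fit_terms)
        except NeurotmeError:
            continue
        for term in betas:
            betas[term].append(res.coef(term))
    hr_recovery = {}
    for term, vals in betas.items():
        vals = np.array(vals)
        true_beta = cohort_config.true_log_hr[term]
        hr_recovery[term] = {
            "true_hr": float(np.exp(true_beta)),
            "mean_hr": float(np.exp(vals.mean())) if len(vals) else None,
            "bias_log": float(vals.mean() - true_beta) if len(vals) else None,
            "rmse_log": float(np.sqrt(((vals - true_beta) ** 2).mean()))
            if len(vals) else None,
            "n_fits": int(len(vals)),
        }
    return {
        "n_slides": n_slides,
        "la_exact_rate": float(np.mean(la_exact)) if la_exact else None,
        "la_mae": float(np.mean(la_err)) if la_err else None,
        "classifier_accuracy_mean": float(np.mean(accs)) if accs else None,
        "n_replicates": n_replicates,
        "hr_recovery": hr_recovery,
    }
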