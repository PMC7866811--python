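# neurotme

Spatial tumor-microenvironment analysis for pancreatic ductal
adenocarcinoma (PDAC): nerve fiber density, lymphoid aggregate counting
from immune-cell point patterns, tumor cellularity, and Cox survival
modelling of how these measures relate to overall mortality.

## The problem

The desmoplastic stroma of PDAC hosts fibroblasts, immune cells and —
less studied — small nerve fibers, which co-localize with lymphoid
aggregates (candidate tertiary lymphoid structures).  Quantifying this
spatial organization from annotated whole-slide data requires a chain of
reproducible steps that is usually performed semi-manually: counting small
nerve fascicles, measuring tumor vs stroma areas, classifying stromal
cells, estimating immune-cell density surfaces, counting aggregates and
feeding the per-patient measures into survival models.  `neurotme`
implements that chain as a library + CLI for analysts working from
annotation exports (GeoJSON polygons, cell/fascicle CSV tables), plus a
synthetic tissue and cohort generator so every stage can be verified
against planted ground truth.

## Core quantities

* **Nerve fiber density (NFD)** — the number of nerve fascicles with
  diameter < 100 μm in 20 contiguous ×200 fields (modelled as 1.1 mm
  square tiles; the maximum-count window is reported).  Binned
  negative (0) / weak (1–10) / high (>10).
* **Tumor cellularity (TC)** — with per-label annotation areas,
  `stroma = total − (normal + atrophic + tumor)` and
  `TC = tumor / (tumor + stroma)`.
* **Lymphoid aggregate (LA) count** — a Gaussian kernel density estimate
  of immune-cell centroids on a 100 × 100 grid,
  f̂(g) = (1/n) Σᵢ K_h(g − xᵢ), is thresholded at a fraction of its
  maximum; connected components holding at least 20 immune cells are
  counted as aggregates, and the count is dichotomized at ≥5.
* **Survival models** — Cox proportional hazards h(t|x) = h₀(t) exp(βᵀx)
  with Efron ties and Wald inference: univariate screening adjusted for
  age/gender/BMI, pairwise interaction checks, backward selection
  (removal at p ≥ 0.05, hierarchy enforced), and an exploratory
  {LA, NFD, TC, LA×NFD} model with delta-method within-stratum hazard
  ratios.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Generate a synthetic slide with five planted lymphoid aggregates and run
the full per-slide analysis:

```python
from neurotme import SlideSimConfig, generate_slide
from neurotme.pipeline import run_slide

slide, truth = generate_slide(SlideSimConfig(k_aggregates=5), seed=7)
report = run_slide(slide)
print(truth.true_k, report.la_count, report.la_ge5)
print(report.nfd_count, report.nfd_category)
print(round(report.tc, 3), report.phenotype)
print(round(report.mean_distance_um, 1), report.classifier_accuracy)
```

prints

```
5 5 True
19 high
0.087 lymphocyte_predominant
880.7 1.0
```

reading: all 5 planted aggregates were recovered (`la_ge5 = True` is the
covariate used in survival models); the hotspot window holds 19 small
fascicles, i.e. high NFD; tumor cellularity of this synthetic slide is
0.087 with a lymphocyte-predominant immune infiltrate; the mean predicted-
immune-cell distance to the nearest tumor gland is 880.7 μm, and the
nearest-centroid classifier reproduced every planted cell label.

The same pipeline runs from the shell on slide directories
(`annotations.geojson`, `cells.csv`, `fascicles.csv`):

```bash
neurotme simulate --out cohort/ --n-slides 20 --seed 1
neurotme run-slide --slide cohort/p0000 --out report.csv
neurotme run-cohort --slides cohort/ --clinical cohort/clinical.csv --out results/
```

`run-cohort` writes `slide_reports.csv`, the screening table
(`table1.csv`), the interaction model (`interaction_model.json`) and
Kaplan–Meier curves per LA/NFD subgroup.

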