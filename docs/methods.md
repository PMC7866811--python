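# Methods

`neurotme` re-implements, as a tested and reusable pipeline, a spatial
analysis of the pancreatic-cancer tumor microenvironment: scoring nerve
fiber density and tumor cellularity per slide, classifying stromal cells
into immune cells and fibroblasts, measuring immune-cell distances to tumor
glands, counting lymphoid aggregates from a kernel density estimate of
immune-cell centroids, and relating these measures to overall survival with
Cox proportional-hazards models.  Because the original patient data are not
public, the package ships a synthetic tissue/cohort generator with fully
recorded ground truth, and every stage is validated against that truth or
against independent numerical oracles.

## Coordinate and data model

All coordinates are physical micrometres in the slide-scanner image
convention (origin top-left, y down).  A slide consists of region
annotations (simple polygon rings labelled `total_tissue`,
`normal_pancreas`, `atrophic_pancreas`, `normal_duodenum`, `tumor_gland`,
`roi`), cell centroids with three morphometric features (nucleus area μm²,
circularity in (0, 1], stain intensity ≥ 0), and nerve fascicle positions
with diameters.  Annotations travel as GeoJSON FeatureCollections with the
region class in a `label` property; cells and fascicles as fixed-column CSV.
Polygons with holes are out of scope.

## Per-slide scores

**Nerve fiber density (NFD).**  The score counts nerve fascicles with
diameter *strictly* below 100 μm (large trunks, which are the ones subject
to perineural invasion, are excluded by size) over 20 contiguous microscope
fields at ×200 magnification.  Two formalization choices were open and are
resolved as follows:

* a ×200 field is modelled as a 1100 μm square — the field-of-view diameter
  of a standard 20× objective (field number 22 mm / 20) is ≈1.1 mm;
* "20 continuous fields" is a contiguous 20-tile window over the ROI
  bounding-box tile grid, and the *maximum-count* (hotspot) window is
  reported, because a hotspot convention is deterministic and reproducible
  where a pathologist's choice of fields is not.  The default window is a
  run in row-major raster order; a rectangular-block window (all factor
  pairs of `n_fields`) is available via `FieldGridConfig(window_mode="block")`.
  Ties between windows break to the first in raster order.  Grids smaller
  than 20 tiles use the single all-tile window.

Counts are binned negative (0), weak (1–10), high (>10); `binary_high`
(high vs not) is the covariate used downstream.

**Tumor cellularity (TC).**  From summed annotation areas:
`stroma = total − (normal + atrophic + tumor)` and
`tc = tumor / (tumor + stroma)`.  Component areas exceeding the total (up
to a 1e-6 relative tolerance for shared boundaries) raise an error, as does
a zero denominator.

**Dominant immunophenotype.**  Lymphocyte- vs neutrophil-predominant by
subtype counts; zero immune cells is its own category; exact ties go to
lymphocyte-predominant (documented arbitrary convention).

## Cell classifier

The interactively trained cell classifier of the original workflow is
formalized as a nearest-centroid model in z-scored feature space (scales =
pooled within-class standard deviations).  It is deterministic, serializes
to JSON, and is restricted to the ROI excluding tumor-gland interiors —
tumor cells never enter classification because glands are
annotation-defined.  Degenerate features (zero pooled spread) are dropped
with a warning; if all are degenerate, unit scales keep the model defined.
Distance ties classify as immune.  No accuracy figure is inherited from the
original workflow (none was reported); the classifier is validated by
recovery of planted synthetic labels (≥99% when class means are ≥3 pooled
sd apart) and by chance-level behaviour on indistinguishable classes.

## Spatial statistics

**Distances.**  Per-cell distance to the nearest tumor gland is 0 inside a
gland, else the minimum Euclidean distance to any gland boundary (the
digital-pathology convention).  Verified to 0.1 μm against a brute-force
oracle that samples boundaries at 0.05 μm steps.

**Density field.**  An axis-aligned Gaussian KDE evaluated at the centers
of a 100 × 100 grid over the ROI bounding box,
f̂(g) = (1/n) Σᵢ K_h(g − xᵢ), with per-axis bandwidth h = sd · n^(−1/6)
(Scott's rule in two dimensions) by default.  The implementation is
separable; tests compare every grid value against a non-factorized
double-sum evaluation at 1e-8.  Fewer than two points, or zero spread in an
axis when the bandwidth must be estimated, is a degenerate-input error (the
detection wrapper maps it to a count of zero).

**Aggregate detection.**  The grid is binarized at
`rel_threshold × max(grid)` (default 0.25), connected components are
labelled (4-connectivity by default, to avoid diagonal bridging), each
immune cell is assigned to the component whose region contains it, and
components with ≥ `min_member_cells` (default 20) assigned cells are kept.
The number of kept components is the lymphoid-aggregate count, dichotomized
at ≥5 for survival modelling.  This threshold-and-count rule is a declared
proxy for the manual reading of dark/light-blue heat-map clusters; all
three parameters are configuration, and no claim is made that it replicates
a pathologist's eye.

**Detection bandwidth.**  Scott's rule is the right default for
*visualizing* a slide-wide density (and matches the default of the KDE
implementation the original workflow used), but it is a global-smoothness
rule: at slide scale it yields bandwidths of several hundred μm, which
fuses any aggregates closer than ~2 mm into one component.  In a
measurement on 100 synthetic slides with 0–8 planted aggregates, detection
on the Scott-bandwidth field recovered the exact count in 20% of slides,
versus 100% with a fixed 75 μm bandwidth (≈1.5× the within-aggregate
scatter of 50 μm).  The default detection pathway
(`count_lymphoid_aggregates`, and the pipeline) therefore uses a fixed
75 μm bandwidth; `estimate_density` itself keeps Scott's rule, and both
accept overrides.

## Synthetic data

**Slides.**  Immune cells are a superposition of a homogeneous Poisson
background and a Thomas cluster process: `k` aggregate centers placed
uniformly with minimum mutual separation 8 × cluster sd (so "aggregate" is
well defined; configurable), each with Poisson(150) offspring scattered
isotropically with sd 50 μm.  Offspring falling outside the ROI are
discarded (slight edge thinning).  Centers are also kept ≥2 × cluster sd
away from tumor glands: aggregates are stromal structures, and this keeps
the end-to-end pathway (which classifies stromal cells only) consistent
with the planted truth.  Fibroblasts are homogeneous Poisson.  Tumor glands
are non-overlapping randomly perturbed ellipses (radii 150–400 μm).  A
configurable fraction (default 0.7) of nerve fascicles is placed within
150 μm of an aggregate center — emulating the observed co-localization of
small nerve fibers with lymphoid aggregates — and the rest uniformly;
diameters are log-normal (median 40 μm, log-sd 0.5), so a small fraction
exceeds the 100 μm counting cut-off, as in real tissue.

Defaults: 5 × 5 mm ROI, background immune intensity 4 × 10⁻⁶ /μm² (~100
cells), fibroblast intensity 2 × 10⁻⁵ /μm² (~500 cells).  No spatial
intensities were reported for the original cohort; these values are chosen
for a sparse stromal background in which an aggregate of ~150 cells is a
conspicuous object, and are documented here rather than claimed as measured
values.  With ≥~500 background cells under the default relative-threshold
detector, background density fluctuations begin to percolate into spurious
≥20-cell components on aggregate-free slides, so the sparse default is also
the regime in which the count "0 aggregates" is well defined.  Class-
conditional feature distributions (immune: small round strongly stained
nuclei; fibroblast: large elongated weakly stained) are ~3 pooled sd apart,
the regime the classifier is validated in.

What the generator does *not* emulate: nucleus textures and images,
anisotropic or curved aggregates (TLS are often ovoid with substructure),
within-slide intensity gradients, gland-adjacent immune gradients, and any
correlation between NFD, aggregate count and cellularity at the patient
level.  Passing tests therefore demonstrate correctness of the algorithms
under the stated point-process model, not performance on real tissue.

**Cohorts.**  Covariate marginals default to the study cohort's summary
statistics: age ~ N(66, 10) years, BMI ~ N(25.7, 4.3) kg/m², 48.19% female
(`gender01` = 1 for female), high NFD with probability 72/166, ≥5 lymphoid
aggregates with probability 71/166, tumor cellularity ~ N(0.36, 0.20)
truncated to [0, 1].  Covariates are independent — only marginals are
known, and no correlation structure is invented silently (planted effects,
including `"a:b"` product terms, are explicit configuration).  Survival
times are inverse-CDF draws from an exponential baseline under proportional
hazards, T = −log U / (λ₀ exp(βᵀx)), the simplest model satisfying the Cox
assumption exactly; the baseline rate λ₀ = log 2 / 20 per month gives a
20-month median survival typical of resected pancreatic cancer, and
independent Uniform(0, 64 months) censoring yields ≈40% censoring under
null effects, a plausible follow-up pattern for such a cohort.
`fixed_binary_counts` pins exact arm sizes for two-arm designs.

## Survival analysis

Cox partial-likelihood fitting, Kaplan–Meier estimation and the log-rank
test are delegated to `lifelines`; this package owns the protocol.  Efron's
approximation is used for tied event times (less biased than Breslow under
the heavy ties of month-resolution follow-up; simulated times here are
continuous, so ties are absent in tests).  Inference is Wald throughout:
HR = exp(β̂), 95% limits exp(β̂ ± 1.96 se), two-sided normal p-values.
Degenerate designs (constant or collinear columns, zero events) are
rejected before fitting.

The protocol: (1) univariate screening of each candidate adjusted for age,
gender and BMI, relevant if p < 0.05; (2) pairwise interaction checks among
relevant variables at the 5% level; (3) backward selection at removal
threshold p ≥ 0.05 with the adjusters never removable and the hierarchy
principle enforced (a main effect cannot leave while its interaction
remains — the hierarchy rule is this package's explicit choice); (4) the
exploratory aggregate-burden model {LA≥5, NFD-high, TC, LA×NFD, LA×TC}, in
which LA×TC is dropped and the model refitted when its p ≥ 0.05, and
within-stratum NFD hazard ratios are reported as exp(β_nfd + β_int) (LA≥5)
and exp(β_nfd) (LA<5) with delta-method intervals from the coefficient
covariance.  A hand-computed Cox score test at β = 0 provides the
cross-check that the log-rank test equals the score test on tie-free data.
Proportional-hazards diagnostics are out of scope; the interaction-model
output carries a note recommending an external PH check.

## Parameter-recovery summaries

Recovery studies (`neurotme.recovery`, `scripts/acceptance.py`) summarize
the recovered hazard ratio as the exponentiated mean log-HR across
replicates (the geometric mean).  HR estimates are approximately
log-normal; the arithmetic mean of exp(β̂) converges to exp(β + SE²/2) and
systematically overstates effects at small n (at n = 166 with a
unit-variance-0.04 continuous covariate the inflation is ~13%), whereas the
geometric mean is consistent.  All recovery targets use 500 replicates at
the original sample sizes (n = 166 cohorts; n = 71 with a fixed 36/35 split
for the stratum analysis).

## Numerical choices and degenerate inputs

* Polygon simplicity is checked via geometric validity; rings given closed
  are stored open.  Areas are orientation-independent.
* Cells exactly on a region boundary count as inside (covering semantics).
* The fascicle diameter cut-off is strict (< 100 μm); a fascicle of exactly
  100 μm is never counted.
* Empty slides: zero immune cells yield aggregate count 0 and the
  "no immune cells" phenotype rather than errors; the per-slide driver
  records stage failures (e.g. missing fascicle data) in a partial report
  instead of aborting, and the cohort driver does the same for analysis
  stages that a degenerate small cohort makes unfittable.
* All randomness derives from one seed via `numpy.random.SeedSequence`
  spawning, so each slide/replicate is independently regenerable and full
  runs are byte-reproducible.

## Problem sizes in the test suite

Test problem sizes are chosen so the full suite runs in minutes on one
core while keeping Monte-Carlo error well inside asserted bands: recovery
criteria use the 500-replicate / 200-slide designs stated above; module
tests use 20–200 replicates at n = 300–1000 with assertion bands at ≥3–4
Monte-Carlo standard errors; oracle comparisons (KDE double-sum, boundary
sampling, Monte-Carlo area) use 50 point sets, 10,000 cell/gland pairs and
10⁶ samples respectively.

## Known limitations

* The aggregate detector is a declared proxy for a manual reading; its
  parameters were not calibrated against pathologist counts.
* Scott's-rule visualization and fixed-bandwidth detection answer different
  questions; heat maps and counts are therefore not derived from the same
  field unless a bandwidth is forced.
* The synthetic cohort cannot validate the proportional-hazards *checking*
  step (out of scope) nor any claim about real-tissue classifier accuracy.
* Field-grid NFD assumes the ROI bounding box is tissue; very non-convex
  ROIs will include empty tiles in candidate windows (counts are unaffected
  since empty tiles contribute zero, but window placement may be).
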