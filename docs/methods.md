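# Methods

This note records the quantitative definitions, the statistical model, the
default parameters and the numerical choices behind `petdmax`, together
with known limitations.

## 1. Image model and units

A volume is a 3-D array of body-weight SUV values on a regular grid with
per-axis spacing in mm (`SUVVolume`). SUV is dimensionless:
`SUV = activity[kBq/mL] × body_weight[g] / injected_dose[kBq]`, computed by
`activity_to_suv` only for decay-corrected activity. Axis 2 is axial by
default; the axial axis is configurable per volume. Volumes are in mL
(voxel count × spacing product / 1000), TLG in g (MTV × SUVmean with
dimensionless SUV), distances in cm (mm / 10).

## 2. Segmentation

Lesions are connected components of `{v : SUV(v) > T}` with **strict**
inequality and an absolute threshold `T = 2.5` by default. Connectivity is
6, 18 or 26 (default 26, i.e. faces, edges and corners). A component is a
lesion only if its occupied axial slices contain a run of at least
`min_axial_slices = 2` **contiguous** slices; this suppresses single-slice
noise specks while keeping any sphere of radius ≥ 6 mm at ≤ 4 mm axial
spacing. Exclusion masks (same grid shape) remove physiologic uptake
before thresholding. Labels are assigned in decreasing component size,
ties broken by the lexicographically smallest voxel index, so labelling is
fully deterministic.

## 3. Features

Per lesion, statistics are computed over exactly the component's voxels:
SUVmax, SUVmean, MTV, TLG. The *targeted* lesion is the one with the
highest SUVmax (ties: larger MTV, then smaller label). Patient-level
MTV_TOT and TLG_WB are plain sums, hence exactly additive under any
repartition of the voxels.

**Dmax** is the maximum over all lesion pairs of the Euclidean distance
between lesions, reported in cm with the realizing pair and its site
combination (`primary-node`, `node-distant`, …, sorted alphabetically by
class rank primary < node < distant). Two modes:

- `centroid` (default): distance between unweighted voxel-centroid
  physical coordinates; matches the common definition in dissemination
  studies and is translation-invariant and spacing-equivariant.
- `voxel_extremes`: largest voxel-to-voxel distance over the pair
  (computed with `scipy.spatial.distance.cdist`); always ≥ the centroid
  value.

Ties between pairs are broken toward the smallest label pair. Dmax is
undefined (raises) for fewer than 2 lesions; such patients are ineligible
downstream.

## 4. Survival statistics

### Cox proportional hazards

The partial likelihood is maximized by damped Newton iterations
(analytic gradient and Hessian, step-halving, tolerance 1e-9, at most 60
iterations). Tied event times use the **Efron** correction by default,
with **Breslow** available via the `ties` option. Risk-set sums are
reverse cumulative sums after sorting by time; a fully vectorized path is
used when all event times are distinct. The linear predictor is shifted
by its maximum before exponentiation (the shift cancels in the
likelihood), so overflow cannot occur for bounded coefficients.

Monotone likelihood (separation) is detected and raised as a named
`SeparationError`: divergence of ‖β‖ during iteration, or a flat /
non-finite likelihood when probing at 2β after convergence to a large β.
Singular information matrices raise the same error naming the collinear
covariates. Reported per variable: coefficient, SE from the inverse
observed information, Wald χ² and p; per model: log-likelihood and the
likelihood-ratio χ² against the null. The implementation is
cross-checked in the tests against explicit risk-set enumeration (small
n) and against lifelines' `CoxPHFitter` (coefficients to ~1e-6).

### Model selection

`cox_stepwise` is forward selection by smallest likelihood-ratio p-value
with `p_enter = 0.05`, followed after each inclusion by backward checks
removing any retained variable whose LR p rises above
`p_remove = 0.10`. Visited variable sets are tracked to guarantee
termination; the inclusion/removal history is reported.

### Cutoffs, Kaplan–Meier, log-rank

`roc_best_cutoff` scans the midpoints of consecutive distinct marker
values, maximizing Youden's J = sensitivity + specificity − 1 with
sensitivity = P(marker > c | event) and specificity =
P(marker ≤ c | no event); exact ties in J keep the **lower** cutoff.
Kaplan–Meier curves and the k-group log-rank χ² (df = k − 1) are
delegated to lifelines and verified against hand-enumerated product-limit
and O−E/V formulas in the tests. The three-group analysis crosses
dichotomized Dmax and MTV_TOT into `both_low` / `one_high` / `both_high`,
with values **equal to the cutoff counted as below** it.

### Workflow

The univariate roster is fixed at 13 variables: age, gender, histology
(adenocarcinoma vs other), stage (ordinal by default, binary option),
SUVmax / SUVmean / MTV / TLG of the primary, SUVmax / SUVmean of the
targeted lesion, Dmax, MTV_TOT, TLG_WB. Multivariate candidates are the
variables with univariate LR p < 0.10, plus age always. Retained
continuous variables get ROC cutoffs and dichotomized KM comparisons; the
three-group Dmax × MTV_TOT analysis is always attempted. Reports are
deterministic JSON (sorted keys), with KM step coordinates exportable to
CSV.

## 5. Synthetic cohort generator

Each phantom is a truncated-normal background (mean 0.8, SD 0.2, clipped
at 0 — ~8.5 SD below the threshold, so the background never segments) with
uniform-plateau spherical lesions: one primary plus Poisson(2.2) nodal
lesions near the primary (within 90 mm) and Poisson(2.4) distant lesions,
at least one extra lesion forced so every patient is Dmax-eligible, at
most 12 lesions. Radii are uniform on 6–20 mm, plateau SUV uniform on
4–15 (validated ≥ threshold + margin). Centers are drawn with minimum
separation `2·r_max + voxel diagonal` so distinct truth lesions can never
merge; placement retries are bounded (200 attempts) and failure raises a
"grid too small" error rather than silently degrading. An optional
`coalescent_pair` mode deliberately overlaps two nodal balls, recorded as
**one** truth lesion so truth and segmentation stay comparable. Truth
lesions are stored in exactly the segmentation's label order.

Outcomes follow an exponential proportional-hazards model: hazard
`λ = λ0 · exp(β_dmax · Dmax_cm + β_logmtv · log MTV_TOT)` with defaults
`λ0 = 7e-4` per month, `β_dmax = 0.1` per cm, `β_logmtv = 0.3`;
progression uses a 1.5× hazard multiplier with PFS ≤ OS enforced, and
administrative censoring at 43 months. All randomness flows through
`numpy.random.SeedSequence`, so cohorts are byte-reproducible.

`sample_feature_table` additionally draws purely tabular cohorts —
log-normal Dmax (mean ≈ 30 cm, SD ≈ 21) and MTV_TOT (mean ≈ 156 mL,
SD ≈ 177) matched to advanced-NSCLC study scale, plus noise marker
columns — so that replicated Cox simulations (e.g. 200 × n = 500) are
feasible without rasterizing images.

## 6. Verification strategy

Every algorithmic path has an independent brute-force oracle in the test
suite: BFS flood fill for components, all-pairs scans for Dmax,
closed-form MTV/TLG identities, explicit risk-set enumeration and 1-D
bounded optimization for Cox, hand product-limit and log-rank formulas,
and an exhaustive Youden scan. Calibration is checked statistically:
Wald type-I error at nominal 5% (1000 replicates within binomial bounds),
and median relative bias of both generator effects below 5% at
n = 500 × 200 replicates. End-to-end, noiseless phantoms reproduce
MTV_TOT exactly and Dmax to well within half a voxel diagonal, and
same-seed pipelines produce byte-identical reports.

Problem sizes in the acceptance run (20 phantoms, 50 replicates of
n = 300) are the package's own choice, sized to finish in well under a
minute while exercising every stage; the test suite re-checks the
statistical claims at larger scale.

## 7. Limitations

- Lesions are uniform-plateau spheres: no partial-volume blur, respiratory
  motion, heterogeneous uptake or irregular shapes, so segmentation
  recovery is easier than on clinical data. The generator validates
  realism of scale, not of texture.
- The absolute SUV 2.5 threshold is the classical choice but is scanner-
  and reconstruction-dependent in practice; no adaptive or gradient-based
  segmentation is provided.
- The survival generator is exponential (constant baseline hazard) with
  purely administrative censoring; real cohorts have non-proportional
  and time-varying effects the workflow does not model.
- Stepwise selection is implemented as specified, but its p-values are
  conditional on selection and should be read descriptively.
- Anatomic lesion classes (primary / node / distant) must be supplied by
  the caller; the package does not localize anatomy.
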