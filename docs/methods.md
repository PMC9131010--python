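# Methods

This note records the models, default parameters, numerical choices and
known limitations behind `streetstress`, in the order the pipeline runs.

## Synthetic study conditions

The package is exercised end to end on synthetic data whose structure
mirrors what the analysis assumes about real streetscapes.

**Scene compositions.** A scene archetype (residential, commercial, park,
arterial) is a vector of 19 positive Dirichlet concentrations over the
Cityscapes training classes plus a void concentration; a scene is one draw
from that Dirichlet, so coverage fractions are non-negative and sum (with
void) to exactly one. The Dirichlet is the simplest parametric family on
the simplex consistent with coverage-fraction semantics. By default,
archetypes are assigned to sample points in contiguous spatial bands, so
scene type itself — not only the residual — carries spatial structure, as
in a real city.

**Latent stress field.** Scores are

    score_i = clip(b0 + β · composition_i + u_i, 0, 100),
    u = (I − ρW)⁻¹ ε,  ε ~ N(0, σ²),

a simultaneous-autoregressive (SAR) residual on the row-standardized
spatial weights. ρ (default 0.7) tunes the strength of spatial clustering;
σ (`noise_sd`, default 5 score points) sets the unexplained variation.
ρ = 0 reduces u to white noise and σ = 0 gives the deterministic linear
limit, which the tests exploit. Clipping to the bounded 0–100 scoring
instrument is applied last. The ground-truth coefficients default to walls
+80 and buildings +60 (stressors) and sky −40, vegetation −30, road −25,
terrain/grass −20, sidewalk −15, car/auto −10 (relievers), with intercept
55: signs chosen so that sign-recovery tests are meaningful, magnitudes so
that composition differences move scores across several stress levels.

**Raters.** A rater scores a composition as
`clip(intercept + coefficients · fractions + N(0, noise_sd), 0, 100)`,
consuming a per-rater seeded noise stream so sessions replay exactly.
`RaterProfile.population` draws a panel around the shared ground truth
(10% proportional jitter on coefficients, ±5-point intercept offsets),
emulating subjective variation around a common perception. Inter-rater
variance for this instrument is not characterized anywhere we know of;
noise_sd = 5 (5% of scale) is a package default, not a calibrated value.

**Label rasters.** A composition is realized as an integer raster by
largest-remainder apportionment over the 19 classes plus void (ties broken
by class id), so every class count is within one pixel of exact; the
rendering seed shuffles pixel placement only. This is the inverse of
fraction extraction and exists for round-trip testing.

What the generator does *not* emulate: perspective and occlusion in real
imagery, segmentation errors, rater fatigue or display-timing effects, and
availability gaps in image coverage. Passing tests therefore demonstrate
the correctness and calibration of the analysis machinery under the assumed
data-generating process, not the field validity of stress measurement.

## Sampling geometry

Points are placed at arc lengths 0, s, 2s, … strictly less than each
segment's length (half-open spacing, default s = 50 m). The far endpoint is
never emitted, avoiding doubled points at shared junctions. View requests
are the Cartesian product of points and headings with defaults 0/90/180/270°,
fov 90°, pitch 6°, 640 px. District assignment takes the first polygon
(in input order) that covers the point, boundary included — a deterministic
tie-break for shared edges; all coordinates must be projected planar meters
(the Manhattan metric downstream presumes planar axes).

## Scene composition

Coverage fractions are exact integer pixel counts divided by raster size.
The four per-point views are combined by the unweighted mean of per-view
fractions, which equals the fraction computed on a stitched panorama when
views have equal pixel counts (they do: 640×640 each). Survey vocabulary is
reconciled to Cityscapes once: "grass" → terrain, "auto" → car. Element
summaries use the population SD (a descriptive statistic over the full
image set) and rank elements by descending mean with ties broken by class
id.

## Adversarial scoring

The forest is a bagged ensemble of CART regression trees (scikit-learn
trees; the bootstrap, OOB bookkeeping and importance are authored here so
that per-tree in-bag multisets are first-class). Defaults: 500 trees,
mtry = 6 ≈ p/3 of the 19 features, minimum leaf 2, unlimited depth — the
standard regression-forest regime. The default bootstrap draws n samples
with replacement (≈63.2% unique in bag, the remaining third out of bag),
matching the folklore "two-thirds in, one-third out" description; an exact
two-thirds subsampling mode is provided for comparison.

The permutation importance follows the agreement-indicator form: per tree,
the count of OOB predictions agreeing with the observed score minus the
same count after permuting one feature's column within the OOB set, divided
by N_OOB and averaged over trees. Because predictions are continuous, the
equality indicator is realized as agreement within `agreement_tol` (default
5 score points — half the intervention threshold); a conventional
MSE-increase importance is provided as a cross-check. Trees with an empty
OOB set are skipped and reported.

The loop: each rater scores `n_init = 50` warm-up images presented in a
seeded shuffled order; the model then predicts every subsequent image while
the rater continues scoring. The consecutive-error counter increments when
|prediction − subjective| > 10 and resets to zero on any non-exceedance (a
strict reading of "in a row"); at six it triggers an intervention. During
an intervention the model retrains on *all* subjective scores accumulated
so far — cumulative, not a sliding window — and keeps refitting on
subsequent images until the error falls back under the threshold. Refit
seeds are keyed to the presentation index, so a refit at position k is
reproducible regardless of the path that led there. Final scores are the
last model's predictions for all images; consensus is the weighted mean
across raters (uniform by default — no principled weighting is available).

Holdout evaluation splits round(0.667·n) samples into training by a seeded
permutation and reports held-out MAE (in score units and as % of the
100-point scale), RMSE, and the training fit's OOB error and RMSE.

## Spatial statistics

Weights are a fixed-distance band under the Manhattan metric: w = 1 within
the threshold *inclusive*, 0 outside; inclusivity makes the automatic
threshold — the largest nearest-neighbor distance, i.e. the smallest band
granting every point at least one neighbor — exact. Row standardization
divides each row by its sum; S0 is recorded post-standardization (= n with
no isolates). The binary neighbor relation is kept alongside the
standardized weights for histograms and symmetry checks. An explicit
threshold that isolates some points warns and flags them; isolating all
points is an error.

Global Moran's I uses the cross-product form with E(I) = −1/(n−1). VAR(I)
defaults to the randomization-assumption closed form (the default of the
desktop GIS tools typically used for this analysis), with the
normality-assumption form and a permutation null selectable; p-values are
two-sided. LISA significance uses conditional permutation: the value at i
stays fixed, its neighbors' values are drawn from the remaining n−1
observations; the two-sided pseudo p is (#{|I_i*| ≥ |I_i|} + 1)/(n_perm+1)
with 999 permutations by default. One block of permutation index rows is
generated and shared across points — the standard vectorization strategy —
and is validated in the tests against an exhaustive n = 6 conditional
enumeration. Quadrants come from the signs of the standardized value and
its lag (HH, LL, HL, LH) and are reported only at p < α (default 0.05).
The algebraic identities Σ I_i = S0·I and Moran-scatter slope = I are
tested to 1e−9, and both statistics are tested against naive double-loop
oracles to 1e−10.

## Stress mapping

Natural breaks use the exact Fisher–Jenks dynamic program (O(k·n²)),
run on distinct values weighted by multiplicity so equal values are never
split; determinism and oracle-checkability motivated choosing the exact DP
over the heuristic reallocation variant. A value belongs to the first class
whose upper bound covers it; values outside the fitted envelope clamp to
the end classes with a warning, so classification is total. Tiers group
levels 2-2-2 into Low/Medium/High when k = 6 (1-1-1 when k = 3, which is
also how district means are banded into three colors).

Hexagonal aggregation uses pointy-top hexagons in axial coordinates,
anchored at the data bounding-box minimum corner, nearest-center
assignment, and boundary ties resolved to the lexicographically smaller
(q, r). The hexagon radius has no canonical value and is a required
parameter of the mapping stage.

## Regression

OLS of consensus stress on the eight highest-coverage elements (road, sky,
building, vegetation, sidewalk, car, wall, terrain by default) via
statsmodels, with an explicit rank check that names collinear columns.
Standardized betas are coefficient × SD(x)/SD(y); VIFs come from the
auxiliary-regression definition 1/(1 − R²_j); per-coefficient two-sided
t-tests are reported without multiple-testing correction, mirroring the
conventional reporting style for this analysis. The Durbin–Watson statistic
requires a case ordering, which no convention fixes for spatial points; the
default is ascending point id (acquisition order), configurable. Note that
compositional predictors are intrinsically correlated (fractions compete
for the same pixels), so VIFs well above 1 are expected on synthetic data.

## Pipeline and problem sizes

The orchestrated run derives per-stage seeds from one global seed by stable
hashing of stage names, writes every artifact as a new file, and records a
manifest (versions, seeds, row counts, SHA-256 checksums); identical config
and seed reproduce identical checksums. Default problem sizes — a ~2 km²
network yielding a few hundred points, 2 simulated raters, 150-tree
forests, 199 LISA permutations — complete in seconds while leaving every
statistic well inside its asymptotic regime; the test suite and the
acceptance script use 100–2000-point lattices and 20-replicate designs for
the same reason.

## Known limitations

* The adversarial loop assumes the rater scores every presented image;
  protocols where raters only spot-check after warm-up would need a
  different exceedance detector.
* SAR fields are generated by a dense/sparse LU solve of (I − ρW); for
  n ≫ 10⁴ a sparse iterative solver would be needed.
* The LISA permutation block is shared across points; per-point independent
  draws would remove a negligible correlation between neighbors' pseudo
  p-values at the cost of vectorization.
* Geary's C, Getis–Ord G, kernel or k-nearest weights, spherical distances,
  and geographically weighted regression are out of scope.
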