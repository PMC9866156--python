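# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the known limitations of `nichekit`.

## The study system the synthetic module emulates

The package targets the standard invasion-biology workflow: occurrence
records of a species in its native and invaded ranges, a stack of
co-registered environmental rasters (bioclimatic variables, altitude, a
human-influence layer) under a near-current climate and several future
scenarios, an ensemble of correlative SDMs fitted to presences plus
pseudo-absences, and a niche comparison between ranges in a reduced
environmental space.

Because real occurrence databases and climate downloads are external,
the `synth` module builds a controlled stand-in:

- **Landscapes** are stacks of spatially autocorrelated fields: seeded
  white noise smoothed with a Gaussian kernel (sigma = `autocorr_range`
  cells) and re-standardized to mean 0, sd 1. This is deliberately the
  simplest generator with tunable spatial structure — not a variogram
  simulator. Every generator is a pure function of its seed.
- **The virtual species** has per-variable Gaussian responses
  `exp(-(x - opt)^2 / (2 b^2))` combined by a cellwise product. The
  default species has two driving variables (optimum 0, breadth 0.25 sd)
  and two flat-response nuisance variables. Breadth 0.25 encodes a
  climatic specialist — suitability ≥ 0.5 on only a few percent of the
  landscape — which is the regime where presence–background modelling is
  informative; with breadth ~1 the presence and background score
  distributions overlap so heavily that no model family can discriminate
  (the attainable AUC is ~0.67), which would make every benchmark
  meaningless rather than hard.
- **Occurrences** are cell draws proportional to suitability, placed at
  cell centers (within-cell jitter is opt-in) so that thinning behavior
  is exactly testable.
- **Range pairs** are two disjoint 100×100 landscapes; invasive
  occurrences come from a species whose optima are shifted by a known
  `niche_offset`. Offset 0 is the null case of a perfectly conserved
  niche. The default range-pair species carries the two driving
  variables only: niche comparison operates on predictors that passed
  collinearity filtering and genuinely structure the distribution.
  With independent, standardized layers, including flat-response layers
  in the PCA dilutes the niche signal geometrically (the offset projects
  at ~0.7 of its length while the occurrence cloud inflates toward the
  availability spread), and overlap statistics lose sensitivity; a
  species with nuisance variables can still be passed explicitly.
- **Futures** are parametric perturbations of the baseline stack
  (additive/multiplicative shifts per layer); non-climate layers are
  held constant across scenarios. The projection code path only needs a
  second co-registered stack.

What the generator does **not** emulate: sampling bias, coordinate
error, spatial aggregation of records beyond cell duplication, dispersal
limitation, biotic interactions, and correlated layer structure like
real bioclim variables. Passing tests therefore demonstrate that the
estimators recover known truth under clean sampling — not that any real
dataset satisfies these assumptions.

## Preparation

Cleaning removes exact duplicate coordinates and any record matching a
user-supplied exclusion list (e.g. administrative centroids; no default
list is shipped because such lists are dataset-specific). Thinning keeps
the first record per grid cell, with the cell size a parameter
defaulting to the analysis grid's own cell size. Pseudo-absences are
drawn uniformly without replacement from valid cells that contain no
presence; one draw is shared by all replicates (per-replicate redraw is
available). The collinearity filter is a greedy scan in a user-supplied
priority order (default: column order): a variable is retained iff its
absolute Pearson correlation with every already-retained variable is at
most the threshold (default 0.8). The greedy rule yields a certificate:
every dropped variable correlates above the threshold with some retained
one.

## Model families and defaults

All families share `fit(spec, matrix) -> model` and
`predict(model, features) -> scores in [0, 1]`:

| family | implementation | fixed defaults |
|---|---|---|
| GLM | binomial logistic on linear + quadratic terms | unpenalized, standardized inputs |
| CTA | single classification tree | min leaf 5 |
| RF | random forest | 500 trees |
| GBM | stagewise boosted trees | 2500 trees, depth 3, shrinkage 0.01, early stopping (10-round patience on a 10% internal holdout) |
| ANN | one-hidden-layer perceptron | 5 hidden units; weight decay chosen on an internal 3-fold CV over {1e-3, 1e-1}; 300-iteration budget |
| FDA | linear discriminant on a hinge-basis expansion | hinge knots at the 25/50/75% quantiles per variable |
| MAXENT | penalized presence–background logistic (IWLR form) | linear + quadratic + hinge features, L2 penalty C=1, background weight 100 |
| SRE | per-variable percentile envelope on presences | 2.5–97.5% |

These are fixed, documented defaults; the contract is the interface and
the invariants (scores bounded, determinism given seed, holdout skill on
the virtual species), not bit-compatibility with any R toolchain. The
replicate design fits every family on each of `reps` stratified
train/test splits (default 10 splits at 75/25, presences and
pseudo-absences split together); a family failing on a fold is recorded
as a failed evaluation, never silently dropped.

## Evaluation and ensemble

AUC is the Mann–Whitney statistic (ties count one half). TSS is
maximized over candidate thresholds = distinct observed scores plus
+inf, with "positive iff score ≥ t"; ties in the maximum break toward
the smallest threshold — the largest predicted suitable area, which is
the conservative choice for invasion early warning.

The top k = 3 families by mean (AUC + TSS)/2 (ties: TSS, then name) form
the ensemble. All replicate models of the selected families are combined
by an unweighted mean of continuous scores (TSS-weighted mean behind a
flag); rounding to the integer 0–1000 scale happens once, at ensemble
output. The binarization cutoff is the max-TSS threshold of the pooled
holdout predictions of the per-fold committees, reused unchanged for all
scenario projections; it must fall below the fixed 400/600 class bounds
for the four-class scheme to be well formed, and is clipped into
(0, 400) defensively.

Permutation variable importance is `1 - Pearson r` between ensemble
predictions on the data and on the data with one column permuted,
averaged over `n_perm` permutations, clamped to [0, 1]; a
constant-prediction ensemble yields zero importance everywhere with a
warning. Response curves use the evaluation-strip convention (vary one
variable over a grid, hold the others at their background mean); the
suitable range of a variable is the union of maximal grid intervals
where the curve reaches the 0.6 level.

## Geography

Cell areas are exact spherical: `R^2 * dlambda * (sin(top) - sin(bottom))`
with R = 6371.0 km. Class areas sum to the total valid-cell area to
1e-9 relative; gain − loss equals the suitable-area difference between
scenarios exactly, because both sides are sums of the same per-cell
areas. Centroids are area-weighted means of suitable cell centers
(unweighted and suitability-weighted variants available); longitudes are
averaged arithmetically and a suitable region straddling the
antimeridian is rejected rather than silently averaged. Shifts are
haversine distances with initial bearings.

## Niche dynamics

PCA-env: variables are centered and scaled on the pooled background of
both ranges, the two leading principal axes are fitted on that pooled
background, and all four point sets (two backgrounds, two occurrence
sets) are projected. The niche grid is 100×100 cells spanning the pooled
background scores.

Occupancy: Gaussian KDE with a diagonal bandwidth (Silverman's rule per
axis, per point set; the axis-aligned kernel makes grid evaluation
separable and fast). The availability-corrected occupancy is z ∝ o/e.
Two symmetric quantile cuts stabilize the ratio: the background support
is the set of cells where e reaches the 5th percentile of the density
observed *at the background points themselves*, and the occurrence
density is zeroed below the 5th percentile of its value at the
occurrence points. Without these cuts the division amplifies kernel
tails over empty environment by orders of magnitude (a cell with
e ~ 1e-13 of peak and o ~ 1e-9 of peak dominates the normalized grid)
and the overlap statistic collapses. z is normalized to sum 1.

Overlap is Schoener's D = 1 − ½ Σ|z₁ − z₂|. The analog environment is
the set of cells with background support in both ranges; occupancies are
renormalized inside it. Expansion E = invasive mass on analog cells with
zero native occupancy; stability S = 1 − E identically; unfilling U =
native mass on analog cells with zero invasive occupancy.

The equivalency test pools both occurrence score sets, re-splits them at
random into the original sample sizes, and recomputes D against the
fixed backgrounds; the reported p is lower-tail
`(count(null D <= observed) + 1) / (reps + 1)` — rejecting means the two
niches overlap less than exchangeable samples of one niche would, i.e.
conservatism is violated. The upper tail is also returned. The
similarity test translates the test range's occurrences rigidly so their
centroid lands on a uniformly drawn background-support cell and uses the
upper tail: small p means the observed overlap exceeds what random
placement within the available environment produces. Both tests use the
+1 correction, so no p-value is ever exactly 0.

Calibration caveat: the equivalency null assumes the two ranges'
occurrence scores are exchangeable, which holds only insofar as the two
backgrounds offer similar environments. At the default range size
(100×100 cells, smoothing sigma 2) the offset-0 p-values are uniform; on
substantially smaller ranges (e.g. 60×60) the availability clouds differ
enough that the test becomes anti-conservative — a known property of
this classical test, worth remembering when ranges are small or
environmentally dissimilar.

Predicted-niche-occupancy (PNO) profiles are histograms of one
environmental variable weighted by suitability or occupancy mass,
normalized to sum 1, computed per range for overlay comparison.

## Pipeline and reproducibility

`run_pipeline` executes the stages in workflow order and writes every
table (CSV), map (plain-text grid) and the manifest (JSON) into one run
directory. One master seed drives everything; each stochastic stage
derives its sub-seed as `sha256(master:stage:index) mod 2^31`, so runs
are replicable across machines. Re-running with the same config and seed
reproduces all numeric outputs exactly.

Raster I/O uses one ESRI ASCII grid per layer plus a JSON manifest
(layer names, geotransform, nodata, scenario tag). The format is plain
text, diffable, and readable by standard GIS tools.

## Problem sizes used by the test suite and acceptance script

Default experiment sizes are chosen to estimate each property stably:
60×60 modelling landscapes with 500 presences and 1000 pseudo-absences
for the replicate design; 100×100 range pairs with 300 occurrences per
range for niche dynamics; 99 permutation reps per test; 20 seeds for
recovery experiments and 50 seeds for null calibration. These are the
package's own validation settings, kept at the smallest sizes at which
the measured quantities are stable across seeds.

## Known limitations

- The eight families use fixed documented defaults; no hyperparameter
  search beyond the small internal CVs stated.
- Niche dynamics are restricted to two PCA dimensions, as in the
  classical framework.
- Geographic support is limited to regular lon/lat grids on WGS84; no
  projected CRS.
- The equivalency test inherits the classical sensitivity to
  availability differences (above).
- MaxEnt is the penalized IWLR logistic approximation with linear,
  quadratic and hinge features; it is not feature-for-feature identical
  to the Java implementation.
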