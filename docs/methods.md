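# Methods

This note documents the models and procedures implemented in `sdmpipe`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the package's numerical conventions.

## Grid model and conventions

All rasters are single-band `Grid`s on a shared north-up metric
`GridGeometry`: row 0 is the northernmost row, the origin is the top-left
*corner*, and a point $(x, y)$ maps to
$\mathrm{col} = \lfloor (x - x_0)/c \rfloor$,
$\mathrm{row} = \lfloor (y_0 - y)/c \rfloor$ with half-open cells, so a
point on a shared edge belongs to exactly one cell. Every grid carries a
nodata mask; masked cells are excluded from every statistic, fit and
sampling step, and a `PredictorStack` unifies the masks of its bands so a
cell is usable in all predictors or in none. Water enters only through
this mask.

GeoTIFF I/O writes plain TIFFs with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) and the band names in a
JSON image description; values are stored as float64 with masked cells
set to the nodata sentinel, so `read(write(x)) == x` exactly.

Numerical conventions, chosen where the procedure is conventionally
ambiguous:

* **Median over time** (climate composites): even counts use the mean of
  the central pair; a cell is masked only if masked in every input.
* **Bilinear resampling** of coarse climate grids interpolates between
  the four surrounding coarse *cell centers*; within the outer half-cell
  ring this degenerates to edge extrapolation. If any of the four support
  cells is masked the target cell is masked — no values are fabricated
  next to water. Bilinear interpolation is exact on affine surfaces
  (tested to 1e-9).
* **Vegetation indices**: cells with a zero denominator are masked, not
  clipped, so no infinities reach the classifier. CCCI is implemented as
  NDRE/NDVI (the canopy-chlorophyll definition). TVI defaults to
  $\sqrt{\mathrm{NDVI} + 0.5}$, the standard form; the plain additive
  variant is available via `IndexSpec(tvi_form="additive")` because both
  readings occur in the applied literature. Negative radicands are
  masked.
* **Road rasterisation** tests the cell *center* against the buffered
  polylines (Euclidean point-to-segment distance ≤ buffer), consistent
  with the point-to-cell convention; the default buffer is 50 m per side
  at 30 m cells.
* **Backscatter** is converted as $10\log_{10}(x)$; non-positive cells
  (physically impossible power) are masked with a warning.

## Thinning

Field presence records cluster heavily (several GPS fixes per patch), so
occurrences are thinned to one randomly selected record per cell. The
choice within a multiply-occupied cell is uniform and seeded; thinning is
idempotent and the output size always equals the number of distinct
occupied cells.

## Pseudo-absence generation by environmental profiling

With presence-only data the absences must be manufactured, and *where*
they are placed determines what the classifier learns. The two-step
profiling implemented here: presence cells are removed, then the
standardized environmental space (z-scores per band over land cells,
population SD; constant bands dropped) is clustered with k-means
(Euclidean metric, k-means++ seeding, five restarts, best
within-cluster sum of squares). Cells belonging to clusters that contain
no presence are taken to be environmentally distinct from occupied
habitat and form the eligible pool. If every cluster is occupied the
rule falls back to clusters whose presence density is below the global
average, with a warning — but that fallback signals a profiling failure
more than a usable profile (see next paragraph). Sampling is
block-balanced: each spatial block receives as many pseudo-absences as
it has presences, drawn uniformly without replacement from the eligible
cells of that block; eligible cells rarely lie in presence-bearing
blocks, so the documented global-pool fallback is the common path, and
the global balance (as many 0s as 1s) always holds.

**Choice of k.** The cluster count is the resolution of the
environmental profile and the default is k = 150 (clamped to one tenth
of the number of land cells on small landscapes). The profile only works
if presence-free clusters exist: with a few hundred presences and a
coarse partition (k ≈ 10) every cluster is occupied, the density
fallback engages, and pseudo-absences degenerate into near-background
samples. Because presences are a graded draw from the suitability
surface, scoring presences against background has a low discrimination
ceiling regardless of the classifier (on the default synthetic scenario
the AUC of the *true* suitability against such pseudo-absences is about
0.59). At k = 150 — roughly one cluster per three presences — unoccupied
clusters reliably exist and are genuinely unsuitable (mean true
suitability of eligible cells ≈ 0.08), restoring the intended contrast.
Users with much larger or smaller presence sets should scale k
accordingly (k of order presences/3).

## Ensemble model

Blocks are square tiles of 10×10 cells (300 m) by default, large enough
to exceed the autocorrelation range of the synthetic predictors while
leaving hundreds of blocks; ids are row-major and edge blocks truncated.
Each of the ten iterations:

1. draws its own block-balanced pseudo-absences (iteration seed
   = master seed + iteration index),
2. randomly assigns the data-bearing blocks 70/30 to train/validation
   (share rounded over blocks; redrawn with an incremented seed, at most
   100 times, until both partitions contain a presence-bearing block),
3. fits a random forest (scikit-learn, 500 trees, seeded) on the training
   rows — one row per point carrying all band values,
4. predicts the full probability surface and a binary surface
   (threshold 0.5, the canonical cut for balanced classes),
5. is evaluated on its validation rows.

Aggregation over iterations: the HSI map is the per-cell mean
probability, its uncertainty the per-cell *population* SD (the ten runs
are the whole ensemble, not a sample); the binary map is a majority vote
where a cell is suitable only if strictly more than half of the unmasked
votes are 1 — an even 5–5 split conservatively yields absence; impurity
importances are normalized to 100% per iteration and averaged, so the
mean relative contributions also sum to 100. A 3.5% contribution
threshold selects the "impactful" predictor subset for reduced reruns.
All seeds derive from the master seed, so a rerun with the same
configuration reproduces every probability raster bit-for-bit.

## Validation metrics

Implemented natively so the conventions are explicit: AUC_ROC uses the
rank (Mann–Whitney) formulation with midrank ties — the probability that
a random presence outscores a random pseudo-absence; AUC_PR is average
precision, the step-wise sum $\sum_i (R_i - R_{i-1}) P_i$ over unique
score thresholds, with no trapezoidal interpolation (the trapezoid on PR
is biased); sensitivity and specificity come from the thresholded binary
predictions. Cross-iteration summaries report the mean and population
SD. Evaluation always uses the validation partition of each iteration,
scoring that iteration's held-out presences against its own held-out
pseudo-absences.

## Change analysis

Change maps difference the *continuous* HSI surfaces (masks unioned);
the binary majority maps feed only the area accounting, which converts
suitable cell counts to km², takes first differences between consecutive
years, and expresses each year as a percentage of a configured total
area, with headline figures rounded to the nearest whole percent. The
package ships the published annual suitable-area series for Akagera
National Park (1,122 km² total) as reference input; feeding it through
the accounting reproduces the published change column and a maximum
annual share of 32.52% → 33% in 2023.

## Synthetic landscapes

`synth_landscape` emulates the statistical structure the pipeline
assumes of satellite-derived inputs: continuous predictors are Gaussian
random fields (white noise smoothed with a Gaussian kernel, then
standardized; correlation length 8 cells by default, chosen to be of the
same order as the block size so spatial leakage is a real hazard the
block CV must handle); land cover is an auxiliary smooth field cut into
six equal-quantile classes and one-hot expanded; 5% of the map is water;
a piecewise-linear road with a spur crosses the extent and is rasterised
with the 50 m buffer. The true suitability is
$\sigma(\beta_0 + \sum_j \beta_j z_j + \beta_r \cdot \mathrm{road})$
with defaults $\beta = (1.5, -1.0, 0.8)$ on three of twenty continuous
bands, $\beta_r = 1$, and $\beta_0 = -1$ (mean suitability ≈ 0.35, so
both suitable and unsuitable habitat are plentiful). Presences (default
400) are drawn without replacement with probability ∝ suitability ×
(1 + 5·road), mimicking road-bound field access, and jittered within
their cell.

What the generator does *not* emulate: radiometrically realistic
reflectance or backscatter, inter-band correlation structure of real
sensors, temporal weather dynamics, non-stationary niches, and
observation error in the GPS positions. Passing the recovery benchmark
therefore demonstrates that the pipeline's statistics work as designed
under its own assumptions — not that a particular real-world map is
correct.

## Benchmark problem sizes

The reference benchmark (`sdmpipe.experiments.recovery_replicate`, used
by `scripts/acceptance.py` and the acceptance tests) runs the default
200×200-cell scenario: ten replicates with consecutive seeds, each a
full pipeline run (ensemble of ten 500-tree forests). On this scenario
the mean spatial-block validation AUC_ROC is ≈ 0.94–0.95 and the four
true drivers rank in the top five of mean importance in ≈ 9–10 of 10
replicates; a replicate takes ~30 s on one CPU. Unit and property tests
use smaller landscapes (40–60 cells a side, reduced forests) chosen to
exercise the same code paths quickly.

## Known limitations

* Profiled pseudo-absences make the classification task partly
  self-referential: the model learns the contrast the profiling created.
  Validation AUC should be read as ranking quality against that
  contrast, not against true absences.
* The density fallback (all clusters occupied) yields weak profiles;
  the package warns but proceeds.
* Block balance is aspirational under profiling (eligible cells avoid
  presence blocks); only global balance is guaranteed.
* GeoTIFFs are written in a local metric CRS without an EPSG code;
  reprojection between CRSs is out of scope.
* Importances are impurity-based and inherit their known bias toward
  high-cardinality continuous features; the binary road band's
  contribution is if anything understated.
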