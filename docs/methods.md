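# Methods

This note documents the model, its parameters, the synthetic-data
generator's assumptions, and the numerical and design choices made where
the design was genuinely open.

## Model and assumptions

The composite AGNPS risk score is a linear two-level weighted sum of twelve
dimensionless indicators (see README for the equations). The model is
purely multiplicative-free: no interactions between indicators, risk
contributions add. Its key assumptions are

- **Reference-value normalization.** Every raw layer is meaningful only
  relative to a reference `E_i` (a policy standard, a safe-usage level, or
  a long-term regional mean). `C = E` always maps to index 1.0, the
  boundary between low and medium risk being ≪ that (grade cut 0.7 on the
  weighted composite, not per index).
- **Uniform spatialization of county statistics.** County totals
  (fertilizer, pesticide) are dispersed evenly over the county's farmland
  cells; intensive county statistics (water quality, runoff modulus,
  densities, livestock ratios) are painted uniformly over the county or a
  land-use mask. No within-county gradient is modelled, so all
  within-county spatial structure in the result comes from the terrain,
  distance and land-use indicators.
- **Strict missing data.** A cell lacking any indicator is nodata in the
  composite. Renormalizing the remaining weights would silently change the
  model, so it is never done.

## Indicators: parameters, units, defaults

| id | raw quantity (units) | reference | direction |
|----|---------------------|-----------|-----------|
| I1 | fertilizer intensity (kg/ha farmland) | 250 | positive |
| I2 | pesticide intensity (kg/ha farmland) | 2.5 | positive |
| I3 | livestock: Nemerow of 3 ratios (–) | already scaled | positive |
| I4 | rainfall erosivity R (J·cm/(ha·h)) | 100 | positive |
| I5 | 7×7 relief amplitude of DEM (m) | 50 | positive |
| I6 | soil erodibility K by land-use class | 0.25 (config) | positive |
| I7 | farmland slope (degrees) | 15 | positive |
| I8 | distance to water (m) | 1500 | negative |
| I9 | water quality: Nemerow of COD/NH₃-N/TP C/S indices | already scaled | positive |
| I10 | runoff generation modulus | 61.95 | negative |
| I11 | river density / 0.404 (km/km²) and lake density / 0.025 (km²/km²), averaged | 1 | negative |
| I12 | paddy share of farmland (–) | 0.3339 | negative |

Decisions taken where the published description leaves the operation open:

- **Cap.** All normalized indices are capped at 10. Negative-direction
  indices diverge as `C → 0` (a cell on a river bank has distance 0);
  the cap keeps composites finite while lying safely above the
  extremely-high-risk cut of 5.0, so capping can never demote a grade.
  The equivalent raw-value clamp is `C ≥ E/10`.
- **I5 statistic.** The 7×7 neighborhood statistic over the DEM is taken
  as the elevation *range* (relief amplitude); `focal_statistic` also
  offers mean/min/max, and edges use truncated windows (the common GIS
  neighborhood-statistics behavior), not padding.
- **I6 lookup.** Soil-erodibility K per land-use class is configuration.
  The defaults (paddy 0.25, dry land 0.32, forest 0.15, water 0,
  artificial 0.05, other 0.28; reference 0.25) follow common USLE K
  magnitudes by cover type and are not survey-calibrated.
- **I7 form.** A continuous `slope/15°` ratio on farmland (0 elsewhere)
  rather than a step classification; only the 15° reference is published.
- **I11 combination.** River and lake density components are combined by
  unweighted mean before inversion; the evaluation standard's component
  weights are not published.
- **I12 spatialization.** The paddy-retention index is assigned on paddy
  cells; non-paddy farmland receives the capped (worst) value — farmland
  without paddy has no retention capacity at all — and non-farmland cells 0.
  A `paddy_zone_wide` switch paints the county value everywhere instead.
- **I3 breeding mask.** The "suitable breeding area" over which the
  livestock composite is painted defaults to dry land ∪ other; configurable.
- **Nemerow form.** `P = sqrt((mean² + max²)/2)`; for nonnegative inputs
  `mean ≤ P ≤ max` and P is homogeneous of degree 1 — both are tested.

## Grading and trajectory classification

Grade boundaries are closed where the published class definitions are
explicit ("≤ 0.7" → grade 1, "≥ 5.0" → grade 5) and right-closed in the
interior: grade 2 on (0.7, 1.0], 3 on (1.0, 3.0], 4 on (3.0, 5.0). The
convention is centralized in `GradeScale`.

Trajectory categories over three epochs: all digits equal → one of five
`no_change_grade_k`; non-decreasing with a strict rise → `increase`;
non-increasing with a strict fall → `decline`; otherwise `fluctuation`.
This monotone-trajectory rule makes the six groups an exact partition of
the 125 possible codes (emitted by `transition_table()` for audit) and
reads the canonical `123` example as a risk increase. The 3-digit base-10
packing bounds grades at 9; the model uses 1–5.

## Kernel density

Quartic (biweight) kernel `K(d) = 3/(πh²)(1 − d²/h²)²` for `d < h`, planar
Euclidean distance, evaluated at cell centers, reported per km². The kernel
integrates to 1, so the surface integrates to the at-risk point count away
from edges (tested to 1% for points ≥ 2h from the boundary). Bandwidth is a
required analysis choice with default `h = 30 cell widths` (900 m at 30 m
cells). A useful scale anchor: a solid block of at-risk 30 m cells wider
than `h` saturates the surface at one point per cell area ≈ **1111 km⁻²**,
so peaks near that value indicate fully contiguous at-risk areas rather
than scattered cells. The default source selection is grade ≥ 3 (the
highest grade observed in typical low-risk regions); when a study region
contains genuinely high-risk areas, `min_grade=4` isolates them.

## Getis-Ord Gi*

Standard self-inclusive Gi* with binary weights (queen/rook contiguity or
a fixed distance band), z against the global mean and population standard
deviation, two-sided normal p values, and `Gi_Bin` classes at the
1.645/1.960/2.576 quantiles (90/95/99%). Benjamini-Hochberg FDR adjustment
of the p values is available but off by default. The default analysis unit
is the county (zonal mean of the composite); cell-level analysis is
supported and is the right unit when the region has only a dozen counties —
with n ≈ 12 the normal approximation essentially cannot produce a 99%
class, a sample-size limit, not a code path difference. A unit whose
window spans every unit has a vanishing variance term; its z is set to 0
and flagged not significant.

## Synthetic landscapes

The generator emulates a mountainous agricultural region at 30 m
resolution: default 200×200 cells, 12 Voronoi counties. All fields are
Gaussian-smoothed white noise (length scale per layer), so spatial
autocorrelation is controllable but there is no hydrological realism — no
drainage network, no valley-bottom paddy preference beyond the land-use
field's ordering, no correlation between county statistics and terrain.
Passing tests therefore demonstrate the *pipeline's* correctness and
sensitivity, not calibration to any real region.

Defaults (one-time choices, in realistic magnitudes for an intensive
agricultural province): land-use shares water 2%, paddy 17%, dry land 22%
(farmland 39%), other 6%, artificial 3%, forest 50%; DEM base 200 m,
amplitude 500 m, length scale 25 cells; erosivity mean 60, sd 35; county
fertilizer intensity ~N(330, 60) kg/ha, pesticide ~N(2.2, 0.5) kg/ha,
livestock ratios ~N(0.4, 0.15), water-quality C/S indices ~N(0.8, 0.25),
runoff modulus ~N(75, 12), river density ~N(0.40, 0.08) km/km², lake
density ~N(0.025, 0.006) km²/km². Under these conditions the composite
typically spans ≈ 0.3–2.6 — the no/low/medium range.

**Planted clusters** perturb raw inputs, not outputs: the generator runs
the real scoring pipeline on the unperturbed scene, computes the per-cell
composite deficit to the target grade's mid-interval value (0.35 / 0.85 /
2.0 / 4.0 / 6.0 for grades 1–5), and spreads the equivalent index
increment equally over the fertilizer, pesticide and erosivity levers
(effective weights 0.2352, 0.1458, 0.0670). A target that would push any
lever past the cap or below zero raises as infeasible — grade 5 is
unreachable by construction with these three levers, which is the intended
behavior, not a defect. Recovery of planted clusters by kernel density and
by cell-level Gi* is part of the test suite.

**Epoch drift** multiplies selected counties' fertilizer/pesticide
intensities geometrically per epoch and optionally converts a seeded random
fraction of farmland to artificial land per step. Zero drift gives
bit-identical epochs, hence 100% no-change — the null the transition tests
pin down.

## Numerical choices and problem sizes

- All layer algebra is done in float64 with nodata as NaN internally;
  weighted sums iterate keys in sorted order so results are bit-identical
  under layer permutation.
- The distance transform is exact Euclidean (cell-center to cell-center);
  focal windows use NaN-aware sliding views.
- Oracle tests compare the vectorized implementations against plain
  double-loop references on random grids up to 20×20 across ≥ 50 seeds
  (tolerance 1e-9; 1e-10 for Gi* z scores).
- End-to-end validation runs on a 200×200, 12-county, 3-epoch scene with
  one planted grade-4 cluster — large enough for stable spatial statistics
  while keeping the full suite in a few seconds.

## Known limitations

- Rainfall erosivity is consumed as an input layer; it is not derived from
  rainfall records. Likewise K is a lookup, not a soil-survey product.
- No reprojection or resampling: all layers of an analysis must share
  geometry exactly, and geometry mismatches are errors by design.
- Zone borders are crisp: each cell belongs to exactly one county.
- The Gi* p values assume the normal approximation; no conditional
  permutation inference is implemented.
- Published regional headline figures (score ranges, category percentages,
  density peaks) depend on proprietary government rasters and are not
  reproducible from synthetic scenes; the pipeline reproduces the *methods*
  and their in-text worked values, and the synthetic conditions land in the
  same magnitude ranges.
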