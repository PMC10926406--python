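# Methods

## The suitability engine

The engine is an open, deterministic implementation of the classical
ecoclimatic-index family of process-based distribution models.  Each grid
cell carries 52 weekly climatological normals (Tmin, Tmax, rainfall,
radiation); weekly mean temperature is (Tmin+Tmax)/2.

**Growth.**  Weekly temperature and moisture indices are trapezoids over the
threshold quadruples DV0–DV3 (°C) and SM0–SM3 (soil-moisture fractions): zero
at or below the limiting low threshold, rising linearly to 1 at the lower
optimum, 1 across the optimal plateau, falling linearly to zero at the
limiting high threshold.  The boundary convention is *closed at zero*: the
index is exactly 0 at the limiting thresholds themselves, which makes edge
behaviour determinate and testable.  The annual Growth Index is
GI = 100·mean_w(TI_w·MI_w).

**Moisture.**  Soil moisture comes from a single-bucket weekly budget:
`store ← clamp(store + rain + 7·topup − evap, 0, 2·capacity)` with
evaporative demand `evap = max(0, evap_coeff·T)`.  The budget starts half
full and runs two identical annual cycles; the second (spun-up) cycle is
returned as a fraction of capacity in [0, 2].  Defaults: capacity 100 mm,
evap_coeff 1.0 mm per °C-week, chosen so that a wet-tropics cell saturates,
a desert cell empties, and the standard 2.5 mm/day irrigation top-up is
enough to push a warm desert cell onto the moisture optimum — the three
regimes the engine must distinguish.  This bucket is an explicit,
fully-configurable hydrology; it has no drainage term, so persistent
surpluses settle at saturation (fraction 2.0) rather than at an intermediate
equilibrium, and the moisture optimum SM2 = 2.0 is set accordingly.

**Stress and persistence.**  Four stresses (cold, heat, dry, wet) accumulate
linearly above/below their thresholds at their weekly rates and cap at 100;
EI = GI·Π(1 − S/100).  Linear accumulation (`stress_mode: linear` in spirit)
is a transparent simplification of compounding weekly stress; it preserves
the qualitative structure — EI ≤ GI, lethal stress zeroes EI, widening any
tolerance interval never shrinks the suitable range — which the property
suite checks on seeded worlds.  Generations per year are
floor(annual degree-days above DV0 / PDD).

**Parameter defaults.**  Only DV0 = 8.7 °C (the laboratory minimum
developmental threshold of fall armyworm on maize) is an externally fixed
value.  DV1 = 18, DV2 = 32, DV3 = 38 °C are in the range used by published
process-based models of the species; SM0 = 0.10, SM1 = 0.25, SM2 = 2.0,
SM3 = 2.5 and the stress block (TTCS = 5 °C at 1.5 units/°C-week;
TTHS = 40 °C at 0.2; SMDS = 0.15 at 20; SMWS = 2.0 at 20) are reconstructed
working defaults consistent with the bucket above: cold stress is strong
enough to exclude year-round persistence where winters dip below ~5 °C,
which produces the characteristic temperate pattern of seasonal-only risk
(GI > 0, EI = 0).  PDD = 455 °C·days.  The YAML export marks the block as
reconstructed; none of these values should be quoted as a published
parametrization.

## The synthetic world

The generator emulates the *structure* of a global climatology without any
real data: weekly mean temperature is `T_eq − lapse·|lat| + A(|lat|)·sin`
with amplitude growing 0.25 °C per degree of latitude and the southern
hemisphere phase-shifted exactly 26 weeks; rainfall is constant per week
within three Hadley-style belts (wet tropics |lat| < 15°, deserts 15–25°,
moist temperate beyond); radiation is a smooth deterministic insolation
proxy.  The default world is 240 × 120 cells spanning ±40° latitude and
±80° longitude (40′ cells — a deliberately compact stand-in for a 10′
global grid that keeps full-pipeline runtime at seconds); rectangular
irrigated patches sit inside the desert belts, ~35 % of cells carry maize
area (uniform 500–5000 ha), and a 6 × 4 grid of rectangular regions doubles
as country labels and reporting regions.

Because the construction is closed-form, the cells that are climatically
optimal *every* week (temperature on [DV1, DV2], rainfed moisture on
[SM1, SM2]) are known exactly; under the default parameters this
`truth_suitable_band` (|lat| ≲ 13°) must score GI = EI = 100, which the test
suite asserts.  Occurrence samples are drawn cell-wise proportional to EI,
then contaminated with known rates of uniform spatial noise, exact
duplicates under a different source, and country labels inconsistent with
the region grid — the three defect classes the curation stage must remove;
ground-truth flags are retained so recovery is checkable record by record.
Pipeline defaults (2,000 base records, 5 % noise, 15 % duplicates, 10 %
mislabels) represent a moderately messy multi-source compilation.

What the generator does *not* emulate: weather variability around normals,
realistic rainfall seasonality, orography and coastlines, spatially
autocorrelated sampling effort, or real administrative boundaries.  Passing
tests therefore demonstrate algorithmic correctness and internal
consistency, not predictive skill on real landscapes.

## Occurrence curation

Cleaning drops, in order: missing coordinates; coordinates outside
[−180, 180] × [−90, 90]; points outside the label grid (a drop reason, not
an error); records whose stated country disagrees with the label grid at
their cell; and later records duplicating an earlier one's coordinates
(rounded to 4 decimals) and country — a declared cross-source duplicate
rule, since no canonical definition exists.  Grid deduplication keeps the
earliest record per climate-grid cell using half-open cells anchored at
(−180, −90); the far north/east boundary belongs to the last cell.  Both
steps report per-source original/cleaned/unique counts whose rows must sum
to the totals.

## Bioclim derivation

Quarters are all 52 *circular* 13-week windows, never calendar quarters, so
hemispheres are treated symmetrically; driest/wettest windows minimise or
maximise summed rain, coldest/warmest minimise or maximise mean temperature,
ties going to the earliest window.  Seasonality variables are coefficients
of variation (100·sd/mean, population sd); the temperature CV is taken in
kelvin by default (`bio4_kelvin=True`) so the ratio has an absolute scale.
Isothermality is BIO2/BIO7, defined as 0 when the annual range is 0.  Only
the 13 retained predictors plus the two helpers they require (BIO2, BIO5)
are computed; the niche module accepts any variable superset.

## Niche analysis

**Ranking.**  A presence-vs-background random forest is fitted on an
internal 70/30 split; each variable is permuted 10–20 times on the held-out
30 % and the increase in classification error recorded.  The reported MAD is
the median absolute deviation of those increases *about zero* — the robust
magnitude of the error increase — and is the ordering statistic; the median
increase is reported alongside.  Held-out evaluation (rather than per-tree
out-of-bag bookkeeping) keeps the statistic honest for fully-grown forests
while remaining deterministic under a seed.  Constant columns get importance
0 with a warning count.

**PCA.**  Correlation PCA (variables standardised to unit variance);
components ordered by explained variance with the sign convention that each
component's largest-magnitude loading is positive, making loadings tables
reproducible.  The √(1/k) rule of thumb flags high-ranked loadings.

**Occupancy.**  Separable Gaussian KDE with per-axis Silverman bandwidth
(σ·n^(−1/6); scalar override available, and required for degenerate score
sets) on a shared R × R grid spanning the pooled background extent padded
10 %.  Occupancy is the *ratio-corrected* density — occurrence density over
background availability where the background is positive — renormalised to
sum 1, so unevenly available environment does not masquerade as preference.

**Metrics.**  Expansion is invaded occupancy mass on cells with zero native
occupancy, within the environment available to both ranges, as a share of
invaded mass there; stability is its exact complement; unfilling is native
occupancy mass on cells with zero invaded occupancy, within the environment
available to the invaded range.  "Zero" means below 1e−12 of total mass (a
floating guard).  Backgrounds are the union of cells of each range's region
set.  On the default zonally symmetric world the two hemispheric ranges
offer identical environments, so the pipeline's self-consistent outcome is
(expansion, stability, unfilling) ≈ (0, 1, 0); non-trivial geometries are
exercised in the test suite with offset-Gaussian densities against
brute-force cell-sum oracles.

## Overlay accounting

Habitation defaults to the stated rule (suitable iff GI > 0 or EI > 0); a
`persistence_only` switch restricts it to EI > 0 for the stricter
"persistent presence" reading.  Downscaling replicates each coarse cell into
factor² children (composition-preserving by construction); extensive
quantities such as maize hectares are divided by factor² before replication
so totals are conserved.  All shares are weighted by maize area in hectares,
and conditional co-suitability shares are rounded to one decimal with
largest-remainder rounding so each row sums to exactly 100.0.  EI risk bins
are none (= 0), [0, 5), [5, 34), [34, 62), [62, 100], with shared edges
owned by the upper bin — a declared resolution of the overlapping printed
ranges.  Cell areas, where needed, use the spherical band formula
R²·Δλ·(sin φ₂ − sin φ₁).

## Problem sizes and numerical choices

The standard test world is 60 × 30 cells (same ±40° window, 8× coarser);
full-scale checks (vectorised-vs-scalar engine equivalence, overlay row
sums, ground-truth recovery) run on the default 240 × 120 world.  The
acceptance script uses the default world, a 300-cell scalar-oracle
subsample, and 100 random-forest recovery replicates (300 samples, 10
decoys, 100 trees each).  All randomness flows through named per-stage
seeds; the engine itself contains none.

## Known limitations

- The stress model is linear, not compounding; absolute EI values are not
  comparable with proprietary implementations, only orderings and
  zero-sets.
- The bucket hydrology has no runoff/drainage term (see above).
- The niche background is region-based; buffer-based backgrounds would
  change the availability masks and hence the metrics.
- Synthetic rainfall has no seasonality, so dry-season dynamics and the
  wet-stress pathway are exercised only by constructed series in tests.
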