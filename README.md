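# perilmap

Process-based climate-suitability modelling and multi-peril pest risk mapping
for maize pests, built around the fall armyworm (*Spodoptera frugiperda*), a
migratory lepidopteran that has invaded maize systems across Africa and Asia.

The package is aimed at pest-risk analysts and quantitative ecologists who
want a transparent, fully tested implementation of the standard
CLIMEX-style / niche-overlap / co-occurrence toolchain, exercised end-to-end
on seeded synthetic worlds with analytically known ground truth.

## What it computes

**Ecoclimatic suitability engine** (`perilmap.engine`).  For each grid cell
with 52-week climate normals, weekly growth indices are trapezoidal in
temperature (thresholds DV0 < DV1 ≤ DV2 < DV3, °C) and soil moisture
(SM0 < SM1 ≤ SM2 < SM3, fractions of a single-bucket water budget):

    GI = 100 · mean_w( TI_w · MI_w )                          (Growth Index, 0–100)
    EI = GI · Π_s (1 − S_s/100),  s ∈ {cold, dry, heat, wet}  (Ecoclimatic Index)

where each stress accumulates linearly over the year, e.g.
`CS = min(100, Σ_w THCS·max(0, TTCS − T_w))`.  GI > 0 marks climates that can
carry a seasonal population; EI > 0 marks potential year-round persistence.
Generation counts use degree-days: `floor(Σ_w 7·max(0, T_w − DV0) / PDD)`.
Rainfed and irrigated (2.5 mm/day top-up) scenarios are composited through an
irrigation mask.  The default fall-armyworm block sets DV0 = 8.7 °C, the
laboratory developmental minimum of the pest on maize; the remaining values
are reconstructed working defaults (see `docs/methods.md`).

**Niche overlap** (`perilmap.niche`).  Predictors (bioclim variables derived
from weekly normals by `perilmap.bioclim`) are ranked by random-forest
permutation importance, the top k enter a correlation PCA, and occurrence vs
background kernel densities on the two-axis environment space yield the COUE
proportions:

    expansion  = share of invaded-range occupancy outside the native niche
    stability  = 1 − expansion
    unfilling  = share of native occupancy absent from the invaded range

with a 25 % density quantile delimiting marginal climates.

**Multi-peril overlay** (`perilmap.overlay`).  Per-pest suitability becomes a
binary habitation value (GI > 0 or EI > 0), co-habitation is the per-cell sum
over pests, and intersecting with a maize-area grid gives per-region shares
of maize at seasonal/year-round risk and — conditional on focal-pest
suitability — the share co-suitable for exactly k additional pests, plus
one-degree latitudinal band profiles by EI risk category.

**Synthetic worlds** (`perilmap.synthetic_world`) generate seeded climates
with closed-form structure (latitude-driven seasonal cycles, rain belts,
irrigated desert patches, maize surfaces, contaminated occurrence samples),
so every stage is testable without external data.

## Worked example

```python
from perilmap import WorldConfig, make_climate_world, faw_default, run_scenarios

world = make_climate_world(WorldConfig(seed=42))      # 240 x 120 cells, ±40°
surface = run_scenarios(world.climate, faw_default(), world.irrigation_mask)

print(f"EI > 0 (year-round risk): {100 * (surface.EI > 0).mean():.1f}% of cells")
print(f"GI > 0 (seasonal risk):   {100 * (surface.GI > 0).mean():.1f}% of cells")
```

prints

```
EI > 0 (year-round risk): 76.0% of cells
GI > 0 (seasonal risk):   77.7% of cells
```

i.e. three-quarters of this synthetic planet supports year-round populations
(it is tropics-heavy by construction), and a further sliver of temperate
cells supports only seasonal growth — there the pest can complete
generations in summer but accumulated cold stress drives EI to 0.  The
9,120 cells of the analytically known optimal band all score EI = 100, and
irrigated desert patches average EI ≈ 82 where the rainfed scenario gives 0.

The same analysis runs end-to-end from the shell:

```
perilmap run --seed 42 --outdir out/        # world → curate → … → multiperil
perilmap simulate-world --seed 7 --outdir world/
perilmap suitability --climate world/climate.nc --irrigation world/irrigation_mask.asc --outdir suit/
```

Each run writes a `manifest.json` listing every artifact with its stage and
SHA-256, and reruns with the same seeds are byte-identical.

## Layout

- `src/perilmap/` — library modules (engine, bioclim, niche, curation,
  overlay, synthetic_world, pipeline, cli)
- `tests/` — unit, property and acceptance suites (pytest + hypothesis)
- `docs/methods.md` — model description, parameter defaults and rationale,
  numerical choices, limitations
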