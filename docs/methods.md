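# Methods

This note records the models, conventions and numerical choices behind
`orbitlakes`, and what the synthetic experiments do and do not demonstrate.

## Input model

The pipeline consumes monthly ternary rasters (LAND=0, WATER=1, MISSING=2).
Stacks are read/written as plain TIFF (per-month files or one multi-page
file) via `tifffile`; because plain TIFF carries no geo-metadata, the
affine transform and CRS identifier travel in a JSON sidecar
(`georef.json` in a stack directory, `<file>.georef.json` otherwise). The
transform uses the upper-left cell-corner convention, row-major 0-based
indices, and polygons are traced on cell edges, so polygon area in
projected units equals `pixel_count × pixel_area` exactly for axis-aligned
grids. Vector output is GeoJSON (one possibly multi-part polygon feature
per lake, attributes round-tripping losslessly); ESRI Shapefile output is
not provided and requesting it raises.

The unit pixel area is 0.0009 km² (a 30 m × 30 m Landsat cell) and scales
by `factor²` under block downsampling.

## Phase 1: delineation

* Occurrence = 100 × (#months WATER) / (#months not MISSING); cells never
  observed are NaN. The denominator deliberately conditions on
  observation — an always-cloudy pixel is unknown, not dry.
* Binarization keeps occurrence **strictly greater than** 10%;
  NaN → False. Connected components default to 8-connectivity (shorelines
  are diagonal-heavy at 30 m; 4-connectivity is available by config), and
  component ids are assigned by raster-scan order of each component's
  first pixel, making extraction deterministic.
* Size filter keeps components of **at least** 100 pixels (0.09 km²).
* River filter: `e` = number of erosions with a 3×3 square structuring
  element (cells beyond the raster border are background) until the shape
  is empty; the morphological score is `4e²/N`, uncapped (a solid odd
  square scores slightly above 1, e.g. 21×21 → 484/441); `river_flag`
  is strict `score < 0.05`. The inscribed-square guarantee that can
  actually be proven is side `2e−1` (the shape survives `e−1` erosions),
  which is what the tests assert; `4e²` is treated as the score's
  approximation of that square, not as a guarantee.
* Records are flagged, never deleted; `drop_rivers` reproduces removal.
* Optional river-line overlap flags buffer vector lines by 1 or 4 km
  (assuming a metric projected CRS) and test polygon intersection.

## Phase 2: ORBIT correction

State: a permutation `order` of the lake's pixels (position 0 = lowest
elevation) and integer levels `k[t] ∈ [0, N]`; the corrected extent at `t`
is the prefix `{order[0..k[t])}`. Objective:

```
J(order, k) = Σ_t Σ_i cost(obs[i,t], assigned[i,t]) + λ Σ_{t≥1} |k[t] − k[t−1]|
cost = w_water  if observed WATER assigned land
       w_land   if observed LAND assigned water
       0        if agreement or observed MISSING
```

Defaults: `w_water=3`, `w_land=1` (water observations are markedly more
reliable than land observations in pixel-based products, and the 3:1 ratio
is the production choice), `λ=0.5` per pixel of level change (enough to
interpolate fully-missing months without smothering real seasonal change),
`γ=1` (weight of imputed cells when re-scoring pixel wetness),
`max_iter=10`.

Numerical scheme:

* **Level fit (exact).** Given an ordering, per-month costs `c_t(k)` come
  from prefix sums of the rank-sorted observations. With `λ=0` each month
  is an independent argmin; with `λ>0` the exact minimizer over all level
  series is found by dynamic programming over (month, level), using
  two-pass running-minimum convolutions for the `λ|Δk|` transition
  (O(T·N) total). Ties break toward the smaller level everywhere, so
  all-missing months with `λ=0` take level 0 (and are warned about), while
  with `λ>0` they interpolate between neighbours at the smallest
  cost-equal level.
* **Ordering update (heuristic re-sort).** Pixels are stably re-sorted by
  `s_i = w_water·#WATER_i − w_land·#LAND_i + γ(#missing-assigned-water_i −
  #missing-assigned-land_i)`; stability preserves the current order among
  ties, making the update idempotent and the whole fit deterministic — no
  randomness exists anywhere in the correction path.
* **Outer loop.** Initialization is the observed-wetness sort (γ-term
  zero, ties by raster-scan index). Iterations alternate ordering update
  and exact level fit; an iteration is accepted only if the objective
  strictly decreases, and the best state encountered is returned, so the
  accepted-objective sequence is non-increasing by construction. On
  well-behaved single-basin inputs the wetness initialization is already
  near a fixed point and the loop typically terminates after one rejected
  update; the exact level fit does most of the corrective work.

Per-month metadata: `pct_corrected` = 100 × flipped observed labels /
observed labels; `pct_imputed` = 100 × missing cells / lake cells (both
within the lake's analysis mask); months with no observation at all carry
`all_missing_flag` and are still written, keeping time axes rectangular.

Lake-local stacks are cropped to the reference bounding box (+2 px pad);
an outside pixel is retained only if it is water **and** shares a
connected water component with the reference extent in at least 5 months;
all other outside pixels are forced to land, which keeps neighbouring
waterbodies out of the ordering. Lakes above 100 km² are corrected on a
10× block-aggregated grid (block → water if more than half of its
non-missing cells are water, missing only if all are missing; ragged edges
pad with missing), bounding the O(T·N) cost for the largest lakes.

## Quality scores and gate

`CS = ΣP[t] / ΣW[t]` with `P[t]` the water pixels outside the month's
largest connected component (`P[t]=0` for dry months); an always-dry stack
gets CS = 0 rather than NaN — such a record should fail on ES, not on CS.
`ES` counts months with water count strictly below 10% of the reference
size. The gate is `ES ≤ 156 AND CS < 0.2` (inclusive vs strict exactly as
published); 156 is an empirical constant tuned on 384-month records, so an
optional fractional mode rescales it by `T/384` for shorter series (off by
default). Scores are computed on corrected stacks by default; a raw mode
scores the input instead, and the two agree exactly on noise-free input.

## Evaluation

Accuracy against an annotated reference (WATER=1, LAND=0, MASKED
excluded): predictions encode WATER→1, LAND→0, MISSING→0.5, and accuracy
is `1 − mean|ref − pred|` over non-masked cells — the denominator is the
count of valid cells, generalizing the full-grid `R·C` form to references
with annotator-masked regions (masked pixels are removed, not scored 0.5).
The restricted variant additionally drops cells that the reference and
both compared predictions all label land; an empty survivor set yields a
flagged undefined result, not an exception. Map selection keeps frames
with any update (`pct_corrected + pct_imputed > 0`), at most 90% missing,
and year ≥ 2000; optional seeded sampling weights frames by inverse
frequency of 10-point update-percentage bins to de-skew toward
heavily-updated maps.

## Synthetic generator

What it emulates: a fixed bathymetry (bowl, tilted plane, two-basin,
flat-ephemeral, ribbon archetypes; a seeded 1e-4 jitter breaks elevation
ties), monthly levels `mean + A·sin(2πt/12) + trend·t + N(0, σ)`, truth
`water(t) = {bathymetry < level[t]}` (strict inequality), then asymmetric
flips (defaults `p_water_flip=0.05 < p_land_flip=0.15`, mirroring the
conservatism of water labels) and missingness applied **after** flips so
MISSING dominates: MCAR disks of radius 3 px at 20% expected coverage
(clouds), plus shoreline-conditional missingness (rate 0.3 within a 1-px
Chebyshev band of the true boundary, emulating classifier unconfidence at
edges). The flip and missingness magnitudes are stand-ins — no
quantitative error model exists for the real product — so every recovery
number reported by the tests is conditional on these rates. Default study
conditions: 40×40 bowl, T=60 months, level mean 0.5, amplitude 0.25,
σ=0.05.

What it does not emulate: radiometric texture, spatially correlated flip
errors, lake-type diversity (wetlands, farm-pond clusters), changing
bathymetry. Passing recovery tests therefore show the estimator is
correct under its own assumptions and robust to the modeled noise — not
that real-world accuracy will match.

Multi-lake scenes compose independently generated lakes side by side on a
dry canvas (used to test extraction + per-lake isolation); the two-basin
archetype deliberately violates the single-basin assumption, and tests
assert its ordering recovery *degrades* relative to the bowl.

## Problem sizes and determinism

Tests and the acceptance script run on lakes of ~300–1600 pixels over
12–60 months, and the stochastic recovery suite uses 50 generator seeds —
sizes at which the exact DP and brute-force cross-checks (exhaustive
enumeration over all `(N+1)^T` level series for N ≤ 8, T ≤ 4) are
feasible, chosen as the package's own verification scale. All randomness
is confined to the synthetic generator and flows from explicit integer
seeds; the correction path itself is fully deterministic, so identical
inputs and config give byte-identical outputs.

## Known limitations

* The ordering update is a heuristic re-sort, not an exact M-step; the
  outer loop guards against it with the strict-decrease acceptance rule,
  and on hard inputs the result can be a local optimum (the tiny-instance
  tests assert it is never worse than the truth-anchored solution).
* A lake whose basins fill independently (farm ponds, frequently split
  lakes) violates the core assumption; CS is the guard, not a fix.
* The 10% occurrence threshold inherits its known artefacts: lakes
  connected ≥10% of months merge; ephemeral lakes below the threshold are
  never delineated.
* Shapefile output and on-the-fly reprojection are out of scope; GeoJSON
  in a projected CRS is the vector interchange format.
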