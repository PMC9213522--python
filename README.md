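# orbitlakes

Monthly surface-area time series for individual lakes and reservoirs, built
from noisy pixel-based land/water/missing classification maps.

Pixel-based surface-water products (monthly Landsat-derived land/water
grids) track water at the pixel level but not at the level of the discrete
waterbodies that limnologists, hydrologists and water managers actually
reason about — and the pixel maps carry substantial classification error
and cloud-driven missing data, so naively counting water pixels per month
produces wildly jumpy area series. `orbitlakes` turns such maps into
per-lake products in two phases:

1. **Delineation.** Threshold the water *occurrence* layer (percent of
   observed months a pixel is water) at >10%, take connected components,
   keep components of ≥100 pixels, and flag river-like shapes by a
   morphological score `4e²/N` (where `e` is the number of 3×3 binary
   erosions needed to empty the shape and `N` its pixel count; low scores
   mean long thin, lotic shapes; the flag threshold is 0.05).
2. **Correction (ORBIT).** A lake in a single basin fills and drains along
   its bathymetry: a pixel is wet only if every lower pixel is wet. ORBIT
   (Ordering Based Information Transfer) represents each lake as a latent
   elevation ordering of its pixels plus a monthly fill level `k[t]`, and
   estimates both from the noisy stack by coordinate descent on

   `J = Σ_t Σ_i cost(obs[i,t], assigned[i,t]) + λ Σ_t |k[t] − k[t−1]|`

   with `cost = w_water` (default 3) for overruling an observed water
   pixel, `w_land` (default 1) for overruling an observed land pixel, and 0
   for missing pixels — water labels are more trustworthy than land labels
   in these products, hence the 3:1 asymmetry. The corrected extent at
   month `t` is exactly the `k[t]` lowest-ranked pixels, so every output
   frame is physically consistent (all extents are nested), missing data
   are imputed, and the temporal term carries information across cloudy
   months.

Each lake then gets quality scores: the **Connected Component Score**
`CS = ΣP[t]/ΣW[t]` (water pixels outside the largest component, aggregated
over months — detects multi-basin violations) and the **Ephemeral Score**
`ES` (months with area below 10% of the reference size). The published
reliability gate keeps lakes with `ES ≤ 156 & CS < 0.2`. Monthly areas are
`water_pixel_count × 0.0009 km²` (one 30 m Landsat cell), with per-month
`%corrected` / `%imputed` metadata and low-confidence-run flagging.

A synthetic-lake generator (parametric bathymetries, seasonal water levels,
asymmetric label noise, cloud-blob and shoreline-conditional missingness)
provides ground-truthed fixtures for every stage, and an evaluation module
scores predicted maps against annotated references (missing predictions
count 0.5; a restricted variant drops pixels that reference and both
compared maps all call land).

## Worked example

```python
import orbitlakes as ol

cfg = ol.SyntheticLakeConfig(seed=42)     # 40x40 bowl, 60 months, default noise
stack, truth = ol.generate(cfg)           # ternary stack + ground truth
result = ol.run_pipeline(stack)           # extract -> correct -> score -> areas

rec = result.records[0]
print(f"lake {rec.lake_id}: N={rec.n_pixels} px ({rec.area_km2:.4f} km2), "
      f"e={rec.erosion_count}, morph score={rec.morph_score:.3f}, river={rec.river_flag}")
print(f"quality: CS={rec.cs:.4f}, ES={rec.es}, reliable={rec.reliable_flag}")
table = result.area_tables[rec.lake_id]
print(f"mean monthly area {table['area_km2'].mean():.4f} km2, "
      f"mean imputed {table['pct_imputed'].mean():.1f}%, "
      f"mean corrected {table['pct_corrected'].mean():.1f}%")
```

prints

```
lake 0: N=1516 px (1.3644 km2), e=16, morph score=0.675, river=False
quality: CS=0.0042, ES=0, reliable=True
mean monthly area 0.7335 km2, mean imputed 20.5%, mean corrected 13.1%
```

The delineated lake is compact (morphological score 0.675, far above the
0.05 river threshold), essentially single-component (CS ≈ 0), never
ephemeral (ES = 0), hence reliable. About 20% of the lake's pixels per
month were missing in the input and received imputed labels; 13% of the
observed labels were overruled as physically inconsistent. Comparing
against the known truth for this seed, per-month map accuracy rises from
0.824 (raw observations, missing scored 0.5) to 0.946 after correction,
and the learned pixel ordering tracks the true bathymetry with Spearman
correlation 0.95.

The same steps are available as a CLI:

```bash
orbitlakes simulate --kind bowl --shape 40,40 -T 60 --seed 42 --out sim/
orbitlakes run --stack sim/stack --out out/
# out/: lakes.geojson, area_timeseries.csv, config.yaml
```

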