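# pondpredict

Quantify the environmental predictability of ponds from multispectral
satellite image time series.

The package implements a full pipeline:

1. **Water detection** — a two-condition per-pixel assessment: a pixel is a
   water candidate when its MNDWI = (green − mir)/(green + mir) is strictly
   positive, and candidates with NIR reflectance ≥ 0.4 are reclassified as
   salt crust (a false-positive source in saline ponds). Cloud pixels are
   propagated untouched.
2. **Time series** — per-pond water-surface areas (water pixels × pixel
   area) with cloud-uncertainty bounds `[area, area_max]`, monthly
   aggregation (averaging the least-clouded observations per month), the
   monthly-balanced mean area, and the hydroperiod.
3. **Discrete predictability** — Colwell-style constancy/contingency/
   predictability on 12-month contingency tables under five state
   definitions: `COL_wd` (wet/dry), `COL_ANa` / `COL_ANw` (mean ± 70%
   neighborhood, all data vs. wet-only mean), `COL_MAXlin` / `COL_MAXg`
   (thirds or quarters of the maximum area).
4. **Continuous predictability** — a penalized cubic-spline seasonal curve
   fitted to normalized area vs. day-of-year (smoothing chosen by GCV);
   predictability is the reciprocal of the residual standard deviation
   (`GAM_a` and `GAM_w` differ in the normalizing mean).
5. **Model comparison** — Pearson correlations of the per-pond estimates
   across models, chord distance √(2 − 2r), UPGMA clustering with ordinary
   bootstrap clade support, and a threshold cut into model clusters.
6. **Synthetic data** — seeded generators for multiband scenes (archetype
   spectra + noise) and pond series (seasonal curve, year effects, dry
   truncation, cloud loss) so every stage is testable without external data.

## Command line

```sh
# synthetic end-to-end run
pondpredict synth series --seed 3 --n-ponds 5 --out areas.csv
pondpredict predict --areas areas.csv --out estimates.csv
pondpredict compare --estimates estimates.csv --n-boot 10000 --seed 42 \
    --cut 0.90 --out comparison/

# raster pipeline
pondpredict synth scenes --n-scenes 8 --out scenes/        # or your own GeoTIFFs
pondpredict classify --manifest scenes/scenes.csv --bands green=1,nir=2,mir=3 \
    --out labels/
pondpredict areas --labels labels/ --mask scenes/ponds.tif --out areas.csv
pondpredict freqmap --labels labels/ --out freq.tif
pondpredict series --areas areas.csv --pond 1
```

Scene inputs are multiband GeoTIFFs listed in a manifest CSV
(`scene_id,path,date`, ISO-8601 dates). Every analysis constant
(thresholds, spline basis size, bootstrap settings) can be overridden with
a YAML file passed as `--config`; the defaults are the published values.

## Layout

```
src/pondpredict/
  raster_io.py        GeoTIFF scenes, pond masks, label rasters, manifests
  water_detection.py  MNDWI + salt filter classification, pond areas, freq map
  timeseries.py       series assembly, balanced mean, hydroperiod, monthly agg
  colwell.py          contingency tables and the five discrete models
  gam.py              penalized-spline seasonal fit, 1/SD_res index
  model_compare.py    correlations, chord distance, UPGMA, bootstrap, cut
  synthetic.py        seeded scene and series generators with known truth
  config.py, cli.py   run configuration and the command-line interface
```
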