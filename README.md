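# sdmpipe

Presence-only species distribution modelling for landscape-scale invasion
monitoring: from predictor rasters and field presence points to annual
habitat-suitability maps and change statistics.

The package was built around the problem of mapping the invasive shrub
*Lantana camara* in Akagera National Park (Rwanda) from satellite-derived
predictors and road-bound field surveys, but every component is generic:
it is aimed at ecologists and remote-sensing analysts who have presence
records (no true absences), a stack of gridded environmental predictors,
and need defensible suitability maps with spatially honest validation.

## The method

Let the landscape be a 30 m grid with predictor bands
$x_1, \dots, x_p$ (terrain, climate, soil, land cover, SAR backscatter in
dB, multispectral reflectance and vegetation indices such as
$\mathrm{NDVI} = (\mathrm{NIR}-\mathrm{RED})/(\mathrm{NIR}+\mathrm{RED})$,
plus a binary 50 m road buffer). Given presences only:

1. **Thinning** — presences are reduced to one randomly chosen record per
   grid cell, removing GPS pseudo-replication.
2. **Pseudo-absence profiling** — the standardized environmental space of
   all land cells is partitioned by k-means; cells in clusters containing
   no presence are "environmentally distinct" and form the pseudo-absence
   pool. Pseudo-absences are drawn per spatial block to match the block's
   presence count, so the data are balanced globally and spatially.
3. **Spatial-block cross-validated ensemble** — data-bearing blocks
   (default 10×10 cells) are split 70/30 into training and validation;
   a random forest ($n_{\text{trees}}=500$) is fitted per iteration and
   the habitat suitability index (HSI) is the mean class-1 probability
   over ten iterations, with a per-cell SD, a majority-vote binary map
   (ties → absence), and mean per-predictor relative contributions (%).
4. **Validation** — AUC$_{\text{ROC}}$ (Mann–Whitney form, ties ½),
   AUC$_{\text{PR}}$ (average precision), sensitivity and specificity on
   each iteration's held-out blocks.
5. **Change analysis** — interannual HSI difference maps and a suitable
   area table in km² with first differences and percent of total area.

A synthetic-landscape generator (spatially autocorrelated Gaussian
fields, categorical land cover, water mask, random road network, and
presences sampled from a known logistic suitability surface with road
access bias) makes the whole pipeline testable end to end, including
recovery of the planted drivers.

## Worked example

`python examples/run_ensemble_synthetic.py` generates the default
synthetic scenario (200×200 cells, 20 continuous bands of which
`band_01`, `band_02`, `band_03` carry the signal, plus land cover and a
road effect), samples 400 road-biased presences, and runs the full
ensemble. It prints:

```
landscape: 27 bands, 2000 water cells; 400 presences thinned to 400 (one per cell)
validation over 10 iterations (spatial-block 70/30 splits):
  AUC_ROC 0.940 (SD 0.018), AUC_PR 0.944 (SD 0.017)
  sensitivity 0.889, specificity 0.840
top-5 predictors by mean relative contribution (%):
  band_01     16.1 <- true driver
  band_03      7.2 <- true driver
  Roads        7.2 <- true driver
  band_02      6.7 <- true driver
  band_07      4.8
HSI surface: mean 0.534, range [0.027, 0.983]; majority-vote suitable fraction 0.559
```

AUC near 0.94 under *spatial-block* validation and all four planted
drivers in the top five show the model recovers the generating signal
rather than spatial autocorrelation. The other examples demonstrate
predictor construction (`build_predictor_stack.py`), environmental
profiling on a two-regime landscape (`profile_pseudoabsences.py`), and
suitable-area accounting on the published Akagera series
(`area_change_accounting.py`), where the 2023 maximum of 364.85 km²
against the 1,122 km² park is 32.52%, i.e. 33% of the park.

There is also a thin CLI: `sdm simulate`, `sdm all --config cfg.yml
--seed 42 --out run/`, `sdm change a.tif b.tif`.

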