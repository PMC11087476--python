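# sizesel

Temperature and the size structure of predator-prey interactions in
stomach-content surveys.

Warming oceans are expected to shrink ectotherm predators faster than
their prey, reshaping who can eat whom. `sizesel` is a Python library (and
thin CLI) for quantifying that process from the standard field data of
midwater fish surveys — stomach contents, zooplankton hauls and station
covariates — built around three quantities:

* **PPMR**, the predator-prey mass ratio of each stomach:
  predator mass (g) divided by the abundance-weighted mean prey mass
  `Σcᵢmᵢ/Σcᵢ` (g), analysed as log₁₀ PPMR;
* **prey-size preference**: within each sampling location and
  10^0.05 g predator size class, the normalised ratio of the realised
  (diet) to environmental (zooplankton) kernel density estimates on the
  log₁₀ prey-mass axis — flat under neutral, density-dependent feeding —
  summarised by its mean, the average preferred prey size;
* **community structure**: per-haul Shannon-Wiener diversity
  `H = −Σ pᵢ ln pᵢ` of square-root-transformed species densities.

Temperature effects are estimated with linear mixed models (random
intercept for year, random SST slope by species), selected by AIC,
checked for residual spatial autocorrelation with Moran's I, and reported
as percent change per °C (`100·(1−10^slope)`). A synthetic survey
generator with known ground truth (temperature-structured species
niches, lognormal prey pools, size-biased feeding kernels) makes every
stage testable by parameter recovery. It is aimed at quantitative
ecologists working on food-web size structure who want the full chain —
unit-safe preprocessing to effect sizes — reproducible from one config.

## Worked example

Recover a known feeding kernel from ~10⁴ simulated prey draws
(`examples/03_prey_size_preference.py`):

```bash
$ python examples/03_prey_size_preference.py
 class_index  n_predators  n_prey  mean_preferred_log10
           9           52    1061             -2.771192
          10          448    9044             -2.767877

estimated mean preferred prey size: -2.768 log10 g
true kernel optimum:                -2.750 log10 g
```

Each row is one predator size class in one sampling location; the
KDE-ratio estimate of the average preferred prey size lands within 0.02
log₁₀ units of the generating kernel's optimum. Or recover a temperature
effect on body size (`examples/04_temperature_effects.py`):

```bash
$ python examples/04_temperature_effects.py
log10_predator_mass:
  SST slope -0.0301 +/- 0.0028 log10 per degC (~6.7% decline per degC)
  Moran's I on residuals: I=+0.208, p=0.02
log10_ppmr:
  SST slope -0.0220 +/- 0.0047 log10 per degC (~4.9% decline per degC)
  Moran's I on residuals: I=+0.140, p=0.09
```

The generating truth here is a −0.03 log₁₀ g per °C decline; both fitted
slopes sit within two standard errors of it. The remaining examples cover
simulation (`01`), PPMR arithmetic (`02`) and the end-to-end pipeline with
its manifest (`05`).

The same stages are available from the shell:

```bash
sizesel simulate --out data/ --seed 1
sizesel ppmr --data data/ --out ppmr.csv
sizesel fit --table ppmr.csv --response log10_ppmr --out coef.csv
sizesel run --config pipeline.yaml        # all five stages + manifest
```

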