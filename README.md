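# habsuit

Regional habitat-suitability modelling for presence-only species records,
with field validation through an imperfect-detection occupancy model and a
browse-based habitat-quality index. The package implements the full recipe
as reusable, tested components and can exercise everything end-to-end on
synthetic landscapes with a known generating truth.

## What it does

- **Occurrence preparation** (`habsuit.occurrences`): accuracy/cleared-land
  cleaning, elevational subregion splitting at 500 m, replicated random
  spatial thinning at a 2-km minimum distance with a holdout set, and
  greedy Pearson-correlation screening (|r| > 0.75) of predictor layers.
- **Sampling-effort bias surface** (`habsuit.bias`): Gaussian kernel density
  of target-group records rescaled affinely to [1, 30].
- **Maximum-entropy SDM** (`habsuit.maxent`): hinge-feature basis, L1-
  regularised log-loss minimised by cyclic coordinate descent (default
  regularisation multiplier 2, tolerance 1e-5, up to 1000 cycles, 10,000
  bias-weighted background points), entropy-calibrated logistic output,
  replicated 75/25 training partitions with rank-based test AUC, per-variable
  percent contribution, response curves, and the suitability-class
  area/record frequency table in nine 0.1-wide bins.
- **Occupancy model** (`habsuit.occupancy`): zero-inflated detection-history
  likelihood with logit links on occupancy and detection, covariates on both,
  multi-start ML, AIC selection tables with Akaike weights, parametric-
  bootstrap goodness of fit (chi-squared, p, c-hat), delta-method intervals
  for fitted occupancy, and Pearson validation against modelled suitability.
- **Habitat quality** (`habsuit.habitat_quality`): Point-Quarter stem density
  (Pollard's unbiased estimator), species composition and basal area, a
  configurable browse-class-weighted habitat-quality index, and per-subregion
  OLS of the index against suitability.
- **Synthetic data** (`habsuit.synth`): Gaussian-random-field predictor
  stacks with categorical layers and a known logistic suitability truth,
  observer-biased presence sampling, stratified Bernoulli detection
  histories (7 nights, trip-varying detection), and Poisson tree patterns
  measured with the Point-Quarter protocol.
- **Pipeline and CLI** (`habsuit.pipeline`, `habsuit.cli`): raster and CSV
  I/O (ESRI ASCII grids, plain-text CSVs), a validated declarative run
  configuration, and orchestration of the full analysis with seeded,
  reproducible stages and audit manifests.

## CLI

```sh
habsuit simulate --out bundle --seed 1 --size 120 --sites 65
habsuit prep --presences bundle/occurrences.csv --cleared bundle/cleared.asc \
    --dem bundle/stack/dem.asc --out prep --sets 5 --min-dist 2000
habsuit bias --points bundle/occurrences.csv --points bundle/target_group.csv \
    --template bundle/stack/cont_1.asc --out bias.asc
habsuit fit-maxent --presences prep/subregion1_set1.csv --stack bundle/stack \
    --bias bias.asc --out sdm --replicates 20 --reg 2 --seed 7
habsuit classify --map sdm/suitability.asc --holdout prep/subregion1_holdout.csv \
    --out class_frequency.csv
habsuit fit-occupancy --history bundle/detection_history.csv \
    --sites bundle/sites.csv --model "psi(.),p(.)" \
    --model "psi(suitability),p(.)" --out selection.csv
habsuit hq-index --transects bundle/transects.csv \
    --browse-classes bundle/browse_classes.csv --out hq.csv
habsuit run-all --input-dir bundle --output-dir out
```

All stochastic stages consume named seeds; reruns with the same
configuration reproduce the same numbers.

## File formats

- Rasters: ESRI ASCII grid (`.asc`), cell-centre registered, north-up,
  `NODATA_value` honoured; all layers of a stack must share the grid exactly.
- Occurrences: CSV with columns `x,y,accuracy_m,date,source` in projected
  metre coordinates.
- Detection histories: CSV `site,night_1..night_T` with 0/1/NA, plus
  per-site and per-site-night covariate CSVs; models are named with spec
  strings such as `psi(suitability),p(trip)`.
- Transects: CSV `site,station,quadrant,distance_m,species,dbh_cm`, with a
  `species,class` browse-class map.
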