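# phytocommune

Analysis toolkit for chemical-ecology studies that pair LC-MS plant
metabolomics with insect community surveys across a spatial hierarchy
(sites > elevation subsites > plots > individual plants > months).

The package implements, as tested reusable components:

- **`synthetic`** — a generator for feature tables, sample metadata and
  herbivore communities with full planted ground truth: compound classes
  with characteristic retention-time / m/z / relative-mass-defect
  distributions, block-structured covariance modules, internal-standard
  channels, batch effects, and community responses driven by planted
  standardized path coefficients.
- **`qc`** — feature-table quality control: pseudospectrum grouping by
  co-elution and cross-sample correlation (single linkage, r >= 0.7),
  ammonium-adduct removal (NH4+/H+ spacing 17.026549 Da), representative
  selection by maximum mean abundance, and a per-feature batch-effect
  ANOVA filter (p < 0.10).
- **`annotate`** — compound-class annotation: nitrogen-rule parity
  partition of nominal protonated masses, relative mass defect in ppm,
  Gaussian-mixture clustering over standardized (rt, m/z, RMD) with BIC
  model selection, class-window labeling, and normalization to
  class-matched internal standards (naringenin / naringin /
  cholecystokinin fragment) and dry extracted mass.
- **`diversity`** — Shannon effective numbers (Hill q=1) aggregated over
  hierarchy levels, Manhattan / Jaccard distance matrices, multivariate
  dispersion around group centroids in principal-coordinate space (with
  negative-eigenvalue correction) plus its homogeneity ANOVA, PERMANOVA
  with exact enumeration for small designs, a dispersion gate for
  composition tests, OLS gradient models, and parasitoid-success rates.
- **`network`** — unsigned weighted correlation networks: soft-threshold
  power selection by scale-free fit, topological overlap, average-linkage
  module detection with a static tree cut (min size 5), first-PC module
  eigenvalues with kME hub scores, eigenvalue-correlation merging at
  height 0.25, and module-partitioned dispersion ranking.
- **`pathmodel`** — observed-variable path analysis: a small `y ~ x` /
  `a ~~ b` model syntax, maximum-likelihood fitting of the implied
  covariance (chi-square with the n-1 convention, AIC), iterative pruning
  of tagged chemistry paths, and direct/indirect/total effect
  decomposition.
- **`pipeline` / CLI** — one-config orchestration of the full chain:
  simulate or load data -> QC -> annotate/normalize -> diversity and
  dispersion/composition statistics -> network modules -> path models,
  with a JSON run report including the module x class confusion matrix.

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (hand oracles,
brute-force enumerations, planted-structure recovery, Monte-Carlo
calibration); the rest are unit and property tests per module.

## CLI

```bash
phytocommune simulate --seed 1 --out data/            # synthetic dataset + truth
phytocommune qc --features data/feature_table.csv --metadata data/metadata.csv \
    --rt-window 5 --corr-min 0.7 --adduct-tol 0.005 --batch-alpha 0.10 --out out/qc
phytocommune annotate --features out/qc/features_qc.csv --metadata data/metadata.csv --out out/ann
phytocommune diversity --features out/ann/features_normalized.csv --metadata data/metadata.csv --level subsite
phytocommune dispersion --features ... --metadata ... --group-by subsite
phytocommune permanova --features ... --metadata ... --permutations 9999
phytocommune network --features ... --power 8 --min-size 5 --merge-height 0.25 --out out/net
phytocommune sem --model model.txt --data plots.csv --prune --alpha 0.05
phytocommune run --config config.yaml --seed 1 --out out/run   # full pipeline
```

`run` expects a YAML config with either a `synthetic:` block (optionally
overriding the hierarchy) or an `inputs:` block of CSV paths, plus
optional `qc:`, `annotation:`, `network:`, `dispersion:` and `sem:`
parameter overrides; all values default to the analysis constants above
and are echoed into the report.

## Data formats

Feature tables are CSV with one row per feature (`feature_id`, `rt_s`,
`mz`, optional `is_standard`/`standard_class`) followed by one column per
sample. Metadata CSV is indexed by `sample_id` with `site`, `subsite`,
`plot`, `individual`, `month`, `batch`, `elevation_m`, `dry_mass_g`.
Herbivore data are plot x collection morphotype count CSVs plus a
per-larva rearing outcome table (`adult` / `parasitoid` / `died`).
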