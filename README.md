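# phenoselect

Phenomic selection from near-infrared spectra (NIRS) in multi-environment
plant-breeding trials. The package covers the full analysis chain:

- **`phenoselect.synthetic`** — simulation of replicated field-trial
  designs (partially replicated, alpha-lattice, single replicate) with
  plot-level NIR spectra and trait values. The per-wavelength variance
  split between genotype, genotype-by-environment (G×E) and noise is
  controlled exactly, and a tunable fraction of the trait's genetic and
  G×E variance is made linearly predictable from the spectra.
- **`phenoselect.trial_models`** — REML linear mixed models for the trial
  series (`y = mu + g + l + r + b + gl + e`): variance components,
  genotype BLUEs with the mean standard error of a difference (SED),
  per-wavelength spectra BLUEs with singularity-driven wavelength removal,
  Cullis heritability, and Table-style trait summaries.
- **`phenoselect.preprocess`** — Savitzky–Golay derivative filtering
  (trimmed grid), column centering/scaling, technical-replicate averaging,
  genotype-mean aggregation, and the eight feature-engineering scenarios
  (FES 1–8) combining filtering × mean/BLUE aggregation × scaling.
- **`phenoselect.predictors`** — ridge-regression BLUP with a
  one-dimensional REML shrinkage search (`lambda = sigma2_e / sigma2_u`)
  via a single kernel eigendecomposition, and univariate NIPALS partial
  least squares with CV-based component selection.
- **`phenoselect.evaluate`** — repeated k-fold cross-validated prediction
  ability (Pearson correlation, genotype folds), Savitzky–Golay grid
  search with a parsimony tie-break, and the three breeding scenarios
  (within-environment CV, cross-environment transfer, series-level
  prediction of new genotypes from a central environment).
- **`phenoselect.dapc`** — discriminant analysis of principal components
  (PCA → optional k-means with BIC → LDA) with repeated stratified CV for
  choosing the retained PC count.
- **`phenoselect.io` / `phenoselect.cli`** — CSV dialects (plot tables,
  `wl_<nm>` spectra matrices), JSON reports with config hashes, and the
  command-line interface.

## Command line

```bash
phenoselect simulate --n-genotypes 150 --environments E1,E2,E3 --seed 1 \
    --out-dir results/sim
phenoselect fit-blues --plots results/sim/plot_table.csv \
    --spectra results/sim/plot_spectra.csv --trait trait
phenoselect preprocess --spectra results/sim/plot_spectra.csv \
    --window 49 --poly 2 --deriv 1 --out results/filtered.csv
phenoselect tune-sg --plots results/sim/plot_table.csv \
    --spectra results/sim/plot_spectra.csv --fes 8 --model rrblup \
    --cv-replicates 50 --seed 1
phenoselect scenario 1 --plots results/sim/plot_table.csv \
    --spectra results/sim/plot_spectra.csv --fes 8 --sg 2 1 29
phenoselect dapc --spectra results/sim/plot_spectra.csv \
    --plots results/sim/plot_table.csv --label environment
phenoselect run --config run.yaml --seed 1 --out-dir results/run1
```

Every result file embeds the seed and a hash of the run configuration;
re-running the same configuration reproduces the numbers byte for byte
(timestamps excluded).

## Notes on conventions

- Savitzky–Golay output grids are trimmed by `(w-1)/2` points per edge;
  derivatives are per nm.
- Column scaling statistics are always learnt on training data only
  (per CV fold, or on the training environment/series in scenarios 2–3).
- Cross-validation ability defaults to the per-fold-mean Pearson
  correlation (the pooled variant is available but carries a known
  negative bias).
- Unreplicated within-environment datasets automatically fall back to raw
  spectra in place of BLUEs.
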