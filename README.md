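# mtquant

Quantification pipeline for microtubule-pool assays, driven end-to-end by a
synthetic data generator with recorded ground truth. It implements:

- **Immunofluorescence intensity quantification** (`mtquant.intensity`):
  integrated density over a region of interest (identically positive area x
  mean gray value), positive-cutoff selection from the ROI intensity
  histogram (Otsu, background-mode + k·MAD, or half-maximum), tyr/glu
  microtubule ratio with below-detection handling, focal-plane selection by
  maximal thresholded area, microtubule-network area (threshold, closing,
  hole filling, largest component), and per-well plate normalization to a
  nuclear stain.
- **Gel densitometry** (`mtquant.fractionation`): background-subtracted band
  densities (linear baseline or rolling minimum), percent polymerized
  `100·P/(P+S)` per analyte from paired lanes, loading-control
  normalization.
- **Growth-cone invasion scoring** (`mtquant.growthcone`): total cone mask T
  from the actin/membrane union, proximal glu-occupied mask Pgc, peripheral
  ROI = T \ Pgc, and the percentage of the ROI covered by tyr-positive
  pixels.
- **Group statistics** (`mtquant.stats`): one-way ANOVA, Dunnett many-to-one
  comparisons with critical values computed by deterministic quadrature of
  the equicorrelated multivariate-t probability (no hard-coded tables),
  Student-Newman-Keuls all-pairwise stepwise testing, two-sample t-tests,
  viability normalization to percent of control, and dose-response
  summarization with a run-based shape label (flat / monotone / bimodal).
- **Synthetic fixtures** (`mtquant.synth`): filamentous two-channel cell
  images (controllable tyr/glu partition, a below-detection regime,
  z-stacks with a declared maximal plane), fan-shaped growth cones with an
  exactly tracked invasion fraction, paired P/S lane profiles with known
  polymer fractions, and dose-response plate tables (bimodal, sigmoid or
  null) with a per-well cell-count covariate. Every fixture carries a
  `GroundTruth` record and is bit-reproducible from `(params, seed)`.

## CLI

```sh
# generate a fixture directory (TIFF channels, lane/plate CSVs, ground truth)
mtquant simulate --out runs/demo --seed 1

# quantify it (results.csv + report.json with a provenance block)
mtquant quantify --in runs/demo --out runs/demo_results --seed 1

# human-readable summary
mtquant report --in runs/demo_results
```

Both commands accept `--config config.yaml` (see `mtquant.config.RunConfig`
for the schema; unknown keys are rejected). Identical config + seed yields
byte-identical fixture and result files.

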