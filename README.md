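# sctwas

Cell-type-level transcriptome-wide association studies (TWAS) from GWAS
summary statistics, with expression predictors distilled from epigenomic
feature vectors.

The workflow has three steps:

1. **Predict** — a four-layer MLP (`sctwas.ctpred`) maps a per-gene
   epigenomic feature vector (5,313 tracks aggregated over the central four
   128-bp bins of a 196,608-bp TSS-centered window) to a cell-type-specific
   expression percentile. Targets come from per-cell-type pseudobulk
   aggregation of single-cell counts (`sctwas.pseudobulk`).
2. **Linearize** — the MLP is run on personalized feature vectors for every
   individual of a reference genotype panel to form an in-silico expression
   reference; each gene's reference row is then fitted with a cis-SNP
   elastic net (`sctwas.linearize`), validated by 10-fold cross-validated
   Spearman correlation, and exported as a PredictDB-style SQLite weight
   database plus a dosage-covariance TSV.
3. **Associate** — per-gene Z-scores are computed from GWAS summary
   statistics, the SNP weights, and reference-panel dosage variances
   (`sctwas.associate`), followed by cross-cell-type statistics: ACAT
   (Cauchy) p-value combination, Bonferroni thresholds, Storey pi1/m1,
   precision/recall against a silver-standard list, LD-block accounting,
   and shared / enriched / specific cell-type classification
   (`sctwas.multicell`).

A deterministic synthetic epigenome oracle (`sctwas.simulate`) stands in
for an external sequence-to-epigenome predictor so the whole pipeline runs
at desk scale with known ground truth: genotypes with AR(1) linkage
structure, feature matrices whose central bins respond (partly
nonlinearly) to cis dosages, negative-binomial pseudobulk counts, and
marginal GWAS summary statistics from a planted-causal-gene phenotype.
External predictors can be plugged in through the
`sctwas.epifeatures.CallableBackend` adapter contract.

## CLI

```bash
# end-to-end on synthetic data
sctwas run --workdir out/demo --seed 7 --profile small

# or stage by stage, resuming from persisted artifacts
sctwas simulate   --workdir out/demo --config run.toml
sctwas pseudobulk --workdir out/demo
sctwas features   --workdir out/demo
sctwas train      --workdir out/demo
sctwas linearize  --workdir out/demo
sctwas assoc      --workdir out/demo
sctwas stats      --workdir out/demo
```

`--profile small` uses 53 feature tracks (fast); `--profile full` uses the
5,313-track geometry. A TOML config can set simulation, QC, MLP, and
elastic-net parameter blocks; every run writes `manifest.json` with seeds
and SHA-256 hashes of all artifacts.

Example `run.toml`:

```toml
workdir = "out/demo"
seed = 7
profile = "small"

[simulation]
n_individuals = 60
n_genes = 30
n_cell_types = 2
gwas_n = 3000
causal_genes = [["G0004", "CT0", 1.2]]

[mlp]
max_epochs = 120

[elastic_net]
n_alphas = 15
```

## File formats

VCF 4.2 (genotypes), MatrixMarket + TSV (cells), TSV (annotation,
pseudobulk, percentiles, summary statistics, covariances), SQLite
(PredictDB-style weights), HDF5 or TSV (feature vectors), JSON (ground
truth, manifests). Coordinates are 0-based half-open internally and
1-based only at I/O boundaries.
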