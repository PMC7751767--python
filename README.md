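# fieldomics

Spatially aware analysis of single-plant field omics data: a reusable
pipeline for removing systematic effects from molecular profiles of plants
grown on a field grid, screening for spatial autocorrelation, scoring
expression variability, inferring spatially adjusted co-expression networks
with guilt-by-association function prediction, and predicting individual
phenotypes from molecular features — plus a synthetic field-data generator
with known ground truth to exercise every stage.

## What it does

| module | role |
| --- | --- |
| `synthetic_field` | field layouts, spatial Gaussian-process factors (spherical kernel + nugget), count-type expression, metabolites with missingness, phenotypes, planted ontology modules |
| `preprocess` | CPM filtering, median-of-ratios size factors, pseudocount + log2; Grubbs outlier masking, low-rank imputation, quantile normalization |
| `spatial_lme` | per-feature REML fits of fixed group effects with spherical-covariance errors, variance decomposition, matrix residualization |
| `spatial_stats` | Moran's I screening (inverse-distance weights), BH adjustment, Ward clustering of autocorrelated profiles, cluster-phenotype correlation, distance-matrix layer correlations |
| `variability` | CV, gamma-GLM mean-CV² trend, normCV scores, rank-based ontology tests |
| `coexpr_network` | spatially adjusted pairwise correlations (REML; exact Pearson in the degenerate case), Bonferroni edge selection, fixed-edge-count thresholding, topology statistics |
| `go_prediction` | OBO parsing, true-path propagation, hypergeometric neighborhood enrichment, recall/precision/F curves, relative-performance classification |
| `phenotype_pred` | rational-quadratic GLS single-feature associations, nested 10-fold CV elastic nets / random forests, pooled/median out-of-fold R², permutation p-values |
| `pipeline` | one CLI and config orchestrating all stages over TSV/OBO inputs |

## CLI

```sh
fieldomics simulate --out demo --rows 6 --cols 10 --genes 60 --seed 7
fieldomics run --data-dir demo --out-dir demo_run --seed 1
fieldomics correct counts_log2.tsv layout.tsv --effects batch,doh,snp
fieldomics autocorr residuals.tsv layout.tsv --out moran.tsv
fieldomics network residuals.tsv layout.tsv --alpha 0.01
```

`fieldomics run` writes every stage output plus a `manifest.json` with
config, input hashes and stage tallies; re-runs with the same seed are
byte-identical.

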