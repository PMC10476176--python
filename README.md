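# phyloexpr

Phylogeny-aware cross-species comparative transcriptomics of longevity,
as a tested, reusable pipeline:

- **Normalization & specificity** — count filtering (low-expression,
  dominant-gene, minimum-species), TMM-factor computation, log2(TMM-RPKM+1)
  normalization, per-species aggregation, the Tau specificity index, and
  top-variance PCA.
- **Life history** — allometric residual traits (MLres, FTMres), a
  Phylopars-style Brownian-motion conditional-expectation imputer (joint
  multivariate-normal model with phylogenetic trait covariance ⊗ tree
  covariance plus diagonal noise, REML-fitted), PCoA phylogenetic
  eigenvectors, and a benchmarking harness (NRMSE, slope bias) over
  MCAR / weight-dependent / distance-dependent missingness grids.
- **Per-gene association** — OLS / Brownian-motion / Ornstein–Uhlenbeck
  regressions of expression on longevity traits with ML model selection,
  the two-step robust P-value procedure (P_robust after dropping the
  largest-residual species; P_max over subsequent leave-one-out refits),
  Westfall–Young min-P family-wise adjustment by trait resampling
  (shuffle or parametric-BM modes), and the ≥2-trait longevity-gene caller
  at the P_robust.adj < 0.005 / P_max.adj < 0.05 cutoffs.
- **Polygenic enrichment** — SUMSTAT gene-set scores with directional
  scoring, within-bin covariate rescaling, normal/empirical null P values,
  and Fisher-exact category enrichment (pLI, haploinsufficiency, gene age,
  disease, cancer categories).
- **Selection integration** — exact 1-D PAM lifespan partitioning, and the
  IU / RU / ID / RD classification crossing association direction with the
  relaxation parameter k from externally produced selection tables.
- **Synthetic data** — seeded generators for ultrametric trees,
  log-allometric traits with BM residuals, trait-tracking expression under
  iid/BM/OU residuals with ortholog-dropout masks, negative-binomial
  counts, missingness mechanisms, and coupled selection tables, all with
  serialized ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the heavier calibration / recovery /
benchmark checks (several minutes); the rest of the suite is fast.

## CLI

All stages are subcommands of a single entry point; every randomized
stage takes `--seed` and writes the exact config used next to its
outputs.

```sh
# simulate a full dataset (tree, counts, metadata, traits, truth, selection)
phyloexpr simulate --seed 1 --out-dir sim --n-species 32 --n-genes 200

# filter + TMM-RPKM normalize + tau + PCA
phyloexpr normalize --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --lengths sim/gene_lengths.tsv --min-species 10 --out-dir norm

# impute missing life-history values (add --evaluate for the benchmark grid)
phyloexpr impute --life-history sim/life_history.tsv --tree sim/tree.nwk \
    --out-dir imp --seed 1

# per-gene robust phylogenetic regression + longevity-gene calling
phyloexpr pgls --species-mean norm/species_mean.liver.tsv \
    --life-history imp/imputed.tsv --tree sim/tree.nwk \
    --out-dir pgls --seed 1 --n-perm 1000

# SUMSTAT gene-set enrichment
phyloexpr enrich --scores pgls/associations.tsv --gmt sets.gmt \
    --score-column slope --direction positive --out-dir enr

# IU/RU/ID/RD classification against a selection (k) table
phyloexpr classify --calls pgls/longevity_genes.tsv \
    --selection sim/selection.tsv --out-dir cls

# everything end to end on a small simulated dataset
phyloexpr run-all --seed 1 --out-dir pipeline_out
```

## File formats

TSV for matrices and tables (genes × samples with a `gene_id` column;
sample metadata keyed by `sample_id` with `species`, `tissue`,
`replicate`, `batch`), Newick for trees (branch lengths in Myr), GMT for
gene sets, and a TSV schema `gene  k  p  omega1  omega2  omega3` for
selection tables. Absent orthologs are `NA` cells — a masked state
distinct from zero counts.
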