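# sigconnect

Reproducibility QC, connectivity mapping and gene-set enrichment for
targeted (surrogate-panel) and whole-transcriptome count data, with a
synthetic-study generator so the entire pipeline runs end to end without any
external downloads.

The pipeline covers:

- **expression_core** (`sigconnect.expression`) — count-matrix data model and
  TSV I/O, low-count filtering (strict `mean < 10` removal), isoform
  aggregation by summation, average log2 fold-change (L2FC) profiles,
  probe-to-gene collapsing, relative-viability percentages and the
  hyphen-joined treatment-id convention
  (`chemical-<conc>uM-24h-rn-hep-<study>`).
- **qc_metrics** (`sigconnect.qc`) — per-sample read depth and zero-count
  fractions on raw counts, technical (within-batch) and biological
  (cross-batch, replicate-matched) Pearson correlations, median-of-ratios
  size factors with a `log2(x/s + 1)` variance-stabilization stand-in, and
  PCA scores for batch-effect visualization.
- **diffexpr** (`sigconnect.diffexpr`) — a per-gene linear-model DEG caller
  on stabilized log counts (additive batch covariate in `corrected` mode),
  Benjamini-Hochberg adjustment, DEG overlap/concordance reports, union-DEG
  matrices and Venn counts. Externally computed DEG tables with the same TSV
  schema can be dropped in.
- **signature_builder** (`sigconnect.signatures`) — top-`nq` up/down query
  signatures and top-`nr` restricted reference profiles with deterministic
  lexicographic tie-breaking; default grids `nq = 100..1000 by 100`,
  `nr = 1000..6000 by 1000`.
- **connectivity_scores** (`sigconnect.connectivity`) — the five scoring
  algorithms: signed Jaccard index (`sji`), bidirectional gene set total
  enrichment score (`gtes`, built on a shared weighted Kolmogorov-Smirnov
  running-sum statistic), extreme cosine (`xc`), extreme Pearson (`xcp`) and
  extreme Spearman (`xcs`), plus ranked retrieval with NaN-last ordering.
- **retrieval_benchmark** (`sigconnect.benchmark`) — rank-of-correct-hit
  evaluation (chemical-identity matching, punctuation-insensitive),
  Fr1/Fr5/Fr10 metrics, the exhaustive (algorithm, nq, nr) grid and
  best-rank summary tables with median/mean rank rows.
- **gsea_hallmark** (`sigconnect.gsea`) — GMT parsing, collection
  restriction with size flags (sets outside [15, 500] are scored but
  flagged), permutation GSEA with size-matched random-set nulls, NES/p/FDR,
  NES concordance between assays, and signed significance classification.
- **nes_clustering** (`sigconnect.clustering`) — Ward clustering of
  L2FC/NES columns (ward.D2 convention: unsquared Euclidean input),
  newick dendrogram export, ST/WT nearest-neighbor pairing, Welch
  cluster-difference tests with BH correction and discriminating-set
  selection (`delta > 2.5`, `fdr < 5e-4`, both strict).
- **synthetic_data** (`sigconnect.simulate`) — negative-binomial count
  simulation with mechanism programs, per-gene batch effects, lognormal
  library sizes and dropout calibrated to 15-40% per-sample zero fractions;
  a program-stratified surrogate panel; and a decoy-laden reference L2FC
  database with a ground-truth answer key.

## CLI

All stages read and write plain TSV; identical inputs and seeds give
byte-identical outputs.

```bash
sigconnect simulate --seed 0 --out-dir data/           # synthetic study
sigconnect qc       --counts data/counts_wt.tsv --annotation data/annotation_wt.tsv \
                    --meta data/meta_wt.tsv --out qc.tsv
sigconnect profiles --counts data/counts_wt.tsv --annotation data/annotation_wt.tsv \
                    --meta data/meta_wt.tsv --pseudocount 0.5 --out profiles.tsv
sigconnect degs     --counts data/counts_wt.tsv --annotation data/annotation_wt.tsv \
                    --meta data/meta_wt.tsv --chemical cmpd-01 --concentration 50 \
                    --mode corrected --out degs.tsv
sigconnect connect  --query profiles.tsv --db data/reference.tsv \
                    --nq 200 --nr 1000 --algorithm sji --top 10 --out hits.tsv
sigconnect benchmark --queries profiles.tsv --db data/reference.tsv \
                    --answer-key data/answer_key.tsv \
                    --nq 100:1000:100 --nr 1000:6000:1000 \
                    --algorithms sji,gtes,xc,xcp,xcs --out grid.tsv
sigconnect gsea     --ranking ranking.tsv --gmt data/gene_sets.gmt \
                    --nperm 1000 --seed 17 --out gsea.tsv
sigconnect cluster  --nes nes.tsv --k 3 --delta-min 2.5 --fdr-max 5e-4 \
                    --out-prefix clust
```

## Documented stand-ins

- The DEG caller replaces a negative-binomial Wald test with a per-gene
  linear model on `log2(count/size_factor + 0.5)`; exact parity with
  NB-GLM tooling is out of scope, and external DEG tables are accepted.
- Variance stabilization is median-of-ratios size factors plus
  `log2(x/s + 1)`, preserving rank/variance behaviour for PCA only.
- The `sji` normalization (mean of signed per-pair Jaccard indices, bounded
  in [-1, 1]) and the bidirectional `gtes` composition (query tails scored
  in the reference ranking plus reference tails in the query ranking,
  bounded in [-4, 4]) are documented choices; each is isolated behind a
  single function for easy substitution.
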