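# evmirna

Analysis pipeline for extracellular-vesicle (EV) small-RNA count data across
multiple cell-source groups. It covers:

- **Harmonization** of miRNA count files coming from two different alignment
  pipelines (zero-filling of features absent on one side, arm-suffix
  resolution of `-3p`/`-5p`-less names using the sole expressed arm in the
  reference pipeline plus chromosome-location agreement).
- **Normalization**: counts per million (CPM), median-of-ratios size factors,
  `log2(normalized + 1)`, and PCA with variance explained.
- **Detection partitioning**: assignment of each detected miRNA to the exact
  subset of groups expressing it (the cells of a multi-group Venn), under
  pluggable detection rules, plus per-group top-k abundance rankings with
  commonly/uniquely-abundant flags.
- **Differential expression**: all-pairwise negative-binomial Wald tests with
  trend-shrunken method-of-moments dispersions and Benjamini–Hochberg FDR,
  applied per pairwise table.
- **Signature calling**: the tissue-specificity index τ
  (`τ = Σ(1 − x_i/x_max)/(N−1)`), consensus-upregulated sets, and a
  three-criteria key-miRNA filter (abundance ∧ upregulation ∧ enrichment,
  where enrichment is `τ > 0.7` or fold change > 5 in ≥ 2 comparisons).
- **Group statistics**: an assumption-driven router that sends grouped
  measurements to ANOVA+Tukey, Brown–Forsythe/Welch ANOVA+Dunnett T3,
  Kruskal–Wallis+Dunn, unpaired/Welch t, lognormal t/Welch, or Mann–Whitney
  based on Shapiro–Wilk and spread tests.
- **Simulation**: a seeded negative-binomial count generator with the study
  design (groups CM, CF, HCMVEC, Mac with 3/3/3/4 replicates), known ground
  truth, structural zeros, and two pipeline file dialects, so every stage is
  testable offline.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py::TestCriterion1DetectionBenchmark` requires the
deposited count data for GEO series **GSE311002** prepared under
`data/GSE311002/` (see below); it fails with instructions when the data is
absent, as in offline environments. All other tests are self-contained.

## CLI

```bash
evmirna simulate  --outdir sim --n-features 500 --seed 1 --dialects
evmirna harmonize --primary sim/dialect_a.tsv --reference sim/dialect_b.tsv \
                  --metadata sim/metadata.tsv --annotations sim/annotations.tsv --outdir out
evmirna landscape --counts sim/counts.tsv --metadata sim/metadata.tsv --outdir out
evmirna diffexp   --counts sim/counts.tsv --metadata sim/metadata.tsv --outdir out
evmirna signature --counts sim/counts.tsv --metadata sim/metadata.tsv --outdir out
evmirna groupstats --table measurements.tsv --design two_group --scale-hint lognormal_candidate
evmirna run-all   --config pipeline.yaml
```

Count files are tab-separated (first column header `miRNA`, one column per
sample); metadata is a two-column `sample`/`group` table. Exit codes:
0 success, 2 configuration error, 3 data/format error, 4 statistical
degeneracy.

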