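# dmrkit

A toolkit for studying focal, canonical DNA hypomethylation from
whole-genome bisulfite sequencing, end to end:

- **DMR calling** from per-CpG methylation tables: seed-and-extend
  segmentation over per-CpG group-mean differences, an exact Mann–Whitney
  rank test on per-sample regional means, Benjamini–Hochberg FDR control,
  merging of regions closer than 50 bp, and a within-group-SD
  ("canonicality") filter. Default thresholds: ≥10 CpGs, |mean difference|
  ≥ 0.2, q ≤ 0.05, within-group SD ≤ 0.1.
- **Covariate sensitivity regression**: per-DMR OLS of regional methylation
  on genotype + sex + log(age).
- **Annotation enrichment**: fraction of gene bodies / promoters / TSS
  windows / enhancers containing at least one DMR (≥1 bp overlap), with
  pairwise chi-squared / Fisher tests, plus per-sample per-category mean
  methylation.
- **Cross-genome correspondence**: UCSC chain-file liftover of DMR
  coordinates, direct (≥1 bp) and within-10-kb proximity comparison of two
  DMR sets, in both directions.
- **Single-cell integration**: cell QC (≥250 expressed genes, ≥500 reads,
  ≤10% mitochondrial — strict inequalities), depth normalization to 10,000
  with log1p, per-cluster Welch-test DEG calling with conjunctive p ≤ 0.05
  and |log2 ratio| ≥ 1 gates, recurrent-DEG detection, expressing-fraction
  Fisher tests, nearest-centroid lineage annotation against reference
  profiles, and DEG↔DMR proximity linking.
- **Synthetic data generator** (`dmrkit.simulate`): seeded CpG landscapes
  with islands, planted hypomethylated regions whose depth scales with a
  severity tier, beta-binomial read counts at ~18x coverage, block-shuffled
  genome pairs with valid chain files, and clustered single-cell count
  matrices with planted DEGs — all with ground-truth tables for recovery
  scoring.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: worked-example
arithmetic checks, brute-force oracle equivalence (BH, exact Mann–Whitney,
Fisher, chi-squared, interval queries), planted-region recovery, null
calibration and severity ordering over 20 seeds, liftover round trips, and
the single-cell QC/DEG gates.

## CLI

```bash
# end-to-end demo on synthetic data
dmrkit run --seed 1 --out demo/

# or stage by stage
dmrkit simulate --seed 1 --out sim/
dmrkit call-dmrs --meth-dir sim/meth --metadata sim/metadata.tsv \
    --test mutant --ref control --out-prefix dmrs/calls
dmrkit annotate --dmrs dmrs/calls.dmrs.tsv --annotations sim/annotations.bed \
    --meth-dir sim/meth --metadata sim/metadata.tsv --out-prefix ann/out
dmrkit liftover-compare --a dmrs/calls.dmrs.tsv --b other.dmrs.tsv \
    --chain sim/forward.chain --k 10000 --out cmp/out
dmrkit scrna-qc --scrna-dir sim/scrna --out-prefix sc/qc
dmrkit scrna-deg --scrna-dir sim/scrna --test mutant --ref control \
    --out-prefix sc/deg
dmrkit integrate --degs sc/deg.degs.tsv --dmrs dmrs/calls.dmrs.tsv \
    --genes sim/annotations.bed --k 10000 --out-prefix links/out
dmrkit report --run-dir demo/ --out demo/report.tsv
```

Calling parameters can be overridden with `--params params.yaml`, whose
keys mirror `DmrParams` field names (`min_cpgs`, `min_mean_diff`,
`max_fdr`, `max_within_group_sd`, `merge_gap_bp`, ...). Every run writes a
`*.manifest.json` with the full parameter echo and input checksums.
Exit codes: 0 ok, 2 validation error, 3 missing input.

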