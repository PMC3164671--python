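# striatarget

Integrative identification of transcription-factor direct targets, built as a
tested, reusable pipeline over synthetic data with known ground truth:

- **peak annotation** — map binding peaks to genes by TSS-distance windows
  (10 kb outer / 1 kb inner) and classify genomic context (TSS overlap,
  exon, intron, 5'/3' flank);
- **differential expression** — per-gene Welch t on log2 two-group data,
  fold-change (≥1.25) and p (<0.05) thresholds, Benjamini–Hochberg FDR, and
  a two-tailed Fisher exact test for overrepresentation questions;
- **motif analysis** — TRANSFAC-style PWM log2-odds scanning with an
  empirically sampled genomic background (Z-score p < 0.001 against the
  mean/SD of scores at up to 10 M non-repeat locations), degenerate
  consensus expansion (`AGG/TTCA`, `AG[AT]GTG`), and exhaustive canonical
  k-mer discovery as a deterministic stand-in for EM motif finders;
- **conservation** — branch-length scoring of motif instances over a
  multi-species alignment and Newick tree (total length of the minimal
  spanning subtree of the matching species), with the retention rule
  *score > 1 in ≥ 4 distinct peak sequences*;
- **integration & enrichment** — ChIP × expression intersection into a
  direct-target list with an up/down split, and hypergeometric / EASE
  gene-set enrichment;
- **synthetic data** — seeded generators for a repeat-masked genome, gene
  models, peaks with planted motif instances, alignments evolved along a
  fixed tree (Jukes–Cantor) with elevated motif conservation, and an
  expression matrix with planted fold changes — all with a ground-truth
  record used by the parameter-recovery tests.

All coordinates are 0-based half-open internally; BED is native and 1-based
inclusive gene tables are converted at the boundary.

## Command line

```bash
# write a complete synthetic dataset (genome, peaks, genes, expression,
# alignments, tree, PWMs, gene sets, config, ground truth)
striatarget demo --seed 7 --out demo_data

# run the whole pipeline from its config; outputs per-stage TSVs
# (with stage/config-hash/seed headers) plus report.json
striatarget -v run --config demo_data/config.yaml --out demo_run
```

Per-stage subcommands (`annotate`, `de`, `integrate`, `scan`, `discover`,
`conserve`, `enrich`) read and write the same TSVs; see `striatarget
COMMAND --help`. Reruns with the same config are byte-identical.

## Layout

```
src/striatarget/
  io_formats.py             FASTA/BED/gene-table/TRANSFAC/MAF-like/Newick/TSV IO
  synthetic_data.py         seeded generators + ground truth
  peak_annotation.py        TSS windows and location classes
  differential_expression.py  Welch t, BH FDR, thresholds, Fisher exact
  motif_analysis.py         log-odds PWMs, empirical background, k-mers
  conservation.py           branch-length scores and retention rule
  integration_enrichment.py target integration, hypergeometric/EASE
  pipeline.py               orchestration, config, demo dataset
  cli.py                    click entry points
  data/                     printed-table fixture, toy PWMs
```
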