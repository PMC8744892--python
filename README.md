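# ernascope

Enhancer RNAs (eRNAs) are short-lived, mostly non-polyadenylated
transcripts produced at active cis-regulatory elements. When a
ligand-activated transcription factor such as the glucocorticoid receptor
(GR) binds an intergenic site, the presence and regulation of eRNA at
that site is one of the most direct readouts of the element's activity.
`ernascope` is a Python library for finding and analysing such
eRNA-producing binding sites from nascent-transcription data (4sU-seq /
GRO-seq fragments) together with ChIP-seq peak calls — and for testing
every step of that analysis on synthetic experiments with known ground
truth.

It is aimed at computational biologists who have (or can simulate)
per-replicate peak calls, fragment-level nascent-transcription evidence,
and chromatin-feature count data, and who want a tested, reproducible
implementation of this analysis rather than a pile of one-off scripts.

## What it computes

- **Reproducible cistrome** — peaks with ≥ 1 bp overlap between two
  biological replicates, blacklist filtering, nearest-*expressed*-gene
  annotation, and location classes; a site is *intergenic* when it
  overlaps no gene feature and its center is > 1 kb from every TSS.
- **Quantification** — unstranded fragment counting in fixed windows
  (MAPQ ≥ 20, fragment length 50–1000 bp), with the windowed TPM

      TPM[f, s] = counts[f, s] · 1000 / (library_size[s] · length[f])

  and an expression gate at the 5th percentile of the non-zero mean TPM.
- **eGBS calling** — two routes: transcript-based (expressed intergenic
  transcripts overlapping an intergenic bound site by ≥ 1 bp) and
  site-centric (nascent counts in 588 bp windows — four nucleosomes —
  around every reproducible site, gated, then filtered to intergenic
  sites), plus polyadenylation designation and active/poised chromatin
  classes (ATAC ∧ H3K4me1 ∧ ± H3K27ac at 10 bp overlap resolution).
- **Differential expression** — a self-contained negative-binomial Wald
  test, `K ~ NB(μ·s_j·2^(x·LFC), α)` with `var = μ + αμ²`, whose size
  factors `s_j` are injectable: transcriptome-derived factors for eRNA
  windows, reads-in-peaks (RiP) reciprocal factors for chromatin assays.
  Regulation classes use padj < 0.05 (Benjamini–Hochberg) and fold
  change > 1.5.
- **Chromatin dynamics** — per-assay differential occupancy at regulated
  enhancers, Spearman correlation of feature changes with eRNA changes,
  and Kolmogorov–Smirnov-gated Wilcoxon–Mann–Whitney tests of each
  regulation group against the unchanged reference.
- **Tissue comparison** — overlap of two tissues' eGBS repertoires at
  1 bp resolution, of their nearest-target-gene sets (flagging
  *convergent* genes shared without any site overlap), and the
  tissue-specificity of regulated gene programs.
- **Synthetic experiments** — a first-class generator
  (`ernascope.synthetic`) that emits the whole input universe (GTF, BED
  peak sets, fragment BEDs with mapping-quality columns, count matrices)
  with controlled reproducibility, tissue sharing, condition effects and
  chromatin-feature coupling, and a truth table for every site, gene and
  transcript.

## Worked example

`examples/` contains one narrative script per capability. The first one
simulates an experiment, rebuilds the cistrome and calls eRNA-producing
sites:

```sh
$ python examples/01_call_enhancer_rnas.py
reproducible binding sites (>=1 bp overlap between replicates): 500
eRNA-producing intergenic sites (eGBS): 200 (gate threshold 1.05e-05 TPM)
recall 99.5%, precision 99.5% vs truth
```

500 of the simulated peaks replicate; 400 of them are intergenic, 200
carry true eRNA transcription, and the caller recovers those almost
exactly — the percentile gate removes the 50-fold weaker background
transcription at the rest. Differential testing with
transcriptome-substituted size factors then recovers the simulated
regulation:

```sh
$ python examples/02_differential_erna_expression.py
...
induced eRNAs: 61, repressed: 59 of 200 eGBS (padj < 0.05, |fold change| > 1.5)
truth-differential enhancers recovered: 99.2%
```

(60 induced and 60 repressed enhancers at |log2FC| = 2 were simulated.)
The remaining scripts demonstrate chromatin-feature correlation (open
chromatin, H3K27ac and BRD4 track eRNA output; H3K4 methylation does
not) and the two-tissue comparison.

The same analysis is scriptable end-to-end from a shell:

```sh
ernascope simulate --seed 1 --out run/          # full synthetic run
ernascope cistrome --rep1 r1.bed --rep2 r2.bed --gtf genes.gtf --out cistrome.tsv
ernascope quantify --fragments s1.bed --windows cistrome.tsv --width 588 --out counts.tsv
ernascope diff --counts counts.tsv --samples samples.tsv --out de.tsv
```

Every written table carries a JSON sidecar with the stage, package
version and config hash; a rerun with the same config and seed is
byte-identical.

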