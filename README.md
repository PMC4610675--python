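# txcomplexity

Analysis toolkit for asking whether a gene set is unusual in its
*transcript complexity* and splicing architecture, relative to
length-matched random control lists drawn from a reference pool:

- **annotation model** — GTF and UCSC refFlat/refGene parsing into a
  locus → transcript → exon hierarchy (0-based half-open coordinates),
  with locus-span lengths, a >1 Mb locus filter, and plain-text gene
  lists (optionally with per-symbol study-evidence counts).
- **complexity enrichment** — transcripts-per-locus statistics
  (mean, 1..5/6+ histogram), a length-matched bootstrap engine
  (each control gene within ±10% of its matched test gene's locus
  length, 1000 control lists, empirical p floored at 1/N), plus
  robustness helpers (leave-top-k-out, evidence filtering,
  mRNA-length / large-exon statistics, disease-database enrichment of
  >5-transcript loci).
- **sequence features** — GC content of 60-nt windows centred on the
  TSS, first donor, first acceptor and internal donor/acceptor splice
  boundaries; the donor–acceptor GC gap; canonical splice-motif
  scanning (GGTAA/GGTGA donors, CAGGT/TAGGT acceptors).
- **splice events** — pairwise, strand-aware classification of
  structural differences between a locus's transcripts into skipped
  exon / alternative donor / alternative acceptor / other, with
  locus-wide signature deduplication and event-type proportion
  bootstraps.
- **isoform expression** — transcript × tissue abundance tables,
  highest-expressed-variant per gene, tissue dominance fractions, and
  bootstrap enrichment of lung (or any tissue) dominance.
- **synthetic data** — a generator for annotations, genome sequence,
  expression tables, gene lists and disease-database memberships with
  planted, machine-checkable ground truth, so the entire pipeline is
  testable offline.

## CLI

```bash
# generate a synthetic bundle (GTF + FASTA + expression TSV + lists + truth)
txc synth --out demo/ --seed 1 --n-loci 300

# length-matched bootstrap of mean transcripts per locus
txc complexity --list demo/gene_list.txt --annotation demo/annotation.gtf \
    --pool demo/pool.txt --stat mean_transcripts --n 1000 --seed 1

# GC windows, donor-acceptor gap, canonical motif fractions
txc gc --list demo/gene_list.txt --annotation demo/annotation.gtf \
    --genome demo/genome.fa

# splice-event classification and proportions
txc events --list demo/gene_list.txt --annotation demo/annotation.gtf

# tissue dominance of the top isoform per gene
txc tissue --list demo/gene_list.txt --expression demo/expression.tsv

# full pipeline from a YAML config
txc run --config run.yaml
```

A `run.yaml` looks like:

```yaml
annotation: demo/annotation.gtf      # or a refFlat file + annotation_format: refflat
genome: demo/genome.fa               # optional; required by the gc stage
expression: demo/expression.tsv      # optional; required by the tissue stage
gene_list: demo/gene_list.txt
pool: demo/pool.txt
stages: [complexity, gc, events, tissue]
n_lists: 1000
tolerance: 0.10
window: 60
seed: 1
out_dir: results/run1
```

Each stage writes a TSV plus a combined `summary.json`; all randomness
fans out from the root seed via fixed per-stage substreams, so reruns
with the same config and seed are identical.

## Expression table format

TSV with columns `transcript_id`, `gene_symbol`, then one column per
tissue holding non-negative FPKM-like abundances (one row per
transcript).

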