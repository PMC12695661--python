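# euseqtools

Toolkit for desk-scale analysis of nascent-transcription (EU-seq style)
perturbation experiments: from strand-aware windowed fragment counting
through asymmetry-corrected fold changes, a fold-change regulation-class
taxonomy with replicate-reproducibility filtering, gene-set overlap
statistics, and promoter-centric CTCF/RAD21/Pol II/ATAC annotation.
A bundled synthetic-data generator plants known ground truth for every
stage so the whole pipeline is testable without any external download.

## Modules

| module | what it does |
| --- | --- |
| `euseqtools.simulate` | miniature genomes: gene models, NB replicate counts with planted fold changes, BED fragments, CTCF/RAD21 peaks with oriented motifs, Pol II/ATAC signals |
| `euseqtools.annotation` | representative-transcript selection (expression + promoter-mark support, longest-isoform fallback) and counting/promoter/antisense window geometry |
| `euseqtools.quantify` | strand-aware fragment counting with exclusion regions, antisense quantification, TPM, low-count/expression filters |
| `euseqtools.differential` | median-of-ratios size factors, asymmetry-corrected log2 fold changes, per-replicate fold changes, Pearson summaries |
| `euseqtools.classify` | regulation classes (HU/IU/SU/NC/SD/ID/HD and variants), small-class merging, two-time-point averaging, reproducibility filter, upstream-antisense calls |
| `euseqtools.setstats` | Fisher overlap enrichment, fold enrichment, Mann–Whitney U with BH correction, two-sample KS, proximity enrichment vs random gene controls |
| `euseqtools.regannot` | promoter peak geometry, PWM motif orientation relative to the gene, anchored Pol II normalization, ATAC differential accessibility with CTCF-height quartiles |
| `euseqtools.cli` | `euseq` command with `simulate / annotate / count / diff / classify / enrich / regannot / run-all` subcommands |

## CLI quick start

```bash
# simulate a dataset with ground truth, then run the pipeline end to end
euseq run-all --out run1 --seed 7 --force

# or stage by stage
euseq simulate --out ds --seed 7 --genes 100
euseq count --fragments ds/fragments --gene-models ds/gene_models.tsv --out counts.tsv
euseq diff --counts counts.tsv --samples ds/samples.tsv \
    --gene-models ds/gene_models.tsv --out diff.tsv
euseq classify --diff diff.tsv --scheme standard --out classes.tsv
```

Configuration files are YAML/JSON; flags override file values. Exit codes:
0 success, 2 validation error, 1 runtime error. All randomness derives from
a single seed; reruns with the same config are byte-identical.

## Conventions

- GTF on disk is 1-based inclusive; BED/narrowPeak 0-based half-open. All
  in-memory intervals are 0-based half-open; conversion lives in
  `euseqtools.io`.
- Counting windows run from the TSS toward the TES and are capped at
  30/90/240 kb for 30/60/120-minute treatments (full gene otherwise).
- The upstream antisense window spans −1.7 kb to −200 bp from the TSS on
  the opposite strand, in gene-strand coordinates.
- Signed peak distances are gene-strand relative (negative = upstream).
- Motif orientation (forward/reverse/both/none) is relative to the gene's
  direction of transcription.

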