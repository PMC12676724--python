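# endotrawl

Discovery, quality scoring and coverage-based detection of tiny (~234-375 kb)
endosymbiont genomes in metagenomes, plus temporal analyses of their
abundance in amplicon count tables. Every stage is testable offline against
a synthetic-data generator with known ground truth.

## What it does

The package chains the stages of a targeted genome-recovery funnel:

1. **simdata** — plants circular symbiont genomes carrying marker genes with
   conserved gene order, simulates reads over a background community,
   fragments genomes into "assemblies", and generates multi-year taxon count
   tables with seasonal blooms. Deterministic per seed; every artifact comes
   with a ground-truth record.
2. **aligncore** — affine-gap local alignment (nucleotide and
   translated-protein via six reading frames), exact k-mer seeded read
   mapping and long-sequence hit finding. Hits can be exported as a
   BLAST-outfmt-6-like TSV.
3. **prescreen** — sequential two-marker read triage using the BLAST Score
   Ratio: datasets are screened for `tlcA` first, survivors for `nosZ`, with
   a strict >5-fold marker-coverage gate at each stage.
4. **recruit** — reference-guided contig recruitment (contigs strictly
   longer than 3 kb with a convincing hit), assembly statistics (N50,
   largest contig), terminal-repeat circularity detection, and a gene-order
   (synteny) audit that flags putative binning errors.
5. **quality** — ORF calling, custom marker-set completeness/contamination
   (e.g. 30/55 markers -> 54.55%), rRNA presence, high/medium/low quality
   tiers, and 16S species assignment (best hit, identity strictly > 98.7%).
6. **detect** — presence calling from per-base coverage using
   `expected breadth = 1 - exp(-0.883 * depth)`; a genome is present when
   its observed breadth is within 15% of expectation (one-sided by default).
7. **timeseries** — relative abundances with family aggregation, detection
   fractions across sampling units, fall-winter season labels
   (21 Sep - 21 Mar inclusive), coexistence richness, and robust bloom
   calling (median + 5 x MAD with a relative-abundance peak floor).
8. **interface** — FASTA/FASTQ/TSV/JSON/YAML I/O, pipeline configuration,
   the end-to-end runner with a reproducible run manifest, and the CLI.

## Command line

```bash
endotrawl simulate --outdir scenario --seed 1            # synthetic inputs
endotrawl screen --reads scenario/reads.fastq --markers scenario/markers.faa \
    --bsr-min 0.4 --cov-min 5 --outdir out
endotrawl recruit --contigs scenario/contigs.fasta \
    --references scenario/reference.fasta --outdir out
endotrawl qc --bin out/bin_reference.fasta --markers scenario/markers.faa --outdir out
endotrawl detect --reads scenario/reads.fastq --genome out/bin_reference.fasta --outdir out
endotrawl timeseries --table counts.tsv --plot blooms.png --outdir out
endotrawl run --config config.yaml                       # full funnel
```

`endotrawl run` executes screen -> recruit -> qc -> detect, skipping
downstream stages for datasets that fail the prescreen, and writes JSON +
TSV reports plus a digest manifest under the configured output directory.
A config template is any YAML with the fields of
`endotrawl.interface.PipelineConfig`.

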