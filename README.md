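# retra

A toolkit for replicate-supported transcriptome re-annotation: it implements
the post-assembly computational stages of a genome-guided re-annotation
pipeline and the downstream analyses, exercised end-to-end on seeded
synthetic data with planted ground truth.

## What it does

- **Consolidation** (`retra.consolidation`): turn N per-replicate assemblies
  from one biological condition into a condition transcriptome — multi-exon
  transcripts grouped by identical intron chain and kept when supported by
  ≥ 2 replicates with FPKM > 1; a one-pass rescue rule for single-replicate
  transcripts whose introns strictly cover a supported novel chain;
  mono-exon transcripts kept only when present in every replicate, with
  extreme boundaries; a strict > 200 bp length filter; associative merging
  across conditions/assemblers; combination with reference annotations
  (reference ids win on exact matches, novel ids are generated).
- **Comparison** (`retra.annotation_compare`): match classes
  (= / c / j / u), precision, dataset summaries (transcribed/exon region
  bases and genome ratios), isoforms-per-gene distributions.
- **Coding potential** (`retra.coding_potential`): consensus verdicts from
  three evidence channels (score table, domain hits, 12-column alignment
  hits): all pass → coding, all fail → noncoding, else ambiguous; unknown
  evidence fails closed.
- **Junction conservation** (`retra.junction_conservation`): ±6 nt spliced
  junction contexts, a built-in Needleman–Wunsch/Gotoh global aligner
  (EMBOSS-style gap 10 / 0.5, NUC.4.4 or BLOSUM62), and rejection rules —
  > 1 gap column, nucleotide identity < 80 %, protein identity < 80 % or
  similarity < 90 % under five fixed residue groups.
- **Genomic features** (`retra.genomic_features`): TSS peak-coverage
  metaprofiles (±10 kb, expression-filtered, strand-flipped), seeded anchor
  shuffling, TTS polyA hexamer scans (AATAAA/ATTAAA, upstream 100 bp),
  GT-AG/GC-AG/AT-AC splice-signature tallies, TE/exon overlap fractions
  (low-complexity/satellite/simple repeats excluded).
- **AS events** (`retra.as_events`): bubble decomposition of isoform pairs
  into SE, IR, A5SS, A3SS, AFE, ALE, MXE (strand-aware; unmatched bubbles
  are reported as "complex", never forced into the seven categories).
- **Expression patterns** (`retra.expression_patterns`): expressed-in-
  condition (> 0.5 FPKM in ≥ 2 samples), tissue aggregation, unique/common
  partitions, housekeeping sets, dominant-isoform switching.
- **Synthetic data** (`retra.synthetic_data`): deterministic seeded
  generators for genome, annotation (planted ORFs, splice signatures, polyA
  signals, AS events), replicate assemblies (dropout, FPKM law, planted
  edge cases), expression matrices (planted housekeeping/switches), homolog
  contexts (planted conservation rates), repeats, and evidence tables.

Internally every coordinate is 0-based half-open; GTF converts at I/O.

## CLI

```sh
retra simulate --seed 7 --out fixtures/ --n-genes 20
retra consolidate --condition liver_wk6_M \
    --replicates fixtures/replicate1.gtf --replicates fixtures/replicate2.gtf \
    --replicates fixtures/replicate3.gtf --replicates fixtures/replicate4.gtf \
    --out cond.gtf --decisions decisions.tsv
retra merge cond1.gtf cond2.gtf --out merged.gtf
retra combine merged.gtf --ref ensembl.gtf --ref refseq.gtf --prefix RTRG. --out combined.gtf
retra compare query.gtf --ref combined.gtf --report compare.tsv
retra summarize combined.gtf --genome-length 2870000000
retra classify-coding --cpat cpat.tsv --domains pfam.tsv --hits blast.tsv \
    --cpat-cutoff 0.364 --evalue 1e-5 --out verdicts.tsv
retra junctions a.gtf --genome genome.fa --out junctions.tsv
retra conserve --query a.gtf --genome genome.fa --homolog-contexts homologs.tsv --out cons.tsv
retra tss-profile a.gtf --expr expr.tsv --meta samples.tsv --sample liver_wk6_M_1 \
    --peaks peaks.bed --flank 10000 --out profile.tsv
retra tts-polya a.gtf --genome genome.fa --window 100 --out polya.tsv
retra splice-signature a.gtf --genome genome.fa
retra te-overlap a.gtf --repeats rmsk.bed
retra as-events a.gtf --out events.tsv --summary dist.tsv
retra expression --matrix expr.tsv --meta samples.tsv --gtf a.gtf --out patterns/
```

The `--cpat-cutoff` option has no default on the CLI: the coding-score
cutoff is species-dependent and must be stated explicitly (0.364 is a
common published convention); it is echoed in every report header, as are
all other thresholds.

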