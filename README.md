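# haploclone

Detection and exact quantification of variant combinations ("clones" or
haplotypes) in one mixed deep-sequencing sample, from read alignments.

Given a reference FASTA and SAM alignments (unpadded or padded dialect,
single reads or mate pairs), haploclone

- extracts atomic variants (SNV/INS/DEL) per read, left-aligns indels, and
  merges mate pairs into fragments (ambiguous overlap evidence is masked,
  never called);
- tabulates exact haplotype counts — every fragment counted once, grouped by
  its combination of selected variants — and converts hits to percentages
  against the fragments that cover all of a haplotype's positions (wild type
  is the clamped complement);
- optionally reconnects haplotypes scattered over an overlapping amplicon
  design: a variant co-occurrence graph is built, the maximum clique is
  extracted as a new haplotype, contributing fragment counts are deducted,
  and the search repeats (capped at 15 rounds / 20 variants);
- annotates coding-sequence (c.) and amino-acid changes when a GenBank or
  tabular CDS annotation is supplied, and exports a deterministic CSV report.

A mixed-clone read simulator with exact ground truth (pre-aligned SAM, no
aligner needed) is included as a first-class module.

## CLI

Analyze one sample:

```sh
haploclone call --sam reads.sam --ref ref.fasta \
    [--annotation cds.gb] [--amplicons design.bed] [--variants selection.txt] \
    [--paired] [--infer] [--min-percent 1.0] \
    [--denominator informative|sum-positions] \
    [--max-rounds 15] [--max-clique-variants 20] \
    --out report.csv
```

- `--variants` is a plain-text list of labels (`c.749G>A`,
  `c.1423_1424ins35`, `g.101A>C`, one per line, `#` comments); without it all
  detected variants are selected (optionally filtered with
  `--min-variant-frequency`).
- `--amplicons` is a BED file; rows sharing a name in column 4 form one
  amplicon read as a mate pair with a gap. `--infer` requires it.
- `--denominator` selects the percentage denominator: `informative`
  (fragments covering all of a row's variant positions; default) or
  `sum-positions` (sum of per-variant coverages).

Simulate a mixture:

```sh
haploclone simulate --config sim.cfg --out-prefix out/sample1
```

with a key-value config such as

```
seed = 42
reference_length = 924
n_fragments = 10000
substitution_rate = 0.01
indel_rate = 0.002
clone = resistant 0.25 snv:300,snv:741
clone = minor 0.05 del:500:3
clone = wt 0.70
```

which writes `out/sample1.sam`, `.fasta`, `.truth.tsv`, `.selection.txt`.

## Layout

| module | role |
| --- | --- |
| `haploclone.alignment_io` | FASTA/SAM/BED/GenBank/selection parsing into the data model |
| `haploclone.variants` | per-read variant calling, indel normalization, labels & aa annotation |
| `haploclone.haplotypes` | mate merging, exact haplotype tabulation |
| `haploclone.quantify` | percentages and wild-type estimation |
| `haploclone.infer` | co-occurrence graph, exact maximum clique, scattered-haplotype reconnection |
| `haploclone.simulate` | ground-truth mixed-clone read simulator |
| `haploclone.report` | thresholding, CSV export, pipeline orchestration |
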