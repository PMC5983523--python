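# coibarcode

Analysis toolkit for COI DNA-barcode reference libraries, built for the
workflow used in regional fish barcoding surveys (the bundled reference
metadata describes a Taiwan Strait marine-fish library): from an aligned
FASTA of ~655 bp COI barcodes plus a four-rank taxonomy table to the
statistics such a survey reports, and to per-species identification
diagnostics.

## What it computes

Given `n` aligned sequences with species / genus / family / order labels:

* **QC** — minimum-length filter (default 600 bp), reading-frame detection
  by minimising in-frame stop codons under the vertebrate mitochondrial
  code, and exclusion of NUMT-suspect records (nuclear pseudogene copies,
  betrayed by in-frame stops in a protein-coding marker).
* **Composition** — base frequencies and GC content per codon position,
  overall and per order; conserved / variable / parsimony-informative /
  singleton site counts; mean identical (ii), transitional (si) and
  transversional (sv) site pairs over all sequence pairs and their ratio
  R = si/sv.
* **Divergence** — Kimura two-parameter distances with pairwise deletion:
  with P and Q the transition and transversion proportions of a pair,

      d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

  stratified into conspecific, congeneric, confamilial and conordinal
  tiers (mean / min / max / SE per tier), the inter/intra fold ratio, and
  the per-species barcoding gap (nearest-neighbour distance minus maximum
  conspecific distance).
* **Tree** — classic neighbor joining on the K2P matrix with deterministic
  tie-breaking, nonparametric bootstrap by column resampling with
  bipartition supports mapped onto the original tree, Newick output, and
  an unrooted monophyly test per species.
* **Diagnostics** — flags for deep conspecific divergence (default ≥ 2%),
  near-zero heterospecific distance (default ≤ 0.1%, a misidentification
  or introgression candidate), and genus-wide species complexes whose
  barcoding gap collapses; consolidated per-species report.
* **Simulation** — a synthetic generator that evolves stop-free COI-like
  alignments down an ultrametric rank tree under a K2P process with
  configurable tier divergences and codon-position composition bias, plus
  planted mislabels/NUMTs with a truth table, so the whole pipeline is
  testable without downloads.

## Worked example

```sh
coibarcode simulate --seed 11 --out demo/sim
coibarcode run --fasta demo/sim/synthetic.fasta \
    --taxonomy demo/sim/synthetic_taxonomy.tsv \
    --out demo/out --replicates 100 --seed 11
```

prints

```
240 sequences, 80 species -> demo/sim
80 species; 80 monophyletic (100.0%)
0 diagnostic flag(s)
```

and `demo/out/divergence_by_rank.tsv` contains

```
level            n_taxa  n_pairs  mean   min    max    se
within_species   80      240      0.21   0.00   0.92   0.01
within_genus     16      1440     6.71   4.60   9.15   0.02
within_family    8       1800     24.02  18.49  29.13  0.04
within_order     4       3600     26.26  18.98  32.15  0.04
```

Read this as: 240 conspecific pairs average 0.21% K2P divergence while
congeneric heterospecific pairs average 6.71% — a ~32-fold separation, so
every species is recovered as monophyletic with full bootstrap support
and no identification flags. `demo/out/` also holds the distance matrix
(CSV + PHYLIP), the bootstrapped Newick tree, the composition and
identification-report tables, and a JSON manifest of parameters and
versions.

The same `run` subcommand works on real data: any aligned, indel-free
FASTA plus a tab-separated taxonomy with columns
`id species genus family order [accession] [source]`. The taxonomy of
the Taiwan Strait reference library (354 GenBank accessions) ships with
the package; `coibarcode.reference.reproduce_reference_analysis` fetches
the sequences, aligns them with an external `mafft`, and runs the full
pipeline.

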