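# celseq2pipe

A processing stack for 3′-tag, UMI-based, barcoded single-cell RNA-seq
data in the CEL-Seq2 style, where read 1 of each pair carries a 6-nt
unique molecular identifier (UMI) followed by a 6-nt cell barcode, and
read 2 carries the cDNA.  It is written for people running or evaluating
such protocols: it designs the barcode sets, demultiplexes the reads,
counts molecules per gene per cell, and computes the spike-in and noise
statistics used to judge protocol performance — and it ships a
ground-truthed simulator so the whole chain is testable without
sequencing data.

## What it computes

**Barcode design.** Barcode sets with minimum pairwise Hamming distance
*d* ≥ 2, so that any single sequencing error yields a sequence matching
no member and the read is dropped rather than assigned to the wrong
cell.  GC content is constrained to 33–67 % and a terminal T is
forbidden.  Greedy accretion over lexicographic candidates yields 720
six-mers under these constraints.

**Demultiplexing.** R2 reads are split per cell by exact barcode lookup
from R1, with the UMI attached to the read name as
`:UMI:<seq>:CELL:<barcode>` so it survives alignment in the SAM query
name.  Accounting is conserved: assigned + unassigned + too-short =
total, on every run.

**Molecule counting.** Aligned reads are assigned to genes with
strand-specific union semantics (a read counts iff exactly one gene's
exons overlap it on the matching strand), then collapsed to distinct
UMIs *k* per (cell, gene).  Because two molecules can draw the same UMI
from the *K* = 4⁶ = 4096 labels, *k* underestimates the molecule count
*m*; the occupancy (binomial) estimator

    m̂ = ln(1 − k/K) / ln(1 − 1/K)

corrects this exactly in expectation (0 ↦ 0, 1 ↦ 1, monotone, convex).
At *k* = 2048 the corrected estimate is 2838.8 — 39 % above the raw
distinct-UMI count.

**QC statistics.** Capture efficiency from a spike-in ladder as the
y-intercept of the ordinary-least-squares fit of log₁₀(observed mean
molecules) on log₁₀(expected molecules) — `efficiency = 10^intercept`,
slope ≈ 1 when counting is linear; per-gene noise as CV² =
variance/mean² (unbiased variance); high-variability genes flagged
against a fitted a/mean + b baseline; and detection-fraction curves
across log-spaced expression bins.

## Worked example

```
$ python examples/04_spikein_efficiency.py
simulated capture efficiency : 0.2
estimated efficiency         : 0.196  (10^intercept)
fitted slope                 : 1.003  (~1 when counting is linear)
spike-ins in fit             : 92 (excluded, observed 0: 0)
```

Fifty simulated cells receive a 92-species spike-in ladder at known
abundances; molecules are captured with probability 0.2, UMI-labelled,
counted and collision-corrected, and the log-log regression recovers
the configured efficiency to within sampling noise.  The other scripts
under `examples/` walk through barcode design, demultiplexing, molecule
counting against ground truth, and the full `celseq2 run` pipeline with
its checksummed manifest.

The same stages are available from the shell:

```
celseq2 design-barcodes -o barcodes.tsv
celseq2 demux --r1 R1.fastq.gz --r2 R2.fastq.gz --barcodes barcodes.tsv -o demux/
celseq2 count --sam-dir aligned/ --gtf genes.gtf -o counts/
celseq2 qc --matrix-dir counts/ --spikeins ercc_expected.tsv -o qc/
celseq2 run --config pipeline.yaml
```

Alignment itself is external (any aligner producing SAM works); the
pipeline can shell out to a configured command template or consume
pre-computed alignments.

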