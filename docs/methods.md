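# Methods

## Barcode code design

Cell barcodes are fixed-length DNA words used as identifiers under a
noisy channel.  A set with minimum pairwise Hamming distance 2 detects
every single substitution: the corrupted word equals no member, so the
read is unassigned rather than misassigned.  Distance 2 cannot
*correct* errors (correction needs distance ≥ 3), and the demultiplexer
therefore matches exactly, by design; a `max_mismatch`-style relaxation
is deliberately not enabled by default.

Construction is greedy accretion over the lexicographic enumeration
(A < C < G < T) of all words passing the composition filters
(GC percentage within inclusive bounds — for 6-mers, GC bounds of
33–67 % admit 2, 3 or 4 G/C bases, since 2/6 = 33.3 % must be
admissible — and a forbidden terminal-base set).  A candidate is
accepted iff its distance to every accepted word meets the minimum.
Greedy maximal codes are not globally maximum, but the procedure is
deterministic, reproducible, and yields 720 words at the standard
operating point — far above plate scale.  For lengths ≤ 4 the
implementation is verified against an independent plain-Python
exhaustive greedy oracle.  Ambiguity codes (N) are rejected throughout:
barcodes are synthesized oligos.

## Read structure and demultiplexing

R1 is 15 bases: UMI (6) then cell barcode (6); bases 13–15 are ignored.
Both lengths and the order are configurable (`ReadStructure`), since
earlier protocol versions used a 5-base UMI.  R1 shorter than
UMI + barcode is dropped and counted (`too_short`).  The UMI and
barcode are attached to the R2 read name as `:UMI:<seq>:CELL:<barcode>`
before the first whitespace, which survives SAM conversion via the
query name and needs no sidecar files.  Reads with N in the UMI are
kept but flagged at demultiplexing; the counting stage drops them
(counted in its report) because an ambiguous UMI cannot participate
safely in collision statistics.  N in the barcode simply fails the
exact lookup.  Quality strings pass through unmodified; no quality
filtering is applied.

Subsampling (`subsample_reads`) draws exactly min(n, total) reads
uniformly without replacement with a seeded generator, preserving input
order, so outputs are byte-identical across runs — a control for
sequencing-depth differences when comparing libraries.

## Feature assignment and molecule counting

Assignment follows htseq-count-style **union** semantics, strand
specific: a read is attributed to a gene iff the set of genes whose
exons overlap any aligned base on the read's strand has size exactly 1.
Zero overlapping genes → `no_feature`; more than one → `ambiguous`
(ties are never broken heuristically — accuracy over yield).
Secondary/supplementary records and records with mapping quality below
10 are discarded as multi-mapped; both the threshold and the flag
behaviour are configuration keys, since either filter is defensible for
3′-tag data.  Coordinates are 0-based half-open internally; GTF input
is converted on load.

Per (cell, gene), reads are collapsed to **distinct UMI sequences** —
exact-sequence identity only, with no within-distance-1 merging.  With
K = 4^umi_length equally likely labels and m molecules, the expected
number of distinct labels is K(1 − (1 − 1/K)^m); inverting at the
observed count k gives the molecule estimate

    m̂(k) = ln(1 − k/K) / ln(1 − 1/K)

computed with `log1p` for numerical stability.  m̂ is exact at k = 0 and
k = 1, strictly increasing and convex, ≥ k everywhere, and → k as
K → ∞.  At saturation (k = K) the formula diverges; the estimate is
capped at its k = K − 1 value (≈ 34 000 for K = 4096) and the entry
counted in the matrix's `saturated` field, keeping output finite and
auditable.  Monte-Carlo inversion checks (1000 replicates at
m ∈ {10, 500, 2000}) recover m within two standard errors, while the
raw distinct count undershoots m = 2000 by ~21 %.

## Spike-in capture efficiency

Spike-in species arrive at known expected molecules per cell (from a
concentration sheet via molecules = amol/µL × 10⁻¹⁸ × N_A × µL /
dilution).  Observed mean molecules per cell (collision-corrected,
averaged over **all** cells — averaging only over detecting cells is a
recorded alternative, not the default) are regressed on expected
molecules in log₁₀–log₁₀ space by ordinary least squares.  The slope is
fit free and reported — slope ≈ 1 indicates linear counting — and
efficiency is defined as 10^intercept; a `fix_slope` option constrains
the slope to 1, making the intercept the mean log-ratio.  Species
observed zero times cannot enter a log fit and are excluded with their
count reported; pseudocounts are deliberately not used, as they bias
the intercept — the quantity of interest.  At least 3 usable species
are required.  Log base 10 is conventional for such plots; the
efficiency value is base-independent given the 10^intercept pairing.

## Noise statistics

Per-gene noise is CV² = s²/x̄² across cells with the unbiased (n − 1)
variance — material at the 20–72-cell scale these experiments run at.
Genes with zero mean are omitted (CV² undefined).  Under Poisson
sampling CV² = 1/mean, which the tests verify on simulated matrices
across means {0.5, 2, 10, 50} at 500 cells.

High-variability genes are flagged against a technical baseline
CV² = a/mean + b fit by linear least squares in [1/mean, 1]; a gene is
flagged when its CV² exceeds `ratio` (default 1.5) times its baseline.
Both the baseline form and the ratio are configurable; the flagging is
a screening device, not a calibrated test.

Detection curves compute, per gene, the fraction of cells with a
nonzero count, bin genes by mean expression on a log₁₀-spaced grid
(right edge inclusive), and report the per-bin average fraction —
monotone non-decreasing in expression under Bernoulli capture, which
the tests assert within one bin of noise.

## Simulator

The generator emulates the data-generating process the pipeline
inverts, per cell and feature:

1. true molecules ~ Poisson(mean), with per-feature means on a
   log-uniform grid; a configurable fraction of genes is
   over-dispersed via a gamma-mixed Poisson with variance =
   `noise_factor` × mean (i.e. CV² = factor/mean, factor-fold the
   Poisson level);
2. captured ~ Binomial(true, capture_efficiency);
3. each captured molecule draws a UMI uniformly from 4^umi_length, so
   collisions arise naturally;
4. each captured molecule yields one R2 read from a fixed window at its
   feature's 3′ end (window = read length; 3′ bias is positional only),
   and one 15-base R1 of UMI + barcode + A-padding with independent
   per-base substitution errors at configured rates (no indels —
   the technical regions are short and the contracts concern
   substitutions);
5. alignments are emitted by construction into a tagged SAM, with
   features laid out as disjoint single-exon loci on one synthetic
   chromosome (genes alternate strand to exercise strandedness;
   spike-ins sit on +).  Genuine aligner output in the same tagged-SAM
   convention can be substituted.

Defaults are a small manually processed experiment: 20 cells, 200
genes at 0.5–100 molecules/cell, a 92-species spike-in ladder spanning
0.5–5000 expected molecules/cell (log-uniform, mimicking a standard
spike-in mix's dynamic range), capture efficiency 0.2 (the order
measured for efficient 3′-tag protocols), 6-nt UMI and barcode, 36-base
R2, zero error rates (realistic substitution rates are ~10⁻³/base and
are opt-in so that round-trip tests are exact).  All randomness flows
from one seeded generator; outputs are byte-identical for a fixed
config.

What the simulator does **not** model: realistic transcript sequence
content, GC/positional amplification bias, PCR/IVT duplication
structure, indels, doublets, or background/ambient molecules.  Passing
round-trip tests therefore demonstrates correctness of the
*computational* contracts (parsing, accounting, deduplication,
correction, estimation) under the stated stochastic model — not
protocol performance on real libraries, which depends on sequencing
data the package only consumes.

## Test problem sizes

Simulation-backed tests run at deliberately small scale — 5–100 cells,
tens to hundreds of genes, 20 replicates for parameter-recovery checks,
1000 replicates for the scalar collision oracle — sizes at which every
statistical tolerance above was derived (two standard errors unless
stated otherwise).  The efficiency-recovery band [0.15, 0.25] at true
0.2 and the ≥ 18/20 replicate requirement come from the observed
replicate spread at those sizes.

## Known limitations

* Greedy codes are maximal, not maximum; the designer targets the
  count bound, not any specific published set (enumeration order of
  historical sets is unknowable).
* Exact-sequence UMI collapsing does not merge sequencing-error UMI
  variants; with 6-nt UMIs at ~10⁻³/base this inflates distinct counts
  by well under 1 %, but it is a modelling choice, not a measurement.
* The collision estimator assumes uniform UMI usage; strong synthesis
  or ligation bias in real UMIs violates this and biases m̂ downward.
* Isoform/splicing quantification is out of scope: 3′-tag data observe
  transcript ends only.
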