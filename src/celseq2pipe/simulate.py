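"""Ground-truthed simulator for 3'-tag UMI RNA-seq runs.

The generative model mirrors the molecular steps the pipeline must
invert.  Per cell and feature, the number of input molecules is Poisson
with a feature-specific mean (optionally gamma-over-dispersed for a set
of flagged "noisy" genes); each molecule is captured independently with
probability ``capture_efficiency``; each captured molecule draws a UMI
uniformly at random from the ``4**umi_length`` labels, so UMI collisions
arise naturally; and each captured molecule yields one R2 read from a
fixed-length window at its gene's 3' end, together with an R1 read
composed of UMI + cell barcode + padding, with independent per-base
substitution errors in the UMI and barcode regions.

Alignments of the R2 reads are emitted by construction (every read is
placed at its true locus with the UMI/cell tag in the query name), so
the counting stage is testable without an external aligner; genuine
aligner output in the same tagged-SAM convention can be substituted.

Simulated features comprise ordinary genes plus a ladder of spike-in
species at known expected abundances, mimicking the 92-species ERCC
mix, which makes capture-efficiency estimation testable against the
configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from celseq2pipe.barcode_design import design_barcodes

__all__ = ["SimConfig", "SimTruth", "SimRun", "ercc_ladder", "simulate_counts", "simulate_run"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated run.

    Defaults reflect a small manually processed experiment: 20 cells,
    a few hundred genes spanning roughly 0.5–100 molecules per cell,
    the 92-species spike-in ladder, and a capture efficiency of 0.2 —
    the scale at which these protocols operate.  Error rates default to
    zero so that round-trip tests are exact; realistic substitution
    rates are of order 1e-3 per base.
    """

    n_cells: int = 20
    n_genes: int = 200
    n_spikeins: int = 92
    gene_mean_range: tuple[float, float] = (0.5, 100.0)
    spike_mean_range: tuple[float, float] = (0.5, 5000.0)
    noise_gene_fraction: float = 0.0
    noise_factor: float = 5.0
    capture_efficiency: float = 0.2
    umi_length: int = 6
    barcode_length: int = 6
    error_rate_barcode: float = 0.0
    error_rate_umi: float = 0.0
    read_length_r2: int = 36
    r1_length: int = 15
    gene_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.capture_efficiency <= 1):
            raise ValueError("capture_efficiency must be in (0, 1]")
        for rate in (self.error_rate_barcode, self.error_rate_umi):
            if not (0 <= rate <= 1):
                raise ValueError("error rates must be in [0, 1]")
        if min(self.n_cells, self.n_genes, self.n_spikeins) < 1:
            raise ValueError("n_cells, n_genes and n_spikeins must be >= 1")
        if self.gene_length < self.read_length_r2:
            raise ValueError("gene_length must be >= read_length_r2")
        if self.r1_length < self.umi_length + self.barcode_length:
            raise ValueError("r1_length must cover UMI + barcode")

    @property
    def umi_space(self) -> int:
        return 4**self.umi_length


@dataclass
class SimTruth:
    """Ground truth of one simulated run.

    Matrices are features × cells; cells are keyed by their barcode
    sequence.  ``distinct_umis`` counts the unique UMI labels actually
    drawn per (feature, cell) — the quantity a perfect deduplicating
    counter would report — and is bounded by ``captured``.
    """

    config: SimConfig
    feature_ids: list[str]
    spikein_ids: list[str]
    cell_barcodes: list[str]
    true_molecules: pd.DataFrame
    captured_molecules: pd.DataFrame
    distinct_umis: pd.DataFrame
    umi_labels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict, repr=False)
    expected_spike_molecules: pd.DataFrame | None = None
    noisy_genes: list[str] = field(default_factory=list)


@dataclass
class SimRun:
    """File layout of a written simulation."""

    out_dir: Path
    reference_fasta: Path
    annotation_gtf: Path
    r1_fastq: Path
    r2_fastq: Path
    alignments_sam: Path
    barcodes_tsv: Path
    expected_molecules_tsv: Path
    truth: SimTruth


def ercc_ladder(n_species: int, min_molecules: float, max_molecules: float) -> pd.DataFrame:
    """Log-uniform ladder of expected molecule abundances per species."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not (0 < min_molecules < max_molecules):
        raise ValueError("need 0 < min_molecules < max_molecules")
    values = np.geomspace(min_molecules, max_molecules, n_species)
    ids = [f"ERCC-{i + 1:05d}" for i in range(n_species)]
    return pd.DataFrame({"spikein_id": ids, "expected_molecules": values})


def _umi_strings(labels: np.ndarray, umi_length: int) -> list[str]:
    """Decode integer UMI labels to DNA strings (base-4, A<C<G<T)."""
    out = []
    for lab in labels:
        chars = []
        for _ in range(umi_length):
            chars.append("ACGT"[lab % 4])
            lab //= 4
        out.append("".join(reversed(chars)))
    return out


def simulate_counts(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw molecule counts, capture events and UMI labels (no reads).

    This is the counts-level core of the simulator: it provides ground
    truth for the counting and QC stages at negligible cost, and
    :func:`simulate_run` materialises the same truth as sequence files.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    barcode_pool = design_barcodes(config.barcode_length, 2, (33, 67), {"T"})
    if len(barcode_pool) < config.n_cells:
        raise ValueError(
            f"only {len(barcode_pool)} barcodes available for {config.n_cells} cells"
        )
    cells = list(barcode_pool.barcodes[: config.n_cells])

    gene_ids = [f"GSIM{i + 1:05d}" for i in range(config.n_genes)]
    gene_means = np.geomspace(*config.gene_mean_range, config.n_genes)
    ladder = ercc_ladder(config.n_spikeins, *config.spike_mean_range) if config.n_spikeins >= 2 else pd.DataFrame(
        {"spikein_id": ["ERCC-00001"], "expected_molecules": [config.spike_mean_range[1]]}
    )
    spike_ids = list(ladder["spikein_id"])
    feature_ids = gene_ids + spike_ids
    means = np.concatenate([gene_means, ladder["expected_molecules"].to_numpy()])

    n_noisy = int(round(config.noise_gene_fraction * config.n_genes))
    noisy = np.zeros(len(feature_ids), dtype=bool)
    if n_noisy and config.noise_factor > 1:
        noisy[rng.choice(config.n_genes, size=n_noisy, replace=False)] = True

    n_feat, n_cells = len(feature_ids), len(cells)
    rates = np.tile(means[:, None], (1, n_cells))
    if noisy.any():
        # gamma-mixed Poisson: variance = noise_factor * mean, i.e. CV² = f/mean
        f = config.noise_factor
        shape = means[noisy][:, None] / (f - 1)
        rates[noisy] = rng.gamma(shape=np.tile(shape, (1, n_cells)), scale=f - 1)
    true = rng.poisson(rates)
    captured = rng.binomial(true, config.capture_efficiency)

    distinct = np.zeros_like(captured)
    labels: dict[tuple[str, str], np.ndarray] = {}
    K = config.umi_space
    for ci, cell in enumerate(cells):
        for fi, feat in enumerate(feature_ids):
            m = int(captured[fi, ci])
            if m == 0:
                continue
            lab = rng.integers(0, K, size=m)
            labels[(cell, feat)] = lab
            distinct[fi, ci] = len(np.unique(lab))

    def frame(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=feature_ids, columns=cells)

    return SimTruth(
        config=config,
        feature_ids=feature_ids,
        spikein_ids=spike_ids,
        cell_barcodes=cells,
        true_molecules=frame(true),
        captured_molecules=frame(captured),
        distinct_umis=frame(distinct),
        umi_labels=labels,
        expected_spike_molecules=ladder,
        noisy_genes=[feature_ids[i] for i in np.where(noisy)[0]],
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.where(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_run(config: SimConfig, out_dir: str | Path) -> SimRun:
    """Write a complete synthetic run: reference, GTF, FASTQ pair, SAM, truth.

    Features are disjoint single-exon loci on one synthetic chromosome
    (genes alternate strand; spike-ins sit on the + strand).  Each
    captured molecule produces one R2 read from the 3'-terminal window
    of its feature, aligned by construction in the emitted SAM with the
    true UMI and cell barcode tagged in the query name, and one R1 read
    of UMI + barcode + A-padding with substitution errors at the
    configured rates.  Output is byte-identical for a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = simulate_counts(config, rng)

    gap = 100
    chrom = "chrSIM"
    loci: list[tuple[str, int, int, str]] = []  # (feature, start0, end0, strand)
    pos = gap
    for i, feat in enumerate(truth.feature_ids):
        strand = "+" if (feat.startswith("ERCC") or i % 2 == 0) else "-"
        loci.append((feat, pos, pos + config.gene_length, strand))
        pos += config.gene_length + gap
    ref_len = pos + gap
    ref = "".join("ACGT"[b] for b in rng.integers(0, 4, size=ref_len))

    ref_fa = out_dir / "reference.fa"
    with open(ref_fa, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, ref_len, 70):
            fh.write(ref[i : i + 70] + "\n")

    gtf = out_dir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for feat, start, end, strand in loci:
            attrs = f'gene_id "{feat}"; transcript_id "{feat}.t1";'
            fh.write(f"{chrom}\tsim\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")

    locus_of = {feat: (start, end, strand) for feat, start, end, strand in loci}
    bc_tsv = out_dir / "barcodes.tsv"
    with open(bc_tsv, "w") as fh:
        for i, bc in enumerate(truth.cell_barcodes):
            fh.write(f"BC{i + 1:04d}\t{bc}\n")
    exp_tsv = out_dir / "expected_molecules.tsv"
    truth.expected_spike_molecules.to_csv(exp_tsv, sep="\t", index=False)
    truth.true_molecules.to_csv(out_dir / "truth_true_molecules.tsv", sep="\t", index_label="feature")
    truth.captured_molecules.to_csv(
        out_dir / "truth_captured_molecules.tsv", sep="\t", index_label="feature"
    )
    truth.distinct_umis.to_csv(out_dir / "truth_distinct_umis.tsv", sep="\t", index_label="feature")

    r1_path = out_dir / "r1.fastq"
    r2_path = out_dir / "r2.fastq"
    sam_path = out_dir / "alignments.sam"
    L = config.read_length_r2
    pad = "A" * (config.r1_length - config.umi_length - config.barcode_length)
    header = {"HD": {"VN": "1.6", "SO": "unknown"}, "SQ": [{"SN": chrom, "LN": ref_len}]}
    read_idx = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, pysam.AlignmentFile(
        str(sam_path), "w", header=header
    ) as sam:
        for cell in truth.cell_barcodes:
            for feat in truth.feature_ids:
                lab = truth.umi_labels.get((cell, feat))
                if lab is None:
                    continue
                start, end, strand = locus_of[feat]
                if strand == "+":
                    window = ref[end - L : end]
                    read_seq = window
                    ref_start = end - L
                else:
                    window = ref[start : start + L]
                    read_seq = window.translate(_COMPLEMENT)[::-1]
                    ref_start = start
                for umi in _umi_strings(lab, config.umi_length):
                    read_idx += 1
                    rid = f"r{read_idx:07d}"
                    umi_obs = _apply_errors(umi, config.error_rate_umi, rng)
                    bc_obs = _apply_errors(cell, config.error_rate_barcode, rng)
                    r1_seq = umi_obs + bc_obs + pad
                    f1.write(f"@{rid}\n{r1_seq}\n+\n{'I' * len(r1_seq)}\n")
                    f2.write(f"@{rid}\n{read_seq}\n+\n{'I' * L}\n")
                    a = pysam.AlignedSegment(sam.header)
                    a.query_name = f"{rid}:UMI:{umi}:CELL:{cell}"
                    a.flag = 16 if strand == "-" else 0
                    a.reference_id = 0
                    a.reference_start = ref_start
                    a.mapping_quality = 42
                    a.cigarstring = f"{L}M"
                    a.query_sequence = window
                    a.query_qualities = pysam.qualitystring_to_array("I" * L)
                    sam.write(a)

    return SimRun(
        out_dir=out_dir,
        reference_fasta=ref_fa,
        annotation_gtf=gtf,
        r1_fastq=r1_path,
        r2_fastq=r2_path,
        alignments_sam=sam_path,
        barcodes_tsv=bc_tsv,
        expected_molecules_tsv=exp_tsv,
        truth=truth,
    )
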