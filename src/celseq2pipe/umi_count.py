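"""3'-tag feature counting with UMI deduplication and collision correction.

Each aligned R2 read carries its UMI and cell barcode in the query name
(attached at demultiplexing).  Reads are assigned to genes with union
semantics — a read counts for a gene iff exactly one gene's exons
overlap any aligned base on the read's strand — and, per (cell, gene),
reads sharing the same UMI are collapsed to one observation.

Distinct-UMI counts undershoot molecule counts because two molecules can
draw the same UMI label (a collision).  With ``K = 4**umi_length``
equally likely labels and ``k`` distinct labels observed, the
occupancy-model (binomial) estimate of the number of molecules is::

    m̂(k) = ln(1 - k/K) / ln(1 - 1/K)

which maps 0 → 0 and 1 → 1 exactly, is strictly increasing and convex
in ``k``, and tends to ``k`` as K → ∞.  At saturation (k = K) the
formula diverges; the estimate is capped at its k = K − 1 value and the
event is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from gffutils.iterators import DataIterator
from intervaltree import IntervalTree

from celseq2pipe.demultiplex import parse_read_tag

__all__ = [
    "FeatureModel",
    "CountMatrix",
    "CountReport",
    "AMBIGUOUS",
    "NO_FEATURE",
    "assign_read_to_feature",
    "collapse_umis",
    "umis_to_molecules",
    "count_run",
]

AMBIGUOUS = "__ambiguous__"
NO_FEATURE = "__no_feature__"


class FeatureModel:
    """Exon intervals per gene, indexed for strand-specific overlap queries.

    Coordinates are 0-based half-open internally; GTF input (1-based,
    closed) is converted on load.  Only ``exon`` features are used and a
    ``gene_id`` attribute is required.
    """

    def __init__(self, exons: Iterable[tuple[str, str, int, int, str]]):
        # exons: (gene_id, reference, start, end, strand), 0-based half-open
        self.genes: dict[str, list[tuple[str, int, int, str]]] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for gene_id, ref, start, end, strand in exons:
            if start >= end:
                raise ValueError(f"malformed interval for {gene_id}: [{start}, {end})")
            if strand not in "+-":
                raise ValueError(f"strand must be + or -, got {strand!r}")
            self.genes.setdefault(gene_id, []).append((ref, start, end, strand))
            tree = self._trees.setdefault((ref, strand), IntervalTree())
            tree[start:end] = gene_id

    @classmethod
    def from_gtf(cls, path: str | Path) -> "FeatureModel":
        exons = []
        for feat in DataIterator(str(path)):
            if feat.featuretype != "exon":
                continue
            gene_ids = feat.attributes.get("gene_id")
            if not gene_ids:
                raise ValueError(f"exon without gene_id at {feat.seqid}:{feat.start}")
            exons.append((gene_ids[0], feat.seqid, feat.start - 1, feat.end, feat.strand))
        return cls(exons)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def overlapping_genes(self, reference: str, blocks: Sequence[tuple[int, int]], strand: str) -> set[str]:
        """Genes whose exons (on the given strand) overlap any aligned block."""
        tree = self._trees.get((reference, strand))
        if tree is None:
            return set()
        hits: set[str] = set()
        for start, end in blocks:
            hits.update(iv.data for iv in tree.overlap(start, end))
        return hits


def assign_read_to_feature(
    alignment: pysam.AlignedSegment,
    model: FeatureModel,
    min_mapq: int = 10,
) -> str:
    """Union-semantics, strand-specific gene assignment of one alignment.

    Returns a gene id, or the ``AMBIGUOUS`` / ``NO_FEATURE`` sentinel.
    The caller is responsible for filtering unmapped and multi-mapped
    records; this function only resolves overlap.
    """
    strand = "-" if alignment.is_reverse else "+"
    hits = model.overlapping_genes(alignment.reference_name, alignment.get_blocks(), strand)
    if not hits:
        return NO_FEATURE
    if len(hits) > 1:
        return AMBIGUOUS
    return hits.pop()


def collapse_umis(
    assignments: Iterable[tuple[str, str, str]],
) -> dict[tuple[str, str], int]:
    """Count distinct UMI sequences per (cell, gene).

    Reads with identical (cell, gene, UMI) collapse to a single
    observation; the same UMI under different genes is counted once for
    each gene (no cross-gene collapsing).
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for cell, gene, umi in assignments:
        seen.setdefault((cell, gene), set()).add(umi)
    return {key: len(umis) for key, umis in seen.items()}


def umis_to_molecules(k: int | float, K: int) -> float:
    """Occupancy-model molecule estimate from a distinct-UMI count.

    ``K`` is the UMI space size (``4**umi_length``).  For ``k == K``
    (saturation) the capped value at ``k = K - 1`` is returned; use
    ``k >= K`` to detect the condition upstream.
    """
    if K < 2:
        raise ValueError("UMI space size K must be >= 2")
    if k < 0 or k > K:
        raise ValueError(f"distinct-UMI count {k} outside [0, {K}]")
    if k == K:
        k = K - 1
    return math.log1p(-k / K) / math.log1p(-1.0 / K)


def _molecule_matrix(umi_counts: pd.DataFrame, K: int) -> pd.DataFrame:
    values = umi_counts.to_numpy(dtype=float)
    capped = np.minimum(values, K - 1)
    with np.errstate(divide="ignore"):
        est = np.log1p(-capped / K) / math.log1p(-1.0 / K)
    return pd.DataFrame(est, index=umi_counts.index, columns=umi_counts.columns)


@dataclass
class CountMatrix:
    """Genes × cells counts in two layers.

    ``umi_counts`` holds distinct-UMI counts (integers, bounded by the
    UMI space size ``K``); ``molecule_estimates`` holds the
    collision-corrected values, which never fall below the distinct-UMI
    count and are zero exactly where no UMI was seen.
    """

    umi_counts: pd.DataFrame
    molecule_estimates: pd.DataFrame
    K: int
    saturated: int = 0  # number of (gene, cell) entries capped at K

    @property
    def genes(self) -> list[str]:
        return list(self.umi_counts.index)

    @property
    def cells(self) -> list[str]:
        return list(self.umi_counts.columns)

    @classmethod
    def from_umi_counts(cls, umi_counts: pd.DataFrame, K: int) -> "CountMatrix":
        saturated = int((umi_counts.to_numpy() >= K).sum())
        return cls(umi_counts, _molecule_matrix(umi_counts, K), K, saturated)

    def to_tsv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.umi_counts.to_csv(out_dir / "umi_counts.tsv", sep="\t", index_label="gene")
        self.molecule_estimates.round(6).to_csv(
            out_dir / "molecules.tsv", sep="\t", index_label="gene"
        )

    @classmethod
    def from_tsv(cls, out_dir: str | Path, umi_length: int = 6) -> "CountMatrix":
        out_dir = Path(out_dir)
        umis = pd.read_csv(out_dir / "umi_counts.tsv", sep="\t", index_col="gene")
        return cls.from_umi_counts(umis, 4**umi_length)

    def to_mtx(self, out_dir: str | Path, layer: str = "umi_counts") -> None:
        """Export a layer as a MatrixMarket triplet plus gene/cell lists."""
        from scipy import io as spio
        from scipy import sparse

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame = getattr(self, layer)
        spio.mmwrite(str(out_dir / f"{layer}.mtx"), sparse.csr_matrix(frame.to_numpy()))
        (out_dir / "genes.txt").write_text("\n".join(self.genes) + "\n")
        (out_dir / "cells.txt").write_text("\n".join(self.cells) + "\n")


@dataclass
class CountReport:
    """Read accounting for a counting run; tallies sum to total records."""

    assigned: int = 0
    ambiguous: int = 0
    no_feature: int = 0
    unmapped: int = 0
    multimapped: int = 0
    umi_with_n: int = 0
    per_file: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return (
            self.assigned
            + self.ambiguous
            + self.no_feature
            + self.unmapped
            + self.multimapped
            + self.umi_with_n
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for name in ("assigned", "ambiguous", "no_feature", "unmapped", "multimapped", "umi_with_n"):
                fh.write(f"{name}\t{getattr(self, name)}\n")
            fh.write(f"total\t{self.total}\n")


def _iter_alignments(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        yield from fh


def count_run(
    alignment_files: Sequence[str | Path] | str | Path,
    model: FeatureModel,
    umi_length: int = 6,
    min_mapq: int = 10,
    cells: Sequence[str] | None = None,
) -> tuple[CountMatrix, CountReport]:
    """Count molecules per gene per cell from tagged SAM alignments.

    Cell identity is taken from the ``:CELL:<barcode>`` component of each
    query name, so one combined SAM or several per-cell SAM files are
    equivalent.  Secondary/supplementary records and records below
    ``min_mapq`` are discarded as multi-mapped; UMIs containing N are
    dropped and counted.  Output is invariant to the order of input
    records.
    """
    if isinstance(alignment_files, (str, Path)):
        alignment_files = [alignment_files]
    report = CountReport()
    triples: list[tuple[str, str, str]] = []
    observed_cells: set[str] = set()
    for path in alignment_files:
        n_records = 0
        for aln in _iter_alignments(path):
            n_records += 1
            _, umi, cell = parse_read_tag(aln.query_name)
            observed_cells.add(cell)
            if aln.is_unmapped:
                report.unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary or aln.mapping_quality < min_mapq:
                report.multimapped += 1
                continue
            if "N" in umi:
                report.umi_with_n += 1
                continue
            gene = assign_read_to_feature(aln, model, min_mapq)
            if gene == NO_FEATURE:
                report.no_feature += 1
            elif gene == AMBIGUOUS:
                report.ambiguous += 1
            else:
                report.assigned += 1
                triples.append((cell, gene, umi))
        report.per_file[str(path)] = n_records

    counts = collapse_umis(triples)
    gene_ids = model.gene_ids()
    cell_ids = sorted(observed_cells) if cells is None else list(cells)
    frame = pd.DataFrame(0, index=gene_ids, columns=cell_ids, dtype=int)
    for (cell, gene), k in counts.items():
        if cell in frame.columns:
            frame.at[gene, cell] = k
    matrix = CountMatrix.from_umi_counts(frame, 4**umi_length)
    return matrix, report
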