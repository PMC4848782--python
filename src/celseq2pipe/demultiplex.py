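"""Demultiplexing of paired-end reads by cell barcode.

In a CEL-Seq2-style run, read 1 (R1) carries only technical sequence —
a 6-nt UMI followed by a 6-nt cell barcode within its first 12 bases of
a 15-base read — while read 2 (R2) carries the cDNA.  Demultiplexing
splits R2 reads into one FASTQ per cell using the barcode from R1, and
attaches the UMI (and cell barcode) to the R2 read identifier as a
``:UMI:<seq>:CELL:<barcode>`` suffix so that the information survives
alignment in the SAM query name without sidecar files.

Barcode matching is exact-only by default: a minimum-distance-2 barcode
set detects any single substitution but cannot uniquely correct it, and
the design goal is that an error never moves a read to the wrong cell.
Mismatched reads are counted as unassigned.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pysam

from celseq2pipe.barcode_design import BarcodeSet

__all__ = [
    "ReadStructure",
    "ReadAnnotation",
    "DemuxReport",
    "parse_r1",
    "assign_barcode",
    "demultiplex_run",
    "subsample_reads",
    "tag_read_id",
    "parse_read_tag",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadStructure:
    """Layout of the technical read (R1).

    ``umi_first=True`` means R1 starts with the UMI followed by the cell
    barcode; bases beyond ``umi_length + barcode_length`` are ignored.
    """

    umi_length: int = 6
    barcode_length: int = 6
    umi_first: bool = True

    def __post_init__(self) -> None:
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")

    @property
    def r1_min_length(self) -> int:
        return self.umi_length + self.barcode_length


@dataclass(frozen=True)
class ReadAnnotation:
    """The (cell barcode, UMI, cDNA read) triple parsed from a read pair."""

    cell_barcode: str
    umi: str
    cdna_sequence: str
    cdna_qualities: str
    original_id: str


@dataclass
class DemuxReport:
    """Per-run accounting; categories always sum to total input pairs."""

    per_barcode: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    too_short: int = 0
    total: int = 0
    umi_with_n: int = 0  # assigned reads whose UMI contains N (flagged, kept)

    @property
    def assigned(self) -> int:
        return sum(self.per_barcode.values())

    def check_conservation(self) -> None:
        if self.assigned + self.unassigned + self.too_short != self.total:
            raise AssertionError("demultiplex accounting does not conserve reads")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for bid in sorted(self.per_barcode):
                fh.write(f"{bid}\t{self.per_barcode[bid]}\n")
            fh.write(f"unassigned\t{self.unassigned}\n")
            fh.write(f"too_short\t{self.too_short}\n")
            fh.write(f"total\t{self.total}\n")
            fh.write(f"umi_with_N\t{self.umi_with_n}\n")


def parse_r1(r1_sequence: str, structure: ReadStructure = ReadStructure()) -> tuple[str, str] | None:
    """Extract ``(umi, barcode)`` from an R1 sequence.

    Returns ``None`` when the read is shorter than the technical region
    (the too-short signal).  Bases beyond the technical region are
    ignored.
    """
    if len(r1_sequence) < structure.r1_min_length:
        return None
    r1_sequence = r1_sequence.upper()
    if structure.umi_first:
        umi = r1_sequence[: structure.umi_length]
        barcode = r1_sequence[structure.umi_length : structure.r1_min_length]
    else:
        barcode = r1_sequence[: structure.barcode_length]
        umi = r1_sequence[structure.barcode_length : structure.r1_min_length]
    return umi, barcode


def assign_barcode(observed: str, barcode_set: BarcodeSet) -> str:
    """Exact membership lookup; returns a barcode id or ``"unassigned"``.

    No mismatch tolerance: with a minimum-distance-2 set a single
    substitution cannot match another member, so the safe response to a
    non-member is to leave the read unassigned.
    """
    return barcode_set.ids.get(observed.upper(), UNASSIGNED)


def tag_read_id(read_id: str, umi: str, barcode: str) -> str:
    """Append the UMI/cell suffix to a read identifier (before whitespace)."""
    head = read_id.split()[0]
    return f"{head}:UMI:{umi}:CELL:{barcode}"


def parse_read_tag(read_id: str) -> tuple[str, str, str]:
    """Recover ``(original_id, umi, barcode)`` from a tagged identifier."""
    head = read_id.split()[0]
    if ":UMI:" not in head or ":CELL:" not in head:
        raise ValueError(
            f"read id {head!r} lacks the :UMI:<seq>:CELL:<barcode> suffix "
            "attached at demultiplexing"
        )
    original, rest = head.split(":UMI:", 1)
    umi, barcode = rest.split(":CELL:", 1)
    return original, umi, barcode


def _read_id_core(name: str) -> str:
    """Pair-comparable read id: text before whitespace, minus a /1 or /2 suffix."""
    head = name.split()[0]
    if head.endswith(("/1", "/2")):
        head = head[:-2]
    return head


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a FASTQ file (gzip-transparent)."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            name = rec.name if rec.comment is None else f"{rec.name} {rec.comment}"
            yield name, rec.sequence, rec.quality or "I" * len(rec.sequence)


def demultiplex_run(
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_set: BarcodeSet,
    structure: ReadStructure = ReadStructure(),
    out_dir: str | Path = ".",
) -> DemuxReport:
    """Split synchronized R1/R2 FASTQ streams into per-cell R2 FASTQ files.

    One ``<barcode_id>.fastq`` per observed cell is written under
    ``out_dir``, each read renamed with the ``:UMI:...:CELL:...`` suffix;
    input order is preserved within each output file.  A pair whose R1 is
    shorter than the technical region is dropped and counted; a barcode
    that is not an exact member (including any N) leaves the pair
    unassigned.  Desynchronized inputs raise immediately, naming the
    first offending pair.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = DemuxReport()
    handles: dict[str, object] = {}
    try:
        r1_iter = _fastq_records(r1_path)
        r2_iter = _fastq_records(r2_path)
        while True:
            rec1 = next(r1_iter, None)
            rec2 = next(r2_iter, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise ValueError("R1 and R2 files have different numbers of reads")
            name1, seq1, _ = rec1
            name2, seq2, qual2 = rec2
            if _read_id_core(name1) != _read_id_core(name2):
                raise ValueError(
                    f"R1/R2 desynchronized: {_read_id_core(name1)!r} vs {_read_id_core(name2)!r}"
                )
            report.total += 1
            parsed = parse_r1(seq1, structure)
            if parsed is None:
                report.too_short += 1
                continue
            umi, barcode = parsed
            bid = assign_barcode(barcode, barcode_set)
            if bid == UNASSIGNED:
                report.unassigned += 1
                continue
            if "N" in umi:
                report.umi_with_n += 1
            report.per_barcode[bid] = report.per_barcode.get(bid, 0) + 1
            if bid not in handles:
                handles[bid] = open(out_dir / f"{bid}.fastq", "w")
            tagged = tag_read_id(name2, umi, barcode)
            handles[bid].write(f"@{tagged}\n{seq2}\n+\n{qual2}\n")
    finally:
        for fh in handles.values():
            fh.close()
    report.check_conservation()
    return report


def subsample_reads(
    fastq_in: str | Path,
    n: int,
    seed: int,
    fastq_out: str | Path,
) -> int:
    """Draw exactly ``min(n, total)`` reads uniformly without replacement.

    Sampling is deterministic for a fixed seed and preserves the input
    order of the retained reads, so repeated runs are byte-identical.
    Returns the number of reads written.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    records = list(_fastq_records(fastq_in))
    rng = np.random.default_rng(seed)
    k = min(n, len(records))
    keep = sorted(rng.choice(len(records), size=k, replace=False)) if k else []
    opener = gzip.open if str(fastq_out).endswith(".gz") else open
    with opener(fastq_out, "wt") as fh:
        for i in keep:
            name, seq, qual = records[i]
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return k
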