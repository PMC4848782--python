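"""Design and validation of cell-barcode sets.

Cell barcodes identify the sample of origin of each read, so a sequencing
error in the barcode must never silently move a read to a different cell.
A set whose pairwise Hamming distance is at least 2 guarantees that any
single substitution produces a sequence that is not another member: the
read becomes unassignable rather than misassigned.  Composition
constraints (GC content bounds, no terminal T) additionally avoid
low-complexity oligos that sequence poorly.

The designer enumerates all sequences of the requested length in
lexicographic order (A < C < G < T), filters on composition, and accepts
a candidate whenever its Hamming distance to every previously accepted
barcode meets the minimum.  Greedy accretion over a fixed enumeration
order makes the output deterministic and reproducible; with length 6,
minimum distance 2, GC between 33 % and 67 % and no terminal T it yields
several hundred barcodes, comfortably above the 96- and 168-well scales
used in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DNA_ALPHABET = ("A", "C", "G", "T")

__all__ = [
    "BarcodeSet",
    "ValidationReport",
    "hamming_distance",
    "gc_percent",
    "design_barcodes",
    "validate_barcode_set",
    "read_barcode_tsv",
]


class InvalidSequenceError(ValueError):
    """A sequence is empty or contains characters outside A/C/G/T."""


def _check_dna(s: str) -> str:
    if not s:
        raise InvalidSequenceError("empty sequence")
    s = s.upper()
    if set(s) - set(DNA_ALPHABET):
        raise InvalidSequenceError(f"non-ACGT characters in {s!r}")
    return s


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ.

    Raises
    ------
    ValueError
        If the sequences have unequal lengths.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def gc_percent(s: str) -> float:
    """GC content of a DNA sequence as a percentage of its length."""
    s = _check_dna(s)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class BarcodeSet:
    """A validated collection of fixed-length DNA barcodes.

    Invariants (checked on construction): uniform length, no duplicates,
    pairwise Hamming distance at least ``min_distance``, GC percentage
    within ``gc_bounds`` (inclusive), and no barcode ending in a base
    from ``forbidden_last``.
    """

    barcodes: tuple[str, ...]
    length: int
    min_distance: int
    gc_bounds: tuple[float, float] = (0.0, 100.0)
    forbidden_last: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        report = validate_barcode_set(
            self.barcodes, self.min_distance, self.gc_bounds, self.forbidden_last
        )
        if not report.valid:
            raise ValueError(f"invalid barcode set: {report.violations}")
        if self.barcodes and len(self.barcodes[0]) != self.length:
            raise ValueError("barcode length does not match declared length")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def __contains__(self, seq: str) -> bool:
        return seq in set(self.barcodes)

    @property
    def ids(self) -> dict[str, str]:
        """Mapping of barcode sequence to a stable identifier (BC0001, ...)."""
        return {seq: f"BC{i + 1:04d}" for i, seq in enumerate(self.barcodes)}

    def to_tsv(self, path: str | Path) -> None:
        """Write ``barcode_id<TAB>sequence`` lines."""
        with open(path, "w") as fh:
            for seq, bid in self.ids.items():
                fh.write(f"{bid}\t{seq}\n")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seq, bid in self.ids.items():
                fh.write(f">{bid}\n{seq}\n")

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        min_distance: int = 1,
        gc_bounds: tuple[float, float] = (0.0, 100.0),
        forbidden_last: Iterable[str] = (),
    ) -> "BarcodeSet":
        seqs = tuple(s.upper() for s in sequences)
        if not seqs:
            raise ValueError("empty barcode list")
        return cls(seqs, len(seqs[0]), min_distance, tuple(gc_bounds), frozenset(forbidden_last))


def read_barcode_tsv(path: str | Path) -> dict[str, str]:
    """Read a ``barcode_id<TAB>sequence`` TSV into an id → sequence mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            bid, seq = line.split("\t")[:2]
            out[bid] = _check_dna(seq)
    return out


@dataclass
class ValidationReport:
    """Outcome of checking a candidate list against design constraints."""

    valid: bool
    violations: list[str]
    bad_pairs: list[tuple[str, str, int]]

    def __bool__(self) -> bool:
        return self.valid


def validate_barcode_set(
    candidates: Sequence[str],
    min_distance: int,
    gc_bounds: tuple[float, float] = (0.0, 100.0),
    forbidden_last: Iterable[str] = (),
) -> ValidationReport:
    """Check every constraint and report all violations.

    Mixed lengths, duplicates, composition failures and every pair below
    ``min_distance`` are reported as violations rather than exceptions.
    """
    violations: list[str] = []
    bad_pairs: list[tuple[str, str, int]] = []
    forbidden = {b.upper() for b in forbidden_last}
    lo, hi = gc_bounds

    seqs = []
    for raw in candidates:
        try:
            seqs.append(_check_dna(raw))
        except InvalidSequenceError as exc:
            violations.append(str(exc))
    if not seqs:
        return ValidationReport(not violations, violations, bad_pairs)

    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        violations.append(f"mixed lengths: {sorted(lengths)}")
    seen: set[str] = set()
    for s in seqs:
        if s in seen:
            violations.append(f"duplicate barcode {s}")
        seen.add(s)
        gc = gc_percent(s)
        if not (lo <= gc <= hi):
            violations.append(f"{s}: GC {gc:.1f}% outside [{lo}, {hi}]")
        if s[-1] in forbidden:
            violations.append(f"{s}: forbidden last base {s[-1]}")
    if len(lengths) == 1:
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                d = hamming_distance(a, b)
                if d < min_distance:
                    bad_pairs.append((a, b, d))
                    violations.append(f"pair ({a}, {b}) at distance {d} < {min_distance}")
    return ValidationReport(not violations, violations, bad_pairs)


def design_barcodes(
    length: int,
    min_distance: int,
    gc_bounds: tuple[float, float] = (0.0, 100.0),
    forbidden_last: Iterable[str] = (),
    max_count: int | None = None,
) -> BarcodeSet:
    """Greedily construct a barcode set satisfying all constraints.

    Candidates of the given length are enumerated lexicographically
    (A < C < G < T); one passing the composition filters is accepted iff
    its Hamming distance to every already-accepted barcode is at least
    ``min_distance``.  The procedure is deterministic, so two calls with
    identical parameters return identical ordered sets.  ``max_count``
    truncates the output after that many acceptances.

    Infeasible constraints yield an empty set with a warning rather than
    an exception.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    lo, hi = gc_bounds
    if not (0 <= lo <= hi <= 100):
        raise ValueError("gc_bounds must satisfy 0 <= lo <= hi <= 100")
    forbidden = {b.upper() for b in forbidden_last}

    accepted: list[str] = []
    # uint8 codepoint matrix of accepted barcodes for vectorised distance checks
    matrix = np.empty((0, length), dtype=np.uint8)
    for tup in product(DNA_ALPHABET, repeat=length):
        seq = "".join(tup)
        gc = 100.0 * (seq.count("G") + seq.count("C")) / length
        if not (lo <= gc <= hi):
            continue
        if seq[-1] in forbidden:
            continue
        row = np.frombuffer(seq.encode(), dtype=np.uint8)
        if matrix.size and int((matrix != row).sum(axis=1).min()) < min_distance:
            continue
        accepted.append(seq)
        matrix = np.vstack([matrix, row])
        if max_count is not None and len(accepted) >= max_count:
            break
    if not accepted:
        warnings.warn(
            "barcode design constraints admit no sequences; returning an empty set",
            stacklevel=2,
        )
    return BarcodeSet(tuple(accepted), length, min_distance, (lo, hi), frozenset(forbidden))
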