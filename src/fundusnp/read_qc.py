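"""Barcode demultiplexing and sequence-level quality filters.

Reads from a multiplexed pyrosequencing run carry a fixed-length nucleotide
barcode at their 5' end identifying the source individual.  This module
assigns reads to individuals by (optionally mismatch-tolerant) prefix match,
trims the barcode, and applies the two pre-assembly filters used for
reduced-representation SNP discovery: removal of reads containing any
ambiguous base (N), and removal of reads shorter than a minimum length
(default 100 bp).  Ambiguity is checked before length, so a short read with
an N is counted as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "BarcodeTable",
    "ConfigurationError",
    "demultiplex",
    "filter_reads",
    "read_fastq",
    "write_fastq",
    "demux_report",
]


class ConfigurationError(ValueError):
    """Raised for unusable run configuration (e.g. an empty barcode table)."""


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities.

    ``sequence`` is over {A, C, G, T, N}; ``qualities`` are Phred integers in
    [0, 60], one per base.  ``individual_id`` is set by demultiplexing.
    """

    read_id: str
    sequence: str
    qualities: list[int] = field(repr=False)
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if self.qualities and (min(self.qualities) < 0 or max(self.qualities) > 60):
            raise ValueError(f"read {self.read_id}: Phred values must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous_base(self) -> bool:
        return "N" in self.sequence


class BarcodeTable:
    """Map from fixed-length barcode strings to individual identifiers."""

    def __init__(self, entries: Mapping[str, str]):
        entries = dict(entries)
        if entries:
            lengths = {len(b) for b in entries}
            if len(lengths) != 1:
                raise ConfigurationError("barcodes must all have the same length")
        self.entries: dict[str, str] = entries

    @property
    def barcode_length(self) -> int:
        if not self.entries:
            raise ConfigurationError("barcode table is empty")
        return len(next(iter(self.entries)))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        """Load a 2-column TSV (barcode, individual_id); '#' lines are comments."""
        entries: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            barcode, individual = parts
            if barcode in entries:
                raise ConfigurationError(f"{path}:{lineno}: duplicate barcode {barcode}")
            entries[barcode.upper()] = individual
        return cls(entries)


def _mismatches(a: str, b: str, cap: int) -> int:
    """Hamming distance between equal-length strings, short-circuited at cap+1."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                break
    return n


def demultiplex(
    reads: Iterable[Read],
    table: BarcodeTable,
    max_mismatch: int = 0,
) -> tuple[list[Read], list[Read]]:
    """Assign reads to individuals by barcode prefix and trim the barcode.

    A read is assigned iff exactly one barcode matches its leading bases
    within ``max_mismatch`` substitutions; ambiguous (multi-hit) and
    unmatched reads are returned unmodified in ``unassigned``.  Assigned
    reads have the barcode removed from both sequence and qualities.
    Input order is preserved in both outputs.
    """
    if len(table) == 0:
        raise ConfigurationError("barcode table is empty")
    length = table.barcode_length
    assigned: list[Read] = []
    unassigned: list[Read] = []
    for read in reads:
        prefix = read.sequence[:length]
        hits = [
            individual
            for barcode, individual in table.entries.items()
            if len(prefix) == length and _mismatches(prefix, barcode, max_mismatch) <= max_mismatch
        ]
        if len(hits) == 1:
            assigned.append(
                Read(
                    read_id=read.read_id,
                    sequence=read.sequence[length:],
                    qualities=read.qualities[length:],
                    individual_id=hits[0],
                )
            )
        else:
            unassigned.append(read)
    return assigned, unassigned


def filter_reads(
    reads: Iterable[Read], min_length: int = 100
) -> tuple[list[Read], int, int]:
    """Apply ambiguity and length filters.

    Returns ``(kept, dropped_ambiguous, dropped_short)``.  A read with any N
    is dropped as ambiguous regardless of length; among N-free reads, those
    with length strictly below ``min_length`` are dropped as short (a read of
    exactly ``min_length`` bases is kept).
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[Read] = []
    dropped_ambiguous = 0
    dropped_short = 0
    for read in reads:
        if read.has_ambiguous_base:
            dropped_ambiguous += 1
        elif len(read) < min_length:
            dropped_short += 1
        else:
            kept.append(read)
    return kept, dropped_ambiguous, dropped_short


def read_fastq(path: str | Path, quality_offset: int = 33) -> list[Read]:
    """Load reads from FASTQ.  offset 33 = Sanger/Phred+33; 64 = old Illumina."""
    if quality_offset == 33:
        fmt = "fastq"
    elif quality_offset == 64:
        fmt = "fastq-illumina"
    else:
        raise ConfigurationError(f"unsupported quality offset {quality_offset}")
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = [min(int(q), 60) for q in rec.letter_annotations["phred_quality"]]
        reads.append(Read(read_id=rec.id, sequence=str(rec.seq).upper(), qualities=quals))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def demux_report(
    assigned: list[Read],
    unassigned: list[Read],
    kept: list[Read] | None = None,
    dropped_ambiguous: int = 0,
    dropped_short: int = 0,
) -> pd.DataFrame:
    """Per-individual QC counts (assigned, and kept after filtering if given)."""
    rows = []
    individuals = sorted({r.individual_id for r in assigned if r.individual_id})
    kept_counts: dict[str, int] = {}
    if kept is not None:
        for r in kept:
            kept_counts[r.individual_id] = kept_counts.get(r.individual_id, 0) + 1
    for ind in individuals:
        row = {"individual": ind, "assigned": sum(1 for r in assigned if r.individual_id == ind)}
        if kept is not None:
            row["kept"] = kept_counts.get(ind, 0)
        rows.append(row)
    summary = {"individual": "__unassigned__", "assigned": len(unassigned)}
    if kept is not None:
        summary["kept"] = 0
    rows.append(summary)
    df = pd.DataFrame(rows)
    df.attrs["dropped_ambiguous"] = dropped_ambiguous
    df.attrs["dropped_short"] = dropped_short
    return df
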