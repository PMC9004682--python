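"""Classify bisulfite-sequencing reads into RNA and DNA origin bins.

In a joint methylome + transcriptome library, cDNA-derived reads retain
their cytosines through bisulfite conversion (appearing almost fully
methylated in non-CG context), whereas genomic reads show the low somatic
non-CG methylation background. A read's mCH ratio therefore separates the
two origins: reads with mCH ratio < 0.5 and at least 3 CH cytosines are
taken as genomic DNA, reads with mCH ratio > 0.9 and at least 3 cytosines
as RNA, and everything else is left ambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ReadMethylationRecord",
    "PartitionThresholds",
    "PartitionSummary",
    "parse_methylation_call_string",
    "classify_read",
    "partition_reads",
    "read_records_tsv",
    "write_records_tsv",
    "read_records_sam",
]

DNA = "DNA"
RNA = "RNA"
AMBIGUOUS = "ambiguous"

# Bismark XM-tag alphabet: upper case = methylated, lower case = unmethylated.
# Z/z CpG, X/x CHG, H/h CHH, U/u unknown context, '.' no cytosine.
_METHYLATED_CH = frozenset("XH")
_UNMETHYLATED_CH = frozenset("xh")
_KNOWN = frozenset("ZzXxHhUu.")


@dataclass(frozen=True)
class ReadMethylationRecord:
    """Per-read methylation call counts by sequence context."""

    read_id: str
    mch: int  # methylated CH calls (CHG + CHH)
    ch: int   # total CH calls
    mcg: int = 0
    cg: int = 0

    def __post_init__(self) -> None:
        if self.mch < 0 or self.ch < 0 or self.mcg < 0 or self.cg < 0:
            raise ValueError(f"negative counts in record {self.read_id!r}")
        if self.mch > self.ch:
            raise ValueError(f"mch > ch in record {self.read_id!r}")
        if self.mcg > self.cg:
            raise ValueError(f"mcg > cg in record {self.read_id!r}")

    @property
    def mch_ratio(self) -> float | None:
        """mCH / CH, or None for reads without CH cytosines."""
        return self.mch / self.ch if self.ch > 0 else None


@dataclass(frozen=True)
class PartitionThresholds:
    """Classification thresholds; inequalities are strict on both sides."""

    dna_max_ratio: float = 0.5
    rna_min_ratio: float = 0.9
    min_cytosines: int = 3

    def __post_init__(self) -> None:
        if not self.dna_max_ratio < self.rna_min_ratio:
            raise ValueError("dna_max_ratio must be < rna_min_ratio")
        if self.min_cytosines < 1:
            raise ValueError("min_cytosines must be >= 1")


class CallStringError(ValueError):
    """Raised for symbols outside the methylation-call alphabet."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"invalid methylation call symbol {symbol!r} at position {position} (1-based)"
        )


def parse_methylation_call_string(call_string: str, read_id: str = "") -> ReadMethylationRecord:
    """Parse an XM-style per-base methylation call string into context counts.

    >>> parse_methylation_call_string("HHHhh").mch_ratio
    0.6
    """
    for pos, sym in enumerate(call_string, start=1):
        if sym not in _KNOWN:
            raise CallStringError(sym, pos)
    mch = sum(call_string.count(c) for c in "XH")
    ch = mch + sum(call_string.count(c) for c in "xh")
    mcg = call_string.count("Z")
    cg = mcg + call_string.count("z")
    return ReadMethylationRecord(read_id=read_id, mch=mch, ch=ch, mcg=mcg, cg=cg)


def classify_read(
    record: ReadMethylationRecord, thresholds: PartitionThresholds = PartitionThresholds()
) -> str:
    """Return "DNA", "RNA" or "ambiguous" for one read.

    Reads with fewer than ``min_cytosines`` CH calls, or with an mCH ratio in
    the closed interval [dna_max_ratio, rna_min_ratio], are ambiguous.
    """
    if record.ch < thresholds.min_cytosines:
        return AMBIGUOUS
    ratio = record.mch / record.ch
    if ratio < thresholds.dna_max_ratio:
        return DNA
    if ratio > thresholds.rna_min_ratio:
        return RNA
    return AMBIGUOUS


@dataclass
class PartitionSummary:
    counts: dict[str, int]
    read_ids: dict[str, list[str]]

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    def fraction(self, origin: str) -> float:
        return self.counts[origin] / self.n_reads if self.n_reads else 0.0


def partition_reads(
    records: Iterable[ReadMethylationRecord],
    thresholds: PartitionThresholds = PartitionThresholds(),
) -> PartitionSummary:
    """Partition reads into disjoint DNA / RNA / ambiguous classes."""
    counts = {DNA: 0, RNA: 0, AMBIGUOUS: 0}
    ids: dict[str, list[str]] = {DNA: [], RNA: [], AMBIGUOUS: []}
    for rec in records:
        origin = classify_read(rec, thresholds)
        counts[origin] += 1
        ids[origin].append(rec.read_id)
    return PartitionSummary(counts=counts, read_ids=ids)


# ---------------------------------------------------------------------------
# I/O: the canonical exchange format is a TSV of per-read counts; SAM input
# with an XM-style tag is supported through pysam.

_TSV_COLUMNS = ["read_id", "mch", "ch", "mcg", "cg"]


def write_records_tsv(records: Iterable[ReadMethylationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for r in records:
            writer.writerow([r.read_id, r.mch, r.ch, r.mcg, r.cg])


def read_records_tsv(path: str | Path) -> list[ReadMethylationRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"missing columns in {path}: {sorted(missing)}")
        for row in reader:
            out.append(
                ReadMethylationRecord(
                    read_id=row["read_id"],
                    mch=int(row["mch"]),
                    ch=int(row["ch"]),
                    mcg=int(row["mcg"]),
                    cg=int(row["cg"]),
                )
            )
    return out


def read_records_sam(path: str | Path, tag: str = "XM") -> Iterator[ReadMethylationRecord]:
    """Yield records from a SAM/BAM file carrying per-base call strings in ``tag``."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or not aln.has_tag(tag):
                continue
            yield parse_methylation_call_string(aln.get_tag(tag), read_id=aln.query_name)
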