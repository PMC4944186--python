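"""Sequence records and FASTA/FASTQ/TSV readers and writers.

Thin wrappers over Biopython's parsers that return the package's own
:class:`SeqRecord` (id, upper-case sequence, optional integer Phred
qualities).  Only Phred+33 FASTQ is supported; that is what the simulators
emit and no legacy data is handled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .taxonomy import Lineage

_DNA = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed FASTA/FASTQ/TSV input."""


@dataclass
class SeqRecord:
    """A sequence with optional per-base Phred quality scores."""

    id: str
    seq: str
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: Optional[str] = None) -> "SeqRecord":
        qual = None if self.qual is None else list(reversed(self.qual))
        return SeqRecord(new_id or self.id, reverse_complement(self.seq), qual)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file; IDs are the first whitespace-delimited header token."""
    records: list[SeqRecord] = []
    with open(path) as fh:
        for ordinal, (header, seq) in enumerate(SimpleFastaParser(fh), start=1):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise FormatError(f"{path}: record #{ordinal} has an empty header")
            seq = seq.replace(" ", "").upper()
            if not seq:
                raise FormatError(f"{path}: record #{ordinal} ({rid!r}) has no sequence")
            records.append(SeqRecord(rid, seq))
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[SeqRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)


def read_fastq(path: str | os.PathLike) -> list[SeqRecord]:
    """Read 4-line-per-record Phred+33 FASTQ with decoded integer qualities."""
    records: list[SeqRecord] = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0]
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: record {rid!r} sequence/quality length mismatch"
                    )
                records.append(
                    SeqRecord(rid, seq.upper(), [ord(c) - 33 for c in qual])
                )
        except ValueError as exc:  # Biopython reports mismatched lengths etc.
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(path: str | os.PathLike, records: Iterable[SeqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise FormatError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            q = "".join(chr(min(q, 93) + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# TSV taxonomy map (sequence_id <tab> lineage string)


def read_taxonomy(path: str | os.PathLike) -> dict[str, Lineage]:
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            out[parts[0]] = Lineage.parse(parts[1])
    return out


def write_taxonomy(path: str | os.PathLike, taxa: dict[str, Lineage]) -> None:
    with open(path, "w") as fh:
        for rid, lineage in taxa.items():
            fh.write(f"{rid}\t{lineage.format()}\n")


def validate_dna(seq: str, *, context: str = "sequence") -> None:
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{context} contains non-DNA characters: {sorted(bad)}")
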