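"""FASTA/FASTQ reading and order-preserving corrected-read writing."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, List, Optional, Sequence

from Bio import SeqIO


@dataclass
class ReadRecord:
    """One input record: id, sequence, optional quality string, file format."""

    id: str
    description: str
    sequence: str
    quality: Optional[str]  # None for FASTA


def _open_text(path: str) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


def sniff_format(path: str) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line[0] == ">":
                return "fasta"
            if line[0] == "@":
                return "fastq"
            raise ValueError(f"{path}: unrecognized sequence format")
    return "fasta"  # empty file: treat as empty FASTA


def read_sequences(path: str) -> tuple[List[ReadRecord], str]:
    """Parse FASTA/FASTQ (gzip-transparent), preserving order and ids.

    Returns the records plus the detected format so output can mirror it.
    Malformed records raise ``ValueError`` naming the offending record.
    """
    fmt = sniff_format(path)
    records: List[ReadRecord] = []
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                qual = None
                if fmt == "fastq":
                    qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                records.append(ReadRecord(rec.id, rec.description, str(rec.seq), qual))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record #{len(records) + 1}: {exc}") from exc
    return records, fmt


def write_sequences(records: Sequence[ReadRecord], path: str, fmt: str,
                    fasta_wrap: int = 80) -> None:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            if fmt == "fastq":
                fh.write(f"@{rec.description or rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
            else:
                fh.write(f">{rec.description or rec.id}\n")
                for i in range(0, len(rec.sequence), fasta_wrap):
                    fh.write(rec.sequence[i:i + fasta_wrap] + "\n")
                if not rec.sequence:
                    fh.write("\n")


def write_corrected(records: Sequence[ReadRecord], results: Sequence, path: str,
                    fmt: str) -> None:
    """Write corrected reads in the input's format and order.

    Aligned reads get their corrected sequence (qualities trimmed or padded
    with Q40 when an indel correction changed the length); unaligned reads
    are passed through unchanged.
    """
    if len(records) != len(results):
        raise ValueError("one alignment result required per input record")
    out: List[ReadRecord] = []
    for rec, res in zip(records, results):
        if not res.aligned:
            out.append(rec)
            continue
        seq = res.corrected_sequence
        qual = rec.quality
        if qual is not None and len(qual) != len(seq):
            qual = (qual[: len(seq)] + "I" * (len(seq) - len(qual)))[: len(seq)]
        out.append(ReadRecord(rec.id, rec.description, seq, qual))
    write_sequences(out, path, fmt)


def read_fasta_sequences(path: str) -> List[str]:
    """Just the sequences of a (possibly gzipped) FASTA, uppercased."""
    records, fmt = read_sequences(path)
    if fmt != "fasta":
        raise ValueError(f"{path}: expected FASTA")
    return [r.sequence.upper() for r in records]
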