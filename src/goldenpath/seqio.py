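"""Sequence I/O: FASTQ/FASTA reading and writing, Phred quality decoding.

All other modules consume :class:`ReadRecord`. Input is the standard
uncompressed (optionally gzipped) 4-line FASTQ with Sanger-offset (33)
qualities; output assemblies are written as wrapped FASTA.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and (optional) Phred string.

    ``seq`` is over {A,C,G,T,N} (lowercase input is upper-cased on ingest);
    ``qual`` uses the Sanger convention (ASCII offset 33) and, when present,
    has the same length as ``seq``.
    """

    name: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("read name must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` from a 4-line FASTQ file, in file order.

    Never loads the whole file; raises ``ValueError`` naming the record
    index on malformed records.
    """
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {index}: {exc}"
                ) from exc
            name = title.split()[0] if title.split() else ""
            if not name:
                raise ValueError(f"empty read name at record index {index}")
            yield ReadRecord(name=name, seq=seq.upper(), qual=qual)
            index += 1


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(name, seq)`` pairs from a FASTA file (upper-cased)."""
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            yield title.split()[0], seq.upper()


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, line_width: int = 60
) -> None:
    """Write ``(name, seq)`` pairs as FASTA, wrapping at ``line_width``.

    Names must be unique (the full header line counts as the name).
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    seen: set[str] = set()
    with open(path, "w") as out:
        for name, seq in records:
            if name in seen:
                raise ValueError(f"duplicate FASTA name: {name!r}")
            seen.add(name)
            out.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                out.write(seq[i : i + line_width] + "\n")


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"read {rec.name!r} has no qualities")
            out.write(f"@{rec.name}\n{rec.seq}\n+\n{rec.qual}\n")


def phred_values(qual: str) -> np.ndarray:
    """Integer Q values of a Sanger-offset quality string."""
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    if arr.size and (arr.min() < 33 or arr.max() > 126):
        raise ValueError("quality string outside printable Sanger range")
    return arr.astype(np.int32) - 33


def mean_phred(qual: str) -> float:
    """Arithmetic mean of per-base integer Phred scores (offset 33)."""
    if not qual:
        raise ValueError("empty quality string")
    return float(phred_values(qual).mean())
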