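"""Small FASTQ/FASTA helpers shared across modules.

Reading goes through Bio.SeqIO; writing is line-oriented (four-line FASTQ
records with a constant quality string — base qualities are never used by
the caller, so none are simulated). Gzipped output is written with a zeroed
mtime so that a fixed simulation seed yields byte-identical files.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

#: constant Phred quality written for every simulated base (Q30)
QUALITY_CHAR = "?"


class _GzTextWriter(io.TextIOWrapper):
    """Gzipped text writer with no filename/mtime in the header, so equal
    content yields byte-identical files regardless of path or wall clock."""

    def __init__(self, path):
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(filename="", fileobj=self._raw, mode="wb", mtime=0)
        super().__init__(self._gz)

    def close(self):
        super().close()
        self._raw.close()


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            return _GzTextWriter(path)
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a plain or gzipped FASTQ file."""
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_fastq(records: Iterable[tuple[str, str]], path) -> int:
    """Write (name, sequence) records as FASTQ with constant Q30 qualities."""
    n = 0
    with _open_text(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")
            n += 1
    return n


def write_fasta(sequences: dict[str, str], path) -> None:
    with _open_text(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
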