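"""Small FASTA/FASTQ helpers and sequence utilities.

FASTQ reading/writing is gzip-transparent based on the ``.gz`` suffix so the
pipeline consumes either compressed or plain files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a 4-line FASTQ file.

    The read id is the header token before the first whitespace, with any
    trailing ``/1`` or ``/2`` mate suffix removed.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            lineno += 4
            if not qual:
                raise InputError(f"{path}: truncated FASTQ record near line {lineno}")
            if not header.startswith("@"):
                raise InputError(f"{path}: line {lineno - 3}: expected '@' header")
            if not plus.startswith("+"):
                raise InputError(f"{path}: line {lineno - 1}: expected '+' separator")
            rid = header[1:].split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            yield rid, seq.strip().upper(), qual.strip()


def write_fastq(records, path: str | Path) -> int:
    """Write (read_id, sequence, quality|None) triples as FASTQ; returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            if qual is None:
                qual = "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (header, sequence) tuples from a FASTA file."""
    header = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:]
                chunks = []
            elif line:
                if header is None:
                    raise InputError(f"{path}: sequence before first FASTA header")
                chunks.append(line.upper())
    if header is not None:
        yield header, "".join(chunks)


def write_fasta(records, path: str | Path, width: int = 60) -> int:
    """Write (header, sequence) pairs as FASTA; returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n
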