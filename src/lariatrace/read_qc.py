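"""Ingestion of genome-unmapped paired-end reads and the ambiguous-base prefilter.

The canonical input path is a pair of FASTQ files holding already-extracted
unmapped reads; a SAM/BAM of alignments with unmapped flags is also supported.
Reads are always reported in their original sequencing orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from ._fastx import iter_fastq
from .errors import InputError

DEFAULT_MAX_N_FRAC = 0.05


@dataclass
class ReadRecord:
    """One sequencing read: pair id (no mate suffix), mate of origin, sequence."""

    read_id: str
    mate: int
    sequence: str
    quality: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise InputError(f"read {self.read_id}: mate must be 1 or 2")


@dataclass
class SampleInput:
    sample_id: str
    fastq_r1: str | Path | None = None
    fastq_r2: str | Path | None = None
    total_library_reads: int | None = None


def iter_fastq_reads(
    path: str | Path, mate: int, sample_id: str = ""
) -> Iterator[ReadRecord]:
    for rid, seq, qual in iter_fastq(path):
        yield ReadRecord(rid, mate, seq, qual, sample_id)


def iter_sample_reads(sample: SampleInput) -> Iterator[ReadRecord]:
    """Stream reads from the sample's FASTQ file(s), mate 1 then mate 2."""
    n1 = n2 = 0
    if sample.fastq_r1:
        for rec in iter_fastq_reads(sample.fastq_r1, 1, sample.sample_id):
            n1 += 1
            yield rec
    if sample.fastq_r2:
        for rec in iter_fastq_reads(sample.fastq_r2, 2, sample.sample_id):
            n2 += 1
            yield rec
    if sample.fastq_r1 and sample.fastq_r2 and n1 != n2:
        raise InputError(
            f"sample {sample.sample_id}: R1 has {n1} records but R2 has {n2}"
        )


def select_unmapped(bam_path: str | Path, sample_id: str = "") -> Iterator[ReadRecord]:
    """Yield unmapped reads from a SAM/BAM, in original sequencing orientation.

    Records stored reverse-complemented (reverse-strand flag set) are flipped
    back. Reads lacking mate flags raise.
    """
    import pysam

    with pysam.AlignmentFile(str(bam_path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if not aln.is_unmapped:
                continue
            if aln.is_paired:
                mate = 1 if aln.is_read1 else 2
            else:
                raise InputError(
                    f"{bam_path}: read {aln.query_name} lacks paired mate flags"
                )
            seq = aln.get_forward_sequence()
            if seq is None:
                raise InputError(f"{bam_path}: read {aln.query_name} has no sequence")
            qual = aln.qual if not aln.is_reverse else (
                aln.qual[::-1] if aln.qual else None
            )
            yield ReadRecord(aln.query_name, mate, seq.upper(), qual, sample_id)


def n_fraction(sequence: str) -> float:
    if not sequence:
        return 1.0
    return sequence.count("N") / len(sequence)


def filter_ambiguous(
    reads: Iterable[ReadRecord],
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    discard_log: list[tuple[str, int, str]] | None = None,
) -> Iterator[ReadRecord]:
    """Discard reads whose N fraction strictly exceeds ``max_n_frac``.

    Mates are filtered independently. When ``discard_log`` is given, each
    discarded read appends (read_id, mate, reason).
    """
    for read in reads:
        if n_fraction(read.sequence) > max_n_frac:
            if discard_log is not None:
                discard_log.append((read.read_id, read.mate, "ambiguous_bases"))
            continue
        yield read
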