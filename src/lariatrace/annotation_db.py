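"""Intron database construction.

Parses a GENCODE-style GTF, derives exclusively intronic regions by
strand-aware exon subtraction, filters them on a minimum length, and extracts
the splice-site flanking fragments (20 nt downstream of the 5' splice site,
250 nt upstream of the 3' splice site) that define the lariat search space.

All internal coordinates are 0-based half-open; GTF input is converted from
1-based inclusive on parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._fastx import VALID_BASES, iter_fasta, revcomp, write_fasta
from .errors import ConfigError, InputError, ValidationError

FIVE = "FIVE"
THREE = "THREE"

DEFAULT_MIN_INTRON_LEN = 300
FIVE_LEN = 20
THREE_LEN = 250

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class GeneModel:
    """A gene body with its merged exon intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene body "
                    f"({self.start},{self.end})"
                )


@dataclass(frozen=True)
class IntronicRegion:
    """A maximal exclusively intronic interval on one strand."""

    region_id: str
    gene_ids: tuple[str, ...]
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_ss_pos(self) -> int:
        """Genomic coordinate of the region's 5' boundary in transcription order."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_ss_pos(self) -> int:
        """Genomic coordinate of the region's 3' boundary in transcription order."""
        return self.end if self.strand == "+" else self.start


def make_region_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def parse_region_id(region_id: str) -> tuple[str, int, int, str]:
    chrom, span, strand = region_id.rsplit(":", 2)
    s, e = span.split("-")
    return chrom, int(s), int(e), strand


@dataclass(frozen=True)
class SpliceSiteFragment:
    """A splice-site flanking sequence in transcription orientation.

    ``side == FIVE``: the first 20 nt of the intronic region (downstream of the
    5' splice site). ``side == THREE``: the last 250 nt (upstream of the 3'
    splice site). The sequence equals the genome slice at ``genomic_interval``,
    reverse-complemented for minus-strand regions.
    """

    fragment_id: str
    region_id: str
    side: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_ids: tuple[str, ...]

    def branchpoint_position(self, ref_offset: int) -> int:
        """Map an offset within the fragment to a genomic coordinate."""
        if not 0 <= ref_offset < self.end - self.start:
            raise ValueError(f"offset {ref_offset} outside fragment {self.fragment_id}")
        if self.strand == "+":
            return self.start + ref_offset
        return self.end - 1 - ref_offset


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent-duplicate intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(
    body: tuple[int, int], blocks: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Return maximal sub-intervals of ``body`` not covered by ``blocks``.

    ``blocks`` must be sorted and disjoint (as from :func:`merge_intervals`).
    """
    out: list[tuple[int, int]] = []
    cursor, end = body
    for bs, be in blocks:
        if be <= cursor or bs >= end:
            continue
        if bs > cursor:
            out.append((cursor, bs))
        cursor = max(cursor, be)
        if cursor >= end:
            break
    if cursor < end:
        out.append((cursor, end))
    return out


def parse_annotation(
    gtf_path: str | Path, contig_filter: set[str] | None = None
) -> list[GeneModel]:
    """Parse a GTF into GeneModels with merged exons.

    Exons are collected per ``gene_id`` across all transcripts and merged.
    The gene body is taken from the ``gene`` feature when present, otherwise
    from the exon span. Coordinates convert from 1-based inclusive to 0-based
    half-open.
    """
    bodies: dict[str, tuple[str, str, int, int]] = {}
    has_gene_feature: set[str] = set()
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise InputError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "exon"):
                continue
            if contig_filter is not None and chrom not in contig_filter:
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise InputError(f"{gtf_path}: line {lineno}: bad coordinates") from exc
            if start < 0 or start >= end:
                raise InputError(f"{gtf_path}: line {lineno}: invalid interval")
            if strand not in "+-":
                raise InputError(f"{gtf_path}: line {lineno}: bad strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if not gid:
                raise InputError(f"{gtf_path}: line {lineno}: missing gene_id attribute")
            if gid not in exons:
                exons[gid] = []
                order.append(gid)
            if feature == "gene":
                bodies[gid] = (chrom, strand, start, end)
                has_gene_feature.add(gid)
            else:
                exons[gid].append((start, end))
                bodies.setdefault(gid, (chrom, strand, start, end))

    genes: list[GeneModel] = []
    for gid in order:
        exon_list = merge_intervals(exons[gid])
        chrom, strand, bstart, bend = bodies[gid]
        if exon_list and gid not in has_gene_feature:
            # no explicit gene feature: body = exon span
            bstart = exon_list[0][0]
            bend = max(e for _, e in exon_list)
        gene = GeneModel(gid, chrom, strand, bstart, bend, exon_list)
        gene.validate()
        genes.append(gene)
    return genes


def exclusive_intronic_regions(
    genes: Sequence[GeneModel], subtract_strand: str = "same"
) -> list[IntronicRegion]:
    """Compute exclusively intronic regions by exon subtraction.

    For each gene, the gene body minus the merged exons of every gene on the
    same chromosome and (under ``subtract_strand='same'``) the same strand;
    ``'both'`` subtracts exons regardless of strand. Identical resulting
    intervals from multiple genes are collapsed into one region carrying all
    contributing gene ids, sorted.
    """
    if subtract_strand not in ("same", "both"):
        raise ConfigError(f"subtract_strand must be 'same' or 'both', got {subtract_strand!r}")

    exon_pool: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes:
        key = (g.chrom, g.strand if subtract_strand == "same" else ".")
        exon_pool.setdefault(key, []).extend(g.exons)
    merged_pool = {k: merge_intervals(v) for k, v in exon_pool.items()}

    found: dict[tuple[str, int, int, str], set[str]] = {}
    order: list[tuple[str, int, int, str]] = []
    for g in genes:
        key = (g.chrom, g.strand if subtract_strand == "same" else ".")
        blocks = merged_pool.get(key, [])
        for s, e in subtract_intervals((g.start, g.end), blocks):
            k = (g.chrom, s, e, g.strand)
            if k not in found:
                found[k] = set()
                order.append(k)
            found[k].add(g.gene_id)

    return [
        IntronicRegion(
            region_id=make_region_id(chrom, s, e, strand),
            gene_ids=tuple(sorted(found[(chrom, s, e, strand)])),
            chrom=chrom,
            strand=strand,
            start=s,
            end=e,
        )
        for chrom, s, e, strand in order
    ]


def filter_min_length(
    regions: Sequence[IntronicRegion],
    min_len: int = DEFAULT_MIN_INTRON_LEN,
    allow_overlapping_fragments: bool = False,
) -> list[IntronicRegion]:
    """Keep regions with length >= min_len (order preserved).

    ``min_len`` below 270 (= 20 + 250) would let the two splice-site fragments
    of a region overlap and is refused unless explicitly overridden.
    """
    if min_len < FIVE_LEN + THREE_LEN and not allow_overlapping_fragments:
        raise ConfigError(
            f"min_len={min_len} < {FIVE_LEN + THREE_LEN} would allow overlapping "
            "5'/3' fragments; pass allow_overlapping_fragments=True to override"
        )
    return [r for r in regions if r.length >= min_len]


def extract_fragments(
    regions: Sequence[IntronicRegion],
    genome: Mapping[str, str],
    five_len: int = FIVE_LEN,
    three_len: int = THREE_LEN,
) -> tuple[list[SpliceSiteFragment], list[SpliceSiteFragment]]:
    """Extract the FIVE (first ``five_len`` nt) and THREE (last ``three_len`` nt)
    fragments of each region, in transcription orientation.

    ``genome`` maps contig name to sequence (a ``pyfaidx.Fasta`` works via
    ``str(genome[chrom][s:e])``; plain dict of strings also works).
    """
    fives: list[SpliceSiteFragment] = []
    threes: list[SpliceSiteFragment] = []
    for region in regions:
        if region.length < five_len + three_len:
            raise ValidationError(
                f"region {region.region_id}: length {region.length} < "
                f"{five_len + three_len}; filter regions first"
            )
        contig = genome[region.chrom]
        contig_len = len(contig)
        if region.end > contig_len:
            raise InputError(
                f"region {region.region_id} extends past end of contig "
                f"{region.chrom} (length {contig_len})"
            )
        if region.strand == "+":
            five_iv = (region.start, region.start + five_len)
            three_iv = (region.end - three_len, region.end)
        else:
            five_iv = (region.end - five_len, region.end)
            three_iv = (region.start, region.start + three_len)
        for side, (s, e) in ((FIVE, five_iv), (THREE, three_iv)):
            seq = str(contig[s:e]).upper()
            if region.strand == "-":
                seq = revcomp(seq)
            bad = set(seq) - VALID_BASES
            if bad:
                raise InputError(
                    f"region {region.region_id}: non-ACGTN characters {sorted(bad)} "
                    "in genome slice"
                )
            frag = SpliceSiteFragment(
                fragment_id=f"{region.region_id}:{'5p' if side == FIVE else '3p'}",
                region_id=region.region_id,
                side=side,
                sequence=seq,
                chrom=region.chrom,
                start=s,
                end=e,
                strand=region.strand,
                gene_ids=region.gene_ids,
            )
            (fives if side == FIVE else threes).append(frag)
    return fives, threes


def _fragment_header(frag: SpliceSiteFragment) -> str:
    genes = ",".join(frag.gene_ids)
    return (
        f"{frag.fragment_id}|{frag.region_id}|{genes}|{frag.strand}|"
        f"{frag.chrom}:{frag.start}-{frag.end}"
    )


def write_fragment_fasta(fragments: Sequence[SpliceSiteFragment], path: str | Path) -> int:
    """Write fragments as FASTA with provenance-bearing headers."""
    return write_fasta(((_fragment_header(f), f.sequence) for f in fragments), path)


def read_fragment_fasta(path: str | Path) -> list[SpliceSiteFragment]:
    """Read fragments written by :func:`write_fragment_fasta` (lossless round-trip)."""
    out: list[SpliceSiteFragment] = []
    for header, seq in iter_fasta(path):
        parts = header.split("|")
        if len(parts) != 5:
            raise InputError(f"{path}: malformed fragment header {header!r}")
        fragment_id, region_id, genes, strand, span = parts
        chrom, coords = span.rsplit(":", 1)
        s, e = (int(x) for x in coords.split("-"))
        side = FIVE if fragment_id.endswith(":5p") else THREE
        out.append(
            SpliceSiteFragment(
                fragment_id=fragment_id,
                region_id=region_id,
                side=side,
                sequence=seq,
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                gene_ids=tuple(genes.split(",")) if genes else (),
            )
        )
    return out


def write_introns_bed(regions: Sequence[IntronicRegion], path: str | Path) -> int:
    """Write regions as BED6 (name=region_id, score=length)."""
    n = 0
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.length}\t{r.strand}\n"
            )
            n += 1
    return n


def read_introns_bed(path: str | Path) -> list[IntronicRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, s, e, rid, _length, strand = line.rstrip("\n").split("\t")
            out.append(
                IntronicRegion(
                    region_id=rid,
                    gene_ids=(),
                    chrom=chrom,
                    strand=strand,
                    start=int(s),
                    end=int(e),
                )
            )
    return out


def build_intron_database(
    gtf_path: str | Path,
    genome: Mapping[str, str],
    min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
    subtract_strand: str = "same",
    contig_filter: set[str] | None = None,
) -> tuple[list[IntronicRegion], list[SpliceSiteFragment], list[SpliceSiteFragment]]:
    """Full annotation_db chain: parse -> subtract -> filter -> extract."""
    genes = parse_annotation(gtf_path, contig_filter=contig_filter)
    regions = exclusive_intronic_regions(genes, subtract_strand=subtract_strand)
    regions = filter_min_length(regions, min_len=min_intron_len)
    fives, threes = extract_fragments(regions, genome)
    return regions, fives, threes
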