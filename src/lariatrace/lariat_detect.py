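"""Branchpoint-spanning read detection.

A candidate lariat read carries the 3'-intronic sequence ending at the
branchpoint followed by the first nucleotides of the same intron. Detection:

1. exact unique 20-mer match of a 5' splice-site fragment in the read
   (either orientation),
2. trim to the retained 3'-intronic segment (mate-aware, UMI-aware),
3. semi-global alignment of the segment against the 250 nt 3' splice-site
   fragments,
4. mismatch / mismatch-rate / indel filters and a 3' uniqueness requirement,
5. gene/strand/orientation/transcription-order consistency,
6. the mate-strand rule (read 1 sense, read 2 antisense),
7. branchpoint = genomic position aligned to the segment's 3'-terminal base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._align import Alignment, Scoring, semiglobal_align, semiglobal_score
from ._fastx import revcomp
from .annotation_db import (
    IntronicRegion,
    SpliceSiteFragment,
    parse_region_id,
    read_fragment_fasta,
)
from .errors import ConfigError, InputError
from .read_qc import ReadRecord

SENSE = "SENSE"
ANTISENSE = "ANTISENSE"

K5 = 20  # 5' splice-site fragment length


@dataclass(frozen=True)
class DetectParams:
    umi_len: int = 12
    min_segment: int = 20
    max_mismatches: int = 5
    max_mismatch_rate: float = 0.10
    max_indel: int = 3
    # alignments with more than this many separate gap runs are never
    # considered filter-passing when screening non-best fragments
    max_gap_runs: int = 4
    umi_dedup: bool = False
    scoring: Scoring = field(default_factory=Scoring)

    @property
    def pass_score_floor(self) -> int:
        s = self.scoring
        return -(
            self.max_mismatches * s.mismatch
            + self.max_gap_runs * (s.gap_open + s.gap_extend * self.max_indel)
        )


@dataclass(frozen=True)
class FivePrimeMatch:
    read_id: str
    mate: int
    fragment_id: str
    match_start: int
    match_end: int
    orientation: str
    ambiguous: bool = False


@dataclass(frozen=True)
class TrimmedSegment:
    read_id: str
    mate: int
    sequence: str
    source_interval: tuple[int, int]


@dataclass(frozen=True)
class ThreePrimeAlignment:
    fragment_id: str
    orientation: str
    ref_start: int
    ref_end: int
    mismatches: int
    max_indel_len: int
    total_indel_len: int
    score: int
    segment_len: int


@dataclass(frozen=True)
class Align3pResult:
    best: ThreePrimeAlignment | None
    unique: bool
    passing_fragments: tuple[str, ...]


@dataclass(frozen=True)
class LariatCall:
    read_id: str
    sample_id: str
    mate: int
    gene_ids: tuple[str, ...]
    five_region_id: str
    three_region_id: str
    same_region: bool
    chrom: str
    bp_pos: int
    bp_base: str
    mismatches: int
    max_indel_len: int
    strand: str
    umi: str = ""


class AmbiguousKmer:
    """Sentinel index entry: 20-mer shared by distinct fragments/orientations."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "<ambiguous>"


AMBIGUOUS = AmbiguousKmer()


@dataclass
class FragmentDb:
    """The splice-site fragment database the detector searches against."""

    fives: list[SpliceSiteFragment]
    threes: list[SpliceSiteFragment]

    def __post_init__(self) -> None:
        self.five_by_id = {f.fragment_id: f for f in self.fives}
        self.three_by_id = {f.fragment_id: f for f in self.threes}
        self.three_by_region = {f.region_id: f for f in self.threes}
        self.five_by_region = {f.region_id: f for f in self.fives}
        regions: dict[str, IntronicRegion] = {}
        for f in self.fives + self.threes:
            if f.region_id not in regions:
                chrom, s, e, strand = parse_region_id(f.region_id)
                regions[f.region_id] = IntronicRegion(
                    region_id=f.region_id,
                    gene_ids=f.gene_ids,
                    chrom=chrom,
                    strand=strand,
                    start=s,
                    end=e,
                )
        self.regions = regions
        self.index = build_5p_index(self.fives)

    @classmethod
    def load(cls, index_dir: str | Path) -> "FragmentDb":
        index_dir = Path(index_dir)
        fives = read_fragment_fasta(index_dir / "fivess.fa")
        threes = read_fragment_fasta(index_dir / "threess.fa")
        return cls(fives, threes)


def build_5p_index(
    five_fragments: Sequence[SpliceSiteFragment],
) -> dict[str, tuple[str, str] | AmbiguousKmer]:
    """Exact-match lookup: 20-mer -> (fragment_id, orientation) or AMBIGUOUS.

    Fragments containing N are unmatchable and excluded. A 20-mer claimed by
    two distinct fragments, or by one fragment in both orientations
    (reverse-complement palindrome), is marked ambiguous.
    """
    index: dict[str, tuple[str, str] | AmbiguousKmer] = {}
    for frag in five_fragments:
        if len(frag.sequence) != K5:
            raise InputError(
                f"5' fragment {frag.fragment_id} has length {len(frag.sequence)}, "
                f"expected {K5}"
            )
        if "N" in frag.sequence:
            continue
        for kmer, orientation in (
            (frag.sequence, SENSE),
            (revcomp(frag.sequence), ANTISENSE),
        ):
            existing = index.get(kmer)
            if existing is None:
                index[kmer] = (frag.fragment_id, orientation)
            elif isinstance(existing, AmbiguousKmer):
                pass
            elif existing != (frag.fragment_id, orientation):
                index[kmer] = AMBIGUOUS
    return index


def match_5p(
    read: ReadRecord, index: Mapping[str, tuple[str, str] | AmbiguousKmer]
) -> list[FivePrimeMatch]:
    """All exact 20-mer occurrences of indexed fragments at every read offset."""
    seq = read.sequence
    out: list[FivePrimeMatch] = []
    for off in range(len(seq) - K5 + 1):
        hit = index.get(seq[off : off + K5])
        if hit is None:
            continue
        if isinstance(hit, AmbiguousKmer):
            out.append(
                FivePrimeMatch(read.read_id, read.mate, "", off, off + K5, SENSE, True)
            )
        else:
            fragment_id, orientation = hit
            out.append(
                FivePrimeMatch(
                    read.read_id, read.mate, fragment_id, off, off + K5, orientation
                )
            )
    return out


def resolve_unique_5p(
    matches: Sequence[FivePrimeMatch],
) -> tuple[FivePrimeMatch | None, str | None]:
    """Accept iff the read has exactly one unambiguous 5' fragment match."""
    if not matches:
        return None, "no_match"
    if any(m.ambiguous for m in matches):
        return None, "ambiguous_kmer"
    if len(matches) == 1:
        return matches[0], None
    if len({m.fragment_id for m in matches}) > 1:
        return None, "multi_site"
    return None, "multi_position"


def trim_read(
    read: ReadRecord,
    match: FivePrimeMatch,
    umi_len: int = 12,
    min_segment: int = 20,
) -> tuple[TrimmedSegment | None, str | None]:
    """Retain the read portion on the branchpoint side of the 5' match.

    SENSE match: the prefix before the match; ANTISENSE: the suffix after it.
    Mate-1 reads additionally lose their first ``umi_len`` positions (UMI).
    """
    n = len(read.sequence)
    if not (0 <= match.match_start < match.match_end <= n):
        raise ValueError(
            f"match offsets ({match.match_start},{match.match_end}) outside read "
            f"{read.read_id} of length {n}"
        )
    if match.orientation == SENSE:
        lo, hi = 0, match.match_start
    else:
        lo, hi = match.match_end, n
    if read.mate == 1:
        lo = max(lo, umi_len)
    if hi - lo < min_segment:
        return None, "short_segment"
    return (
        TrimmedSegment(read.read_id, read.mate, read.sequence[lo:hi], (lo, hi)),
        None,
    )


def _to_three_alignment(
    aln: Alignment, fragment_id: str, orientation: str
) -> ThreePrimeAlignment:
    return ThreePrimeAlignment(
        fragment_id=fragment_id,
        orientation=orientation,
        ref_start=aln.ref_start,
        ref_end=aln.ref_end,
        mismatches=aln.mismatches,
        max_indel_len=aln.max_indel,
        total_indel_len=aln.total_indel,
        score=aln.score,
        segment_len=aln.query_len,
    )


def _passes_thresholds(aln: ThreePrimeAlignment, params: DetectParams) -> bool:
    return (
        aln.mismatches <= params.max_mismatches
        and aln.mismatches <= params.max_mismatch_rate * aln.segment_len
        and aln.max_indel_len <= params.max_indel
    )


def align_3p(
    segment: TrimmedSegment | str,
    three_fragments: Sequence[SpliceSiteFragment],
    params: DetectParams = DetectParams(),
) -> Align3pResult:
    """Best semi-global alignment of the segment over all 3' fragments.

    Each fragment is scored in both orientations (ANTISENSE aligns the
    segment's reverse complement). A fast score-only screen ranks fragments;
    full alignments with statistics are computed for the best-scoring
    candidates and for every candidate whose score could still pass the
    filters (``params.pass_score_floor``). Uniqueness fails when a distinct
    fragment ties the best score or also passes the filters.
    """
    seq = segment.sequence if isinstance(segment, TrimmedSegment) else segment
    if len(seq) < 20:
        raise ConfigError(f"segment shorter than 20 nt ({len(seq)})")
    if not three_fragments:
        return Align3pResult(None, True, ())

    queries = {SENSE: seq, ANTISENSE: revcomp(seq)}
    screened: list[tuple[int, str, str]] = []  # (score, fragment_id, orientation)
    frag_by_id = {f.fragment_id: f for f in three_fragments}
    for frag in three_fragments:
        for orientation in (SENSE, ANTISENSE):
            score = semiglobal_score(queries[orientation], frag.sequence, params.scoring)
            screened.append((score, frag.fragment_id, orientation))

    best_score = max(s for s, _, _ in screened)
    floor = min(best_score, params.pass_score_floor)

    detailed: dict[tuple[str, str], ThreePrimeAlignment] = {}
    for score, fid, orientation in screened:
        if score < floor:
            continue
        aln = semiglobal_align(
            queries[orientation], frag_by_id[fid].sequence, params.scoring
        )
        detailed[(fid, orientation)] = _to_three_alignment(aln, fid, orientation)

    # winner: higher score, then SENSE before ANTISENSE on the same fragment,
    # then lexicographic fragment_id, then smaller ref_start
    winner = min(
        (a for a in detailed.values() if a.score == best_score),
        key=lambda a: (-a.score, a.fragment_id, a.orientation != SENSE, a.ref_start),
    )

    passing: set[str] = set()
    for (fid, _), aln in detailed.items():
        if _passes_thresholds(aln, params):
            passing.add(fid)
    ties = {fid for s, fid, _ in screened if s == best_score}
    others = (passing | ties) - {winner.fragment_id}
    return Align3pResult(winner, not others, tuple(sorted(passing)))


def filter_3p(
    alignment: ThreePrimeAlignment,
    segment_len: int | None = None,
    params: DetectParams = DetectParams(),
    unique: bool = True,
) -> tuple[bool, str | None]:
    """Apply the mismatch-count, mismatch-rate, indel-run and uniqueness filters.

    Thresholds are strict: >5 mismatches, rate >10%, gap run >3 nt fail;
    the boundary values pass.
    """
    n = segment_len if segment_len is not None else alignment.segment_len
    if alignment.mismatches > params.max_mismatches:
        return False, "mismatch_count"
    if alignment.mismatches > params.max_mismatch_rate * n:
        return False, "mismatch_rate"
    if alignment.max_indel_len > params.max_indel:
        return False, "indel"
    if not unique:
        return False, "multi_3p"
    return True, None


def consistency_checks(
    five_region: IntronicRegion,
    three_region: IntronicRegion,
    five_orientation: str,
    three_orientation: str,
) -> tuple[bool, str | None, bool]:
    """Gene/strand/orientation/transcription-order consistency.

    Returns (pass, fail_reason, same_region).
    """
    same_region = five_region.region_id == three_region.region_id
    if not set(five_region.gene_ids) & set(three_region.gene_ids):
        return False, "gene_mismatch", same_region
    if five_region.strand != three_region.strand:
        return False, "strand_mismatch", same_region
    if five_orientation != three_orientation:
        return False, "orientation_mismatch", same_region
    if not same_region:
        if five_region.strand == "+":
            ordered = five_region.five_ss_pos <= three_region.three_ss_pos
        else:
            ordered = five_region.five_ss_pos >= three_region.three_ss_pos
        if not ordered:
            return False, "order", same_region
    return True, None, same_region


def mate_strand_check(mate: int, orientation: str) -> bool:
    """Read 1 must map sense to the transcript, read 2 antisense."""
    if mate not in (1, 2):
        raise InputError(f"mate must be 1 or 2, got {mate}")
    return orientation == (SENSE if mate == 1 else ANTISENSE)


def call_branchpoint(
    alignment: ThreePrimeAlignment, fragment: SpliceSiteFragment
) -> tuple[str, int, str]:
    """Branchpoint = genomic position of the fragment base aligned to the
    segment's transcription-orientation 3'-terminal base (ref_end - 1)."""
    offset = alignment.ref_end - 1
    pos = fragment.branchpoint_position(offset)
    base = fragment.sequence[offset]
    return fragment.chrom, pos, base


def detect_read(
    read: ReadRecord, db: FragmentDb, params: DetectParams = DetectParams()
) -> tuple[LariatCall | None, str | None]:
    """Run the full per-read chain; returns (call, first_failing_stage)."""
    if len(read.sequence) < K5:
        return None, "no_match"
    matches = match_5p(read, db.index)
    match, reason = resolve_unique_5p(matches)
    if match is None:
        return None, reason
    segment, reason = trim_read(read, match, params.umi_len, params.min_segment)
    if segment is None:
        return None, reason

    result = align_3p(segment, db.threes, params)
    if result.best is None:
        return None, "no_3p_alignment"
    ok, reason = filter_3p(result.best, segment_len=len(segment.sequence), params=params, unique=result.unique)
    if not ok:
        return None, reason

    five_frag = db.five_by_id[match.fragment_id]
    three_frag = db.three_by_id[result.best.fragment_id]
    five_region = db.regions[five_frag.region_id]
    three_region = db.regions[three_frag.region_id]
    ok, reason, same_region = consistency_checks(
        five_region, three_region, match.orientation, result.best.orientation
    )
    if not ok:
        return None, reason
    if not mate_strand_check(read.mate, match.orientation):
        return None, "mate_strand"

    chrom, pos, base = call_branchpoint(result.best, three_frag)
    gene_ids = tuple(sorted(set(five_region.gene_ids) & set(three_region.gene_ids)))
    umi = read.sequence[: params.umi_len] if read.mate == 1 else ""
    call = LariatCall(
        read_id=read.read_id,
        sample_id=read.sample_id,
        mate=read.mate,
        gene_ids=gene_ids,
        five_region_id=five_region.region_id,
        three_region_id=three_region.region_id,
        same_region=same_region,
        chrom=chrom,
        bp_pos=pos,
        bp_base=base,
        mismatches=result.best.mismatches,
        max_indel_len=result.best.max_indel_len,
        strand=five_region.strand,
        umi=umi,
    )
    return call, None


#: pipeline stages in order, used for audit/manifest bookkeeping
STAGE_ORDER = (
    "input",
    "five_prime_matched",
    "trimmed_retained",
    "three_prime_passed",
    "consistency_passed",
    "mate_strand_passed",
    "calls",
)

_FAIL_STAGE = {
    "no_match": "five_prime_matched",
    "multi_site": "five_prime_matched",
    "multi_position": "five_prime_matched",
    "ambiguous_kmer": "five_prime_matched",
    "short_segment": "trimmed_retained",
    "no_3p_alignment": "three_prime_passed",
    "mismatch_count": "three_prime_passed",
    "mismatch_rate": "three_prime_passed",
    "indel": "three_prime_passed",
    "multi_3p": "three_prime_passed",
    "gene_mismatch": "consistency_passed",
    "strand_mismatch": "consistency_passed",
    "orientation_mismatch": "consistency_passed",
    "order": "consistency_passed",
    "mate_strand": "mate_strand_passed",
}


def stage_counts(n_input: int, audit: Sequence[tuple[str, int, str]]) -> dict[str, int]:
    """Per-stage surviving-read counts from the audit log (non-increasing)."""
    failed_at = {stage: 0 for stage in STAGE_ORDER}
    for _, _, reason in audit:
        failed_at[_FAIL_STAGE[reason]] += 1
    counts = {"input": n_input}
    remaining = n_input
    for stage in STAGE_ORDER[1:]:
        remaining -= failed_at[stage]
        counts[stage] = remaining
    return counts


def dedup_calls(calls: Sequence[LariatCall]) -> list[LariatCall]:
    """Collapse calls sharing (UMI, branchpoint); UMI-less reads never collapse."""
    seen: set[tuple[str, str, int]] = set()
    out: list[LariatCall] = []
    for call in calls:
        if call.umi:
            key = (call.umi, call.chrom, call.bp_pos)
            if key in seen:
                continue
            seen.add(key)
        out.append(call)
    return out


def detect_sample(
    reads: Iterable[ReadRecord],
    db: FragmentDb,
    params: DetectParams = DetectParams(),
) -> tuple[list[LariatCall], list[tuple[str, int, str]], int]:
    """Detect lariat calls for one sample.

    Returns (calls sorted by sample/chrom/position/read id, audit log of
    (read_id, mate, first failing stage), number of input reads).
    """
    calls: list[LariatCall] = []
    audit: list[tuple[str, int, str]] = []
    n_input = 0
    for read in reads:
        n_input += 1
        call, reason = detect_read(read, db, params)
        if call is not None:
            calls.append(call)
        else:
            audit.append((read.read_id, read.mate, reason))
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.bp_pos, c.read_id, c.mate))
    if params.umi_dedup:
        calls = dedup_calls(calls)
    return calls, audit, n_input


CALL_COLUMNS = (
    "sample_id",
    "read_id",
    "mate",
    "gene_ids",
    "five_region_id",
    "three_region_id",
    "same_region",
    "chrom",
    "bp_pos",
    "bp_base",
    "mismatches",
    "max_indel",
    "strand",
)


def write_calls_tsv(calls: Sequence[LariatCall], path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.sample_id,
                        c.read_id,
                        c.mate,
                        ",".join(c.gene_ids),
                        c.five_region_id,
                        c.three_region_id,
                        c.same_region,
                        c.chrom,
                        c.bp_pos,
                        c.bp_base,
                        c.mismatches,
                        c.max_indel_len,
                        c.strand,
                    )
                )
                + "\n"
            )
    return len(calls)


def write_branchpoints_bed(calls: Sequence[LariatCall], path: str | Path) -> int:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.bp_pos}\t{c.bp_pos + 1}\t{c.read_id}\t"
                f"{c.mismatches}\t{c.strand}\n"
            )
    return len(calls)


def write_audit_tsv(audit: Sequence[tuple[str, int, str]], path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tfail_stage\n")
        for rid, mate, reason in audit:
            fh.write(f"{rid}\t{mate}\t{reason}\n")
    return len(audit)
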