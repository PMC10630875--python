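"""Core detection chain: 5' matching, trimming, 3' alignment, filters,
consistency, mate/strand rule, branchpoint calling, per-read composition."""

from __future__ import annotations

import random

import pytest

from lariatrace._fastx import revcomp
from lariatrace.annotation_db import (
    SpliceSiteFragment,
    exclusive_intronic_regions,
    extract_fragments,
)
from lariatrace.errors import ConfigError, InputError
from lariatrace.lariat_detect import (
    ANTISENSE,
    SENSE,
    DetectParams,
    FivePrimeMatch,
    FragmentDb,
    ThreePrimeAlignment,
    align_3p,
    build_5p_index,
    call_branchpoint,
    consistency_checks,
    detect_read,
    detect_sample,
    filter_3p,
    match_5p,
    mate_strand_check,
    resolve_unique_5p,
    trim_read,
)
from lariatrace.read_qc import ReadRecord

from .conftest import make_gene, random_seq
from .oracles import window_scan_5p


def _five(seq, fid="F1", region="chr1:100-500:+"):
    chrom, span, strand = region.rsplit(":", 2)
    s, e = (int(x) for x in span.split("-"))
    iv = (s, s + 20) if strand == "+" else (e - 20, e)
    return SpliceSiteFragment(fid, region, "FIVE", seq, chrom, iv[0], iv[1], strand, ("G1",))


class TestBuild5pIndex:
    def test_sense_and_antisense_resolve(self, rng):
        seq = random_seq(rng, 20)
        index = build_5p_index([_five(seq)])
        assert index[seq] == ("F1", SENSE)
        assert index[revcomp(seq)] == ("F1", ANTISENSE)

    def test_duplicate_sequence_marked_ambiguous(self, rng):
        seq = random_seq(rng, 20)
        index = build_5p_index([_five(seq, "F1"), _five(seq, "F2")])
        from lariatrace.lariat_detect import AmbiguousKmer

        assert isinstance(index[seq], AmbiguousKmer)
        assert isinstance(index[revcomp(seq)], AmbiguousKmer)

    def test_fragment_with_n_excluded(self, rng):
        seq = "N" + random_seq(rng, 19)
        assert build_5p_index([_five(seq)]) == {}

    def test_wrong_length_raises(self, rng):
        with pytest.raises(InputError, match="length"):
            build_5p_index([_five(random_seq(rng, 19))])


class TestMatch5p:
    def test_planted_sense_match(self, rng):
        frag = _five(random_seq(rng, 20))
        index = build_5p_index([frag])
        read = ReadRecord("r", 1, random_seq(rng, 40) + frag.sequence + random_seq(rng, 10))
        matches = match_5p(read, index)
        assert len(matches) == 1
        m = matches[0]
        assert (m.fragment_id, m.orientation, m.match_start, m.match_end) == (
            "F1",
            SENSE,
            40,
            60,
        )

    def test_planted_antisense_match(self, rng):
        frag = _five(random_seq(rng, 20))
        index = build_5p_index([frag])
        read = ReadRecord("r", 2, random_seq(rng, 10) + revcomp(frag.sequence) + random_seq(rng, 30))
        (m,) = match_5p(read, index)
        assert (m.orientation, m.match_start, m.match_end) == (ANTISENSE, 10, 30)

    def test_two_occurrences_two_matches(self, rng):
        frag = _five(random_seq(rng, 20))
        index = build_5p_index([frag])
        read = ReadRecord("r", 1, frag.sequence + "ACGTACGTAC" + frag.sequence)
        matches = match_5p(read, index)
        assert [m.match_start for m in matches] == [0, 30]

    def test_equals_bruteforce_window_scan(self, rng):
        frags = [_five(random_seq(rng, 20), f"F{i}") for i in range(5)]
        index = build_5p_index(frags)
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(20, 200)))
            if rng.random() < 0.7:
                f = frags[int(rng.integers(0, len(frags)))]
                ins = f.sequence if rng.random() < 0.5 else revcomp(f.sequence)
                pos = int(rng.integers(0, len(seq) - 19))
                seq = seq[:pos] + ins + seq[pos + 20 :]
            read = ReadRecord("r", 1, seq)
            got = [(m.match_start, (m.fragment_id, m.orientation)) for m in match_5p(read, index)]
            assert got == window_scan_5p(seq, index)


class TestResolveUnique5p:
    def _m(self, fid="F1", start=0, ambiguous=False):
        return FivePrimeMatch("r", 1, fid, start, start + 20, SENSE, ambiguous)

    def test_no_match(self):
        assert resolve_unique_5p([]) == (None, "no_match")

    def test_single_match_accepted(self):
        m = self._m()
        assert resolve_unique_5p([m]) == (m, None)

    def test_two_sites_rejected(self):
        assert resolve_unique_5p([self._m("F1"), self._m("F2", 40)])[1] == "multi_site"

    def test_same_site_two_positions_rejected(self):
        assert (
            resolve_unique_5p([self._m("F1"), self._m("F1", 40)])[1] == "multi_position"
        )

    def test_ambiguous_kmer_rejected(self):
        assert resolve_unique_5p([self._m(ambiguous=True)])[1] == "ambiguous_kmer"


class TestTrimRead:
    def _read(self, mate=1, n=150):
        random.seed(0)
        return ReadRecord("r", mate, "".join(random.choice("ACGT") for _ in range(n)))

    def test_mate1_sense_keeps_prefix_minus_umi(self):
        read = self._read(mate=1)
        m = FivePrimeMatch("r", 1, "F1", 52, 72, SENSE)
        seg, reason = trim_read(read, m)
        assert reason is None
        assert seg.sequence == read.sequence[12:52]
        assert seg.source_interval == (12, 52)

    def test_mate1_sense_short_segment_rejected(self):
        read = self._read(mate=1)
        m = FivePrimeMatch("r", 1, "F1", 28, 48, SENSE)
        seg, reason = trim_read(read, m)
        assert seg is None and reason == "short_segment"

    def test_mate2_antisense_keeps_suffix(self):
        read = self._read(mate=2)
        m = FivePrimeMatch("r", 2, "F1", 60, 80, ANTISENSE)
        seg, reason = trim_read(read, m)
        assert seg.sequence == read.sequence[80:150]
        assert len(seg.sequence) == 70

    def test_mate2_no_umi_trim(self):
        read = self._read(mate=2)
        m = FivePrimeMatch("r", 2, "F1", 30, 50, SENSE)
        seg, _ = trim_read(read, m)
        assert seg.sequence == read.sequence[0:30]

    def test_mate1_antisense_umi_does_not_cut_suffix(self):
        read = self._read(mate=1)
        m = FivePrimeMatch("r", 1, "F1", 20, 40, ANTISENSE)
        seg, _ = trim_read(read, m)
        assert seg.source_interval == (40, 150)

    def test_out_of_range_match_raises(self):
        read = self._read()
        m = FivePrimeMatch("r", 1, "F1", 140, 160, SENSE)
        with pytest.raises(ValueError, match="outside read"):
            trim_read(read, m)


def _three(seq, fid="T1", region="chr1:1000-1400:+"):
    chrom, span, strand = region.rsplit(":", 2)
    s, e = (int(x) for x in span.split("-"))
    iv = (e - 250, e) if strand == "+" else (s, s + 250)
    return SpliceSiteFragment(fid, region, "THREE", seq, chrom, iv[0], iv[1], strand, ("G1",))


class TestAlign3p:
    def test_identity_segment(self, rng):
        frag = _three(random_seq(rng, 250))
        segment = frag.sequence[200:240]
        res = align_3p(segment, [frag])
        best = res.best
        assert (best.ref_start, best.ref_end) == (200, 240)
        assert best.mismatches == 0 and best.total_indel_len == 0
        assert best.orientation == SENSE
        assert res.unique

    def test_one_substitution(self, rng):
        frag = _three(random_seq(rng, 250))
        seg = list(frag.sequence[200:240])
        seg[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[10]]
        res = align_3p("".join(seg), [frag])
        assert res.best.mismatches == 1
        assert (res.best.ref_start, res.best.ref_end) == (200, 240)

    def test_antisense_segment(self, rng):
        frag = _three(random_seq(rng, 250))
        res = align_3p(revcomp(frag.sequence[100:160]), [frag])
        assert res.best.orientation == ANTISENSE
        assert (res.best.ref_start, res.best.ref_end) == (100, 160)

    def test_duplicate_fragment_not_unique(self, rng):
        seq = random_seq(rng, 250)
        res = align_3p(seq[50:90], [_three(seq, "T1"), _three(seq, "T2")])
        assert not res.unique

    def test_distinct_fragments_unique(self, rng):
        f1 = _three(random_seq(rng, 250), "T1")
        f2 = _three(random_seq(rng, 250), "T2")
        res = align_3p(f1.sequence[50:90], [f1, f2])
        assert res.unique and res.best.fragment_id == "T1"

    def test_short_segment_raises(self, rng):
        with pytest.raises(ConfigError, match="shorter than 20"):
            align_3p(random_seq(rng, 12), [_three(random_seq(rng, 250))])


class TestFilter3p:
    def _aln(self, mismatches=0, max_indel=0, segment_len=60):
        return ThreePrimeAlignment(
            "T1", SENSE, 0, segment_len, mismatches, max_indel, max_indel, -mismatches, segment_len
        )

    def test_six_mismatches_fail(self):
        ok, reason = filter_3p(self._aln(mismatches=6, segment_len=100))
        assert (ok, reason) == (False, "mismatch_count")

    def test_five_mismatches_len60_pass(self):
        ok, reason = filter_3p(self._aln(mismatches=5, segment_len=60))
        assert ok, reason

    def test_rate_12_5_pct_fail(self):
        ok, reason = filter_3p(self._aln(mismatches=5, segment_len=40))
        assert (ok, reason) == (False, "mismatch_rate")

    def test_rate_exactly_10_pct_pass(self):
        ok, reason = filter_3p(self._aln(mismatches=4, segment_len=40))
        assert ok

    def test_indel_4_fail_3_pass(self):
        assert filter_3p(self._aln(max_indel=4)) == (False, "indel")
        assert filter_3p(self._aln(max_indel=3))[0]

    def test_not_unique_fails(self):
        assert filter_3p(self._aln(), unique=False) == (False, "multi_3p")


def _db_two_introns(rng):
    """One + gene with two introns >=300 nt, plus a - gene, as a FragmentDb."""
    genome = {"chr1": random_seq(rng, 4000)}
    g1 = make_gene(
        "G1", "chr1", "+", 100, 1700,
        [(100, 200), (550, 650), (1600, 1700)],
    )  # introns (200,550) len 350 and (650,1600) len 950
    g2 = make_gene("G2", "chr1", "-", 2000, 2900, [(2000, 2100), (2800, 2900)])
    regions = exclusive_intronic_regions([g1, g2])
    fives, threes = extract_fragments(regions, genome)
    return genome, FragmentDb(fives, threes)


class TestConsistencyChecks:
    def test_same_region_passes(self, rng):
        _, db = _db_two_introns(rng)
        r = db.regions["chr1:200-550:+"]
        ok, reason, same = consistency_checks(r, r, SENSE, SENSE)
        assert ok and same

    def test_gene_mismatch(self, rng):
        _, db = _db_two_introns(rng)
        r1 = db.regions["chr1:200-550:+"]
        r2 = db.regions["chr1:2100-2800:-"]
        ok, reason, _ = consistency_checks(r1, r2, SENSE, SENSE)
        assert (ok, reason) == (False, "gene_mismatch")

    def test_order_upstream_five_ok_multi_intron(self, rng):
        _, db = _db_two_introns(rng)
        first = db.regions["chr1:200-550:+"]
        second = db.regions["chr1:650-1600:+"]
        ok, reason, same = consistency_checks(first, second, SENSE, SENSE)
        assert ok and not same

    def test_order_five_downstream_fails(self, rng):
        _, db = _db_two_introns(rng)
        first = db.regions["chr1:200-550:+"]
        second = db.regions["chr1:650-1600:+"]
        ok, reason, _ = consistency_checks(second, first, SENSE, SENSE)
        assert (ok, reason) == (False, "order")

    def test_orientation_mismatch(self, rng):
        _, db = _db_two_introns(rng)
        r = db.regions["chr1:200-550:+"]
        ok, reason, _ = consistency_checks(r, r, SENSE, ANTISENSE)
        assert (ok, reason) == (False, "orientation_mismatch")


class TestMateStrandCheck:
    @pytest.mark.parametrize(
        "mate,orientation,expected",
        [
            (1, SENSE, True),
            (1, ANTISENSE, False),
            (2, SENSE, False),
            (2, ANTISENSE, True),
        ],
    )
    def test_four_scenarios(self, mate, orientation, expected):
        assert mate_strand_check(mate, orientation) is expected

    def test_bad_mate_raises(self):
        with pytest.raises(InputError):
            mate_strand_check(3, SENSE)


class TestCallBranchpoint:
    def test_plus_strand_full_ref_end(self, rng):
        genome = random_seq(rng, 2000)
        frag = _three(genome[1150:1400], region="chr1:1000-1400:+")
        aln = ThreePrimeAlignment("T1", SENSE, 200, 250, 0, 0, 0, 0, 50)
        chrom, pos, base = call_branchpoint(aln, frag)
        assert (chrom, pos) == ("chr1", 1399)
        assert base == genome[1399]

    def test_minus_strand_full_ref_end(self, rng):
        genome = random_seq(rng, 2000)
        frag = _three(revcomp(genome[1100:1350]), region="chr1:1100-1500:-")
        aln = ThreePrimeAlignment("T1", SENSE, 200, 250, 0, 0, 0, 0, 50)
        chrom, pos, base = call_branchpoint(aln, frag)
        assert pos == 1100
        assert base == revcomp(genome[1100])

    def test_plus_strand_ref_end_240(self, rng):
        genome = random_seq(rng, 2000)
        frag = _three(genome[1150:1400], region="chr1:1000-1400:+")
        aln = ThreePrimeAlignment("T1", SENSE, 190, 240, 0, 0, 0, 0, 50)
        _, pos, _ = call_branchpoint(aln, frag)
        assert pos == 1389


def _region_seq(genome, region):
    seq = genome[region.chrom][region.start : region.end]
    return revcomp(seq) if region.strand == "-" else seq


def _lariat_read(genome, region, bp_offset, split, mate, umi="ACGTACGTACGT"):
    intron = _region_seq(genome, region)
    L = len(intron)
    bp_idx = L - 1 - bp_offset
    chunk = intron[bp_idx - split + 1 : bp_idx + 1]
    fill = 150 - split - (12 if mate == 1 else 0)
    core = chunk + intron[:fill]
    seq = umi + core if mate == 1 else revcomp(core)
    if region.strand == "+":
        bp_pos = region.start + bp_idx
    else:
        bp_pos = region.end - 1 - bp_idx
    return ReadRecord("lar1", mate, seq, sample_id="s1"), bp_pos


class TestDetectRead:
    def test_planted_mate1_lariat_called_at_bp(self, rng):
        genome, db = _db_two_introns(rng)
        region = db.regions["chr1:200-550:+"]
        read, bp_pos = _lariat_read(genome, region, bp_offset=30, split=40, mate=1)
        call, reason = detect_read(read, db)
        assert reason is None
        assert (call.chrom, call.bp_pos) == ("chr1", bp_pos)
        assert call.bp_base == genome["chr1"][bp_pos]
        assert call.same_region and call.strand == "+"
        assert call.gene_ids == ("G1",)
        assert call.umi == "ACGTACGTACGT"

    def test_planted_mate2_lariat_antisense_path(self, rng):
        genome, db = _db_two_introns(rng)
        region = db.regions["chr1:200-550:+"]
        read, bp_pos = _lariat_read(genome, region, bp_offset=25, split=50, mate=2)
        call, reason = detect_read(read, db)
        assert reason is None
        assert call.bp_pos == bp_pos and call.mate == 2

    def test_minus_strand_gene_mate1(self, rng):
        genome, db = _db_two_introns(rng)
        region = db.regions["chr1:2100-2800:-"]
        read, bp_pos = _lariat_read(genome, region, bp_offset=20, split=45, mate=1)
        call, reason = detect_read(read, db)
        assert reason is None
        assert call.strand == "-" and call.bp_pos == bp_pos
        assert call.bp_base == revcomp(genome["chr1"][bp_pos])

    def test_exonic_read_no_match(self, rng):
        genome, db = _db_two_introns(rng)
        read = ReadRecord("bg", 1, "ACGTACGTACGT" + genome["chr1"][100:200] + genome["chr1"][550:588])
        call, reason = detect_read(read, db)
        assert call is None and reason == "no_match"

    def test_mate2_sense_fails_mate_strand(self, rng):
        genome, db = _db_two_introns(rng)
        region = db.regions["chr1:200-550:+"]
        read1, _ = _lariat_read(genome, region, bp_offset=30, split=40, mate=2)
        # rebuild as if it were mate1-style (sense) but labeled mate 2
        intron = _region_seq(genome, region)
        core = intron[-71:-31] + intron[:110]
        read = ReadRecord("x", 2, core, sample_id="s1")
        call, reason = detect_read(read, db)
        assert call is None and reason == "mate_strand"

    def test_call_invariants(self, rng):
        genome, db = _db_two_introns(rng)
        region = db.regions["chr1:650-1600:+"]
        read, _ = _lariat_read(genome, region, bp_offset=40, split=60, mate=1)
        call, _ = detect_read(read, db)
        assert call.mismatches <= 5
        assert call.max_indel_len <= 3
        five = db.regions[call.five_region_id]
        three = db.regions[call.three_region_id]
        assert set(call.gene_ids) <= set(five.gene_ids) & set(three.gene_ids)
        assert five.strand == three.strand == call.strand
        assert three.start <= call.bp_pos < three.end


class TestDetectSample:
    def test_order_invariant_and_sorted(self, rng):
        genome, db = _db_two_introns(rng)
        reads = []
        for i, (rid, off, split) in enumerate(
            [("a", 30, 40), ("b", 25, 55), ("c", 35, 45)]
        ):
            region = db.regions["chr1:200-550:+" if i % 2 == 0 else "chr1:650-1600:+"]
            read, _ = _lariat_read(genome, region, off, split, mate=1)
            reads.append(
                ReadRecord(rid, 1, read.sequence, sample_id="s1")
            )
        reads.append(ReadRecord("junk", 1, random_seq(rng, 150), "s1"))
        calls_fwd, audit_fwd, n_fwd = detect_sample(reads, db)
        calls_rev, audit_rev, n_rev = detect_sample(list(reversed(reads)), db)
        assert calls_fwd == calls_rev
        assert n_fwd == n_rev == 4
        keys = [(c.sample_id, c.chrom, c.bp_pos, c.read_id) for c in calls_fwd]
        assert keys == sorted(keys)

    def test_umi_dedup_collapses_duplicates(self, rng):
        genome, db = _db_two_introns(rng)
        region = db.regions["chr1:200-550:+"]
        read, _ = _lariat_read(genome, region, 30, 40, 1)
        dup = ReadRecord("dup", 1, read.sequence, sample_id="s1")
        calls, _, _ = detect_sample([read, dup], db, DetectParams(umi_dedup=True))
        assert len(calls) == 1
        calls2, _, _ = detect_sample([read, dup], db, DetectParams())
        assert len(calls2) == 2
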