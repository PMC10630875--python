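"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's production code paths: the alignment
oracle enumerates op strings recursively with branch-and-bound on score; the
interval oracle checks per-base membership.
"""

from __future__ import annotations

from lariatrace._align import Scoring

_RANK = {"M": 0, "X": 1, "D": 2, "I": 3}


def _gap_cost(last_op: str | None, op: str, scoring: Scoring) -> int:
    if op == last_op:
        return scoring.gap_extend
    return scoring.gap_open + scoring.gap_extend


def enumerate_optimal_alignments(query: str, ref: str, scoring: Scoring = Scoring()):
    """All score-optimal semi-global alignments as (score, ref_start, ref_end, ops).

    Alignments never start or end with a reference-consuming gap (those are
    strictly dominated under positive gap costs).
    """
    assert scoring.match <= 0 and scoring.gap_open + scoring.gap_extend > 0
    m, n = len(query), len(ref)
    best = [-(10**9)]
    found: list[tuple[int, int, int, str]] = []

    def rec(qi: int, rj: int, last_op: str | None, score: int, ops: list[str], a: int):
        if score < best[0]:
            return  # future ops cannot increase the score
        if qi == m:
            if score > best[0]:
                best[0] = score
                found.clear()
            if score == best[0]:
                found.append((score, a, rj, "".join(ops)))
            # fall through: alignments may continue with I only (trailing D
            # is dominated); continuing costs, so only relevant if pruned later
        if qi < m and rj < n:
            sub = scoring.match if query[qi] == ref[rj] else -scoring.mismatch
            op = "M" if query[qi] == ref[rj] else "X"
            ops.append(op)
            rec(qi + 1, rj + 1, op, score + sub, ops, a)
            ops.pop()
        if qi < m:
            ops.append("I")
            rec(qi + 1, rj, "I", score - _gap_cost(last_op, "I", scoring), ops, a)
            ops.pop()
        if qi < m and rj < n and qi > 0:  # interior D only
            ops.append("D")
            rec(qi, rj + 1, "D", score - _gap_cost(last_op, "D", scoring), ops, a)
            ops.pop()

    for a in range(n + 1):
        rec(0, a, None, 0, [], a)
    return [f for f in found if f[0] == best[0]]


def alignment_stats(ops: str) -> tuple[int, int, int]:
    """(mismatches, total_indel, max_indel) from an op string."""
    mm = ops.count("X")
    ti = ops.count("D") + ops.count("I")
    max_run = run = 0
    prev = ""
    for op in ops:
        if op in "DI":
            run = run + 1 if op == prev else 1
            max_run = max(max_run, run)
        else:
            run = 0
        prev = op
    return mm, ti, max_run


def canonical_oracle_alignment(query: str, ref: str, scoring: Scoring = Scoring()):
    """The canonical optimal alignment under the package's published total
    order, selected by exhaustive enumeration.

    Returns (score, ref_start, ref_end, mismatches, total_indel, max_indel, ops).
    """
    candidates = enumerate_optimal_alignments(query, ref, scoring)

    def key(item):
        score, a, rj, ops = item
        mm, ti, _ = alignment_stats(ops)
        rops_ranks = [_RANK[op] for op in reversed(ops)]
        return (-score, a, mm, ti, rj, rops_ranks)

    score, a, rj, ops = min(candidates, key=key)
    mm, ti, max_run = alignment_stats(ops)
    return score, a, rj, mm, ti, max_run, ops


def intronic_bases_bruteforce(genes, chrom: str, strand: str) -> set[int]:
    """Per-base oracle: positions inside some same-(chrom,strand) gene body and
    inside no exon of any gene on that chromosome and strand."""
    in_body: set[int] = set()
    in_exon: set[int] = set()
    for g in genes:
        if g.chrom != chrom or g.strand != strand:
            continue
        in_body.update(range(g.start, g.end))
        for s, e in g.exons:
            in_exon.update(range(s, e))
    return in_body - in_exon


def window_scan_5p(sequence: str, kmer_to_hit: dict, k: int = 20):
    """Brute-force all-window scan: (offset, hit) for every indexed window."""
    out = []
    for off in range(len(sequence) - k + 1):
        hit = kmer_to_hit.get(sequence[off : off + k])
        if hit is not None:
            out.append((off, hit))
    return out
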