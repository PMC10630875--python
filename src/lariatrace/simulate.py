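"""Synthetic data generator.

Produces a random genome, a GENCODE-style GTF of multi-exon genes on both
strands, stranded 2x150 paired-end background mRNA reads (read 1 sense with a
12 nt UMI prefix, read 2 antisense), and planted lariat-junction reads whose
3'-intronic portion ends at a known branchpoint and is followed by the
intron's 5' end. Every planted read carries a truth record with the exact
genomic branchpoint and a detectability verdict, so detector recall and
precision are measurable without external data.

All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._fastx import revcomp, write_fasta, write_fastq
from .annotation_db import IntronicRegion, make_region_id
from .errors import ConfigError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    seed: int = 1
    n_chroms: int = 2
    chrom_len: int | None = None  # derived from gene layout when None
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 4)
    exon_len_range: tuple[int, int] = (120, 200)
    intron_lens: tuple[int, ...] = (150, 400, 600)  # below and above 300
    read_len: int = 150
    umi_len: int = 12
    n_background_pairs: int = 100
    n_lariat_reads: int = 50
    bp_offset_range: tuple[int, int] = (18, 45)  # BP distance upstream of 3'SS
    split_range: tuple[int, int] = (25, 100)  # 3'-side nt in the junction read
    substitution_rate: float = 0.0
    n_rate: float = 0.0
    fraction_mate2_lariats: float = 0.5
    insert_size: int = 300
    bp_adenine_prob: float = 0.9
    min_intron_len: int = 300

    def __post_init__(self) -> None:
        for name in ("n_chroms", "n_genes", "n_background_pairs", "n_lariat_reads"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for rate in (self.substitution_rate, self.n_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("error rates must lie in [0, 1]")
        lo, hi = self.bp_offset_range
        if not (0 < lo <= hi <= 250):
            raise ConfigError("bp_offset_range must lie within (0, 250]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in (
            "exons_per_gene",
            "exon_len_range",
            "intron_lens",
            "bp_offset_range",
            "split_range",
        ):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    kind: str  # background | lariat
    gene_id: str
    region_id: str
    bp_chrom: str
    bp_pos: int  # -1 for background
    bp_base: str
    mate_carrying_junction: int  # 0 for background
    detectable: bool
    reason: str  # empty when detectable


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    genes: list[SimGene]
    reads_r1: list[tuple[str, str]] = field(default_factory=list)
    reads_r2: list[tuple[str, str]] = field(default_factory=list)
    truth: list[TruthRecord] = field(default_factory=list)

    def intron_regions(self) -> list[IntronicRegion]:
        """Genes never overlap, so every intron is an exclusively intronic region."""
        out = []
        for g in self.genes:
            for s, e in g.introns:
                out.append(
                    IntronicRegion(
                        region_id=make_region_id(g.chrom, s, e, g.strand),
                        gene_ids=(g.gene_id,),
                        chrom=g.chrom,
                        strand=g.strand,
                        start=s,
                        end=e,
                    )
                )
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def gen_genome_and_annotation(config: SimConfig) -> SimData:
    """Lay out genes with alternating exons/introns and generate the genome.

    Genes are placed round-robin over chromosomes with intergenic gaps;
    strands alternate so both are represented. Reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    gap = 400
    cursors = [gap] * max(config.n_chroms, 1)
    genes: list[SimGene] = []
    intron_choices = list(config.intron_lens)
    for gi in range(config.n_genes):
        ci = gi % config.n_chroms
        chrom = f"chr{ci + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_len_range[0], config.exon_len_range[1] + 1))
            for _ in range(k)
        ]
        intron_lens = [
            intron_choices[int(rng.integers(0, len(intron_choices)))]
            for _ in range(k - 1)
        ]
        start = cursors[ci]
        pos = start
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        for idx, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if idx < len(intron_lens):
                introns.append((pos, pos + intron_lens[idx]))
                pos += intron_lens[idx]
        cursors[ci] = pos + gap
        genes.append(SimGene(f"G{gi + 1:04d}", chrom, strand, start, pos, exons, introns))

    chrom_lens: dict[str, int] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        needed = cursors[ci] + gap
        if config.chrom_len is not None:
            if needed > config.chrom_len:
                raise ConfigError(
                    f"gene layout needs {needed} bp on {chrom} but chrom_len is "
                    f"{config.chrom_len}"
                )
            chrom_lens[chrom] = config.chrom_len
        else:
            chrom_lens[chrom] = needed

    genome = {chrom: _random_seq(rng, n) for chrom, n in chrom_lens.items()}
    return SimData(config=config, genome=genome, genes=genes)


def write_genome_fasta(data: SimData, path: str | Path) -> None:
    write_fasta(sorted(data.genome.items()), path)


def write_gtf(data: SimData, path: str | Path) -> None:
    """GENCODE-style GTF (1-based inclusive) with gene/transcript/exon rows."""
    with open(path, "w") as fh:
        for g in data.genes:
            attrs = f'gene_id "{g.gene_id}";'
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                )


def _region_seq(genome: dict[str, str], region: IntronicRegion) -> str:
    seq = genome[region.chrom][region.start : region.end]
    return revcomp(seq) if region.strand == "-" else seq


def gen_lariat_read(
    genome: dict[str, str],
    region: IntronicRegion,
    bp_offset: int,
    split: int,
    mate: int,
    config: SimConfig,
    rng: np.random.Generator,
    read_id: str,
) -> tuple[tuple[str, str], tuple[str, str], TruthRecord]:
    """One lariat read pair plus its truth record.

    The junction-carrying read is ``split`` intronic nt ending at the
    branchpoint, followed by the intron's first nucleotides. Mate-1 junction
    reads get a UMI prefix and are emitted sense; mate-2 junction reads are
    emitted reverse-complemented. The partner mate is drawn from intron
    sequence clear of the intron's 5' end.
    """
    intron = _region_seq(genome, region)
    L = len(intron)
    bp_idx = L - 1 - bp_offset
    chunk_start = bp_idx - split + 1
    if chunk_start < 0 or bp_idx >= L:
        raise ConfigError(
            f"bp_offset={bp_offset}, split={split} inconsistent with region "
            f"length {L}"
        )
    umi = _random_seq(rng, config.umi_len)
    five_fill = config.read_len - split - (config.umi_len if mate == 1 else 0)
    if five_fill < 0 or five_fill > L:
        raise ConfigError(f"split={split} inconsistent with read_len/intron length")
    chunk = intron[chunk_start : bp_idx + 1]
    core = chunk + intron[:five_fill]

    # partner mate: intron window that cannot contain the intron's first 20 nt
    # as a complete 20-mer (window start >= 1 guarantees that)
    if chunk_start - 20 >= 30:
        wlo, whi = 20, chunk_start
    else:
        wlo, whi = 1, L
    win_len = min(config.read_len, whi - wlo)
    if whi - wlo > win_len:
        wstart = wlo + int(rng.integers(0, whi - wlo - win_len + 1))
    else:
        wstart = wlo
    window = intron[wstart : wstart + win_len]

    if mate == 1:
        r1 = umi + core
        r2 = revcomp(window)
    else:
        r2 = revcomp(core)
        r1 = umi + window[: config.read_len - config.umi_len]

    if region.strand == "+":
        bp_pos = region.start + bp_idx
    else:
        bp_pos = region.end - 1 - bp_idx
    bp_base = intron[bp_idx]

    reasons = []
    if L < config.min_intron_len:
        reasons.append("intron_below_min_len")
    if split < 20:
        reasons.append("segment_below_20")
    if five_fill < 20:
        reasons.append("five_prime_portion_below_20")
    if bp_offset + split > 250:
        reasons.append("junction_outside_3p_fragment")
    truth = TruthRecord(
        read_id=read_id,
        kind="lariat",
        gene_id=region.gene_ids[0] if region.gene_ids else "",
        region_id=region.region_id,
        bp_chrom=region.chrom,
        bp_pos=bp_pos,
        bp_base=bp_base,
        mate_carrying_junction=mate,
        detectable=not reasons,
        reason=";".join(reasons),
    )
    return (read_id, r1), (read_id, r2), truth


def gen_background_pairs(
    data: SimData, rng: np.random.Generator
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[TruthRecord]]:
    """Exon-only mRNA pairs: read 1 = UMI + sense, read 2 = antisense."""
    config = data.config
    mrnas: list[tuple[str, str]] = []
    for g in data.genes:
        seq = "".join(data.genome[g.chrom][s:e] for s, e in g.exons)
        if g.strand == "-":
            seq = revcomp(seq)
        if len(seq) >= config.insert_size:
            mrnas.append((g.gene_id, seq))
    if config.n_background_pairs > 0 and not mrnas:
        raise ConfigError("no transcript long enough for the configured insert size")

    r1s: list[tuple[str, str]] = []
    r2s: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_background_pairs):
        gene_id, mrna = mrnas[int(rng.integers(0, len(mrnas)))]
        pos = int(rng.integers(0, len(mrna) - config.insert_size + 1))
        umi = _random_seq(rng, config.umi_len)
        rid = f"bg{i + 1:07d}"
        r1 = umi + mrna[pos : pos + config.read_len - config.umi_len]
        frag_end = pos + config.insert_size
        r2 = revcomp(mrna[frag_end - config.read_len : frag_end])
        r1s.append((rid, r1))
        r2s.append((rid, r2))
        truths.append(
            TruthRecord(rid, "background", gene_id, "", "", -1, "", 0, False, "background")
        )
    return r1s, r2s, truths


def inject_errors(
    reads: Sequence[tuple[str, str]], config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Per-base i.i.d. substitutions and N replacements (N wins on overlap)."""
    if config.substitution_rate == 0.0 and config.n_rate == 0.0:
        return list(reads)
    out = []
    for rid, seq in reads:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n = arr.shape[0]
        if config.substitution_rate > 0.0:
            hit = rng.random(n) < config.substitution_rate
            idx = np.nonzero(hit)[0]
            for i in idx:
                choices = _BASES[_BASES != arr[i]]
                arr[i] = choices[int(rng.integers(0, len(choices)))]
        if config.n_rate > 0.0:
            hit = rng.random(n) < config.n_rate
            arr[hit] = ord("N")
        out.append((rid, arr.tobytes().decode("ascii")))
    return out


def simulate(config: SimConfig) -> SimData:
    """Full simulation: genome, annotation, background and lariat reads, truth.

    Branchpoint genome bases are forced to adenine (in transcription
    orientation) with probability ``bp_adenine_prob`` before reads are drawn;
    detectability never depends on the base.
    """
    data = gen_genome_and_annotation(config)
    rng = np.random.default_rng(config.seed + 1)

    regions = data.intron_regions()
    eligible = [
        r
        for r in regions
        if r.length >= config.min_intron_len
        and r.length >= config.bp_offset_range[1] + config.split_range[1] + 1
    ]
    if config.n_lariat_reads > 0 and not eligible:
        raise ConfigError("no intron long enough to plant lariat reads")

    # plan lariat reads, then force branchpoint bases before drawing sequences
    plans: list[tuple[IntronicRegion, int, int, int]] = []
    for _ in range(config.n_lariat_reads):
        region = eligible[int(rng.integers(0, len(eligible)))]
        bp_offset = int(
            rng.integers(config.bp_offset_range[0], config.bp_offset_range[1] + 1)
        )
        split = int(rng.integers(config.split_range[0], config.split_range[1] + 1))
        mate = 2 if rng.random() < config.fraction_mate2_lariats else 1
        plans.append((region, bp_offset, split, mate))

    mutable = {chrom: bytearray(seq.encode("ascii")) for chrom, seq in data.genome.items()}
    for region, bp_offset, _, _ in plans:
        if rng.random() >= config.bp_adenine_prob:
            continue
        bp_idx = region.length - 1 - bp_offset
        if region.strand == "+":
            pos, base = region.start + bp_idx, ord("A")
        else:
            pos, base = region.end - 1 - bp_idx, ord("T")  # A in transcription sense
        mutable[region.chrom][pos] = base
    data.genome = {chrom: bytes(b).decode("ascii") for chrom, b in mutable.items()}

    bg_r1, bg_r2, bg_truth = gen_background_pairs(data, rng)
    lar_r1: list[tuple[str, str]] = []
    lar_r2: list[tuple[str, str]] = []
    lar_truth: list[TruthRecord] = []
    for i, (region, bp_offset, split, mate) in enumerate(plans):
        r1, r2, truth = gen_lariat_read(
            data.genome, region, bp_offset, split, mate, config, rng, f"lar{i + 1:07d}"
        )
        lar_r1.append(r1)
        lar_r2.append(r2)
        lar_truth.append(truth)

    data.reads_r1 = inject_errors(bg_r1 + lar_r1, config, rng)
    data.reads_r2 = inject_errors(bg_r2 + lar_r2, config, rng)
    data.truth = bg_truth + lar_truth
    return data


TRUTH_COLUMNS = (
    "read_id",
    "kind",
    "gene_id",
    "region_id",
    "bp_chrom",
    "bp_pos",
    "bp_base",
    "mate_carrying_junction",
    "detectable",
    "reason",
)


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.read_id,
                        t.kind,
                        t.gene_id,
                        t.region_id,
                        t.bp_chrom,
                        t.bp_pos,
                        t.bp_base,
                        t.mate_carrying_junction,
                        t.detectable,
                        t.reason,
                    )
                )
                + "\n"
            )
    return len(truth)


def write_sim_outputs(data: SimData, out_dir: str | Path, gzip_fastq: bool = False) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = {
        "genome": out_dir / "sim_genome.fa",
        "gtf": out_dir / "sim.gtf",
        "r1": out_dir / f"sim_R1{ext}",
        "r2": out_dir / f"sim_R2{ext}",
        "truth": out_dir / "truth.tsv",
    }
    write_genome_fasta(data, paths["genome"])
    write_gtf(data, paths["gtf"])
    write_fastq(((rid, seq, None) for rid, seq in data.reads_r1), paths["r1"])
    write_fastq(((rid, seq, None) for rid, seq in data.reads_r2), paths["r2"])
    write_truth_tsv(data.truth, paths["truth"])
    return paths
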