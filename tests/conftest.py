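from __future__ import annotations

import numpy as np
import pytest

from lariatrace.annotation_db import GeneModel


BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def write_gtf(path, rows):
    """rows: (chrom, feature, start0, end0, strand, gene_id) with 0-based
    half-open coordinates, converted to GTF's 1-based inclusive on write."""
    with open(path, "w") as fh:
        for chrom, feature, start, end, strand, gid in rows:
            fh.write(
                f"{chrom}\ttest\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{gid}.1";\n'
            )


def make_gene(gene_id, chrom, strand, start, end, exons):
    return GeneModel(gene_id, chrom, strand, start, end, list(exons))
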