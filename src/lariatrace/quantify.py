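"""Per-sample lariat quantification and group comparison.

Lariats per million = lariat read count / (library reads / 1e6). The group
comparison reports the ratio of unrounded group means and a Welch two-sample
t-test on the per-million values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy import stats

from .errors import ConfigError


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    group: str
    n_lariat_reads: int
    total_reads: int
    lariats_per_million: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_lpm_a: float
    mean_lpm_b: float
    fold_enrichment: float  # nan when mean_lpm_b == 0
    mean_count_a: float
    mean_count_b: float
    t_statistic: float
    p_value: float


def summarize_sample(
    n_calls: int,
    total_reads: int | None,
    sample_id: str,
    group: str = "",
    input_read_count: int | None = None,
) -> SampleSummary:
    """Summarize one sample's calls against its library-size denominator.

    ``total_reads`` should be the total sequenced reads of the library; when
    absent, ``input_read_count`` (the unmapped-read input count) is used as an
    approximation with a warning.
    """
    if total_reads is None:
        if input_read_count is None:
            raise ConfigError(
                f"sample {sample_id}: no total_reads and no input read count"
            )
        warnings.warn(
            f"sample {sample_id}: using unmapped-read input count "
            f"({input_read_count}) as the per-million denominator",
            stacklevel=2,
        )
        total_reads = input_read_count
    if total_reads <= 0:
        raise ConfigError(f"sample {sample_id}: total_reads must be > 0")
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        n_lariat_reads=n_calls,
        total_reads=total_reads,
        lariats_per_million=n_calls / (total_reads / 1e6),
    )


def compare_groups(
    summaries: Sequence[SampleSummary], group_a: str, group_b: str
) -> GroupComparison:
    """Group means of LPM and counts, fold = mean_a / mean_b, Welch's t-test."""
    a = [s for s in summaries if s.group == group_a]
    b = [s for s in summaries if s.group == group_b]
    if not a or not b:
        raise ConfigError(
            f"need at least one sample per group ({group_a}: {len(a)}, "
            f"{group_b}: {len(b)})"
        )
    lpm_a = [s.lariats_per_million for s in a]
    lpm_b = [s.lariats_per_million for s in b]
    mean_a = sum(lpm_a) / len(lpm_a)
    mean_b = sum(lpm_b) / len(lpm_b)
    fold = mean_a / mean_b if mean_b != 0 else math.nan
    if len(a) > 1 and len(b) > 1:
        t, p = stats.ttest_ind(lpm_a, lpm_b, equal_var=False)
    else:
        t, p = math.nan, math.nan
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_lpm_a=mean_a,
        mean_lpm_b=mean_b,
        fold_enrichment=fold,
        mean_count_a=sum(s.n_lariat_reads for s in a) / len(a),
        mean_count_b=sum(s.n_lariat_reads for s in b) / len(b),
        t_statistic=float(t),
        p_value=float(p),
    )


def write_summary_tsv(summaries: Sequence[SampleSummary], path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tn_lariat_reads\ttotal_reads\tlariats_per_million\n")
        for s in summaries:
            fh.write(
                f"{s.sample_id}\t{s.group}\t{s.n_lariat_reads}\t{s.total_reads}\t"
                f"{s.lariats_per_million:.6g}\n"
            )
    return len(summaries)


def write_comparison_tsv(cmp: GroupComparison, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "group_a\tgroup_b\tmean_lpm_a\tmean_lpm_b\tfold_enrichment\t"
            "mean_count_a\tmean_count_b\tt_statistic\tp_value\n"
        )
        fold = f"{cmp.fold_enrichment:.6g}" if not math.isnan(cmp.fold_enrichment) else "NA"
        fh.write(
            f"{cmp.group_a}\t{cmp.group_b}\t{cmp.mean_lpm_a:.6g}\t"
            f"{cmp.mean_lpm_b:.6g}\t{fold}\t{cmp.mean_count_a:.6g}\t"
            f"{cmp.mean_count_b:.6g}\t{cmp.t_statistic:.6g}\t{cmp.p_value:.6g}\n"
        )
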