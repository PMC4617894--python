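"""Enhancer regulatory-load pipeline.

Peak regions reproducible across replicates are extended to a fixed
length, assigned to their single nearest TSS within a distance cap, and
counted per gene; genes in the top decile of enhancer count with at least
a minimum number of enhancers form the high-regulatory-load (HRL) set.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TARGET_LENGTH = 450
MAX_TSS_DISTANCE = 500_000
HRL_TOP_FRACTION = 0.10
HRL_MIN_COUNT = 7


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chromosome label must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path: str) -> list[GenomicInterval]:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in frame.itertuples()]


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _by_chrom(intervals: Iterable[GenomicInterval]):
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort()
    return out


def _has_overlap(iv: GenomicInterval, sorted_chrom: dict) -> bool:
    ivs = sorted_chrom.get(iv.chrom)
    if not ivs:
        return False
    starts = np.array([x.start for x in ivs])
    # only intervals starting before iv.end can overlap
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    return any(other.end > iv.start for other in ivs[:hi])


def reproducible_regions(replicates: Sequence[Sequence[GenomicInterval]]
                         ) -> list[GenomicInterval]:
    """Intervals of the first replicate overlapping every other replicate.

    Overlap means >=1 shared base pair.  The first replicate acts as the
    reference representation of the reproducible regions.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    others = [_by_chrom(rep) for rep in replicates[1:]]
    out = []
    for iv in replicates[0]:
        if all(_has_overlap(iv, rep) for rep in others):
            out.append(iv)
    return sorted(out)


def extend_to_length(regions: Iterable[GenomicInterval],
                     target_length: int = TARGET_LENGTH
                     ) -> list[GenomicInterval]:
    """Grow short intervals symmetrically to the target length.

    Odd remainders go to the end side; intervals already at or beyond the
    target are unchanged.  Extension is clipped at coordinate 0 with the
    lost bases pushed to the right so the output keeps the target length.
    """
    out = []
    for iv in regions:
        length = len(iv)
        if length >= target_length:
            out.append(iv)
            continue
        add = target_length - length
        left = add // 2
        right = add - left
        start = iv.start - left
        end = iv.end + right
        if start < 0:
            end -= start
            start = 0
        out.append(GenomicInterval(iv.chrom, start, end))
    return out


def read_tss_table(path: str) -> pd.DataFrame:
    """TSV with columns gene_id, chrom, tss, strand (strand optional)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss"}
    if not required <= set(frame.columns):
        raise ValueError(f"TSS table needs columns {sorted(required)}")
    return frame


def assign_nearest_gene(regions: Sequence[GenomicInterval],
                        tss: pd.DataFrame,
                        max_distance: int = MAX_TSS_DISTANCE
                        ) -> dict[GenomicInterval, str]:
    """Single nearest gene (by TSS-to-midpoint distance) within the cap.

    Equidistant TSSs are broken by lexicographic gene id, with a warning.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for c, g in tss.groupby("chrom")
    }
    out: dict[GenomicInterval, str] = {}
    for iv in regions:
        table = by_chrom.get(iv.chrom)
        if table is None:
            continue
        dist = np.abs(table["tss"].to_numpy(dtype=float) - iv.midpoint)
        best = dist.min()
        if best > max_distance:
            continue
        candidates = sorted(table.loc[dist == best, "gene_id"])
        if len(candidates) > 1:
            warnings.warn(
                f"equidistant TSSs for {iv.chrom}:{iv.start}-{iv.end}; "
                f"picking {candidates[0]!r}")
        out[iv] = candidates[0]
    return out


@dataclass
class RegulatoryLoadTable:
    """Per-gene enhancer count, descending rank and HRL flag."""

    counts: pd.Series       # gene -> enhancer count (>= 1)
    ranks: pd.Series        # descending rank, average ties
    hrl: set[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "count": self.counts,
            "rank": self.ranks,
            "hrl": self.counts.index.isin(sorted(self.hrl)),
        })


def regulatory_load(assignments: dict[GenomicInterval, str]) -> RegulatoryLoadTable:
    """Count assigned regions per gene and rank genes by count."""
    counts = pd.Series(list(assignments.values()),
                       dtype=object).value_counts().astype(int)
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    ranks = counts.rank(ascending=False, method="average")
    return RegulatoryLoadTable(counts=counts, ranks=ranks, hrl=set())


def select_hrl(table: RegulatoryLoadTable,
               top_fraction: float = HRL_TOP_FRACTION,
               min_count: int = HRL_MIN_COUNT) -> set[str]:
    """Genes in the top ``top_fraction`` by enhancer count with count >=
    ``min_count``.  Count ties at the decile boundary are kept.
    """
    counts = table.counts
    if counts.empty:
        raise ValueError("regulatory load table is empty")
    n_top = max(1, math.ceil(top_fraction * len(counts)))
    boundary = counts.sort_values(ascending=False).iloc[n_top - 1]
    cutoff = max(int(boundary), min_count)
    selected = set(counts.index[counts >= cutoff])
    table.hrl = selected
    return selected


def expression_shift(hrl_expr: Sequence[float],
                     other_expr: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS test between HRL-gene and other-gene expression."""
    hrl = np.asarray(hrl_expr, dtype=float)
    other = np.asarray(other_expr, dtype=float)
    if hrl.size == 0 or other.size == 0:
        raise ValueError("both expression sets must be non-empty")
    res = stats.ks_2samp(hrl, other)
    return float(res.statistic), float(res.pvalue)


def load_pipeline(replicates: Sequence[Sequence[GenomicInterval]],
                  tss: pd.DataFrame,
                  target_length: int = TARGET_LENGTH,
                  max_distance: int = MAX_TSS_DISTANCE,
                  top_fraction: float = HRL_TOP_FRACTION,
                  min_count: int = HRL_MIN_COUNT,
                  extend_before_overlap: bool = True) -> RegulatoryLoadTable:
    """Extension -> replicate intersection -> assignment -> HRL selection.

    The default order extends each replicate's regions before requiring
    cross-replicate overlap; ``extend_before_overlap=False`` swaps the two
    steps.
    """
    if extend_before_overlap:
        reps = [extend_to_length(rep, target_length) for rep in replicates]
        common = reproducible_regions(reps)
    else:
        common = extend_to_length(reproducible_regions(replicates),
                                  target_length)
    assignments = assign_nearest_gene(common, tss, max_distance)
    table = regulatory_load(assignments)
    select_hrl(table, top_fraction, min_count)
    return table
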