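"""Genomic interval data model and overlap algebra.

All coordinates are 0-based half-open (BED convention). GFF3 input is
converted on read. Interval collections are thin wrappers around pandas
DataFrames sorted by (chrom, start), which keeps every operation a
vectorised sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score"]


class ValidationError(ValueError):
    """An interval or annotation violates its invariants."""


def _as_peak_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in PEAK_COLUMNS:
        if col not in df.columns:
            if col == "name":
                df["name"] = [f"peak_{i}" for i in range(len(df))]
            elif col == "score":
                df["score"] = 0.0
            else:
                raise ValidationError(f"missing required column {col!r}")
    df = df[PEAK_COLUMNS]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["score"] = df["score"].astype(float)
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"interval {df.iloc[i]['name']} has start >= end "
            f"({df.iloc[i]['start']} >= {df.iloc[i]['end']})"
        )
    if (df["score"] < 0).any():
        raise ValidationError("scores must be >= 0")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


@dataclass
class PeakSet:
    """Scored intervals for one factor / mark / replicate.

    Intervals are kept sorted by (chrom, start). ``merged`` peak sets
    additionally contain no overlapping intervals.
    """

    factor: str
    replicate: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self) -> None:
        self.intervals = _as_peak_frame(pd.DataFrame(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def centres(self) -> np.ndarray:
        iv = self.intervals
        return ((iv["start"].to_numpy() + iv["end"].to_numpy()) // 2).astype(np.int64)


@dataclass
class GeneAnnotation:
    """Gene models with a strand-aware TSS per gene.

    ``genes`` columns: gene_id, chrom, start, end, strand, exon_bp.
    TSS = start for '+' strand genes and end - 1 for '-' strand genes
    (half-open coordinates). ``enhancers`` is an optional table of
    designated enhancer loci (chrom, start, end, active) carried along
    by the simulator.
    """

    genes: pd.DataFrame
    enhancers: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = self.genes.copy()
        required = ["gene_id", "chrom", "start", "end", "strand"]
        for col in required:
            if col not in g.columns:
                raise ValidationError(f"gene table missing column {col!r}")
        if "exon_bp" not in g.columns:
            g["exon_bp"] = g["end"] - g["start"]
        if g["gene_id"].duplicated().any():
            raise ValidationError("gene_ids must be unique")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        g["start"] = g["start"].astype(np.int64)
        g["end"] = g["end"].astype(np.int64)
        g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        self.genes = g.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)


def merge(intervals: pd.DataFrame) -> pd.DataFrame:
    """Collapse intervals into the minimal disjoint set covering the same
    bases; intervals that touch (share a boundary base) are merged.
    Scores of merged members are summed, names joined with ','.
    """
    if len(intervals) == 0:
        return intervals.copy()
    df = _as_peak_frame(intervals)
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is None or row.chrom != cur[0] or row.start > cur[2]:
            if cur is not None:
                out.append(cur)
            cur = [row.chrom, row.start, row.end, [row.name], row.score]
        else:
            cur[2] = max(cur[2], row.end)
            cur[3].append(row.name)
            cur[4] += row.score
    out.append(cur)
    return pd.DataFrame(
        [(c, s, e, ",".join(n), sc) for c, s, e, n, sc in out], columns=PEAK_COLUMNS
    )


def merge_peakset(ps: PeakSet, factor: str | None = None, replicate: str = "merged") -> PeakSet:
    return PeakSet(factor or ps.factor, replicate, merge(ps.intervals))


def overlap_any(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Boolean per interval of ``a``: does it share >= 1 bp with any
    interval of ``b``? Half-open, so [100,200) vs [200,300) is False.
    """
    result = np.zeros(len(a), dtype=bool)
    bi = b.intervals
    for chrom, grp in a.intervals.groupby("chrom", sort=False):
        other = bi[bi["chrom"] == chrom]
        if other.empty:
            continue
        # sweep over merged b-intervals: a overlaps iff some b.start < a.end
        # and b.end > a.start
        bs = other["start"].to_numpy()
        be = other["end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        bs, be = bs[order], be[order]
        cummax_end = np.maximum.accumulate(be)
        a_start = grp["start"].to_numpy()
        a_end = grp["end"].to_numpy()
        # index of last b with bs < a_end
        idx = np.searchsorted(bs, a_end, side="left") - 1
        hit = (idx >= 0) & (cummax_end[np.clip(idx, 0, None)] > a_start)
        result[grp.index.to_numpy()] = hit
    return result


def peaks_lost(wt: PeakSet, ko: PeakSet) -> PeakSet:
    """Intervals of ``wt`` with no any-bp overlap in ``ko`` — the peaks
    "lost" in the knockout, the unit of the recruitment analysis.
    """
    keep = ~overlap_any(wt, ko)
    return PeakSet(wt.factor, f"{wt.replicate}_lost", wt.intervals[keep].reset_index(drop=True))


def nearest_gene(peaks: PeakSet, ann: GeneAnnotation) -> pd.Series:
    """Map each peak to the gene whose TSS minimises |TSS - centre|.

    Distance is centre-to-TSS, strand ignored; ties broken by
    lexicographically smaller gene_id. Peaks on chromosomes without any
    gene map to None.
    """
    out = pd.Series([None] * len(peaks), index=peaks.intervals.index, dtype=object)
    centres = peaks.centres()
    for chrom, grp in peaks.intervals.groupby("chrom", sort=False):
        genes = ann.genes[ann.genes["chrom"] == chrom]
        if genes.empty:
            continue
        # sort TSS; on ties keep lexicographically smaller gene_id first
        g = genes.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = g["tss"].to_numpy()
        ids = g["gene_id"].to_numpy()
        c = centres[grp.index.to_numpy()]
        right = np.searchsorted(tss, c, side="left")
        left = right - 1
        best = np.empty(len(c), dtype=object)
        for k in range(len(c)):
            cands = []
            if right[k] < len(tss):
                # first entry of an equal-TSS run carries the smallest gene_id
                cands.append((abs(int(tss[right[k]]) - int(c[k])), ids[right[k]]))
            if left[k] >= 0:
                j0 = int(np.searchsorted(tss, tss[left[k]], side="left"))
                cands.append((abs(int(tss[j0]) - int(c[k])), ids[j0]))
            best[k] = min(cands)[1]
        out.iloc[grp.index.to_numpy()] = best
    return out


def venn3(a: Iterable, b: Iterable, c: Iterable) -> dict[str, int]:
    """Cardinalities of the 7 disjoint regions of a 3-set Venn diagram.

    Keys: '100','010','001','110','101','011','111' — 1 marks membership
    in (a, b, c) respectively. Counts sum to |a ∪ b ∪ c|.
    """
    sa, sb, sc = set(a), set(b), set(c)
    regions = {k: 0 for k in ("100", "010", "001", "110", "101", "011", "111")}
    for x in sa | sb | sc:
        key = f"{int(x in sa)}{int(x in sb)}{int(x in sc)}"
        regions[key] += 1
    return regions


def union_base_count(intervals: pd.DataFrame) -> int:
    """Total bases covered by the union of the intervals."""
    m = merge(intervals)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())
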