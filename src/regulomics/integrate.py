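"""Cross-dataset integration: peak-to-gene sets, overlap reports,
direction-of-change regression, dependency (recruitment) analysis and
fold-gain of binding sites.

These are the computations that turn peak sets and differential
expression results into the headline percentages of a
factor-vs-complex recruitment analysis: how many binding-dependent
peaks overlap the factor, whether expression changes in two mutants
point the same way (least-squares R²), and how many fold more sites a
factor occupies in one background than another.

Percentages round half away from zero to the nearest integer; fold
ratios to one decimal — the granularity at which such results are
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DEResult
from .intervals import GeneAnnotation, PeakSet, nearest_gene, overlap_any, peaks_lost


class IntegrationError(ValueError):
    pass


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class GeneSet:
    label: str
    members: set[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    n_intersection: int
    percentage: int | None          # 100·|A∩B|/|A|, None when |A|=0
    up: int | None = None           # direction split of the intersection
    down: int | None = None


@dataclass
class DirectionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    pairs: pd.DataFrame


def peak_gene_set(peaks: PeakSet, ann: GeneAnnotation, label: str = "") -> GeneSet:
    """Deduplicated nearest-gene ids of all peaks."""
    if len(ann) == 0:
        raise IntegrationError("empty gene annotation")
    genes = nearest_gene(peaks, ann).dropna()
    return GeneSet(
        label=label or f"{peaks.factor}_genes",
        members=set(genes),
        provenance=f"nearest gene of {len(peaks)} {peaks.factor} peaks",
    )


def overlap_report(a: GeneSet, b: GeneSet, de: DEResult | None = None) -> OverlapReport:
    """|A|, |B|, |A∩B| and the percentage of A in B; optionally the
    up/down split of the intersection by DE log2fc sign."""
    inter = a.members & b.members
    pct = _round_half_away(100.0 * len(inter) / len(a)) if len(a) else None
    up = down = None
    if de is not None:
        sig = de.de_genes()
        lfc = de.table["log2fc"]
        up = sum(1 for g in inter if g in sig and lfc.get(g, 0) > 0)
        down = sum(1 for g in inter if g in sig and lfc.get(g, 0) < 0)
    return OverlapReport(len(a), len(b), len(inter), pct, up, down)


def direction_correlation(
    de_x: DEResult, de_y: DEResult, gene_universe: Iterable[str] | None = None
) -> DirectionFit:
    """Least-squares fit of log2fc_y on log2fc_x over genes DE in both.

    R² equals the squared Pearson correlation of the pairs. Used to ask
    whether two mutants move shared target genes in the same direction.
    """
    shared = de_x.de_genes() & de_y.de_genes()
    if gene_universe is not None:
        shared &= set(gene_universe)
    shared = sorted(shared)
    if len(shared) < 3:
        raise IntegrationError(f"only {len(shared)} shared DE genes; need >= 3")
    x = de_x.table.loc[shared, "log2fc"].to_numpy(float)
    y = de_y.table.loc[shared, "log2fc"].to_numpy(float)
    fit = stats.linregress(x, y)
    return DirectionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(shared),
        pairs=pd.DataFrame({"log2fc_x": x, "log2fc_y": y}, index=shared),
    )


@dataclass
class DependencyReport:
    n_wt: int
    n_lost: int
    n_lost_bound: int
    pct_lost_bound: int | None       # of lost peaks, % overlapping the factor
    pct_of_all: float                # lost-and-bound as % of all WT peaks, 1 dp


def dependency_analysis(
    complex_wt: PeakSet, complex_ko: PeakSet, factor_wt: PeakSet
) -> DependencyReport:
    """Recruitment test: of complex-subunit peaks lost in the factor
    knockout, how many were factor-bound in WT?

    A factor that recruits the complex should account for most lost
    peaks; a small percentage argues against recruitment.
    """
    lost = peaks_lost(complex_wt, complex_ko)
    if len(lost) == 0:
        return DependencyReport(len(complex_wt), 0, 0, None, 0.0)
    bound = overlap_any(lost, factor_wt)
    n_bound = int(bound.sum())
    return DependencyReport(
        n_wt=len(complex_wt),
        n_lost=len(lost),
        n_lost_bound=n_bound,
        pct_lost_bound=_round_half_away(100.0 * n_bound / len(lost)),
        pct_of_all=round(100.0 * n_bound / len(complex_wt), 1),
    )


def fold_gain(a: PeakSet, b: PeakSet) -> float:
    """|a| / |b| rounded to one decimal (e.g. sites gained in a KO)."""
    if len(b) == 0:
        raise IntegrationError("denominator peak set is empty")
    return round(len(a) / len(b), 1)


def premature_activation_fraction(
    de_wt_differentiation: DEResult, de_mutant_selfrenewal: DEResult
) -> int | None:
    """Of genes upregulated on differentiation in WT, the percentage
    already upregulated in the mutant under self-renewal. None when no
    gene is up in the first contrast."""
    up_wt = de_wt_differentiation.de_genes("up")
    if not up_wt:
        return None
    up_mut = de_mutant_selfrenewal.de_genes("up")
    return _round_half_away(100.0 * len(up_wt & up_mut) / len(up_wt))
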