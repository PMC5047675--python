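"""RNA-seq quantification / differential expression and qPCR analysis.

The differential-expression test is a negative-binomial conditional
exact test in the classic DESeq style: counts are normalised by
median-of-ratios size factors, per-gene dispersions are estimated by the
method of moments and shrunk half-way toward a smooth log-mean trend,
and the p-value for a two-group contrast is the probability, conditional
on the pooled total, of splits at least as extreme as the observed one.
Benjamini–Hochberg controls the FDR.

qPCR support covers bulk ΔΔCt fold changes and the single-cell –ΔCt
normalisation (–ΔCt = −(Ct_gene − mean Ct_housekeeping) per cell) with
average-linkage clustering under pairwise-complete missing-value
handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


class ExpressionError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Gene × sample integer counts plus gene lengths and a design table.

    ``design`` is indexed by sample and must carry a ``condition``
    column; genotype/replicate columns are free-form metadata.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ExpressionError("counts must be non-negative")
        if not np.allclose(c.to_numpy(), np.round(c.to_numpy())):
            raise ExpressionError("counts must be integral")
        missing = set(c.columns) - set(self.design.index)
        if missing:
            raise ExpressionError(f"samples missing from design: {sorted(missing)}")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(c.index)
            if (self.gene_lengths <= 0).any():
                raise ExpressionError("gene lengths must be > 0")


@dataclass
class DEResult:
    table: pd.DataFrame            # gene, baseMean, log2fc, pvalue, fdr
    size_factors: pd.Series
    dispersions: pd.Series
    contrast: tuple[str, str]
    alpha_fdr: float = 0.05

    def de_genes(self, direction: str | None = None) -> set[str]:
        t = self.table
        sel = t["fdr"] <= self.alpha_fdr
        if direction == "up":
            sel &= t["log2fc"] > 0
        elif direction == "down":
            sel &= t["log2fc"] < 0
        return set(t.index[sel])


def fpkm(m: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads."""
    if m.gene_lengths is None:
        raise ExpressionError("FPKM requires gene lengths")
    if (m.gene_lengths <= 0).any():
        raise ExpressionError("zero-length gene in annotation")
    depth = m.counts.sum(axis=0)
    if (depth <= 0).any():
        raise ExpressionError("a sample has zero total counts")
    kb = m.gene_lengths / 1_000.0
    millions = depth / 1e6
    return m.counts.div(kb, axis=0).div(millions, axis=1)


def size_factors(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors, rescaled to median 1.

    Falls back to upper-quartile scaling (with a warning) when no gene
    has all-positive counts.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    arr = counts.to_numpy(float)
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        logs = np.log(arr[allpos])
        geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - geo, axis=0))
    else:
        warnings.warn("no all-positive gene; falling back to upper-quartile scaling")
        uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 1.0 for col in arr.T])
        sf = uq
    sf = sf / np.median(sf)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _dispersion_trend(mean_norm: np.ndarray, phi_mom: np.ndarray) -> np.ndarray:
    """Smooth dispersion-vs-log-mean trend: robust linear fit of
    method-of-moments dispersions against 1/mean (gamma-family style
    phi(mu) = a0/mu + a1, coefficients clamped at zero)."""
    ok = (mean_norm > 0) & np.isfinite(phi_mom) & (phi_mom > 0)
    if ok.sum() < 10:
        return np.full_like(mean_norm, max(np.nanmedian(phi_mom[ok]) if ok.any() else 0.01, 1e-8))
    x = 1.0 / mean_norm[ok]
    y = phi_mom[ok]
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 1e-8)
    return a0 / np.maximum(mean_norm, 1e-8) + a1


def _nb_exact_pvalue(ka: int, kb: int, mu_a: float, mu_b: float, phi: float) -> float:
    """Conditional exact two-sided p-value for an NB two-group split.

    Given the pooled total n = ka + kb, sums the probabilities of all
    splits (a, n−a) no more likely than the observed one, normalised by
    the total — the classic DESeq exact test.
    """
    n = ka + kb
    if n == 0:
        return 1.0
    a = np.arange(n + 1)
    if phi <= 1e-12:
        # Poisson limit: conditional law is binomial
        logp = stats.binom.logpmf(a, n, mu_a / (mu_a + mu_b))
    else:
        r_a, r_b = 1.0 / phi, 1.0 / phi
        logp = stats.nbinom.logpmf(a, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
            n - a, r_b, r_b / (r_b + mu_b)
        )
    logp -= logp.max()
    p = np.exp(logp)
    obs = p[ka]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum() / p.sum()))


def de_test(
    m: CountMatrix,
    contrast: tuple[str, str],
    alpha_fdr: float = 0.05,
    shrink_weight: float = 0.5,
) -> DEResult:
    """NB exact-style differential expression between two conditions.

    ``contrast = (conditionA, conditionB)``; log2fc is A over B on
    size-factor-normalised means. Dispersions: per-gene method of
    moments, shrunk ``shrink_weight``-weighted toward the fitted
    log-mean trend.
    """
    cond = m.design["condition"]
    cols_a = [s for s in m.counts.columns if cond.loc[s] == contrast[0]]
    cols_b = [s for s in m.counts.columns if cond.loc[s] == contrast[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ExpressionError(
            f"need >= 2 replicates per condition (got {len(cols_a)} vs {len(cols_b)}); "
            "dispersion cannot be estimated otherwise"
        )
    sub = m.counts[cols_a + cols_b]
    sf = size_factors(sub)
    norm = sub / sf
    mean_all = norm.mean(axis=1).to_numpy()

    # method-of-moments dispersion from within-group variability
    na, nb = len(cols_a), len(cols_b)
    va = norm[cols_a].var(axis=1, ddof=1).to_numpy()
    vb = norm[cols_b].var(axis=1, ddof=1).to_numpy()
    ma = norm[cols_a].mean(axis=1).to_numpy()
    mb = norm[cols_b].mean(axis=1).to_numpy()
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    pooled_mean = (na * ma + nb * mb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = (pooled_var - pooled_mean) / pooled_mean**2
    phi_mom = np.where(np.isfinite(phi_mom), np.maximum(phi_mom, 0.0), 0.0)
    trend = _dispersion_trend(pooled_mean, phi_mom)
    phi = shrink_weight * phi_mom + (1.0 - shrink_weight) * trend

    sf_a, sf_b = sf[cols_a].sum(), sf[cols_b].sum()
    tot_a = sub[cols_a].sum(axis=1).to_numpy()
    tot_b = sub[cols_b].sum(axis=1).to_numpy()
    pvals = np.ones(len(sub))
    for g in range(len(sub)):
        mu = pooled_mean[g]
        if mu == 0:
            continue
        pvals[g] = _nb_exact_pvalue(
            int(tot_a[g]), int(tot_b[g]), mu * sf_a, mu * sf_b, float(phi[g])
        )
    pseudo = 0.5
    log2fc = np.log2((ma + pseudo) / (mb + pseudo))
    table = pd.DataFrame(
        {
            "baseMean": mean_all,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=sub.index,
    )
    return DEResult(
        table=table,
        size_factors=sf,
        dispersions=pd.Series(phi, index=sub.index, name="dispersion"),
        contrast=contrast,
        alpha_fdr=alpha_fdr,
    )


def pca_embed(
    m: CountMatrix, n_top_variable: int = 500
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on log2(FPKM + 1) of the most variable genes.

    Genes are centred; the SVD supplies the components; signs are fixed
    so the first gene's loading on each PC is non-negative. Returns
    (sample coordinates on all PCs, variance-explained fractions).
    """
    if m.counts.shape[1] < 3:
        raise ExpressionError("PCA needs >= 3 samples")
    x = np.log2(fpkm(m) + 1.0)
    var = x.var(axis=1)
    if n_top_variable > len(var):
        warnings.warn(f"only {len(var)} genes available; using all")
        n_top_variable = len(var)
    top = var.sort_values(ascending=False).index[:n_top_variable]
    xt = x.loc[top]
    centred = xt.sub(xt.mean(axis=1), axis=0).to_numpy().T  # samples × genes
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    signs = np.where(vt[:, 0] < 0, -1.0, 1.0)
    coords = u * s * signs
    explained = s**2 / max((s**2).sum(), 1e-300)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=m.counts.columns, columns=cols), explained


# ------------------------------------------------------------ qPCR / Ct


@dataclass
class CtMatrix:
    """Gene × cell qPCR cycle-threshold values; NaN marks dropout.

    –ΔCt = −(Ct_gene − mean Ct_housekeeping) per cell; missing Ct yields
    missing –ΔCt.
    """

    ct: pd.DataFrame
    housekeeping: tuple[str, ...] = ("Atp5a1", "Ppia", "Gapdh")
    normalized: pd.DataFrame | None = None


def delta_ct_normalize(c: CtMatrix) -> pd.DataFrame:
    """Per-cell –ΔCt normalisation against the housekeeping mean.

    Cells with no housekeeping measurement at all are dropped with a
    warning. The housekeeping rows themselves are also normalised (their
    mean –ΔCt is 0 by construction).
    """
    hk = [g for g in c.housekeeping if g in c.ct.index]
    if not hk:
        raise ExpressionError("no housekeeping genes present in Ct table")
    hk_mean = c.ct.loc[hk].mean(axis=0, skipna=True)
    dead = hk_mean.isna()
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} cells lacking all housekeeping Ct values")
    kept = c.ct.loc[:, ~dead]
    norm = -(kept - hk_mean[~dead])
    c.normalized = norm
    return norm


def _pairwise_complete_euclidean(x: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Euclidean distance over shared observed coordinates, rescaled by
    sqrt(p/shared); rows sharing <2 observations with some other row are
    flagged. Unresolvable distances fall back to the matrix max."""
    n, p = x.shape
    d = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            k = int(both.sum())
            if k >= 2:
                d[i, j] = d[j, i] = np.sqrt(((x[i, both] - x[j, both]) ** 2).sum() * p / k)
            else:
                d[i, j] = d[j, i] = np.nan
    if np.isnan(d).any():
        mx = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0
        for i in range(n):
            if np.isnan(d[i]).sum() > 0:
                flagged.append(i)
        d = np.where(np.isnan(d), mx * 2, d)
    return d, flagged


def hcluster_genes_cells(normalized: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Average-linkage leaf orders for genes (rows) and cells (columns)
    under pairwise-complete Euclidean distance."""
    if normalized.shape[0] < 2:
        raise ExpressionError("need >= 2 genes to cluster")

    def leaf_order(x: np.ndarray, labels: list[str]) -> list[str]:
        d, flagged = _pairwise_complete_euclidean(x)
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        order = [labels[i] for i in hierarchy.leaves_list(link)]
        for i in flagged:  # unresolvable rows go last
            order.remove(labels[i])
            order.append(labels[i])
        return order

    genes = leaf_order(normalized.to_numpy(float), list(normalized.index))
    cells = leaf_order(normalized.to_numpy(float).T, list(normalized.columns))
    return genes, cells


def relative_expression(
    ct_target_treated: float,
    ct_hk_treated: float,
    ct_target_control: float,
    ct_hk_control: float,
) -> float:
    """Bulk qPCR fold change by the 2^−ΔΔCt method; NaN in → NaN out."""
    vals = [ct_target_treated, ct_hk_treated, ct_target_control, ct_hk_control]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return float("nan")
    ddct = (ct_target_treated - ct_hk_treated) - (ct_target_control - ct_hk_control)
    return float(2.0 ** (-ddct))
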