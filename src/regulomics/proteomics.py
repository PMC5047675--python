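"""AP-MS interactor calling and anchor-relative stoichiometry.

Interactors are called from label-free (LFQ) intensities with a
moderated two-sample statistic (SAM-style fudge factor s0) against a
label-permutation null. Stoichiometry follows the iBAQ convention:
background-corrected bait-IP intensity divided by the theoretical
tryptic peptide count approximates molar abundance; ratios are taken to
an anchor subunit (the sum of the proteins occupying one complex slot,
e.g. Mbd2 + Mbd3 for NuRD). Under the one-bait-one-anchor-per-complex
assumption, a bait:anchor ratio S means a fraction 1/S of the bait is
resident in the complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


class ProteomicsError(ValueError):
    pass


@dataclass
class ProteinIntensityTable:
    """Protein × run LFQ intensities (NaN = not quantified).

    ``groups`` maps run → 'bait' or 'control'; ``peptide_counts`` holds
    theoretical tryptic peptides per protein (identity fallback = 1).
    """

    intensities: pd.DataFrame
    groups: pd.Series
    peptide_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.intensities.dropna(how="all").to_numpy() <= 0).any():
            vals = self.intensities.to_numpy()
            if np.nanmin(vals) <= 0:
                raise ProteomicsError("intensities must be > 0 where present")
        if self.peptide_counts is None:
            self.peptide_counts = pd.Series(1, index=self.intensities.index)
        self.peptide_counts = self.peptide_counts.reindex(self.intensities.index).fillna(1)
        if (self.peptide_counts < 1).any():
            raise ProteomicsError("peptide counts must be >= 1")

    def runs(self, group: str) -> list[str]:
        return [r for r in self.intensities.columns if self.groups.loc[r] == group]


@dataclass
class VolcanoResult:
    table: pd.DataFrame  # log2_enrichment, statistic, fdr, significant
    s0: float
    fdr_alpha: float
    n_permutations: int

    def significant_proteins(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


@dataclass
class StoichiometryTable:
    table: pd.DataFrame  # abundance, ratio_to_anchor
    anchor_proteins: tuple[str, ...]
    bait: str

    @property
    def s_bait(self) -> float:
        return float(self.table.loc[self.bait, "ratio_to_anchor"])


def impute_missing(
    t: ProteinIntensityTable, downshift: float = 1.8, width: float = 0.3, seed: int = 0
) -> ProteinIntensityTable:
    """Left-shifted normal imputation of missing log-intensities.

    Per run, missing values are drawn from N(mean − downshift·sd,
    (width·sd)²) of that run's observed log10 intensities — the standard
    treatment of left-censored LFQ data. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = t.intensities.copy()
    for run in out.columns:
        col = out[run]
        obs = np.log10(col.dropna())
        if obs.empty:
            raise ProteomicsError(f"run {run!r} has no observed values to impute from")
        miss = col.isna()
        if miss.any():
            draw = rng.normal(obs.mean() - downshift * obs.std(ddof=1), width * obs.std(ddof=1), size=int(miss.sum()))
            out.loc[miss, run] = 10.0**draw
    return ProteinIntensityTable(out, t.groups.copy(), t.peptide_counts.copy())


def _moderated_t(x: np.ndarray, y: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """SAM-style statistic on log2 data: diff / (pooled se + s0)."""
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    sp = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2) * (1 / nx + 1 / ny))
    diff = mx - my
    return diff, diff / (sp + s0)


def volcano_test(
    t: ProteinIntensityTable,
    s0: float = 0.1,
    fdr_alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
) -> VolcanoResult:
    """Permutation-FDR interactor calling, bait IP vs control IP.

    Missing values must be imputed beforehand (see
    :func:`impute_missing`). The FDR at a protein's |statistic| is the
    mean number of permutation statistics at least as large, divided by
    the observed count at least as large. Significance additionally
    requires positive enrichment.
    """
    bait_runs, ctrl_runs = t.runs("bait"), t.runs("control")
    if len(bait_runs) < 3 or len(ctrl_runs) < 3:
        raise ProteomicsError("need >= 3 replicates per group")
    if t.intensities[bait_runs + ctrl_runs].isna().any().any():
        raise ProteomicsError("impute missing values before testing")
    logi = np.log2(t.intensities[bait_runs + ctrl_runs].to_numpy(float))
    nb = len(bait_runs)
    cols = np.arange(logi.shape[1])
    diff, stat = _moderated_t(logi[:, :nb], logi[:, nb:], s0)

    # unordered partitions: a label swap mirrors the two-sided statistic,
    # so keep one representative per {left, right} split and drop the
    # identity partition
    seen, perms = set(), []
    for c in combinations(cols, nb):
        key = frozenset(c)
        mirror = frozenset(np.setdiff1d(cols, list(c)))
        identity = frozenset(cols[:nb])
        if key == identity or mirror == identity or mirror in seen:
            continue
        seen.add(key)
        perms.append(c)
    rng = np.random.default_rng(seed)
    if len(perms) < 2:
        raise ProteomicsError("fewer than 2 distinct label permutations")
    if len(perms) > n_permutations:
        idx = rng.choice(len(perms), size=n_permutations, replace=False)
        perms = [perms[i] for i in idx]
    null_stats = []
    for c in perms:
        left = np.array(c)
        right = np.setdiff1d(cols, left)
        _, s = _moderated_t(logi[:, left], logi[:, right], s0)
        null_stats.append(np.abs(s))
    null_abs = np.concatenate(null_stats)
    n_perm = len(perms)

    obs_abs = np.abs(stat)
    order = np.sort(obs_abs)
    null_sorted = np.sort(null_abs)
    fdr = np.empty_like(obs_abs)
    for i, a in enumerate(obs_abs):
        n_obs = (obs_abs >= a).sum()
        n_null = len(null_sorted) - np.searchsorted(null_sorted, a, side="left")
        fdr[i] = min(1.0, (n_null / n_perm) / max(n_obs, 1))
    # q-value convention: best achievable FDR over thresholds that still
    # include the protein (|stat| <= its own); makes FDR non-increasing
    # in |stat|
    rank = np.argsort(obs_abs, kind="mergesort")
    fdr[rank] = np.minimum.accumulate(fdr[rank])
    significant = (fdr <= fdr_alpha) & (diff > 0)
    table = pd.DataFrame(
        {
            "log2_enrichment": diff,
            "statistic": stat,
            "fdr": fdr,
            "significant": significant,
        },
        index=t.intensities.index,
    )
    return VolcanoResult(table=table, s0=s0, fdr_alpha=fdr_alpha, n_permutations=n_perm)


def stoichiometry(
    t: ProteinIntensityTable,
    complex_members: list[str],
    anchor_proteins: list[str],
    bait: str,
) -> StoichiometryTable:
    """Anchor-relative stoichiometry of complex members in the bait IP.

    abundance = (mean bait-IP − mean control-IP intensity, clamped at 0)
    / theoretical peptide count; S_p = abundance_p / Σ abundance over the
    anchor proteins.
    """
    bait_runs, ctrl_runs = t.runs("bait"), t.runs("control")
    present_anchors = [a for a in anchor_proteins if a in t.intensities.index]
    if not present_anchors:
        raise ProteomicsError(f"anchor proteins {anchor_proteins} not in table")
    proteins = [p for p in complex_members if p in t.intensities.index]
    mean_bait = t.intensities.loc[proteins, bait_runs].mean(axis=1, skipna=True).fillna(0.0)
    mean_ctrl = (
        t.intensities.loc[proteins, ctrl_runs].mean(axis=1, skipna=True).fillna(0.0)
        if ctrl_runs
        else pd.Series(0.0, index=proteins)
    )
    abundance = (mean_bait - mean_ctrl).clip(lower=0.0) / t.peptide_counts.loc[proteins]
    anchor_total = abundance.loc[[a for a in present_anchors]].sum()
    if anchor_total <= 0:
        raise ProteomicsError("anchor abundance is zero; no stoichiometry denominator")
    table = pd.DataFrame(
        {"abundance": abundance, "ratio_to_anchor": abundance / anchor_total}
    )
    return StoichiometryTable(table=table, anchor_proteins=tuple(present_anchors), bait=bait)


def fraction_in_complex(s_bait: float) -> int:
    """Percentage of the bait resident in the complex: 100 / S, rounded
    to the nearest integer percent, under the one-bait-one-anchor
    assumption. S < 1 would mean more complexes than bait and is
    rejected as inconsistent with that assumption.
    """
    if s_bait < 1:
        raise ProteomicsError("S_bait < 1 is inconsistent with one bait copy per complex")
    return int(round(100.0 / s_bait))
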