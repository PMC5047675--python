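"""Synthetic multi-omics data with planted ground truth.

Every input the pipeline consumes — replicated ChIP peak sets, histone-mark
signal tracks, RNA-seq count matrices, AP-MS LFQ intensity tables and
single-cell qPCR Ct tables — can be generated here from a single
:class:`SimConfig`. Each generator is a pure function of the config
(including its seed) and returns latent truth (reproducible-pair labels,
planted fold changes, complex composition, cell-population labels)
alongside the data. Truth is for testing only; analysis stages never see
it.

The defaults describe an ESC-like study: a small two-chromosome genome,
three ChIP'd factors with correlated occupancy, a 14-fold molar excess of
the bait protein over its complex, a two-population single-cell panel of
pluripotency and neural markers, and negative-binomial expression counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, PeakSet
from .tracks import SignalTrack


class ConfigError(ValueError):
    """A SimConfig value is inconsistent or infeasible."""


DEFAULT_COMPLEX = {
    # NuRD-like composition, copies per complex; Mbd3+Mbd2 share one slot
    "Sall4": 1.0,   # bait
    "Mbd3": 0.8,
    "Mbd2": 0.2,
    "Chd4": 1.0,
    "Mta2": 2.0,
    "Hdac1": 2.0,
    "Rbbp4": 4.0,
    "Gatad2b": 2.0,
    "Cdk2ap1": 1.0,
}

PLURIPOTENCY_GENES = ["Esrrb", "Pou5f1", "Nanog", "Zfp42", "Klf2", "Klf4"]
NEURAL_GENES = ["Sema6a", "Hes5", "Nkx6-1", "Sox1", "Ascl1", "Hes6"]
HOUSEKEEPING_GENES = ["Atp5a1", "Ppia", "Gapdh"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    seed            master seed; fixed seed ⇒ byte-identical outputs.
    n_chrom         chromosomes in the toy genome.
    chrom_length    length of each chromosome, bp.
    n_genes         gene models to place (non-overlapping).
    n_enhancers     designated enhancer loci (intergenic and intragenic).
    factors         ChIP'd factor names; the first is the reference factor
                    for the pairwise co-occupancy probabilities.
    cooccupancy     co-occupancy probability of each factor with the
                    reference factor, in [0,1]; entry 0 is ignored.
    pi1             fraction of truly reproducible peaks per replicate pair.
    rho             score correlation of the reproducible component.
    planted_lfc     condition → {gene_id: log2 fold change vs reference}.
    nb_dispersion   NB overdispersion phi (var = mu + phi mu^2).
    complex_spec    protein → copies per complex; must include the bait.
    bait            bait protein name.
    anchors         proteins summed into the stoichiometry anchor.
    bait_excess     S: molar excess of bait over intact complexes (S >= 1).
    noise_cv        LFQ coefficient of variation (log-normal noise).
    censor_quantile LFQ left-censoring quantile (values below → missing).
    dropout_p       single-cell Ct dropout probability for marker genes.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_enhancers: int = 300
    active_enhancer_fraction: float = 0.5
    factors: Sequence[str] = ("Sall4", "Mbd3", "Chd4")
    cooccupancy: Sequence[float] = (1.0, 0.6, 0.5)
    occupancy_rate: float = 0.5
    pi1: float = 0.7
    rho: float = 0.8
    idr_mu: float = 2.0
    idr_sigma2: float = 1.0
    peak_width: int = 300
    bin_width: int = 50
    background_rate: float = 1.0
    mark_enrichment: Mapping[str, float] = field(
        default_factory=lambda: {"H3K4me3": 8.0, "H3K4me1": 6.0, "H3K27ac": 6.0, "Ep300": 4.0}
    )
    reference_condition: str = "2iLIF_WT"
    planted_lfc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    base_mean_log: float = 4.5
    base_mean_sd: float = 1.2
    nb_dispersion: float = 0.05
    libsize_cv: float = 0.15
    complex_spec: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPLEX))
    bait: str = "Sall4"
    anchors: Sequence[str] = ("Mbd3", "Mbd2")
    bait_excess: float = 14.0
    n_background_proteins: int = 80
    n_ip_replicates: int = 3
    noise_cv: float = 0.2
    censor_quantile: float = 0.15
    n_cells_a: int = 40
    n_cells_b: int = 35
    ct_separation: float = 6.0
    dropout_p: float = 0.1

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length must be > 0")
        if not (0.0 <= self.pi1 <= 1.0):
            raise ConfigError("pi1 must be in [0,1]")
        for p in (self.occupancy_rate, self.active_enhancer_fraction, self.censor_quantile):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("probabilities must be in [0,1]")
        if not (0.0 <= self.dropout_p <= 1.0):
            raise ConfigError("dropout_p must be in [0,1]")
        if self.bait_excess < 1:
            raise ConfigError("bait_excess S must be >= 1")
        if len(self.factors) != len(self.cooccupancy):
            raise ConfigError("factors and cooccupancy must have equal length")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the simulation."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


# deterministic stream ids, one per generator
_GENOME, _PEAKS, _SIGNAL, _COUNTS, _LFQ, _CT = range(6)

MIN_GENE_BP = 2_000
MAX_GENE_BP = 8_000
ENHANCER_BP = 400


def make_genome(config: SimConfig) -> GeneAnnotation:
    """Place non-overlapping gene models and designated enhancer loci.

    Genes get uniform lengths in [2, 8] kb, random strands, and one TSS
    each (strand-aware). Enhancers (400 bp) are dropped both between and
    inside genes, at least 2 kb from every TSS, and a configured fraction
    is flagged active.
    """
    rng = config.rng(_GENOME)
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chrom)
    capacity_needed = config.n_genes / config.n_chrom * (MAX_GENE_BP + 200)
    if capacity_needed > config.chrom_length:
        raise ConfigError(
            f"cannot place {config.n_genes} genes of up to {MAX_GENE_BP} bp "
            f"on {config.n_chrom} x {config.chrom_length} bp chromosomes"
        )
    rows = []
    for ci, idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        n = len(idx)
        lengths = rng.integers(MIN_GENE_BP, MAX_GENE_BP + 1, size=n)
        slack = config.chrom_length - int(lengths.sum())
        if slack < n + 1:
            raise ConfigError(f"genome too small for {n} genes on {chrom}")
        # distribute the intergenic slack as n+1 random gaps
        gaps = rng.multinomial(slack - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start, end = pos, pos + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{idx[k]:04d}", chrom, start, end, strand, int(lengths[k])))
            pos = end
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "exon_bp"])

    ann = GeneAnnotation(genes)
    tss_by_chrom = {c: g["tss"].to_numpy() for c, g in ann.genes.groupby("chrom")}
    enh_rows, placed = [], {c: [] for c in tss_by_chrom}
    tries = 0
    while len(enh_rows) < config.n_enhancers:
        tries += 1
        if tries > 200 * config.n_enhancers:
            raise ConfigError("genome too small to place requested enhancers")
        chrom = f"chr{int(rng.integers(config.n_chrom)) + 1}"
        start = int(rng.integers(0, config.chrom_length - ENHANCER_BP))
        centre = start + ENHANCER_BP // 2
        if np.min(np.abs(tss_by_chrom.get(chrom, np.array([0])) - centre), initial=1 << 30) < 2_000:
            continue
        if any(abs(p - start) < 2 * ENHANCER_BP for p in placed[chrom]):
            continue
        placed[chrom].append(start)
        active = bool(rng.random() < config.active_enhancer_fraction)
        enh_rows.append((chrom, start, start + ENHANCER_BP, active))
    enh = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "active"])
    enh = enh.sort_values(["chrom", "start"]).reset_index(drop=True)
    return GeneAnnotation(ann.genes, enhancers=enh)


def simulate_peak_replicates(
    annotation: GeneAnnotation, config: SimConfig
) -> tuple[dict[str, list[PeakSet]], dict[str, pd.DataFrame]]:
    """Two scored peak replicates per factor, with latent truth.

    Candidate loci are TSSs and enhancer centres. The reference factor
    occupies each locus with ``occupancy_rate``; every other factor keeps
    a reference-occupied locus with its co-occupancy probability and adds
    unshared loci so its marginal rate stays comparable. A fraction
    ``pi1`` of each factor's loci is reproducible: present in both
    replicates with bivariate-normal log scores (correlation ``rho``).
    The rest carry independent background scores, and a small number of
    replicate-private noise peaks (scaled by 1 - pi1) is appended.
    """
    if len(config.factors) == 0:
        raise ConfigError("factor list is empty")
    if not (0.0 < config.pi1 <= 1.0):
        raise ConfigError("pi1 must be in (0,1]")
    rng = config.rng(_PEAKS)
    if annotation.enhancers is None:
        raise ConfigError("annotation carries no enhancer loci")
    loci = np.concatenate(
        [annotation.genes["tss"].to_numpy(), (annotation.enhancers["start"] + ENHANCER_BP // 2).to_numpy()]
    )
    chroms = np.concatenate(
        [annotation.genes["chrom"].to_numpy(), annotation.enhancers["chrom"].to_numpy()]
    )
    n_loci = len(loci)
    ref_occ = rng.random(n_loci) < config.occupancy_rate

    peaks: dict[str, list[PeakSet]] = {}
    truth: dict[str, pd.DataFrame] = {}
    half = config.peak_width // 2
    for fi, factor in enumerate(config.factors):
        c = float(config.cooccupancy[fi]) if fi > 0 else 1.0
        if not (0.0 <= c <= 1.0):
            raise ConfigError("co-occupancy probabilities must be in [0,1]")
        keep = ref_occ & (rng.random(n_loci) < c)
        extra = (~ref_occ) & (rng.random(n_loci) < config.occupancy_rate * (1.0 - c))
        occ = np.flatnonzero(keep | extra) if fi > 0 else np.flatnonzero(ref_occ)
        n = len(occ)
        reproducible = rng.random(n) < config.pi1
        # reproducible scores: bivariate normal on the log scale
        mu, s2, r = config.idr_mu, config.idr_sigma2, config.rho
        cov = [[s2, r * s2], [r * s2, s2]]
        z_rep = rng.multivariate_normal([mu, mu], cov, size=n)
        z_bg = rng.standard_normal((n, 2))
        z = np.where(reproducible[:, None], z_rep, z_bg)
        scores = np.exp(z)
        jitter = rng.integers(-30, 31, size=(n, 2))
        rows = {0: [], 1: []}
        rec = []
        for k, li in enumerate(occ):
            centre = int(loci[li])
            name = f"{factor}_loc{li}"
            for r_i in (0, 1):
                s = max(0, centre - half + int(jitter[k, r_i]))
                rows[r_i].append((chroms[li], s, s + config.peak_width, name, scores[k, r_i]))
            rec.append((name, chroms[li], centre, bool(reproducible[k])))
        # replicate-private noise peaks, vanish as pi1 -> 1
        n_noise = int(round(0.2 * (1.0 - config.pi1) * n))
        for r_i in (0, 1):
            for j in range(n_noise):
                chrom = f"chr{int(rng.integers(config.n_chrom)) + 1}"
                s = int(rng.integers(0, config.chrom_length - config.peak_width))
                rows[r_i].append(
                    (chrom, s, s + config.peak_width, f"{factor}_noise{r_i}_{j}", float(np.exp(rng.standard_normal())))
                )
        cols = ["chrom", "start", "end", "name", "score"]
        peaks[factor] = [
            PeakSet(factor, "rep1", pd.DataFrame(rows[0], columns=cols)),
            PeakSet(factor, "rep2", pd.DataFrame(rows[1], columns=cols)),
        ]
        truth[factor] = pd.DataFrame(rec, columns=["name", "chrom", "centre", "reproducible"])
    return peaks, truth


def simulate_score_pairs(
    pi1: float,
    n: int,
    seed: int,
    mu: float = 2.0,
    sigma2: float = 1.0,
    rho: float = 0.8,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicate score pairs drawn directly from the IDR mixture model.

    A fraction ``pi1`` of pairs is reproducible (bivariate normal log
    scores, correlation ``rho``); the rest carry independent standard
    normal log scores. Returns the pair table (score1/score2 at
    synthetic non-overlapping loci) and the latent reproducible labels —
    the distilled substrate for testing the IDR fitter.
    """
    if not (0.0 < pi1 <= 1.0):
        raise ConfigError("pi1 must be in (0,1]")
    rng = np.random.default_rng(seed)
    rep = rng.random(n) < pi1
    cov = [[sigma2, rho * sigma2], [rho * sigma2, sigma2]]
    z = np.where(
        rep[:, None],
        rng.multivariate_normal([mu, mu], cov, size=n),
        rng.standard_normal((n, 2)),
    )
    pairs = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 300,
            "name": [f"pair{i}" for i in range(n)],
            "score1": np.exp(z[:, 0]),
            "score2": np.exp(z[:, 1]),
        }
    )
    return pairs, rep


def simulate_signal(
    annotation: GeneAnnotation,
    peaks: Mapping[str, Sequence[PeakSet]] | None,
    config: SimConfig,
) -> dict[str, SignalTrack]:
    """Binned coverage tracks for histone marks and (optionally) factors.

    Promoter windows (TSS ± 500 bp) are enriched for H3K4me3; enhancer
    loci for H3K4me1; H3K27ac and Ep300 only at enhancers flagged active.
    Factor tracks are enriched over the union of that factor's replicate
    peaks. Elsewhere the signal is flat Poisson background. A multiplier
    of 0 disables enrichment for that mark entirely.
    """
    for mark in config.mark_enrichment:
        if mark not in {"H3K4me3", "H3K4me1", "H3K27ac", "Ep300"}:
            raise ConfigError(f"unknown mark {mark!r}")
    if config.chrom_length % config.bin_width:
        raise ConfigError("bin_width must divide chrom_length")
    rng = config.rng(_SIGNAL)
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    enh = annotation.enhancers
    if enh is None:
        raise ConfigError("annotation carries no enhancer loci")

    def regions_for(mark: str) -> pd.DataFrame:
        if mark == "H3K4me3":
            g = annotation.genes
            return pd.DataFrame(
                {"chrom": g["chrom"], "start": g["tss"] - 500, "end": g["tss"] + 500}
            )
        if mark == "H3K4me1":
            return enh[["chrom", "start", "end"]]
        return enh.loc[enh["active"], ["chrom", "start", "end"]]

    tracks: dict[str, SignalTrack] = {}

    def build(regions: pd.DataFrame, mult: float) -> SignalTrack:
        track = SignalTrack.zeros(sizes, config.bin_width)
        for chrom, v in track.values.items():
            rate = np.full(len(v), config.background_rate)
            if mult > 0:
                sel = regions[regions["chrom"] == chrom]
                for row in sel.itertuples(index=False):
                    b0 = max(0, int(row.start) // config.bin_width)
                    b1 = min(len(v), -(-int(row.end) // config.bin_width))
                    rate[b0:b1] = config.background_rate * mult
            track.values[chrom] = rng.poisson(rate).astype(float)
        return track

    for mark, mult in config.mark_enrichment.items():
        tracks[mark] = build(regions_for(mark), mult)
    if peaks:
        for factor, reps in peaks.items():
            iv = pd.concat([ps.intervals for ps in reps], ignore_index=True)
            tracks[factor] = build(iv[["chrom", "start", "end"]], 8.0)
    return tracks


def simulate_counts(
    annotation: GeneAnnotation, design: pd.DataFrame, config: SimConfig
) -> tuple["CountMatrix", pd.DataFrame]:
    """Negative-binomial gene×sample counts with planted fold changes.

    Per-gene baseline means are log-normal; per-sample library-size
    factors are log-normal with CV ``libsize_cv``; condition effects are
    the planted log2 fold changes relative to ``reference_condition``.
    Returns the CountMatrix and a truth table (gene, base_mean, lfc per
    condition).
    """
    from .expression import CountMatrix

    rng = config.rng(_COUNTS)
    if "condition" not in design.columns:
        raise ConfigError("design must have a 'condition' column")
    conditions = list(dict.fromkeys(design["condition"]))
    counts_per = design["condition"].value_counts()
    if (counts_per < 2).any():
        raise ConfigError("each condition needs >= 2 samples")
    for cond in conditions:
        if cond != config.reference_condition and cond not in config.planted_lfc:
            raise ConfigError(f"condition {cond!r} absent from planted_lfc mapping")

    genes = annotation.genes["gene_id"].to_numpy()
    n_g, n_s = len(genes), len(design)
    base = np.exp(rng.normal(config.base_mean_log, config.base_mean_sd, size=n_g))
    sigma_ls = np.sqrt(np.log1p(config.libsize_cv**2))
    size_f = np.exp(rng.normal(0.0, sigma_ls, size=n_s))
    lfc = pd.DataFrame(0.0, index=genes, columns=conditions)
    for cond, mapping in config.planted_lfc.items():
        for gid, v in mapping.items():
            if gid in lfc.index:
                lfc.loc[gid, cond] = float(v)

    mat = np.zeros((n_g, n_s), dtype=np.int64)
    phi = float(config.nb_dispersion)
    for j, (sample, row) in enumerate(design.iterrows()):
        mu = base * (2.0 ** lfc[row["condition"]].to_numpy()) * size_f[j]
        if phi <= 1e-12:
            mat[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            p = r / (r + mu)
            mat[:, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=genes, columns=design.index)
    lengths = pd.Series(annotation.genes["exon_bp"].to_numpy(), index=genes, name="gene_length")
    truth = lfc.copy()
    truth.insert(0, "base_mean", base)
    cm = CountMatrix(counts=counts, gene_lengths=lengths, design=design)
    return cm, truth


def simulate_lfq(config: SimConfig) -> tuple["ProteinIntensityTable", pd.DataFrame]:
    """LFQ intensity table for a bait IP vs control IP experiment.

    Intensities follow the iBAQ convention: molar abundance × theoretical
    tryptic peptide count. Complex members appear in bait-IP runs in
    proportion to copies-per-complex; the bait itself is at ``bait_excess``
    molar excess over intact complexes. Control runs carry background
    binders only (background is also present in bait runs). Log-normal
    noise at ``noise_cv``; intensities below the per-run
    ``censor_quantile`` are blanked (left-censoring).
    """
    from .proteomics import ProteinIntensityTable

    rng = config.rng(_LFQ)
    spec = dict(config.complex_spec)
    if config.bait not in spec:
        raise ConfigError(f"bait {config.bait!r} missing from complex_spec")
    if not any(a in spec for a in config.anchors):
        raise ConfigError("no anchor protein present in complex_spec")
    if config.bait_excess < 1:
        raise ConfigError("bait_excess S must be >= 1")

    members = list(spec)
    backgrounds = [f"bg{k:03d}" for k in range(config.n_background_proteins)]
    proteins = members + backgrounds
    peptide_counts = pd.Series(
        rng.integers(5, 51, size=len(proteins)), index=proteins, name="peptide_count"
    )

    complex_amount = 1e6  # arbitrary molar units of intact complex
    molar_bait = {}
    for p in members:
        molar_bait[p] = spec[p] * complex_amount
    molar_bait[config.bait] = config.bait_excess * complex_amount  # total bait pulled down
    bg_molar = np.exp(rng.normal(np.log(complex_amount) - 3.0, 1.0, size=len(backgrounds)))

    n_rep = config.n_ip_replicates
    runs = [f"bait_{i + 1}" for i in range(n_rep)] + [f"ctrl_{i + 1}" for i in range(n_rep)]
    groups = pd.Series(["bait"] * n_rep + ["control"] * n_rep, index=runs, name="group")

    base = pd.DataFrame(0.0, index=proteins, columns=runs)
    for p in members:
        base.loc[p, groups == "bait"] = molar_bait[p] * peptide_counts[p]
    for k, p in enumerate(backgrounds):
        base.loc[p, :] = bg_molar[k] * peptide_counts[p]

    sigma = np.sqrt(np.log1p(config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    noise = np.exp(rng.normal(0.0, sigma, size=base.shape)) if sigma > 0 else 1.0
    intensities = base * noise
    intensities[intensities <= 0] = np.nan
    # left-censoring: blank the lowest censor_quantile of observed values per run
    if config.censor_quantile > 0:
        for run in runs:
            col = intensities[run]
            obs = col.dropna()
            if len(obs):
                cut = obs.quantile(config.censor_quantile)
                intensities.loc[col <= cut, run] = np.nan

    truth = pd.DataFrame(
        {"copies": [spec.get(p, 0.0) for p in proteins], "is_member": [p in members for p in proteins]},
        index=proteins,
    )
    truth.attrs["bait_excess"] = config.bait_excess
    table = ProteinIntensityTable(intensities=intensities, groups=groups, peptide_counts=peptide_counts)
    return table, truth


def simulate_ct(config: SimConfig) -> tuple["CtMatrix", pd.Series]:
    """Single-cell qPCR Ct table with two latent populations.

    Population A (e.g. WT) expresses the pluripotency panel and not the
    neural panel; population B expresses both, with the neural panel
    shifted by ``ct_separation`` cycles. Housekeeping genes carry a
    per-cell offset (pipetting / cell-size variation). Marker-gene
    measurements drop out with probability ``dropout_p``; housekeeping
    genes are always measured so every cell is normalisable.
    """
    from .expression import CtMatrix

    rng = config.rng(_CT)
    if len(HOUSEKEEPING_GENES) < 2:
        raise ConfigError("need >= 2 housekeeping genes")
    n_a, n_b = config.n_cells_a, config.n_cells_b
    cells = [f"cell{j + 1:03d}" for j in range(n_a + n_b)]
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=cells, name="population")
    genes = HOUSEKEEPING_GENES + PLURIPOTENCY_GENES + NEURAL_GENES

    cell_offset = rng.normal(0.0, 1.0, size=n_a + n_b)
    ct = pd.DataFrame(index=genes, columns=cells, dtype=float)
    for j, cell in enumerate(cells):
        hk = 18.0 + cell_offset[j]
        for g in HOUSEKEEPING_GENES:
            ct.loc[g, cell] = hk + rng.normal(0.0, 0.3)
        for g in PLURIPOTENCY_GENES:
            ct.loc[g, cell] = hk + 3.0 + rng.normal(0.0, 0.8)
        neural_delta = 10.0 if labels[cell] == "A" else 10.0 - config.ct_separation
        for g in NEURAL_GENES:
            ct.loc[g, cell] = hk + neural_delta + rng.normal(0.0, 0.8)
    if config.dropout_p > 0:
        marker = PLURIPOTENCY_GENES + NEURAL_GENES
        mask = rng.random((len(marker), len(cells))) < config.dropout_p
        ct.loc[marker] = ct.loc[marker].mask(mask)
    cm = CtMatrix(ct=ct, housekeeping=tuple(HOUSEKEEPING_GENES))
    return cm, labels


def default_design(config: SimConfig, conditions: Sequence[str] | None = None, n_rep: int = 3) -> pd.DataFrame:
    """A balanced design table: ``n_rep`` samples per condition."""
    conditions = list(conditions or [config.reference_condition, *config.planted_lfc])
    rows = []
    for cond in conditions:
        for r in range(n_rep):
            rows.append((f"{cond}_r{r + 1}", cond, r + 1))
    df = pd.DataFrame(rows, columns=["sample", "condition", "replicate"]).set_index("sample")
    return df
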