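# Methods

`regulomics` re-implements, as a tested pipeline, the integrative analysis
used to characterise a transcription factor's relationship to a chromatin
remodelling complex in embryonic stem cells: replicate-filtered ChIP-seq
peak calls, five-class chromatin annotation, binding-profile correlation,
differential expression, AP-MS interaction stoichiometry, and the
cross-dataset reports that tie them together. Every stage runs end to end
on synthetic data with planted ground truth, so the statistical behaviour
of each method is verifiable without any external download.

## Coordinate and format conventions

All intervals are 0-based half-open (BED convention) internally; GFF3 is
converted on read. "Overlap" always means at least one shared base — no
minimum-overlap fraction is applied anywhere. The TSS of a gene is its
`start` on the + strand and `end − 1` on the − strand. Nearest-gene
assignment minimises |TSS − peak centre| with the peak centre at
`floor((start+end)/2)`, strand ignored; distance ties resolve to the
lexicographically smaller gene id. These choices match common
peak-annotation practice and make every report exactly reproducible.

## IDR replicate filtering

Overlapping peaks from two replicates are matched greedily, one-to-one, in
descending score order of replicate 1. Matched pair scores are converted
to ranks, then modelled with a two-component Gaussian copula mixture:

- component 0 (irreproducible): independent standard bivariate normal;
- component 1 (reproducible): mean (μ, μ), variance σ², correlation ρ,
  mixing weight π₁.

The fit is the standard semiparametric pseudo-likelihood iteration:
pseudo-scores are obtained by inverting the current model's mixture
marginal CDF at the empirical ranks `(rank − 0.5)/n`, EM runs to
convergence on those pseudo-scores, and the two steps alternate until the
parameters settle (outer budget 30, EM tolerance 1e-6 on the
log-likelihood, initialisation π₁=0.5, μ=1, σ²=1, ρ=0.5). We initially
evaluated a cheaper one-pass variant that fits directly on normal scores
of ranks; it biased π₁ by up to ~0.3 because the pooled marginal of the
transformed data is forced standard normal, which the unconstrained
mixture then mis-attributes. The iteration removes that bias: across
π₁ ∈ {0.3, 0.5, 0.7, 0.9} at n = 2000 pairs the mean absolute error is
≤ 0.06 in the recovery suite. The log-likelihood is asserted
non-decreasing within each EM run; non-convergence sets a flag rather
than raising.

The local IDR of a pair is the posterior of component 0; the global IDR is
the running mean of sorted local IDRs, and `call_reproducible` keeps pairs
with global IDR ≤ α (default 0.05 — a config value, since the analysis the
pipeline emulates does not state its threshold). Unpaired peaks can never
be called reproducible. The lenient alternative, `merge_replicates`,
returns the overlap-merged union of both replicates and is always a
superset of the IDR-passed loci.

## Chromatin annotation

Peaks are scored against each mark track as mean binned signal within the
peak divided by the genome-wide median (the background unit). The
five-class cascade is:

1. centre within ±1 kb of a TSS, or H3K4me3 ≥ 4× → **promoter**;
2. else H3K4me1 ≥ 2× with H3K4me3 below threshold → **active enhancer**
   if H3K27ac ≥ 2×, otherwise **poised enhancer**;
3. else centre inside a gene extent → **gene body**;
4. else **intergenic**.

The promoter test deliberately precedes the enhancer test, so a
K4me3-high TSS peak is a promoter even when K4me1-high. All four
thresholds and the window are config values
(`ClassificationThresholds`), because published five-class definitions
vary; the defaults were chosen once to sit well clear of both the Poisson
background (enrichment ≈ 1) and the planted enrichment levels of the
simulator (8×/6×/6×). Labels are exhaustive and mutually exclusive by
construction. Ep300 is generated and accepted as a reporting track only —
it plays no role in the cascade.

## Profiles and correlation

Profile matrices hold mean binned signal in 80 × 50 bp bins spanning
±2 kb around peak centres, rows sorted by descending row sum; windows
truncated at a chromosome end are padded with the genome median and
flagged. Dataset–dataset correlation is Pearson r of binary occupancy
vectors over the merged peak universe (scale-free and faithful to
"correlation between peaks"); a binned-signal mode is provided as an
option. Leaf order comes from scipy's average-linkage clustering on
1 − r.

## Differential expression

Counts are normalised by median-of-ratios size factors (upper-quartile
fallback with a warning when no gene has all-positive counts). Per-gene
dispersions use the method of moments on within-group variances, shrunk
50/50 toward a fitted trend φ(μ) = a₀/μ + a₁ (coefficients clamped
non-negative). The two-group p-value is the classic conditional NB exact
test: given the pooled total of a gene, the probabilities of all splits no
more likely than the observed one are summed; the Poisson limit
(dispersion → 0) switches to the conditional binomial. Benjamini–Hochberg
controls FDR at 0.05 by default. On null simulations the realised
false-discovery proportion stays below nominal (the exact test is
slightly conservative), and strongly planted effects (|log2fc| = 2, mean
≥ 100, 3v3) are detected with > 80% power. Log2 fold changes use a 0.5
pseudo-count on normalised means.

PCA embeds samples by SVD of gene-centred log2(FPKM + 1) over the 500
most variable genes (both config values); component signs are fixed so
the first gene's loading is non-negative.

## qPCR

Bulk fold changes use 2^−ΔΔCt. Single-cell tables are normalised per cell
to −ΔCt against the mean of the housekeeping genes (Atp5a1, Ppia, Gapdh
by default); missing Ct values stay missing — no limit-of-detection
imputation — and cells lacking every housekeeping measurement are dropped
with a warning. Gene and cell dendrograms use average linkage on
pairwise-complete Euclidean distances rescaled by √(p/shared); rows that
share fewer than two observations with the rest are placed last and
flagged.

## AP-MS

Missing LFQ values are imputed per run from a normal left-shifted by 1.8
observed-SD with 0.3 observed-SD width (log10 scale) — the standard
treatment of left-censored label-free data. Interactors are called with a
SAM-style moderated statistic (fudge factor s0 = 0.1) on log2
intensities against a label-permutation null; with 3v3 runs the null uses
the 9 distinct unordered partitions (a label swap mirrors a two-sided
statistic and is excluded as redundant). The per-protein FDR is the
q-value convention: the best achievable (null exceedances / observed
exceedances) over thresholds that still include the protein.
Significance requires FDR ≤ 0.01 and positive enrichment.

Stoichiometry follows the iBAQ convention: abundance = (mean bait-IP −
mean control-IP intensity, clamped at 0) / theoretical tryptic peptide
count, which approximates molar amount; ratios are taken to the anchor,
defined as the *sum* of the proteins sharing one complex slot (e.g.
Mbd2 + Mbd3). Under one bait copy and one anchor slot per complex, a
bait:anchor ratio S implies a fraction 100/S % of the bait is
complex-resident; S < 1 is rejected as inconsistent with that assumption.
Peptide counts default to 1 when not supplied, degrading gracefully to
intensity ratios.

## Integration reports

Overlap reports round percentages half away from zero to the nearest
integer, and fold ratios to one decimal — the granularity at which such
results are quoted. The dependency (recruitment) report composes
`peaks_lost` (no shared base in the knockout) with factor overlap and
emits both the percentage of lost peaks that are factor-bound and that
count as a fraction of all wild-type peaks, since the two denominators
answer different questions. Direction-of-change comparisons fit ordinary
least squares over genes significant in both contrasts and report R²
(equal to the squared Pearson correlation by construction).

## Synthetic data

The generators are pure functions of a `SimConfig` (fixed seed ⇒
byte-identical output; independent named substreams per generator), and
always return the latent truth alongside the data — truth is consumed
only by tests, never by analysis stages.

- **Genome**: 2 × 1 Mb chromosomes, 200 non-overlapping genes (2–8 kb,
  random strand) placed by distributing the intergenic slack as random
  gaps; 300 × 400 bp enhancer loci ≥ 2 kb from every TSS, half flagged
  active. Small by design: large enough for stable class fractions and
  oracle checks, small enough that the whole suite runs in seconds.
- **Peak replicates**: candidate loci are TSSs and enhancer centres; the
  reference factor occupies each with probability 0.5, other factors keep
  a reference locus with their pairwise co-occupancy probability and add
  unshared loci to preserve their marginal rate. A fraction π₁ (default
  0.7) of each factor's loci is reproducible — present in both replicates
  with bivariate normal log scores (μ=2, σ²=1, ρ=0.8, the clean
  two-component structure the IDR model assumes); the rest carry
  independent background scores, plus replicate-private noise peaks
  scaled by (1 − π₁). `simulate_score_pairs` exposes the same score model
  at the pair level for testing the fitter directly.
- **Signal**: Poisson counts in 50 bp bins at background rate 1, with the
  rate multiplied by 8 (H3K4me3, promoters), 6 (H3K4me1, enhancers;
  H3K27ac, active enhancers only) or 4 (Ep300, active enhancers); factor
  tracks are built the same way over supplied peak sets. A multiplier of
  0 yields pure background.
- **Counts**: NB with var = μ + φμ², φ = 0.05, log-normal baseline means
  (log-mean 4.5, SD 1.2), log-normal library-size factors (CV 0.15) and
  planted per-gene log2 fold changes per condition.
- **LFQ**: intensity = molar amount × peptide count (so the
  stoichiometry stage has an exact inverse); complex members appear in
  bait runs at copies-per-complex, the bait at S-fold excess (default 14),
  background binders in all runs; log-normal noise at CV 0.2; values
  below the 0.15 run quantile are blanked (left-censoring, matching the
  left-shifted imputation downstream).
- **Ct**: two cell populations (40 + 35), pluripotency and neural marker
  panels with a 6-cycle neural separation, per-cell housekeeping offsets
  (SD 1), 10% marker dropout. Housekeeping genes are always measured so
  every cell is normalisable.

What the simulator does *not* emulate: read-level noise and alignment
artefacts, fragment-size effects, mappability, GC bias, batch structure,
peak-width heterogeneity, or correlated LFQ missingness across runs.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under their model assumptions, not robustness to every
artefact of real sequencing or MS data.

## Problem sizes

The default test and verification runs use: n = 2000 score pairs × 10
seeds × 4 mixing weights for IDR recovery; 2000 genes × 20 seeds (null)
and 500 genes × 5 seeds (power) for DE calibration; 10 seeds for
stoichiometry recovery and volcano calibration; 500-interval instances ×
20 seeds for oracle equivalence. These sizes give stable averages for
every criterion while keeping the whole suite under a minute.

## Known limitations

- IDR is pairwise only; more than two replicates are out of scope, as are
  self-consistency pseudo-replicates.
- The exact test assumes a shared dispersion per gene across groups and
  no interaction structure beyond the single condition factor.
- The five-class enhancer definitions are declared, not inferred; real
  analyses may use H3K27me3 or Ep300 in the poised definition.
- Occupancy correlation treats the peak universe as exchangeable
  intervals; no signal-strength weighting.
- Genome-scale counts (absolute peak or DE gene numbers) depend on the
  raw data of a given study and are not reproduction targets; the
  worked-example arithmetic and calibration properties are.
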