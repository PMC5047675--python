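# regulomics

An integrative ChIP-seq / RNA-seq / AP-MS analysis toolkit for regulatory
genomics, built around the question of whether a transcription factor
recruits — or merely co-occupies chromatin with — a co-repressor complex.
The motivating case is Sall4 and the NuRD (Nucleosome Remodelling and
Deacetylase) complex in mouse embryonic stem cells, but every stage is
generic:

- **Peak reproducibility** — the irreproducible discovery rate (IDR):
  replicate peak pairs are modelled on the rank scale as a two-component
  Gaussian copula mixture (reproducible component: correlated bivariate
  normal with weight π₁; irreproducible: independent standard normal),
  fitted by a semiparametric EM. Peaks with global IDR ≤ α survive. The
  lenient alternative — merging replicates — is also provided.
- **Chromatin annotation** — each peak is assigned to one of five
  classes (promoter, gene body, intergenic, poised enhancer, active
  enhancer) from its position relative to TSSs and its H3K4me3 / H3K4me1
  / H3K27ac fold-enrichment over background.
- **Profiles and correlation** — signal heat-map matrices ±2 kb around
  peak centres, meta-profiles, and dataset–dataset Pearson correlation of
  binary occupancy over the merged peak universe with average-linkage
  clustering.
- **Expression** — FPKM, median-of-ratios size factors, a
  negative-binomial conditional exact test with trend-shrunk dispersions
  and Benjamini–Hochberg FDR, PCA of log2(FPKM+1), plus qPCR utilities:
  2^−ΔΔCt fold changes and single-cell −ΔCt normalisation against
  housekeeping genes with missing-aware hierarchical clustering.
- **AP-MS** — left-shifted imputation of censored LFQ intensities,
  volcano interactor calling (SAM-style statistic, permutation FDR), and
  iBAQ-style anchor-relative stoichiometry: with a bait:anchor ratio S
  and one copy of each per complex, a fraction 100/S % of the bait is
  complex-resident.
- **Integration** — nearest-gene assignment of peaks, gene-set overlap
  reports with up/down splits, direction-of-change regression (R²),
  dependency ("recruitment") analysis of peaks lost in a knockout, and
  fold-gain of binding sites.
- **Synthetic data** — a first-class generator that produces every input
  (BED/GFF3/bedGraph/TSV) from a single seeded config with planted
  ground truth: reproducible-pair labels, co-occupancy structure,
  mark-specific enrichment, NB fold changes, complex composition with
  bait excess, and two-population Ct tables.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import regulomics as rg

cfg = rg.SimConfig(seed=42, pi1=0.7, bait_excess=14.0)
ann = rg.make_genome(cfg)
peaks, truth = rg.simulate_peak_replicates(ann, cfg)

# 1. IDR replicate filtering for Sall4
rep1, rep2 = peaks["Sall4"]
paired = rg.pair_replicates(rep1, rep2)
model = rg.fit_idr(paired)
passed = rg.call_reproducible(rg.assign_idr(model, paired), paired, alpha=0.05)
print(f"Sall4: {len(paired)} replicate pairs, fitted pi1 = {model.pi1:.2f}, "
      f"{len(passed)} peaks pass IDR <= 0.05")

# 2. chromatin annotation of the passed peaks
tracks = rg.simulate_signal(ann, None, cfg)
_, counts = rg.classify_peakset(passed, tracks, ann)
print("peak classes:", counts)

# 3. AP-MS stoichiometry at 14-fold bait excess
lfq, _ = rg.simulate_lfq(cfg)
st = rg.stoichiometry(lfq, list(cfg.complex_spec), list(cfg.anchors), cfg.bait)
print(f"bait:anchor stoichiometry S = {st.s_bait:.1f} "
      f"-> fraction in complex = {rg.fraction_in_complex(st.s_bait)}%")
```

prints

```
Sall4: 246 replicate pairs, fitted pi1 = 0.69, 171 peaks pass IDR <= 0.05
peak classes: {'promoter': 67, 'gene_body': 0, 'intergenic': 0, 'poised_enhancer': 49, 'active_enhancer': 55}
bait:anchor stoichiometry S = 11.7 -> fraction in complex = 9%
```

The fitted π₁ (0.69) recovers the planted reproducible fraction (0.7);
the surviving peaks split between promoters and enhancers as planted; and
the noisy LFQ run (CV 0.2) recovers the planted 14-fold bait excess to
within 20%, implying that only a small percentage of the bait is resident
in the complex. In the noiseless limit the recovery is exact:
`rg.fraction_in_complex(14.0)` → `7`.

A command-line interface mirrors the library
(`regulomics simulate | idr | classify | corr | de | ct-normalize |
volcano | stoich | overlap | nearest | venn`); run
`regulomics --help` for details.

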