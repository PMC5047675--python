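"""Five-class chromatin annotation of peaks.

Peaks are partitioned into promoter, gene body, intergenic, poised
enhancer and active enhancer classes from their location relative to
gene models and their mean fold-enrichment for H3K4me3, H3K4me1 and
H3K27ac. The decision cascade (promoter test first, then enhancer, then
gene body, else intergenic) and every threshold are explicit config so
alternative definitions are a config edit away.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, PeakSet
from .tracks import SignalTrack, TrackError

CLASSES = ("promoter", "gene_body", "intergenic", "poised_enhancer", "active_enhancer")
REQUIRED_MARKS = ("H3K4me3", "H3K4me1", "H3K27ac")


@dataclass
class ClassificationThresholds:
    """Minimum mean fold-enrichment over genome-median background per
    mark, plus the promoter window around the TSS (bp)."""

    promoter_window: int = 1000
    tau_k4me3: float = 4.0
    tau_k4me1: float = 2.0
    tau_k27ac: float = 2.0

    def __post_init__(self) -> None:
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")
        if min(self.tau_k4me3, self.tau_k4me1, self.tau_k27ac) <= 0:
            raise ValueError("all enrichment thresholds must be > 0")


def score_against_track(peaks: PeakSet, track: SignalTrack) -> np.ndarray:
    """Per-peak mean binned signal divided by the genome-wide median.

    A zero genome median (pathological track) falls back to the genome
    mean so the ratio stays defined.
    """
    bg = track.genome_median()
    if bg == 0:
        bg = float(np.mean(np.concatenate(list(track.values.values()))))
        if bg == 0:
            raise TrackError("track has no signal anywhere")
    out = np.empty(len(peaks))
    for k, row in enumerate(peaks.intervals.itertuples(index=False)):
        try:
            out[k] = track.window_mean(row.chrom, row.start, row.end) / bg
        except TrackError as exc:
            raise TrackError(f"peak {row.name}: {exc}") from exc
    return out


def classify_peak(
    centre_chrom: str,
    centre: int,
    enrichments: dict[str, float],
    ann: GeneAnnotation,
    thr: ClassificationThresholds,
) -> str:
    """Classify one peak given its centre and per-mark enrichments.

    Cascade: (1) centre within the promoter window of any TSS, or
    H3K4me3-high → promoter; (2) H3K4me1-high without H3K4me3 →
    active_enhancer if H3K27ac-high else poised_enhancer; (3) centre
    inside a gene extent → gene_body; (4) intergenic.
    """
    missing = [m for m in REQUIRED_MARKS if m not in enrichments]
    if missing:
        raise ValueError(f"missing mark enrichments: {missing}; required: {list(REQUIRED_MARKS)}")
    genes = ann.genes[ann.genes["chrom"] == centre_chrom]
    near_tss = (
        not genes.empty
        and (np.abs(genes["tss"].to_numpy() - centre) <= thr.promoter_window).any()
    )
    if near_tss or enrichments["H3K4me3"] >= thr.tau_k4me3:
        return "promoter"
    if enrichments["H3K4me1"] >= thr.tau_k4me1 and enrichments["H3K4me3"] < thr.tau_k4me3:
        if enrichments["H3K27ac"] >= thr.tau_k27ac:
            return "active_enhancer"
        return "poised_enhancer"
    in_gene = (
        not genes.empty
        and ((genes["start"].to_numpy() <= centre) & (centre < genes["end"].to_numpy())).any()
    )
    if in_gene:
        return "gene_body"
    return "intergenic"


def classify_peakset(
    peaks: PeakSet,
    tracks: dict[str, SignalTrack],
    ann: GeneAnnotation,
    thr: ClassificationThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every peak; labels are exhaustive and mutually exclusive.

    Returns (labels table, class counts). Counts always sum to the number
    of peaks.
    """
    thr = thr or ClassificationThresholds()
    missing = [m for m in REQUIRED_MARKS if m not in tracks]
    if missing:
        raise ValueError(f"missing mark tracks: {missing}")
    enr = {m: score_against_track(peaks, tracks[m]) for m in REQUIRED_MARKS}
    centres = peaks.centres()
    labels = []
    for k, row in enumerate(peaks.intervals.itertuples(index=False)):
        e = {m: float(enr[m][k]) for m in REQUIRED_MARKS}
        labels.append(classify_peak(row.chrom, int(centres[k]), e, ann, thr))
    table = peaks.intervals.copy()
    table["peak_class"] = labels
    for m in REQUIRED_MARKS:
        table[f"enr_{m}"] = enr[m]
    counts = Counter(labels)
    return table, {c: counts.get(c, 0) for c in CLASSES}
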