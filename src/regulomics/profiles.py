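"""Signal profiles around peak centres and dataset-dataset correlation.

Profile matrices hold the mean binned signal in fixed windows (default
±2 kb in 50 bp bins) anchored at peak centres, rows sorted by descending
total signal — the layout of a ChIP heat map. Occupancy correlation
turns each dataset into a binary occupancy vector over the merged peak
universe, takes pairwise Pearson r, and orders datasets by
average-linkage hierarchical clustering on 1 − r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import PeakSet, merge, overlap_any
from .tracks import SignalTrack


class ProfileError(ValueError):
    pass


@dataclass
class ProfileMatrix:
    values: np.ndarray          # peaks × bins
    peak_names: list[str]       # row order (descending row sum)
    bin_width: int
    flank: int
    edge_flagged: list[str]     # peaks padded with background at a chrom edge

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame   # symmetric dataset × dataset Pearson r
    order: list[str]       # leaf order from hierarchical clustering
    linkage: np.ndarray


def profile_matrix(
    peaks: PeakSet, track: SignalTrack, flank: int = 2000, bin_width: int = 50
) -> ProfileMatrix:
    """Per-peak signal in ``2*flank/bin_width`` bins centred on the peak.

    Windows truncated by a chromosome end are padded with the genome
    median and the peak is flagged. Rows are sorted by descending row sum
    (heat-map convention).
    """
    if flank % bin_width:
        raise ProfileError("flank must be a multiple of bin_width")
    if track.bin_width != bin_width:
        raise ProfileError(
            f"track bin width {track.bin_width} != requested {bin_width}"
        )
    n_bins = 2 * flank // bin_width
    centres = peaks.centres()
    bg = track.genome_median()
    rows, names, flagged = [], [], []
    for k, row in enumerate(peaks.intervals.itertuples(index=False)):
        v = track.values[row.chrom]
        cb = int(centres[k]) // bin_width
        b0, b1 = cb - n_bins // 2, cb + n_bins // 2
        window = np.full(n_bins, bg)
        lo, hi = max(b0, 0), min(b1, len(v))
        if lo < hi:
            window[lo - b0 : hi - b0] = v[lo:hi]
        if b0 < 0 or b1 > len(v):
            flagged.append(row.name)
        rows.append(window)
        names.append(row.name)
    values = np.asarray(rows, dtype=float).reshape(len(rows), n_bins)
    order = np.argsort(-values.sum(axis=1), kind="mergesort")
    return ProfileMatrix(
        values=values[order],
        peak_names=[names[i] for i in order],
        bin_width=bin_width,
        flank=flank,
        edge_flagged=flagged,
    )


def metaprofile(m: ProfileMatrix) -> np.ndarray:
    """Column means of the profile matrix (the curve above a heat map)."""
    if m.values.shape[0] == 0:
        raise ProfileError("empty profile matrix has no metaprofile")
    return m.values.mean(axis=0)


def occupancy_correlation(
    datasets: dict[str, PeakSet], universe: PeakSet | None = None
) -> CorrelationResult:
    """Pearson correlation of binary occupancy over the peak universe.

    The universe defaults to the overlap-merged union of all datasets'
    peaks. Average-linkage clustering on 1 − r supplies the leaf order
    (scipy's recursive ordering, smaller subtree first).
    """
    if len(datasets) < 2:
        raise ProfileError("need >= 2 datasets to correlate")
    names = list(datasets)
    if universe is None:
        df = pd.concat([ps.intervals for ps in datasets.values()], ignore_index=True)
        universe = PeakSet("universe", "merged", merge(df))
    occ = np.stack([overlap_any(universe, datasets[n]).astype(float) for n in names])
    for k, n in enumerate(names):
        if occ[k].std() == 0:
            raise ProfileError(
                f"dataset {n!r} has constant occupancy over the universe; r undefined"
            )
    r = np.corrcoef(occ)
    mat = pd.DataFrame(r, index=names, columns=names)
    dist = squareform(np.clip(1.0 - r, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    return CorrelationResult(matrix=mat, order=[names[i] for i in leaves], linkage=link)


def binned_signal_correlation(tracks: dict[str, SignalTrack]) -> CorrelationResult:
    """Alternative correlation mode: Pearson r of genome-wide binned
    signal vectors (rather than peak occupancy)."""
    if len(tracks) < 2:
        raise ProfileError("need >= 2 tracks to correlate")
    names = list(tracks)
    vecs = np.stack(
        [np.concatenate([tracks[n].values[c] for c in sorted(tracks[n].values)]) for n in names]
    )
    r = np.corrcoef(vecs)
    mat = pd.DataFrame(r, index=names, columns=names)
    dist = squareform(np.clip(1.0 - r, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    return CorrelationResult(matrix=mat, order=[names[i] for i in leaves], linkage=link)
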