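"""Binned genome-wide signal tracks.

A SignalTrack holds one float vector of fixed-width bins per chromosome —
the substrate of peak classification and profile heat maps. Tracks are
assumed depth-normalised between libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


class TrackError(ValueError):
    pass


@dataclass
class SignalTrack:
    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], bin_width: int) -> "SignalTrack":
        vals = {}
        for chrom, size in chrom_sizes.items():
            if size % bin_width:
                raise TrackError(f"bin width {bin_width} does not divide length of {chrom}")
            vals[chrom] = np.zeros(size // bin_width)
        return cls(bin_width=bin_width, values=vals)

    def chroms(self) -> list[str]:
        return list(self.values)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) * self.bin_width for c, v in self.values.items()}

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean binned signal over [start, end); partial edge bins count
        with their full bin value (bins are the unit of resolution)."""
        if chrom not in self.values:
            raise TrackError(f"chromosome {chrom!r} not covered by track")
        v = self.values[chrom]
        b0 = start // self.bin_width
        b1 = -(-end // self.bin_width)  # ceil
        if b0 < 0 or b1 > len(v):
            raise TrackError(f"window [{start},{end}) outside extent of {chrom}")
        return float(v[b0:b1].mean())

    def genome_median(self) -> float:
        return float(np.median(np.concatenate(list(self.values.values()))))

    def total_bins(self) -> int:
        return sum(len(v) for v in self.values.values())
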