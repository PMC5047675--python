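"""File I/O for the formats the pipeline consumes and emits.

BED6 and bedGraph are tab-separated and go through pandas; GFF3 is read
with gffutils (1-based closed coordinates converted to 0-based half-open
on the way in). All tables round-trip losslessly on the fields the
pipeline uses.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, PeakSet, ValidationError


class ParseError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------- BED6


def read_bed(path: str, factor: str | None = None, replicate: str = "r1") -> PeakSet:
    """Read a BED file (3-6 columns) into a PeakSet."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    if factor is None:
        factor = os.path.splitext(os.path.basename(path))[0]
    return PeakSet(factor, replicate, df)


def write_bed(ps: PeakSet, path: str) -> None:
    df = ps.intervals.copy()
    df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------- GFF3


def read_gff3(path: str) -> GeneAnnotation:
    """Read gene records from a GFF3 file.

    Uses gffutils with an in-memory database. Exon lengths are summed per
    gene where exon features are present; otherwise the gene span is used.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted exceptions on bad input
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from exc
    genes = []
    for g in db.features_of_type("gene"):
        exon_bp = sum(e.end - e.start + 1 for e in db.children(g, featuretype="exon"))
        if exon_bp == 0:
            exon_bp = g.end - g.start + 1
        gene_id = g.attributes.get("ID", [g.id])[0]
        # GFF3 is 1-based closed; convert to 0-based half-open
        genes.append((gene_id, g.seqid, g.start - 1, g.end, g.strand, exon_bp))
    if not genes:
        raise ParseError(f"{path}: no gene features found")
    df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand", "exon_bp"])
    return GeneAnnotation(df)


def write_gff3(ann: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes.itertuples(index=False):
            attrs = f"ID={g.gene_id};exon_bp={g.exon_bp}"
            fh.write(
                f"{g.chrom}\tregulomics\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ------------------------------------------------------------ bedGraph


def write_bedgraph(track: "SignalTrack", path: str) -> None:
    from .tracks import SignalTrack  # noqa: F401  (type only)

    with open(path, "w") as fh:
        for chrom in track.chroms():
            vals = track.values[chrom]
            bw = track.bin_width
            # run-length encode equal neighbouring bins
            start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[start]:
                    fh.write(f"{chrom}\t{start * bw}\t{i * bw}\t{vals[start]:g}\n")
                    start = i


def read_bedgraph(path: str, bin_width: int, chrom_sizes: Mapping[str, int]) -> "SignalTrack":
    from .tracks import SignalTrack

    track = SignalTrack.zeros(chrom_sizes, bin_width)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.start % bin_width or row.end % bin_width:
            raise ParseError(f"{path}: interval [{row.start},{row.end}) not aligned to {bin_width} bp bins")
        track.values[row.chrom][row.start // bin_width : row.end // bin_width] = row.value
    return track


# ------------------------------------------------------------- tables


def read_counts(counts_path: str, design_path: str):
    """Read a gene×sample count TSV plus its design TSV into a CountMatrix."""
    from .expression import CountMatrix

    tab = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = None
    if "gene_length" in tab.columns:
        lengths = tab.pop("gene_length")
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return CountMatrix(counts=tab, gene_lengths=lengths, design=design)


def write_counts(cm, counts_path: str, design_path: str) -> None:
    tab = cm.counts.copy()
    if cm.gene_lengths is not None:
        tab.insert(0, "gene_length", cm.gene_lengths)
    tab.to_csv(counts_path, sep="\t")
    cm.design.to_csv(design_path, sep="\t")
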