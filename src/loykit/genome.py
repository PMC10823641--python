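"""Toy genome model: chromosome lengths and 1 Mb bin definitions.

The package works on chromosome-level and 1 Mb bin-level count summaries,
so a full reference sequence is never needed — only relative chromosome
sizes. Lengths below are approximate GRCh38 assembly lengths in Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Approximate GRCh38 chromosome lengths in megabases.
AUTOSOME_MB: dict[str, int] = {
    "chr1": 248, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 63,
    "chr21": 47, "chr22": 51,
}
CHRX_MB = 155
CHRY_MB = 57

AUTOSOMES: tuple[str, ...] = tuple(AUTOSOME_MB)
ALL_CHROMS: tuple[str, ...] = AUTOSOMES + ("chrX", "chrY")


def chromosome_lengths(include_sex: bool = True) -> dict[str, int]:
    """Chromosome lengths in Mb for the toy genome."""
    lengths = dict(AUTOSOME_MB)
    if include_sex:
        lengths["chrX"] = CHRX_MB
        lengths["chrY"] = CHRY_MB
    return lengths


@dataclass
class GenomeBins:
    """Ordered 1 Mb genomic bins with GC content and blacklist flags.

    ``bins`` columns: chrom, start, end (0-based half-open, bp),
    gc_fraction in [0, 1], blacklist (bool). Bins are sorted by
    (chromosome order, start). Sex and mitochondrial chromosomes are
    excluded from CNV bin sets by construction.
    """

    bins: pd.DataFrame = field(repr=False)
    bin_size: int = 1_000_000

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc_fraction", "blacklist"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")
        bad_gc = ~self.bins["gc_fraction"].between(0, 1)
        if bad_gc.any():
            raise ValueError("gc_fraction outside [0, 1]")

    @property
    def retained(self) -> pd.DataFrame:
        """Bins surviving the blacklist filter."""
        return self.bins.loc[~self.bins["blacklist"]]

    @property
    def n_retained(self) -> int:
        return int((~self.bins["blacklist"]).sum())

    def chrom_slices(self) -> dict[str, np.ndarray]:
        """Positional indices of retained bins per chromosome, in order."""
        retained = self.bins.index[~self.bins["blacklist"]]
        pos = pd.Series(np.arange(len(retained)), index=retained)
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.bins.loc[retained].groupby("chrom", sort=False):
            out[str(chrom)] = pos.loc[sub.index].to_numpy()
        return out

    def to_bed(self, path) -> None:
        cols = self.bins[["chrom", "start", "end"]].copy()
        cols["name"] = [
            f"bin_{i}|gc={g:.3f}|bl={int(b)}"
            for i, (g, b) in enumerate(
                zip(self.bins["gc_fraction"], self.bins["blacklist"])
            )
        ]
        cols.to_csv(path, sep="\t", header=False, index=False)


def make_bins(
    lengths: dict[str, int] | None = None,
    bin_size: int = 1_000_000,
    gc_fraction: float | np.ndarray = 0.41,
    blacklist: np.ndarray | None = None,
) -> GenomeBins:
    """Tile autosomes into fixed-size bins.

    Parameters
    ----------
    lengths
        Chromosome lengths in Mb; defaults to the toy autosomes. Sex
        chromosomes, if present, are dropped (CNV calling is autosomal).
    gc_fraction
        Scalar applied to every bin, or an array with one value per bin.
    blacklist
        Boolean array marking bins excluded as highly repetitive.
    """
    if lengths is None:
        lengths = dict(AUTOSOME_MB)
    lengths = {c: l for c, l in lengths.items() if c not in ("chrX", "chrY", "chrM")}
    rows = []
    for chrom, mb in lengths.items():
        n = int(round(mb * 1_000_000 / bin_size))
        for i in range(n):
            rows.append((chrom, i * bin_size, (i + 1) * bin_size))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    gc = np.broadcast_to(np.asarray(gc_fraction, dtype=float), (len(df),)).copy()
    df["gc_fraction"] = gc
    if blacklist is None:
        blacklist = np.zeros(len(df), dtype=bool)
    df["blacklist"] = np.asarray(blacklist, dtype=bool)
    return GenomeBins(bins=df, bin_size=bin_size)
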