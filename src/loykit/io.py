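"""Plain-text on-disk formats: matrix-market counts, TSV sidecars, BED bins.

A cohort on disk is a directory per modality with ``counts.mtx`` (cells
x chromosomes, sparse matrix-market), ``cells.tsv`` (cell metadata) and
``chroms.tsv`` (column names); CNV bin matrices add a BED file of bin
definitions. Digital-PCR plates travel as CSV (see :mod:`loykit.dpcr`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .containers import CellCoverageTable, CnvBinMatrix, META_COLUMNS
from .genome import GenomeBins


def write_coverage_table(table: CellCoverageTable, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "counts.mtx", sparse.csr_matrix(table.counts.to_numpy()))
    meta = table.meta.copy()
    meta.insert(0, "cell_id", table.meta.index)
    meta.insert(2, "modality", table.modality)
    meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    pd.Series(table.counts.columns, name="chrom").to_csv(
        outdir / "chroms.tsv", sep="\t", index=False
    )


def read_coverage_table(indir) -> CellCoverageTable:
    indir = Path(indir)
    counts = np.asarray(sio.mmread(indir / "counts.mtx").todense(), dtype=np.int64)
    meta = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    chroms = pd.read_csv(indir / "chroms.tsv", sep="\t")["chrom"].tolist()
    modality = str(meta.pop("modality").iloc[0])
    return CellCoverageTable(
        modality=modality,
        counts=pd.DataFrame(counts, index=meta.index, columns=chroms),
        meta=meta[META_COLUMNS],
    )


def write_bin_matrix(mat: CnvBinMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "bin_counts.mtx", sparse.csr_matrix(mat.counts.to_numpy()))
    pd.Series(mat.counts.index, name="cell_id").to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )
    bed = mat.bins[["chrom", "start", "end"]].copy()
    bed["gc_fraction"] = mat.bins["gc_fraction"]
    bed.to_csv(outdir / "bins.bed", sep="\t", header=False, index=False)


def read_bin_matrix(indir) -> CnvBinMatrix:
    indir = Path(indir)
    counts = np.asarray(sio.mmread(indir / "bin_counts.mtx").todense(), dtype=np.int64)
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")["cell_id"]
    bins = pd.read_csv(
        indir / "bins.bed", sep="\t",
        names=["chrom", "start", "end", "gc_fraction"],
    )
    bins["blacklist"] = False
    return CnvBinMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(cells, name="cell_id")),
        bins=bins,
    )


def read_bed_bins(path) -> GenomeBins:
    """Bin definitions from a 4-column BED written by GenomeBins.to_bed."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "name"])
    gc, bl = [], []
    for name in df["name"]:
        fields = dict(kv.split("=") for kv in str(name).split("|")[1:])
        gc.append(float(fields.get("gc", 0.41)))
        bl.append(bool(int(fields.get("bl", 0))))
    out = df[["chrom", "start", "end"]].copy()
    out["gc_fraction"] = gc
    out["blacklist"] = bl
    size = int(out["end"].iloc[0] - out["start"].iloc[0])
    return GenomeBins(bins=out, bin_size=size)
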