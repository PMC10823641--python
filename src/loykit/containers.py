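"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["donor_id", "sex", "age", "cell_type", "disease"]
MODALITIES = ("RNA", "ATAC")
DISEASE_LEVELS = ("control", "AKI", "CKD")


@dataclass
class CellCoverageTable:
    """Per-cell, per-chromosome raw counts for one modality.

    ``counts`` is a cells x chromosomes integer DataFrame (index cell_id);
    for ATAC the entries are fragments falling in retained 1 Mb bins of
    each chromosome, for RNA they are transcript counts. ``meta`` is
    indexed by cell_id with columns donor_id, sex, age, cell_type,
    disease, aligned with ``counts``.
    """

    modality: str
    counts: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share an identical cell index")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate cell_id in coverage table")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise ValueError(f"meta missing columns: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> pd.Series:
        """Per-cell total count (sum over chromosomes)."""
        return self.counts.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    def subset(self, cell_ids) -> "CellCoverageTable":
        return CellCoverageTable(
            modality=self.modality,
            counts=self.counts.loc[cell_ids],
            meta=self.meta.loc[cell_ids],
        )

    def males(self) -> "CellCoverageTable":
        return self.subset(self.meta.index[self.meta["sex"] == "M"])


@dataclass
class CnvBinMatrix:
    """Per-cell autosomal 1 Mb bin counts with bin annotations.

    ``counts`` holds cells x retained-bins values (blacklisted bins are
    excluded up front); ``bins`` is the retained-bin annotation table
    (chrom, start, end, gc_fraction) aligned column-wise with ``counts``.
    """

    counts: pd.DataFrame = field(repr=False)
    bins: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.shape[1] != len(self.bins):
            raise ValueError("counts columns and bins rows disagree")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative bin counts")

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        pos = np.arange(len(self.bins))
        for chrom, sub in self.bins.reset_index(drop=True).groupby("chrom", sort=False):
            out[str(chrom)] = pos[sub.index.to_numpy()]
        return out
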