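"""Chromosome coverage preprocessing for LOY determination.

Raw per-cell chromosome counts are (1) filtered on per-modality depth,
(2) total-count normalized and log-transformed with a pseudocount,
(3) corrected across cell types by the ratio of the global to the
cell-type median, and (4) centered / scaled to unit variance within each
(donor, chromosome, modality) stratum. The scaled chrY values feed the
density-trough and mixture-model genotypers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CellCoverageTable

logger = logging.getLogger(__name__)

SCALED_COLUMNS = [
    "cell_id", "modality", "chrom", "v_norm", "v_corr", "z", "degenerate_flag",
]


class EmptyFilterResult(ValueError):
    """No cell survived QC filtering; carries diagnostic counts."""

    def __init__(self, n_input: int, threshold: int, modality: str):
        self.n_input = n_input
        super().__init__(
            f"no {modality} cell passed the >= {threshold} count filter "
            f"({n_input} cells in input)"
        )


def filter_cells(
    table: CellCoverageTable,
    min_atac_fragments: int = 10_000,
    min_rna_counts: int = 1_000,
) -> CellCoverageTable:
    """Depth filter: keep cells with at least the modality threshold.

    Thresholds are inclusive ("at least"), and filtering is sex-agnostic.
    Raises :class:`EmptyFilterResult` if nothing survives.
    """
    if min_atac_fragments < 0 or min_rna_counts < 0:
        raise ValueError("thresholds must be >= 0")
    thr = min_atac_fragments if table.modality == "ATAC" else min_rna_counts
    keep = table.total >= thr
    if not keep.any():
        raise EmptyFilterResult(table.n_cells, thr, table.modality)
    return table.subset(table.counts.index[keep])


def filter_multiome(
    rna: CellCoverageTable,
    atac: CellCoverageTable,
    min_atac_fragments: int = 10_000,
    min_rna_counts: int = 1_000,
) -> tuple[CellCoverageTable, CellCoverageTable]:
    """Joint filter for multiome cohorts: both thresholds must hold."""
    rna_f = filter_cells(rna, min_atac_fragments, min_rna_counts)
    atac_f = filter_cells(atac, min_atac_fragments, min_rna_counts)
    common = rna_f.counts.index.intersection(atac_f.counts.index)
    if len(common) == 0:
        raise EmptyFilterResult(rna.n_cells, min_rna_counts, "multiome")
    return rna_f.subset(common), atac_f.subset(common)


@dataclass
class CorrectionFactors:
    """Per (chromosome, cell type) median-ratio correction factors."""

    table: pd.DataFrame  # columns: chrom, cell_type, global_median, ct_median, factor

    def factor(self, chrom: str, cell_type: str) -> float:
        sub = self.table[
            (self.table["chrom"] == chrom) & (self.table["cell_type"] == cell_type)
        ]
        return float(sub["factor"].iloc[0]) if len(sub) else 1.0


class ChromosomeCoverageScaler(BaseEstimator, TransformerMixin):
    """Normalize, cell-type-correct and donor-scale chromosome coverage.

    ``fit`` learns the per-(chromosome, cell type) median-ratio
    correction factors; ``transform`` emits a long-format table with
    ``v_norm`` (log1p of the count fraction), ``v_corr`` (median-ratio
    corrected) and ``z`` (standardized within donor x chromosome x
    modality).

    Parameters
    ----------
    male_only_medians
        Compute the correction medians over male cells only (the default;
        females carry no chrY signal). Falls back to all cells when the
        input has no males.
    """

    def __init__(self, male_only_medians: bool = True):
        self.male_only_medians = male_only_medians

    def fit(self, X: CellCoverageTable, y=None) -> "ChromosomeCoverageScaler":
        vn = _v_norm(X)
        meta = X.meta
        if self.male_only_medians and (meta["sex"] == "M").any():
            ref_cells = meta.index[meta["sex"] == "M"]
        else:
            if self.male_only_medians:
                warnings.warn("no male cells; correction medians use all cells")
            ref_cells = meta.index
        vn_ref = vn.loc[ref_cells]
        ct_ref = meta.loc[ref_cells, "cell_type"]
        rows = []
        for chrom in vn.columns:
            global_med = float(vn_ref[chrom].median())
            ct_med = vn_ref[chrom].groupby(ct_ref).median()
            for ct, m in ct_med.items():
                if m == 0.0 and global_med != 0.0:
                    logger.warning(
                        "cell-type median is 0 for %s/%s with nonzero global "
                        "median; correction factor set to 1", chrom, ct,
                    )
                    f = 1.0
                elif m == 0.0:
                    f = 1.0
                else:
                    f = global_med / float(m)
                rows.append((chrom, ct, global_med, float(m), f))
        self.correction_ = CorrectionFactors(
            pd.DataFrame(
                rows,
                columns=["chrom", "cell_type", "global_median", "ct_median", "factor"],
            )
        )
        self.modality_ = X.modality
        return self

    def transform(self, X: CellCoverageTable) -> pd.DataFrame:
        if not hasattr(self, "correction_"):
            raise RuntimeError("scaler is not fitted")
        vn = _v_norm(X)
        long = vn.stack().rename("v_norm").reset_index()
        long.columns = ["cell_id", "chrom", "v_norm"]
        long["modality"] = X.modality
        long = long.merge(
            X.meta[["donor_id", "cell_type"]],
            left_on="cell_id", right_index=True, how="left",
        )
        fac = self.correction_.table[["chrom", "cell_type", "factor"]]
        long = long.merge(fac, on=["chrom", "cell_type"], how="left")
        long["factor"] = long["factor"].fillna(1.0)
        long["v_corr"] = long["v_norm"] * long["factor"]
        long = scale_within_donor(long)
        return long[
            ["cell_id", "donor_id", "cell_type", "modality", "chrom",
             "v_norm", "v_corr", "z", "degenerate_flag"]
        ]


def _v_norm(table: CellCoverageTable) -> pd.DataFrame:
    """log1p of the per-chromosome count fraction; requires total > 0."""
    total = table.total
    if (total <= 0).any():
        raise ValueError("every cell must have total count > 0")
    return np.log1p(table.counts.div(total, axis=0))


def normalize_and_correct(
    table: CellCoverageTable, male_only_medians: bool = True
) -> tuple[pd.DataFrame, CorrectionFactors]:
    """Functional wrapper: fit + transform on the same cohort.

    Returns the long-format scaled table and the correction factors.
    """
    scaler = ChromosomeCoverageScaler(male_only_medians=male_only_medians)
    out = scaler.fit(table).transform(table)
    return out, scaler.correction_


def scale_within_donor(long: pd.DataFrame) -> pd.DataFrame:
    """Standardize ``v_corr`` within (donor, chromosome, modality).

    Sample sd uses the n-1 denominator. Strata with a single cell or
    zero spread get z = 0 and ``degenerate_flag`` set.
    """
    long = long.copy()
    grp = long.groupby(["donor_id", "chrom", "modality"])["v_corr"]
    mean = grp.transform("mean")
    sd = grp.transform("std", ddof=1)
    degenerate = sd.isna() | (sd == 0.0)
    z = (long["v_corr"] - mean) / sd.where(~degenerate, 1.0)
    long["z"] = z.where(~degenerate, 0.0)
    long["degenerate_flag"] = degenerate.to_numpy()
    return long


def chry_z(scaled: pd.DataFrame) -> pd.DataFrame:
    """Per-cell chrY rows of a scaled long table."""
    return scaled[scaled["chrom"] == "chrY"].set_index("cell_id")


def write_scaled(scaled: pd.DataFrame, path) -> None:
    scaled[SCALED_COLUMNS + ["donor_id", "cell_type"]].to_csv(
        path, sep="\t", index=False
    )
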