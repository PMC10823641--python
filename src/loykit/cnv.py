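"""Single-cell autosomal CNV calling from 1 Mb binned fragment counts.

A deliberately lean caller: per-cell bin counts are GC-corrected with a
decile-stratum factor, converted to ratios against a per-bin population
mean of count fractions, segmented per chromosome by least-squares
binary segmentation with a BIC-style penalty, and each segment is called
gain / neutral / loss by fixed fold thresholds. The per-cell CNV burden
is the proportion of retained bins in a non-neutral state — the summary
the downstream association model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .containers import CnvBinMatrix

logger = logging.getLogger(__name__)

LOSS, NEUTRAL, GAIN = -1, 0, 1


def gc_correct(counts: np.ndarray, gc: np.ndarray, n_strata: int = 10) -> np.ndarray:
    """Remove per-cell GC bias with decile-stratum factors.

    Bins are grouped into GC deciles; within each cell, counts in a
    decile are rescaled by (cell's overall mean bin count) / (cell's
    mean count in that decile). The construction preserves each cell's
    total exactly (up to empty strata, which get factor 1).
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    edges = np.quantile(gc, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    if len(edges) < 3:  # effectively a single stratum: nothing to correct
        return counts.copy()
    stratum = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    overall = counts.mean(axis=1, keepdims=True)
    corrected = counts.copy()
    for s in range(len(edges) - 1):
        mask = stratum == s
        if not mask.any():
            continue
        smean = counts[:, mask].mean(axis=1, keepdims=True)
        zero = smean[:, 0] == 0
        if zero.any():
            logger.warning(
                "GC stratum %d has zero mean count in %d cells; factor 1",
                s, int(zero.sum()),
            )
        factor = np.where(zero[:, None], 1.0, overall / np.where(smean == 0, 1.0, smean))
        corrected[:, mask] = counts[:, mask] * factor
    return corrected


def _best_split(prefix: np.ndarray, prefix2: np.ndarray, lo: int, hi: int, min_size: int):
    """Best single change point in x[lo:hi] by least squares.

    ``prefix``/``prefix2`` are cumulative sums of x and x^2 with a
    leading zero. Returns (gain_in_sse, split_index) or (0, -1).
    """
    n = hi - lo
    if n < 2 * min_size:
        return 0.0, -1
    total = prefix[hi] - prefix[lo]
    sse_full = (prefix2[hi] - prefix2[lo]) - total * total / n
    ks = np.arange(lo + min_size, hi - min_size + 1)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = prefix[ks] - prefix[lo]
    right_sum = total - left_sum
    sse_split = (
        (prefix2[hi] - prefix2[lo])
        - left_sum * left_sum / left_n
        - right_sum * right_sum / right_n
    )
    j = int(np.argmin(sse_split))
    return float(sse_full - sse_split[j]), int(ks[j])


def binary_segmentation(
    x: np.ndarray, penalty: float, min_size: int = 10
) -> list[int]:
    """Change points of a 1-D series by recursive binary segmentation.

    A split is accepted when it reduces the residual sum of squares by
    more than ``penalty``. Returns sorted interior breakpoints.
    """
    x = np.asarray(x, dtype=float)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    breaks: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        gain, k = _best_split(prefix, prefix2, lo, hi, min_size)
        if k >= 0 and gain > penalty:
            breaks.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(breaks)


@dataclass
class CnvCallSet:
    """Tri-state per-bin calls plus the per-cell burden statistic."""

    states: pd.DataFrame  # cells x retained bins, values in {-1, 0, 1}
    burden: pd.Series  # per cell, in [0, 1]
    segments: dict  # cell_id -> list of (chrom, start_bin, end_bin, mean_ratio, state)


class CnvCaller(BaseEstimator):
    """Population-mean ratio CNV caller on 1 Mb bins.

    ``fit`` learns the per-bin population mean of depth-normalized,
    GC-corrected counts over the analyzed cells (the spec'd per-library
    analysis unit); ``predict`` segments each cell's ratio series per
    chromosome and calls each segment gain (mean ratio >=
    ``gain_threshold``), loss (<= ``loss_threshold``) or neutral.

    The segmentation penalty is BIC-style: sigma_hat^2 * log(n) per
    change point, with sigma_hat estimated robustly per cell from first
    differences of the ratio series.
    """

    def __init__(
        self,
        gain_threshold: float = 1.2,
        loss_threshold: float = 0.8,
        min_segment_bins: int = 10,
        n_gc_strata: int = 10,
    ):
        self.gain_threshold = gain_threshold
        self.loss_threshold = loss_threshold
        self.min_segment_bins = min_segment_bins
        self.n_gc_strata = n_gc_strata

    def fit(self, X: CnvBinMatrix, y=None) -> "CnvCaller":
        counts = X.counts.to_numpy(dtype=float)
        corrected = gc_correct(
            counts, X.bins["gc_fraction"].to_numpy(), self.n_gc_strata
        )
        totals = corrected.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("cells with zero total bin counts")
        fractions = corrected / totals
        self.population_mean_ = fractions.mean(axis=0)
        if np.any(self.population_mean_ <= 0):
            raise ValueError("population mean is zero for some retained bins")
        self.bins_ = X.bins.reset_index(drop=True)
        self.chrom_slices_ = X.chrom_slices()
        return self

    def predict(self, X: CnvBinMatrix) -> CnvCallSet:
        if not hasattr(self, "population_mean_"):
            raise RuntimeError("caller is not fitted")
        counts = X.counts.to_numpy(dtype=float)
        corrected = gc_correct(
            counts, X.bins["gc_fraction"].to_numpy(), self.n_gc_strata
        )
        fractions = corrected / corrected.sum(axis=1, keepdims=True)
        ratios = fractions / self.population_mean_[None, :]
        n_cells, n_bins = ratios.shape
        states = np.zeros((n_cells, n_bins), dtype=np.int8)
        segments: dict = {}
        cell_ids = list(X.counts.index)
        for i in range(n_cells):
            r = ratios[i]
            diffs = np.diff(r)
            mad = float(np.median(np.abs(diffs)))
            sigma2 = (mad / (0.6745 * np.sqrt(2.0))) ** 2 if mad > 0 else float(np.var(r))
            segs = []
            for chrom, idx in self.chrom_slices_.items():
                series = r[idx]
                if len(series) < self.min_segment_bins:
                    breaks: list[int] = []
                else:
                    penalty = sigma2 * np.log(len(series))
                    breaks = binary_segmentation(
                        series, penalty, self.min_segment_bins
                    )
                bounds = [0] + breaks + [len(series)]
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    m = float(series[lo:hi].mean())
                    if m >= self.gain_threshold:
                        state = GAIN
                    elif m <= self.loss_threshold:
                        state = LOSS
                    else:
                        state = NEUTRAL
                    states[i, idx[lo:hi]] = state
                    segs.append((chrom, int(lo), int(hi), m, state))
            segments[cell_ids[i]] = segs
        burden = (states != NEUTRAL).mean(axis=1)
        return CnvCallSet(
            states=pd.DataFrame(states, index=X.counts.index),
            burden=pd.Series(burden, index=X.counts.index, name="burden"),
            segments=segments,
        )

    def fit_predict(self, X: CnvBinMatrix) -> CnvCallSet:
        return self.fit(X).predict(X)


def segment_and_call(
    mat: CnvBinMatrix,
    gain_threshold: float = 1.2,
    loss_threshold: float = 0.8,
    min_segment_bins: int = 10,
) -> CnvCallSet:
    """Fit the population mean on ``mat`` and call CNV states."""
    return CnvCaller(
        gain_threshold=gain_threshold,
        loss_threshold=loss_threshold,
        min_segment_bins=min_segment_bins,
    ).fit_predict(mat)


def burden_by_genotype(
    burden: pd.Series,
    genotypes: pd.DataFrame,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-cell-type LOY vs XY CNV-burden comparison.

    ``genotypes`` is indexed by cell_id with columns ``genotype``
    ({LOY, XY}) and ``cell_type``. Reports median burden per genotype,
    fold change (median LOY / median XY; mean ratio with a warning when
    the XY median is 0), a two-sided Wilcoxon rank-sum p-value, and
    Bonferroni adjustment over the tested cell types. Cell types with
    fewer than ``min_cells`` cells in either genotype are excluded.
    """
    df = genotypes.join(burden.rename("burden"), how="inner")
    rows = []
    for ct, sub in df.groupby("cell_type"):
        b_loy = sub.loc[sub["genotype"] == "LOY", "burden"].to_numpy()
        b_xy = sub.loc[sub["genotype"] == "XY", "burden"].to_numpy()
        if len(b_loy) < min_cells or len(b_xy) < min_cells:
            logger.info("cell type %s excluded (<%d cells per genotype)", ct, min_cells)
            continue
        med_loy, med_xy = float(np.median(b_loy)), float(np.median(b_xy))
        if med_xy > 0:
            fold = med_loy / med_xy
        else:
            logger.warning("XY median burden is 0 for %s; using mean ratio", ct)
            fold = float(np.mean(b_loy) / np.mean(b_xy)) if np.mean(b_xy) > 0 else np.nan
        if np.all(b_loy == b_loy[0]) and np.all(b_xy == b_xy[0]) and b_loy[0] == b_xy[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(b_loy, b_xy, alternative="two-sided").pvalue)
        rows.append((ct, len(b_loy), len(b_xy), med_loy, med_xy, fold, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "cell_type", "n_loy", "n_xy", "median_loy", "median_xy",
            "fold_change", "p_value",
        ],
    )
    out["p_adj"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni adjustment, capped at 1."""
    return min(p * n_tests, 1.0)
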