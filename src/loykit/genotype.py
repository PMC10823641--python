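"""Per-cell LOY/XY genotyping.

Two routes, mirroring single-modality and multiome data:

* :class:`DensityTroughClassifier` — a Gaussian kernel density is fitted
  to the scaled chrY coverage; in a male cohort with LOY the density is
  bimodal and the trough between the two highest modes is the genotyping
  threshold (cells strictly below it are LOY).
* :class:`SemiSupervisedSphericalGMM` — a two-state Gaussian mixture on
  the joint (z_RNA, z_ATAC) plane with spherical, component-specific
  variances. Cells at the origin (no chrY coverage in either modality)
  are pre-labeled LOY, cells above the median in either modality are
  pre-labeled XY, and EM updates only the unlabeled cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import iqr
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

XY, LOY = 0, 1
UNLABELED = -1


class NoTroughError(RuntimeError):
    """Density is unimodal: there is no between-mode trough to threshold on."""


def nrd0_bandwidth(x: np.ndarray) -> float:
    """R's default kernel bandwidth rule (Silverman's rule of thumb):
    0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    spread_iqr = float(iqr(x)) / 1.349
    spread = min(sd, spread_iqr) if spread_iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(float(np.mean(x))), 1.0)
    return 0.9 * spread * len(x) ** (-0.2)


class DensityTroughClassifier(BaseEstimator, ClassifierMixin):
    """Bimodal-density thresholding of scaled chrY coverage.

    ``fit(z)`` estimates a Gaussian-kernel density on a regular grid
    spanning [min - 3h, max + 3h], locates the modes (local maxima at
    least ``min_mode_rel_height`` of the peak), and sets the threshold
    at the density minimum between the two highest modes. ``predict``
    labels cells 1 (LOY) when z is strictly below the threshold, 0 (XY)
    otherwise; ties go to XY.

    Attributes
    ----------
    threshold_ : float        genotyping threshold (z units)
    status_ : str             "ok" or "no_trough"
    grid_, density_ : arrays  density diagnostics (512 points)
    bandwidth_ : float        kernel bandwidth used
    n_modes_ : int            number of detected modes
    """

    def __init__(
        self,
        grid_size: int = 512,
        min_cells: int = 50,
        min_mode_rel_height: float = 0.01,
        min_mode_points: float = 5.0,
    ):
        self.grid_size = grid_size
        self.min_cells = min_cells
        self.min_mode_rel_height = min_mode_rel_height
        self.min_mode_points = min_mode_points

    def fit(self, X, y=None) -> "DensityTroughClassifier":
        z = np.asarray(X, dtype=float).ravel()
        if len(z) < self.min_cells:
            raise ValueError(
                f"need >= {self.min_cells} cells for density estimation, got {len(z)}"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite coverage values")
        h = nrd0_bandwidth(z)
        grid = np.linspace(z.min() - 3 * h, z.max() + 3 * h, self.grid_size)
        self.grid_ = grid
        self.density_ = _gaussian_kde(z, grid, h)
        self.bandwidth_ = h
        modes = _local_maxima(self.density_)
        peak = self.density_.max()
        # a mode must clear both a relative height floor and the height a
        # handful of isolated points would produce (tail-ripple guard)
        point_height = 1.0 / (len(z) * h * np.sqrt(2 * np.pi))
        floor = max(
            self.min_mode_rel_height * peak, self.min_mode_points * point_height
        )
        modes = [m for m in modes if self.density_[m] >= floor]
        self.n_modes_ = len(modes)
        if len(modes) < 2:
            self.status_ = "no_trough"
            self.threshold_ = np.nan
            self.modes_ = np.array([grid[m] for m in modes])
            return self
        top2 = sorted(sorted(modes, key=lambda m: self.density_[m])[-2:])
        lo, hi = top2
        trough = lo + int(np.argmin(self.density_[lo : hi + 1]))
        self.threshold_ = float(grid[trough])
        self.modes_ = np.array([grid[lo], grid[hi]])
        self.status_ = "ok"
        return self

    def predict(self, X) -> np.ndarray:
        if self.status_ != "ok":
            raise NoTroughError(
                "density is unimodal (no_trough); no genotyping threshold"
            )
        z = np.asarray(X, dtype=float).ravel()
        return (z < self.threshold_).astype(int)


def _gaussian_kde(x: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Gaussian KDE evaluated on a grid, chunked over data points."""
    dens = np.zeros_like(grid)
    norm = 1.0 / (len(x) * h * np.sqrt(2 * np.pi))
    for start in range(0, len(x), 4096):
        chunk = x[start : start + 4096]
        u = (grid[:, None] - chunk[None, :]) / h
        dens += np.exp(-0.5 * u * u).sum(axis=1)
    return dens * norm


def _local_maxima(d: np.ndarray) -> list[int]:
    """Interior local maxima (strict on the left, non-strict right to
    tolerate flat tops)."""
    out = []
    i = 1
    n = len(d)
    while i < n - 1:
        if d[i] > d[i - 1]:
            j = i
            while j < n - 1 and d[j + 1] == d[j]:
                j += 1
            if j < n - 1 and d[j + 1] < d[j]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def estimate_density_threshold(
    z_values, grid_size: int = 512, min_cells: int = 50
) -> DensityTroughClassifier:
    """Fit the KDE trough threshold on scaled chrY coverage values."""
    return DensityTroughClassifier(grid_size=grid_size, min_cells=min_cells).fit(
        z_values
    )


def call_unimodal(
    chry: pd.DataFrame,
    clf: DensityTroughClassifier,
    method: str | None = None,
) -> pd.DataFrame:
    """Threshold genotyping of male cells from scaled chrY coverage.

    ``chry`` is indexed by cell_id with columns ``z``, ``donor_id``, and
    ``modality``. Returns a call set with genotype, posterior (1/0 for
    threshold calls) and threshold provenance.
    """
    if clf.status_ != "ok":
        raise NoTroughError("no_trough: refuse to call genotypes")
    labels = clf.predict(chry["z"].to_numpy())
    modality = chry["modality"].iloc[0] if "modality" in chry else "NA"
    return pd.DataFrame(
        {
            "cell_id": chry.index,
            "donor_id": chry.get("donor_id", pd.Series("NA", index=chry.index)).to_numpy(),
            "method": method or f"{modality.lower()}_trough",
            "genotype": np.where(labels == LOY, "LOY", "XY"),
            "posterior_loy": labels.astype(float),
            "threshold": clf.threshold_,
        }
    )


def loy_proportions(calls: pd.DataFrame) -> tuple[float, pd.Series]:
    """Overall and per-donor proportion of LOY calls."""
    is_loy = calls["genotype"] == "LOY"
    per_donor = is_loy.groupby(calls["donor_id"]).mean()
    return float(is_loy.mean()), per_donor


def init_joint_labels(
    raw_y_rna: np.ndarray,
    raw_y_atac: np.ndarray,
    z_rna: np.ndarray,
    z_atac: np.ndarray,
) -> np.ndarray:
    """Initial partial labels for the joint mixture.

    Cells with zero raw chrY counts in BOTH modalities are labeled LOY
    (the origin); cells with above-median scaled coverage in EITHER
    modality are labeled XY; the rest are unlabeled. A cell matching both
    rules is pathological and keeps the LOY (origin) label.
    """
    raw_y_rna = np.asarray(raw_y_rna)
    raw_y_atac = np.asarray(raw_y_atac)
    z_rna = np.asarray(z_rna, dtype=float)
    z_atac = np.asarray(z_atac, dtype=float)
    origin = (raw_y_rna == 0) & (raw_y_atac == 0)
    above = (z_rna > np.median(z_rna)) | (z_atac > np.median(z_atac))
    n_conflict = int((origin & above).sum())
    if n_conflict:
        logger.warning(
            "%d cells match both the origin (LOY) and above-median (XY) "
            "rules; origin takes precedence", n_conflict,
        )
    y = np.full(len(z_rna), UNLABELED, dtype=int)
    y[above] = XY
    y[origin] = LOY
    return y


class SemiSupervisedSphericalGMM(BaseEstimator):
    """Two-state semi-supervised Gaussian mixture, spherical varying volume.

    Component covariances are sigma_k^2 * I (isotropic, component-specific
    scalar variance). Labeled cells (y in {0, 1}) have their
    responsibilities fixed at the label throughout EM; unlabeled cells
    (y = -1) get soft responsibilities each E-step. Parameters are
    initialized from the labeled cells' sample statistics. Component 1
    is LOY, component 0 is XY.

    With ``labels_as_init_only=True`` the labels seed the initialization
    but are re-estimated like any other cell.
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 500,
        labels_as_init_only: bool = False,
        var_floor: float = 1e-8,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.labels_as_init_only = labels_as_init_only
        self.var_floor = var_floor

    def fit(self, X, y) -> "SemiSupervisedSphericalGMM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (cells x modalities)")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite coordinates")
        n, d = X.shape
        for k, name in ((XY, "XY"), (LOY, "LOY")):
            if not np.any(y == k):
                raise ValueError(f"no labeled {name} cells: cannot initialize")

        resp = np.zeros((n, 2))
        labeled = y != UNLABELED
        resp[labeled, y[labeled]] = 1.0

        # parameters initialized from the labeled cells' sample statistics
        means, variances, weights = self._m_step(X[labeled], resp[labeled], d)
        free = ~labeled if not self.labels_as_init_only else np.ones(n, bool)
        fixed = ~free
        ll_trace = []
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            log_prob = self._log_prob(X, means, variances, weights, d)
            # E-step on free cells only; labeled responsibilities stay fixed
            log_norm = logsumexp(log_prob, axis=1)
            resp[free] = np.exp(log_prob[free] - log_norm[free, None])
            ll = float(log_norm[free].sum())
            if fixed.any():
                ll += float(log_prob[fixed, y[fixed]].sum())
            ll_trace.append(ll)
            means, variances, weights = self._m_step(X, resp, d)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= self.tol * abs(prev_ll):
                self.converged_ = True
                prev_ll = ll
                break
            prev_ll = ll
        self.means_ = means
        self.variances_ = variances
        self.weights_ = weights
        self.responsibilities_ = resp
        self.ll_trace_ = np.asarray(ll_trace)
        self.lower_bound_ = prev_ll
        self.n_iter_ = len(ll_trace)
        return self

    def _m_step(self, X, resp, d):
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            raise RuntimeError("a mixture component lost all its weight")
        weights = nk / len(X)
        means = (resp.T @ X) / nk[:, None]
        variances = np.empty(2)
        for k in range(2):
            sq = ((X - means[k]) ** 2).sum(axis=1)
            variances[k] = float((resp[:, k] * sq).sum() / (d * nk[k]))
        if np.any(variances < self.var_floor):
            k = int(np.argmin(variances))
            name = "LOY" if k == LOY else "XY"
            raise RuntimeError(
                f"degenerate variance in component {name}: "
                f"{variances[k]:.3e} < floor {self.var_floor:.0e}"
            )
        return means, variances, weights

    @staticmethod
    def _log_prob(X, means, variances, weights, d):
        log_prob = np.empty((len(X), 2))
        for k in range(2):
            sq = ((X - means[k]) ** 2).sum(axis=1)
            log_prob[:, k] = (
                np.log(weights[k])
                - 0.5 * d * np.log(2 * np.pi * variances[k])
                - 0.5 * sq / variances[k]
            )
        return log_prob

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        log_prob = self._log_prob(X, self.means_, self.variances_, self.weights_, X.shape[1])
        return np.exp(log_prob - logsumexp(log_prob, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def fit_joint_gmm(
    points: np.ndarray,
    labels: np.ndarray,
    cell_ids=None,
    donor_ids=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    labels_as_init_only: bool = False,
) -> tuple[SemiSupervisedSphericalGMM, pd.DataFrame]:
    """Fit the joint two-modality mixture and emit a call set.

    Labeled cells keep their labels in the output (their responsibilities
    are fixed); unlabeled cells get argmax-responsibility genotypes with
    the LOY posterior recorded.
    """
    model = SemiSupervisedSphericalGMM(
        tol=tol, max_iter=max_iter, labels_as_init_only=labels_as_init_only
    ).fit(points, labels)
    post = model.responsibilities_[:, LOY]
    geno = np.where(post >= 0.5, "LOY", "XY")
    n = len(points)
    calls = pd.DataFrame(
        {
            "cell_id": cell_ids if cell_ids is not None else np.arange(n),
            "donor_id": donor_ids if donor_ids is not None else "NA",
            "method": "joint_gmm",
            "genotype": geno,
            "posterior_loy": post,
            "threshold": np.nan,
        }
    )
    return model, calls


def write_density(clf: DensityTroughClassifier, path) -> None:
    """Density diagnostics (grid, density) as TSV for plotting."""
    pd.DataFrame({"grid": clf.grid_, "density": clf.density_}).to_csv(
        path, sep="\t", index=False
    )
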