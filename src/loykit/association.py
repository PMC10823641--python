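"""Mixed-effects logistic modeling of LOY risk.

The core model is logistic regression of per-cell genotype (LOY = 1) on
cell type, age, CNV burden and disease, with a Gaussian random intercept
per donor:

    logit P(LOY_i) = x_i' beta + u_{d(i)},   u_d ~ Normal(0, sigma^2).

The marginal likelihood integrates over u with a Laplace approximation
per donor (the donor mode is found by a vectorized Newton step), and the
fixed effects, their Wald covariance, odds ratios and 95% CIs are
reported. Marginal probabilities are evaluated at u = 0 (the
population-median donor) with delta-method bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import mannwhitneyu, norm, pearsonr
from sklearn.base import BaseEstimator

_LOG_SIGMA_MIN = -8.0  # sigma ~ 3e-4: numerically an ordinary logistic fit
_LOG_SIGMA_MAX = 3.0


class SeparationError(RuntimeError):
    """A categorical level is all-LOY or all-XY: the MLE diverges."""


class RandomInterceptLogit(BaseEstimator):
    """Laplace-approximation ML logistic regression with a random intercept.

    sklearn-shaped: ``fit(X, y, groups)`` with a numeric design matrix
    ``X`` (including the intercept column), binary ``y`` and integer
    group codes. Fitted attributes: ``coef_`` (fixed effects), ``se_``,
    ``sigma_`` (random-intercept SD), ``cov_`` (Wald covariance of the
    fixed effects), ``loglik_``, ``converged_``, ``u_`` (donor modes).
    """

    def __init__(self, max_iter: int = 200, gtol: float = 1e-7, newton_iter: int = 50):
        self.max_iter = max_iter
        self.gtol = gtol
        self.newton_iter = newton_iter

    # -- Laplace marginal log-likelihood ---------------------------------
    def _donor_modes(self, eta_fixed, y, groups, n_groups, sigma2, u0):
        """Newton maximization of the per-donor joint log density."""
        u = u0.copy()
        for _ in range(self.newton_iter):
            eta = eta_fixed + u[groups]
            p = expit(eta)
            grad = np.bincount(groups, weights=y - p, minlength=n_groups) - u / sigma2
            w = np.bincount(groups, weights=p * (1 - p), minlength=n_groups)
            hess = -(w + 1.0 / sigma2)
            step = grad / hess
            u = u - step
            if np.max(np.abs(step)) < 1e-12:
                break
        return u

    def _loglik(self, params, X, y, groups, n_groups, u_cache):
        beta = params[:-1]
        sigma = np.exp(params[-1])
        sigma2 = sigma * sigma
        eta_fixed = X @ beta
        u = self._donor_modes(eta_fixed, y, groups, n_groups, sigma2, u_cache)
        u_cache[:] = u  # warm start for the next outer evaluation
        eta = eta_fixed + u[groups]
        # Bernoulli log-likelihood at the mode
        ll_data = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        p = expit(eta)
        w = np.bincount(groups, weights=p * (1 - p), minlength=n_groups)
        ll = (
            ll_data
            - float(np.sum(u * u) / (2 * sigma2))
            - 0.5 * float(np.sum(np.log1p(sigma2 * w)))
        )
        return ll

    def fit(self, X, y, groups) -> "RandomInterceptLogit":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        codes, uniques = pd.factorize(groups)
        n_groups = len(uniques)
        if n_groups < 2:
            warnings.warn(
                "fewer than 2 donors: the random-intercept SD is not "
                "identifiable and will sit at the boundary"
            )
        p = X.shape[1]
        u_cache = np.zeros(n_groups)

        # standardize non-constant columns for a well-conditioned
        # optimization; coefficients and covariance are mapped back below
        col_sd = X.std(axis=0)
        varying = col_sd > 0
        has_const = bool((~varying).any())
        col_mean = np.where(varying & has_const, X.mean(axis=0), 0.0)
        scale = np.where(varying, col_sd, 1.0)
        Xs = (X - col_mean) / scale

        def nll(params):
            return -self._loglik(params, Xs, y, codes, n_groups, u_cache)

        x0 = np.zeros(p + 1)
        x0[-1] = np.log(0.3)
        bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": self.gtol},
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise RuntimeError(
                f"GLMM did not converge: {res.message}; |grad| = "
                f"{np.max(np.abs(res.jac)):.3e}"
            )
        # back-transform: beta = T @ beta_s with T undoing the column
        # centering/scaling (centering mass moves onto constant columns)
        T = np.diag(1.0 / scale)
        if has_const:
            const_idx = int(np.flatnonzero(~varying)[0])
            c = float(X[0, const_idx])
            T[const_idx, :] -= col_mean / (scale * c)
        beta_s = res.x[:-1]
        self.params_ = res.x
        self.coef_ = T @ beta_s
        self.sigma_ = float(np.exp(res.x[-1]))
        if res.x[-1] <= _LOG_SIGMA_MIN + 1e-6:
            self.sigma_ = 0.0
        self.loglik_ = -res.fun
        self.converged_ = bool(res.success)
        self.u_ = u_cache.copy()
        self.group_levels_ = uniques

        hess = _numeric_hessian(nll, res.x)
        # Wald covariance of the fixed effects: invert the full observed
        # information, or only its beta block when sigma sits on the
        # boundary (the log-sigma row is then uninformative and pollutes
        # the inverse).
        at_boundary = res.x[-1] <= _LOG_SIGMA_MIN + 1e-4
        try:
            if at_boundary:
                raise np.linalg.LinAlgError
            cov_full = np.linalg.inv(hess)
            cov_beta = cov_full[:p, :p]
            if not np.all(np.diag(cov_beta) > 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov_beta = np.linalg.inv(hess[:p, :p])
        self.cov_ = T @ cov_beta @ T.T
        self.se_ = np.sqrt(np.diag(self.cov_))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """P(LOY) at the population-median donor (u = 0)."""
        eta = np.asarray(X, dtype=float) @ self.coef_
        p1 = expit(eta)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += eps
                xm = x.copy(); xm[i] -= eps
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / eps**2
            else:
                xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
                xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
                xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
                xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H


@dataclass
class GlmmFit:
    """Fitted LOY mixed model with a tidy coefficient table."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray = field(repr=False)
    sigma: float = 0.0
    loglik: float = np.nan
    converged: bool = True
    method: str = "laplace"
    n_cells: int = 0
    n_dropped: int = 0
    model: RandomInterceptLogit | None = field(default=None, repr=False)

    @property
    def table(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.coef,
                "se": self.se,
                "or": np.exp(self.coef),
                "ci_low": np.exp(self.coef - 1.96 * self.se),
                "ci_high": np.exp(self.coef + 1.96 * self.se),
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def build_design(
    cells: pd.DataFrame,
    covariates: list[str],
    reference_celltype: str = "PT",
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept and treatment-coded cell type.

    ``covariates`` may include "cell_type" (expanded to contrasts vs the
    reference), "age", "burden" and "CKD" (indicator from the disease
    column); numeric columns are passed through.
    """
    cols = [np.ones(len(cells))]
    terms = ["(Intercept)"]
    for cov in covariates:
        if cov == "cell_type":
            levels = [
                c for c in pd.unique(cells["cell_type"]) if c != reference_celltype
            ]
            if reference_celltype not in set(cells["cell_type"]):
                raise ValueError(
                    f"reference cell type {reference_celltype!r} absent from data"
                )
            for lv in sorted(levels):
                cols.append((cells["cell_type"] == lv).to_numpy(float))
                terms.append(f"cell_type[{lv}]")
        elif cov == "CKD":
            cols.append((cells["disease"] == "CKD").to_numpy(float))
            terms.append("CKD")
        else:
            cols.append(cells[cov].to_numpy(float))
            terms.append(cov)
    return np.column_stack(cols), terms


def fit_glmm(
    cells: pd.DataFrame,
    covariates: list[str] | None = None,
    reference_celltype: str = "PT",
) -> GlmmFit:
    """Fit the LOY GLMM on a per-cell table.

    ``cells`` must contain ``genotype`` ({LOY, XY} or 0/1), ``donor_id``
    and the requested covariate columns. Cells with missing covariates
    are dropped (complete-case) and counted in ``n_dropped``.
    """
    if covariates is None:
        covariates = [c for c in ("cell_type", "age", "burden") if c in cells.columns]
        if "disease" in cells.columns:
            covariates.append("CKD")
    y = cells["genotype"]
    if y.dtype == object:
        y = (y == "LOY").astype(int)
    work = cells.copy()
    work["_y"] = y
    needed = [c for c in covariates if c not in ("cell_type", "CKD")]
    mask = work[needed].notna().all(axis=1) if needed else pd.Series(True, index=work.index)
    n_dropped = int((~mask).sum())
    work = work.loc[mask]

    if "cell_type" in covariates:
        rates = work.groupby("cell_type")["_y"].mean()
        sep = rates[(rates == 0.0) | (rates == 1.0)]
        if len(sep):
            raise SeparationError(
                f"complete separation in cell type(s): {list(sep.index)}"
            )
    X, terms = build_design(work, covariates, reference_celltype)
    model = RandomInterceptLogit().fit(X, work["_y"].to_numpy(), work["donor_id"].to_numpy())
    return GlmmFit(
        terms=terms,
        coef=model.coef_,
        se=model.se_,
        cov=model.cov_,
        sigma=model.sigma_,
        loglik=model.loglik_,
        converged=model.converged_,
        method="laplace",
        n_cells=len(work),
        n_dropped=n_dropped,
        model=model,
    )


def marginal_probabilities(fit: GlmmFit, grid: pd.DataFrame, design_terms=None) -> pd.DataFrame:
    """Predicted P(LOY) on a covariate grid at u = 0, with Wald bands.

    ``grid`` must carry one column per non-intercept term of the fit
    (cell-type contrasts as indicator columns). Bands come from the delta
    method on the linear predictor.
    """
    if not fit.converged:
        raise RuntimeError("cannot predict from a non-converged fit")
    X = np.column_stack(
        [np.ones(len(grid))]
        + [np.asarray(grid[t], dtype=float) for t in fit.terms[1:]]
    )
    eta = X @ fit.coef
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    out = grid.copy()
    out["prob"] = expit(eta)
    out["prob_low"] = expit(eta - 1.96 * se_eta)
    out["prob_high"] = expit(eta + 1.96 * se_eta)
    return out


def donor_age_correlation(
    proportions: pd.Series,
    ages: pd.Series,
    bin_width_years: float = 10.0,
) -> dict:
    """Pearson correlation of donor-level LOY proportion with age.

    The correlation is computed on donor-level points; an age-binned
    summary (means per ``bin_width_years`` bin) is returned alongside for
    presentation. Zero variance in either variable yields status
    "undefined_correlation".
    """
    df = pd.DataFrame({"proportion": proportions, "age": ages}).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 donors")
    if df["age"].nunique() == 1 or df["proportion"].nunique() == 1:
        return {"status": "undefined_correlation", "donors": df}
    r, p = pearsonr(df["age"], df["proportion"])
    bins = np.floor(df["age"] / bin_width_years) * bin_width_years
    binned = (
        df.groupby(bins)
        .agg(mean_proportion=("proportion", "mean"), n_donors=("proportion", "size"))
        .rename_axis("age_bin")
        .reset_index()
    )
    return {
        "status": "ok",
        "r": float(r),
        "r2": float(r * r),
        "p": float(p),
        "donors": df,
        "binned": binned,
    }


def compare_proportions(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Two-group comparison of donor-level LOY proportions.

    Reports per-group mean +/- sd and a two-sided exact Wilcoxon
    rank-sum p-value on the donor-level proportions.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 donors per group")
    p = float(mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "p": p,
    }
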