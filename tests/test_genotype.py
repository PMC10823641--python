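"""Density-trough thresholding and the semi-supervised spherical GMM."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import loykit as lk
from loykit.genotype import (
    LOY, XY, UNLABELED,
    DensityTroughClassifier, NoTroughError, SemiSupervisedSphericalGMM,
    init_joint_labels,
)


def analytic_trough(weights, means, sds, lo, hi):
    """Grid-minimize the analytic two-component normal mixture density."""
    grid = np.linspace(lo, hi, 20_001)
    dens = sum(w * norm.pdf(grid, m, s) for w, m, s in zip(weights, means, sds))
    return grid[np.argmin(dens)]


class TestDensityTrough:
    def test_balanced_mixture_trough_at_midpoint(self):
        rng = np.random.default_rng(0)
        z = np.concatenate([
            rng.normal(0.0, 0.05, 5000), rng.normal(1.0, 0.05, 5000)
        ])
        clf = DensityTroughClassifier().fit(z)
        oracle = analytic_trough([0.5, 0.5], [0.0, 1.0], [0.05, 0.05], 0.1, 0.9)
        assert clf.status_ == "ok"
        assert clf.threshold_ == pytest.approx(oracle, abs=0.05)

    def test_unbalanced_mixture_trough_near_analytic_minimum(self):
        rng = np.random.default_rng(1)
        z = np.concatenate([
            rng.normal(-2.0, 0.3, 3000), rng.normal(0.0, 0.3, 17_000)
        ])
        clf = DensityTroughClassifier().fit(z)
        oracle = analytic_trough([0.15, 0.85], [-2.0, 0.0], [0.3, 0.3], -1.9, -0.1)
        assert clf.status_ == "ok"
        assert -2.0 < clf.threshold_ < 0.0
        assert clf.threshold_ == pytest.approx(oracle, abs=0.1)

    def test_unimodal_data_reports_no_trough(self):
        rng = np.random.default_rng(2)
        clf = DensityTroughClassifier().fit(rng.normal(0, 1, 10_000))
        assert clf.status_ == "no_trough"
        assert np.isnan(clf.threshold_)
        with pytest.raises(NoTroughError):
            clf.predict([0.0])

    def test_threshold_lies_between_the_two_modes(self):
        rng = np.random.default_rng(3)
        z = np.concatenate([rng.normal(-3, 0.4, 2000), rng.normal(0, 0.6, 8000)])
        clf = DensityTroughClassifier().fit(z)
        assert clf.modes_[0] < clf.threshold_ < clf.modes_[1]

    def test_density_integrates_to_one_on_grid(self):
        rng = np.random.default_rng(4)
        clf = DensityTroughClassifier().fit(rng.normal(0, 1, 2000))
        area = np.trapezoid(clf.density_, clf.grid_)
        assert area == pytest.approx(1.0, abs=0.01)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            DensityTroughClassifier().fit(np.zeros(10))


class TestUnimodalCalls:
    def _fitted_clf(self):
        rng = np.random.default_rng(0)
        z = np.concatenate([rng.normal(-4, 0.3, 1000), rng.normal(0, 1, 9000)])
        return DensityTroughClassifier().fit(z)

    def test_strictly_below_threshold_is_loy_and_tie_is_xy(self):
        clf = self._fitted_clf()
        thr = clf.threshold_
        chry = pd.DataFrame(
            {"z": [thr - 0.01, thr, thr + 0.01],
             "donor_id": ["D0"] * 3, "modality": ["RNA"] * 3},
            index=pd.Index(["a", "b", "c"], name="cell_id"),
        )
        calls = lk.call_unimodal(chry, clf)
        assert calls["genotype"].tolist() == ["LOY", "XY", "XY"]
        assert calls["posterior_loy"].tolist() == [1.0, 0.0, 0.0]

    def test_cohort_proportion_recovered_within_two_points(self, small_multiome):
        co = small_multiome
        scaled, _ = lk.normalize_and_correct(co.tables["RNA"].males())
        chry = lk.chry_z(scaled)
        clf = lk.estimate_density_threshold(chry["z"])
        calls = lk.call_unimodal(chry, clf)
        called, _ = lk.loy_proportions(calls)
        truth = (co.truth.loc[chry.index, "true_genotype"] == "LOY").mean()
        assert abs(called - truth) <= 0.02


class TestInitJointLabels:
    def test_origin_and_median_rules(self):
        raw_r = np.array([0, 5, 3, 9])
        raw_a = np.array([0, 7, 2, 8])
        z_r = np.array([-3.0, 1.0, -0.5, 0.2])
        z_a = np.array([-3.0, -0.2, -0.6, 1.5])
        y = init_joint_labels(raw_r, raw_a, z_r, z_a)
        # c0 at origin -> LOY; c1 above RNA median -> XY;
        # c3 above both medians -> XY; c2 below both, nonzero -> unlabeled
        assert y.tolist() == [LOY, XY, UNLABELED, XY]

    def test_origin_takes_precedence_over_median_rule(self):
        raw = np.zeros(4, dtype=int)
        z = np.array([5.0, -1.0, -1.0, -1.0])
        y = init_joint_labels(raw, raw, z, z)
        assert y[0] == LOY  # above-median but at the origin


def brute_force_em(X, y, n_iter=500, tol=1e-8):
    """Straightforward reference EM for the 2-state spherical mixture."""
    X = np.asarray(X, float)
    n, d = X.shape
    resp = np.zeros((n, 2))
    for i in range(n):
        if y[i] != UNLABELED:
            resp[i, y[i]] = 1.0
    lab = y != UNLABELED

    def m_step(R, pts):
        nk = R.sum(axis=0)
        w = nk / len(pts)
        mu = np.array([(R[:, k, None] * pts).sum(0) / nk[k] for k in range(2)])
        var = np.array([
            (R[:, k] * ((pts - mu[k]) ** 2).sum(1)).sum() / (d * nk[k])
            for k in range(2)
        ])
        return mu, var, w

    mu, var, w = m_step(resp[lab], X[lab])
    prev = -np.inf
    trace = []
    for _ in range(n_iter):
        logp = np.zeros((n, 2))
        for k in range(2):
            sq = ((X - mu[k]) ** 2).sum(1)
            logp[:, k] = (
                np.log(w[k]) - 0.5 * d * np.log(2 * np.pi * var[k])
                - 0.5 * sq / var[k]
            )
        mx = logp.max(axis=1)
        lognorm = mx + np.log(np.exp(logp - mx[:, None]).sum(1))
        ll = lognorm[~lab].sum() + sum(logp[i, y[i]] for i in np.where(lab)[0])
        trace.append(ll)
        for i in range(n):
            if not lab[i]:
                resp[i] = np.exp(logp[i] - lognorm[i])
        mu, var, w = m_step(resp, X)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            break
        prev = ll
    return ll, resp, trace


class TestSemiSupervisedGMM:
    def _clusters(self, seed=0, n=500, sd=0.3):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(-3, sd, (n, 2)),  # LOY cluster near the origin of coverage
            rng.normal(0, sd, (n, 2)),
        ])
        truth = np.array([LOY] * n + [XY] * n)
        return X, truth, rng

    def test_fully_supervised_degenerate_case(self):
        X, truth, _ = self._clusters()
        model = SemiSupervisedSphericalGMM().fit(X, truth)
        assert (model.predict(X) == truth).mean() == 1.0
        for k in (XY, LOY):
            pts = X[truth == k]
            np.testing.assert_allclose(model.means_[k], pts.mean(0), atol=1e-12)
            np.testing.assert_allclose(
                model.variances_[k], ((pts - pts.mean(0)) ** 2).sum() / pts.size,
                atol=1e-12,
            )

    def test_well_separated_clusters_recovered(self):
        X, truth, rng = self._clusters(seed=1)
        # ~10% labeled: origin-most cells LOY, top-coverage cells XY
        y = np.full(len(X), UNLABELED)
        order = X.sum(1).argsort()
        y[order[:50]] = LOY
        y[order[-50:]] = XY
        model = SemiSupervisedSphericalGMM().fit(X, y)
        assert (model.predict(X) == truth).mean() >= 0.99

    def test_matches_brute_force_em_oracle(self):
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.normal(-2.5, 0.5, (40, 2)), rng.normal(0, 0.7, (60, 2))
        ])
        y = np.full(100, UNLABELED)
        y[:10] = LOY
        y[60:75] = XY
        model = SemiSupervisedSphericalGMM().fit(X, y)
        ll_oracle, resp_oracle, _ = brute_force_em(X, y)
        assert model.ll_trace_[-1] == pytest.approx(ll_oracle, abs=1e-6)
        assert (model.predict(X) == resp_oracle.argmax(1)).all()

    def test_loglikelihood_trace_nondecreasing(self):
        X, truth, _ = self._clusters(seed=2, sd=1.2)
        y = np.full(len(X), UNLABELED)
        y[:20] = truth[:20]
        y[-20:] = truth[-20:]
        model = SemiSupervisedSphericalGMM().fit(X, y)
        assert np.all(np.diff(model.ll_trace_) >= -1e-9 * np.abs(model.ll_trace_[:-1]))

    def test_responsibilities_sum_to_one_and_labels_fixed(self):
        X, truth, _ = self._clusters(seed=3)
        y = np.full(len(X), UNLABELED)
        y[:30] = LOY
        y[-30:] = XY
        model = SemiSupervisedSphericalGMM().fit(X, y)
        np.testing.assert_allclose(model.responsibilities_.sum(1), 1.0, atol=1e-12)
        assert (model.responsibilities_[:30, LOY] == 1.0).all()
        assert (model.responsibilities_[-30:, XY] == 1.0).all()

    def test_missing_labeled_state_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        y = np.full(50, UNLABELED)
        y[:5] = XY
        with pytest.raises(ValueError, match="LOY"):
            SemiSupervisedSphericalGMM().fit(X, y)
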