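"""Mixed logistic model, marginal probabilities, donor-level comparisons."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

import loykit as lk
from loykit.association import (
    RandomInterceptLogit, SeparationError, build_design,
)


def cells_frame(y, donor, **cols):
    df = pd.DataFrame({"genotype": np.where(y == 1, "LOY", "XY"), "donor_id": donor})
    for k, v in cols.items():
        df[k] = v
    return df


class TestRandomInterceptLogit:
    def test_single_donor_intercept_is_binomial_mle(self):
        y = np.r_[np.ones(30), np.zeros(270)]
        X = np.ones((300, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = RandomInterceptLogit().fit(X, y, np.zeros(300, int))
        assert m.coef_[0] == pytest.approx(logit(0.1), abs=0.01)
        assert m.sigma_ == pytest.approx(0.0, abs=1e-3)

    def test_sigma_zero_data_matches_ordinary_logistic(self):
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1.0 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        groups = rng.integers(0, 8, n)
        m = RandomInterceptLogit().fit(X, y, groups)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(m.coef_, ref.params, atol=1e-3)
        np.testing.assert_allclose(m.se_, ref.bse, atol=1e-3)

    def test_null_covariate_ci_contains_one(self):
        rng = np.random.default_rng(1)
        n = 8000
        x = rng.normal(size=n)
        groups = rng.integers(0, 10, n)
        u = rng.normal(0, 0.3, 10)
        y = (rng.random(n) < expit(-1.5 + u[groups])).astype(float)
        cells = cells_frame(y, [f"D{g}" for g in groups], age=x)
        fit = lk.fit_glmm(cells, covariates=["age"])
        row = fit.table.set_index("term").loc["age"]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_donor_random_intercept_recovered(self):
        cfg = lk.CohortConfig(
            n_donors=20, n_cells_per_donor=200, seed=2,
            donor_random_intercept_sd=0.8, baseline_loy_logit=-1.5,
            age_effect=0.0, cnv_effect=0.0, disease_effect=0.0,
            celltype_specs=[lk.CellTypeSpec("PT", 1.0, 0.0, 1.0)],
            gain_spec=("chr7", 0.0, 1.5),
        )
        co = lk.simulate_cohort(cfg, make_bin_matrix=False)
        cells = co.truth.rename(columns={"true_genotype": "genotype"})
        fit = lk.fit_glmm(cells, covariates=[])
        assert fit.sigma == pytest.approx(0.8, abs=0.3)

    def test_complete_separation_raises(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        cells = cells_frame(
            y, ["D0"] * 50 + ["D1"] * 50,
            cell_type=["PODO"] * 50 + ["PT"] * 50,
        )
        with pytest.raises(SeparationError, match="PODO"):
            lk.fit_glmm(cells, covariates=["cell_type"])

    def test_reference_celltype_is_baseline(self):
        rng = np.random.default_rng(3)
        n = 2000
        ct = rng.choice(["PT", "TAL", "PODO"], n)
        y = (rng.random(n) < 0.1).astype(float)
        cells = cells_frame(y, rng.choice(["D0", "D1", "D2"], n), cell_type=ct)
        fit = lk.fit_glmm(cells, covariates=["cell_type"], reference_celltype="PT")
        assert "cell_type[PT]" not in fit.terms
        assert {"cell_type[PODO]", "cell_type[TAL]"} <= set(fit.terms)

    def test_missing_covariates_dropped_and_counted(self):
        rng = np.random.default_rng(4)
        n = 400
        y = (rng.random(n) < 0.2).astype(float)
        age = rng.uniform(40, 80, n)
        age[:25] = np.nan
        cells = cells_frame(y, rng.choice(["D0", "D1"], n), age=age)
        fit = lk.fit_glmm(cells, covariates=["age"])
        assert fit.n_dropped == 25
        assert fit.n_cells == n - 25


class TestMarginalProbabilities:
    def _fit(self, coef, se=None, terms=None):
        terms = terms or ["(Intercept)"]
        coef = np.asarray(coef, float)
        se = np.asarray(se if se is not None else np.full(len(coef), 0.1))
        return lk.GlmmFit(
            terms=terms, coef=coef, se=se, cov=np.diag(se**2), sigma=0.0,
        )

    def test_zero_intercept_gives_half(self):
        fit = self._fit([0.0])
        out = lk.marginal_probabilities(fit, pd.DataFrame(index=[0]))
        assert out["prob"].iloc[0] == pytest.approx(0.5)

    def test_age_effect_closed_form(self):
        fit = self._fit([-2.197, 0.1], terms=["(Intercept)", "age"])
        out = lk.marginal_probabilities(fit, pd.DataFrame({"age": [10.0]}))
        assert out["prob"].iloc[0] == pytest.approx(expit(-1.197), abs=1e-4)

    def test_probabilities_and_bands_in_unit_interval(self):
        fit = self._fit([-1.0, 0.05], se=[0.5, 0.02], terms=["(Intercept)", "age"])
        grid = pd.DataFrame({"age": np.linspace(0, 100, 11)})
        out = lk.marginal_probabilities(fit, grid)
        for col in ("prob", "prob_low", "prob_high"):
            assert ((out[col] >= 0) & (out[col] <= 1)).all()
        assert (out["prob_low"] <= out["prob"]).all()
        assert (out["prob"] <= out["prob_high"]).all()
        # single positive coefficient -> monotone in age
        assert (np.diff(out["prob"]) > 0).all()


class TestDonorLevelSummaries:
    def test_perfectly_linear_proportions_r2_one(self):
        ages = pd.Series([40.0, 50, 60, 70, 80])
        props = pd.Series(0.002 * ages.to_numpy() + 0.01)
        out = lk.donor_age_correlation(props, ages)
        assert out["status"] == "ok"
        assert out["r2"] == pytest.approx(1.0)

    def test_constant_proportions_undefined(self):
        out = lk.donor_age_correlation(
            pd.Series([0.1, 0.1, 0.1]), pd.Series([40.0, 50, 60])
        )
        assert out["status"] == "undefined_correlation"

    def test_generator_age_effect_r2_matches_truth_oracle(self):
        cfg = lk.CohortConfig(
            n_donors=20, n_cells_per_donor=300, seed=5,
            donor_ages=list(np.linspace(30, 80, 20)),
            donor_random_intercept_sd=0.3, baseline_loy_logit=-4.5,
            age_effect=0.05, cnv_effect=0.0, disease_effect=0.0,
            gain_spec=("chr7", 0.0, 1.5),
        )
        co = lk.simulate_cohort(cfg, make_bin_matrix=False)
        obs = (
            (co.truth["true_genotype"] == "LOY")
            .groupby(co.truth["donor_id"]).mean()
        )
        ages = co.truth.groupby("donor_id")["age"].first()
        out = lk.donor_age_correlation(obs, ages)
        # oracle: correlation computed directly on the generator's
        # donor-level true LOY probabilities
        p_true = (
            pd.Series(expit(co.truth["eta"]), index=co.truth.index)
            .groupby(co.truth["donor_id"]).mean()
        )
        r_oracle = np.corrcoef(ages, p_true)[0, 1]
        assert out["r2"] == pytest.approx(r_oracle**2, abs=0.15)
        assert out["p"] < 0.01

    def test_exact_wilcoxon_on_separated_groups(self):
        res = lk.compare_proportions([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert res["p"] == pytest.approx(0.1)

    def test_mean_sd_arithmetic(self):
        res = lk.compare_proportions([0.02, 0.08, 0.14], [0.1, 0.2])
        assert res["mean_a"] == pytest.approx(0.08)
        assert res["sd_a"] == pytest.approx(0.06)

    def test_identical_groups_nonsignificant(self):
        res = lk.compare_proportions([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["p"] > 0.5

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValueError):
            lk.compare_proportions([0.1], [0.2, 0.3])


def test_design_matrix_layout():
    cells = pd.DataFrame({
        "cell_type": ["PT", "TAL", "PT"],
        "disease": ["control", "CKD", "CKD"],
        "age": [50.0, 60.0, 70.0],
    })
    X, terms = build_design(cells, ["cell_type", "age", "CKD"], "PT")
    assert terms == ["(Intercept)", "cell_type[TAL]", "age", "CKD"]
    np.testing.assert_array_equal(X[:, 1], [0, 1, 0])
    np.testing.assert_array_equal(X[:, 3], [0, 1, 1])
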