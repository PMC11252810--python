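"""Three-step estimator: oracle equivalences, ground-truth recovery, invariances."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from coben.gscm import (
    cross_validate_r,
    estimate,
    fit_ife_controls,
    impute_and_att,
    project_treated,
)
from coben.panel import PanelDataset, log_transform
from coben.simulate import emissions_like_preset, generate


def small_spec(**kw):
    base = dict(seed=1, n_treated=4, n_control=8, tau_profile=-0.40)
    base.update(kw)
    return emissions_like_preset(**base)


class TestFitControls:
    def test_r0_no_covariates_no_effects_is_trivial(self, small_log_panel):
        fit = fit_ife_controls(
            small_log_panel, 0, covariates=(), additive_effects=False
        )
        assert fit.beta_hat.size == 0
        Y = small_log_panel.wide_outcome(small_log_panel.control_units)
        np.testing.assert_array_equal(fit.resid.to_numpy(), Y.to_numpy())
        assert (fit.fitted.to_numpy() == 0).all()

    def test_r0_beta_equals_pooled_ols(self, small_log_panel):
        """Without factors or intercepts, beta must be plain pooled OLS."""
        fit = fit_ife_controls(small_log_panel, 0, additive_effects=False)
        d = small_log_panel.data
        d = d[~d["treated"]]
        X = d[["log_gdp", "log_gdp_sq"]].to_numpy()
        beta_ols = np.linalg.lstsq(X, d["outcome"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta_hat, beta_ols, atol=1e-10)

    def test_r0_additive_beta_equals_dummy_ols(self, small_log_panel):
        """With two-way intercepts, beta must match an explicit dummy regression."""
        fit = fit_ife_controls(small_log_panel, 0, additive_effects=True)
        d = small_log_panel.data
        d = d[~d["treated"]].reset_index(drop=True)
        X = d[["log_gdp", "log_gdp_sq"]].to_numpy()
        U = pd.get_dummies(d["unit"]).to_numpy(dtype=float)
        Yr = pd.get_dummies(d["year"]).to_numpy(dtype=float)
        design = np.column_stack([X, U, Yr])
        coef = np.linalg.lstsq(design, d["outcome"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta_hat, coef[:2], atol=1e-8)

    def test_factor_space_recovery_low_noise(self):
        """Estimated factors span the true (demeaned) factor paths."""
        sp = generate(small_spec(seed=5, n_control=20, noise_sd=0.01))
        panel = log_transform(sp.panel)
        fit = fit_ife_controls(panel, 2)
        F_hat = fit.factors_hat.to_numpy()
        F_true = sp.truth["factors"].to_numpy()
        F_true = F_true - F_true.mean(axis=0)  # time means absorbed by intercepts
        # canonical correlations via QR
        qh, _ = np.linalg.qr(F_hat)
        qt, _ = np.linalg.qr(F_true)
        sv = np.linalg.svd(qh.T @ qt, compute_uv=False)
        assert sv.min() > 0.99

    def test_r_too_large_rejected(self, small_log_panel):
        with pytest.raises(ValueError, match="infeasible"):
            fit_ife_controls(small_log_panel, 50)

    def test_factor_normalization(self, small_log_panel):
        fit = fit_ife_controls(small_log_panel, 2)
        F = fit.factors_hat.to_numpy()
        T = F.shape[0]
        np.testing.assert_allclose(F.T @ F / T, np.eye(2), atol=1e-8)
        LtL = fit.control_loadings.to_numpy().T @ fit.control_loadings.to_numpy()
        assert abs(LtL[0, 1]) < 1e-8 * max(LtL[0, 0], 1)


class TestProjection:
    def test_duplicated_control_reproduces_loadings(self):
        """On noise-free data, a treated copy of a control gets its loadings."""
        panel = generate(small_spec(seed=4, n_control=10, noise_sd=1e-9)).panel
        d = panel.data
        ctrl = panel.control_units[0]
        clone = d[d["unit"] == ctrl].copy()
        clone["unit"] = "t_clone"
        clone["treated"] = True
        df = pd.concat([d[~d["treated"]], clone], ignore_index=True)
        dup_panel = log_transform(
            PanelDataset(df, panel.covariates, panel.treatment_start)
        )
        fit = fit_ife_controls(dup_panel, 2)
        proj = project_treated(fit, dup_panel)
        np.testing.assert_allclose(
            proj.loadings.loc["t_clone"],
            fit.control_loadings.loc[ctrl],
            atol=1e-6,
        )
        assert proj.pre_fit_rmse["t_clone"] < 1e-8

    def test_r0_residuals_match_ols_oracle(self, small_log_panel):
        """With r=0 and no intercepts the projection leaves pure OLS residuals."""
        fit = fit_ife_controls(small_log_panel, 0, additive_effects=False)
        proj = project_treated(fit, small_log_panel)
        assert proj.loadings.shape[1] == 0
        d = small_log_panel.data
        pre = d[d["treated"] & (d["year"] < small_log_panel.treatment_start)]
        for unit in small_log_panel.treated_units:
            rows = pre[pre["unit"] == unit]
            resid = (
                rows["outcome"].to_numpy()
                - rows[["log_gdp", "log_gdp_sq"]].to_numpy() @ fit.beta_hat
            )
            np.testing.assert_allclose(
                proj.eta_resid[unit].to_numpy(), resid, atol=1e-10
            )

    def test_noise_free_truth_recovered(self):
        """Near noise-free data: imputed counterfactual equals the truth."""
        sp = generate(small_spec(seed=8, n_control=20, noise_sd=1e-8))
        panel = log_transform(sp.panel)
        fit, res = estimate(panel, r=2)
        y0_true = sp.truth["y0_log"][panel.treated_units].loc[2005:]
        np.testing.assert_allclose(
            res.y0_log.loc[2005:].to_numpy(), y0_true.to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(res.att_by_year.to_numpy(), -0.40, atol=1e-5)

    def test_too_few_pre_years_rejected(self):
        spec = emissions_like_preset(
            seed=2, n_treated=2, n_control=8, start_year=2002, end_year=2010,
            tau_profile=-0.1,
        )
        panel = log_transform(generate(spec).panel)
        fit = fit_ife_controls(panel, 2)
        with pytest.raises(ValueError, match="pretreatment"):
            project_treated(fit, panel, pre_years=[2002, 2003])


class TestImputation:
    def test_att_is_cross_unit_mean(self, small_log_panel):
        _, res = estimate(small_log_panel, r=2)
        np.testing.assert_allclose(
            res.att_by_year.to_numpy(),
            res.tau_hat.mean(axis=1).to_numpy(),
            atol=1e-12,
        )

    def test_pretreatment_mean_gap_near_zero(self, small_log_panel):
        """Least-squares projection forces the mean pretreatment gap to ~0."""
        _, res = estimate(small_log_panel, r=2)
        pre_gap = res.gap_by_year.loc[: small_log_panel.treatment_start - 1]
        assert abs(pre_gap.mean()) < 1e-10

    def test_level_counterfactual_is_exp_of_log(self, small_log_panel):
        _, res = estimate(small_log_panel, r=2)
        np.testing.assert_allclose(
            res.y0_level.to_numpy(), np.exp(res.y0_log.to_numpy()), rtol=1e-14
        )

    def test_rotation_invariance(self, small_log_panel):
        """ATT and imputed outcomes do not depend on the factor rotation."""
        fit = fit_ife_controls(small_log_panel, 2)
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        rotated = replace(
            fit,
            factors_hat=pd.DataFrame(
                fit.factors_hat.to_numpy() @ Q,
                index=fit.factors_hat.index,
                columns=fit.factors_hat.columns,
            ),
            control_loadings=pd.DataFrame(
                fit.control_loadings.to_numpy() @ Q,
                index=fit.control_loadings.index,
                columns=fit.control_loadings.columns,
            ),
        )
        res_a = impute_and_att(fit, project_treated(fit, small_log_panel), small_log_panel)
        res_b = impute_and_att(
            rotated, project_treated(rotated, small_log_panel), small_log_panel
        )
        np.testing.assert_allclose(
            res_a.y0_log.to_numpy(), res_b.y0_log.to_numpy(), atol=1e-8
        )
        np.testing.assert_allclose(
            res_a.att_by_year.to_numpy(), res_b.att_by_year.to_numpy(), atol=1e-8
        )

    def test_projection_fit_mismatch_rejected(self, small_log_panel):
        fit2 = fit_ife_controls(small_log_panel, 2)
        fit3 = fit_ife_controls(small_log_panel, 3)
        proj3 = project_treated(fit3, small_log_panel)
        with pytest.raises(ValueError, match="different fit"):
            impute_and_att(fit2, proj3, small_log_panel)


class TestCrossValidation:
    def test_single_candidate_returned(self, small_log_panel):
        fit = cross_validate_r(small_log_panel, candidates=[3])
        assert fit.r == 3
        assert set(fit.mspe_by_r) == {3}

    def test_selected_r_attains_minimum(self, small_log_panel):
        fit = cross_validate_r(small_log_panel, candidates=range(4))
        assert fit.mspe_by_r[fit.r] == min(fit.mspe_by_r.values())

    def test_true_rank_selected_single_seed(self):
        sp = generate(small_spec(seed=21, n_control=15))
        fit = cross_validate_r(log_transform(sp.panel), candidates=range(5))
        assert fit.r == 2

    def test_pure_covariate_model_selects_zero(self):
        sp = generate(small_spec(seed=22, n_factors=0, n_control=15))
        fit = cross_validate_r(log_transform(sp.panel), candidates=range(4))
        assert fit.r == 0

    def test_needs_pretreatment_periods(self):
        spec = emissions_like_preset(
            seed=2, n_treated=2, n_control=6, start_year=2003, end_year=2010,
            tau_profile=-0.1,
        )
        panel = log_transform(generate(spec).panel)
        with pytest.raises(ValueError, match="pretreatment"):
            cross_validate_r(panel, candidates=[0, 1])

    def test_empty_candidates_rejected(self, small_log_panel):
        with pytest.raises(ValueError, match="candidate"):
            cross_validate_r(small_log_panel, candidates=[])
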