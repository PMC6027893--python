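"""Gibbs samplers: chain contracts, invariances, structural reductions."""

import numpy as np
import pandas as pd
import pytest

import gxepred as gp
from gxepred.gxemodels import (ModelError, ModelSpec, fit_gblup_gxe, fit_rkhs1,
                               fit_rkhs2, fit_single_env,
                               potential_scale_reduction)

from conftest import genotype_means


class TestChainContract:
    def test_default_retained_samples(self):
        assert ModelSpec().retained == 3000  # (35000 - 5000) / 10

    def test_retained_honored_in_traces(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values["AWD"].rename("AWD")
        fit = fit_single_env(ks.k_linear, y, short_spec)
        assert fit.retained == short_spec.retained == 500
        for arr in fit.samples.values():
            assert arr.shape == (1, 500)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(model="BayesZ")
        with pytest.raises(ModelError):
            ModelSpec(burn_in=100, n_iter=50)

    def test_zero_variance_phenotype_fails(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = pd.Series(np.ones(100), index=ks.genotype_ids, name="E")
        with pytest.raises(ModelError, match="variance"):
            fit_single_env(ks.k_linear, y, short_spec)

    def test_non_psd_kernel_fails(self, short_spec):
        k = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        y = pd.Series([0.1, -0.2], index=["a", "b"], name="E")
        with pytest.raises(ModelError, match="positive semi-definite"):
            fit_single_env(k, y, short_spec)


class TestSingleEnv:
    def test_shift_invariance_exact_under_same_seed(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values["AWD"].rename("AWD")
        f0 = fit_single_env(ks.k_linear, y, short_spec)
        f1 = fit_single_env(ks.k_linear, y + 50.0, short_spec)
        assert np.allclose(f1.genetic_values, f0.genetic_values, atol=1e-10)
        assert f1.intercepts.iloc[0] == pytest.approx(f0.intercepts.iloc[0] + 50.0)

    def test_predictive_ability_above_chance(self, medium_panel, short_spec):
        # 5-fold masking: genomic predictions correlate with held-out means
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values["AWD"]
        rng = np.random.default_rng(0)
        order = rng.permutation(len(y))
        rs = []
        for fold in range(5):
            val = [ks.genotype_ids[i] for i in order[fold::5]]
            masked = y.copy()
            masked.loc[val] = np.nan
            fit = fit_single_env(ks.k_linear, masked.rename("AWD"), short_spec)
            rs.append(np.corrcoef(fit.predictions.loc[val, "AWD"], y.loc[val])[0, 1])
        t = np.mean(rs) / (np.std(rs, ddof=1) / np.sqrt(len(rs)))
        assert t > 2.13  # one-sided t(4), alpha = 0.05


class TestGblupGxe:
    def test_zero_env_variance_collapses_to_across_env_model(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        fit = fit_gblup_gxe(ks.k_linear, y, short_spec, fixed_variances={"uE": 0.0})
        assert np.allclose(fit.genetic_values["AWD"], fit.genetic_values["CF"])

    def test_zero_main_variance_matches_independent_fits(self, medium_panel):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        pm = float(y.to_numpy().var() / 2)
        spec = ModelSpec(n_iter=8000, burn_in=1500, thin=4, seed=8, prior_mode=pm)
        multi = fit_gblup_gxe(ks.k_linear, y, spec, fixed_variances={"u0": 0.0})
        for env in y.columns:
            single = fit_single_env(
                ks.k_linear, y[env].rename(env),
                ModelSpec(n_iter=8000, burn_in=1500, thin=4, seed=81, prior_mode=pm))
            diff = np.abs(multi.genetic_values[env].to_numpy()
                          - single.genetic_values.iloc[:, 0].to_numpy())
            assert diff.mean() < 0.02 * y[env].std()
            assert diff.max() < 0.10 * y[env].std()

    def test_m2_predictions_beat_single_env_on_same_cells(self):
        # strong cross-environment correlation (rho = 0.9): seeing one
        # environment should lift prediction of the other in >= 80% of reps
        cfg = gp.SimConfig(n_genotypes=100, n_markers=400, var_main=45.0,
                           var_env_specific=5.0, seed=31)
        geno = gp.simulate_genotypes(cfg)
        obs = gp.simulate_trial(geno, cfg)
        y = genotype_means(obs, geno)
        k = gp.linear_kernel(geno, scale=True)
        spec = ModelSpec(n_iter=3000, burn_in=600, thin=4, seed=3)
        wins, n_rep = 0, 25
        rng = np.random.default_rng(12)
        for rep in range(n_rep):
            val = list(rng.choice(y.index, size=20, replace=False))
            masked = y.copy()
            masked.loc[val, "CF"] = np.nan  # observed in AWD only
            multi = fit_gblup_gxe(k, masked, spec)
            single = fit_single_env(k, masked["CF"].rename("CF"), spec)
            r_multi = np.corrcoef(multi.predictions.loc[val, "CF"], y.loc[val, "CF"])[0, 1]
            r_single = np.corrcoef(single.predictions.loc[val, "CF"], y.loc[val, "CF"])[0, 1]
            wins += r_multi > r_single
        assert wins >= 20

    def test_missing_environment_rejected(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values.copy()
        y["CF"] = np.nan
        with pytest.raises(ModelError, match="CF"):
            fit_gblup_gxe(ks.k_linear, y, short_spec)


class TestRkhs1:
    def test_linear_kernel_substitution_equals_gblup_gxe(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        a = fit_gblup_gxe(ks.k_linear, y, short_spec)
        b = fit_rkhs1(ks.k_linear, y, short_spec)
        assert np.allclose(a.predictions, b.predictions, atol=1e-10)

    def test_duplicate_environments_shrink_env_terms(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        col = medium_panel["means"].values["AWD"]
        y = pd.DataFrame({"E1": col, "E2": col})
        fit = fit_rkhs1(ks.k_gauss, y, short_spec)
        v = fit.variances.set_index("parameter")["mean"]
        assert v["sigma2_uE[0]"] + v["sigma2_uE[1]"] < 0.5 * v["sigma2_u0"]

    def test_prior_predictive_with_zero_variances(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        fit = fit_rkhs1(ks.k_gauss, y, short_spec,
                        fixed_variances={"u0": 0.0, "uE": 0.0})
        assert np.allclose(fit.genetic_values, 0.0)
        for env in y.columns:
            assert np.allclose(fit.predictions[env], fit.intercepts[env])
            assert fit.intercepts[env] == pytest.approx(y[env].mean(), abs=0.5)


class TestRkhs2:
    def test_single_environment_delegates(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values[["AWD"]]
        fit = fit_rkhs2(ks.k_gauss, y, short_spec)
        assert fit.model == "RKHS"
        assert fit.env_corr is None

    def test_environment_exchange_symmetry(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        a = fit_rkhs2(ks.k_gauss, y, short_spec)
        b = fit_rkhs2(ks.k_gauss, y[["CF", "AWD"]], short_spec)
        for env in ("AWD", "CF"):
            d = np.abs(a.predictions[env] - b.predictions[env])
            assert d.mean() < 0.05 * y[env].std()
        assert a.env_corr[0, 1] == pytest.approx(b.env_corr[0, 1], abs=0.05)

    def test_diagonal_covariance_matches_independent_fits(self, medium_panel):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        val = list(y.index[:20])
        masked = y.copy()
        masked.loc[val] = np.nan
        pm = float(y.to_numpy().var() / 2)
        spec = ModelSpec(n_iter=8000, burn_in=1500, thin=4, seed=8, prior_mode=pm)
        diag = fit_rkhs2(ks.k_gauss, masked, spec, diagonal_covariance=True)
        assert np.allclose(diag.env_corr, np.eye(2))
        for env in y.columns:
            single = fit_single_env(
                ks.k_gauss, masked[env].rename(env),
                ModelSpec(n_iter=8000, burn_in=1500, thin=4, seed=81, prior_mode=pm))
            a = diag.predictions.loc[val, env].to_numpy()
            b = single.predictions.loc[val].iloc[:, 0].to_numpy()
            assert np.abs(a - b).mean() < 0.08 * y[env].std()
            assert np.corrcoef(a, b)[0, 1] > 0.93


class TestConvergence:
    def test_identical_chains_give_unit_psrf(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        psrf = potential_scale_reduction(np.vstack([x, x]))
        assert abs(psrf - 1.0) < 1e-3

    def test_well_mixed_chains_pass(self, medium_panel):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values["AWD"].rename("AWD")
        spec = ModelSpec(n_iter=4000, burn_in=1000, thin=1, seed=5, n_chains=2)
        fit = fit_single_env(ks.k_linear, y, spec)
        report = gp.check_convergence(fit)
        assert report["available"].all()
        assert (report["psrf"] < 1.1).all()

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        assert potential_scale_reduction(chains) > 1.1

    def test_single_chain_reports_unavailable(self, medium_panel, short_spec):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values["AWD"].rename("AWD")
        fit = fit_single_env(ks.k_linear, y, short_spec)
        report = gp.check_convergence(fit)
        assert not report["available"].any()
        assert not report["flagged"].any()
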