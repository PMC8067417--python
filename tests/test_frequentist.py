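"""REML estimation, Satterthwaite tests, variance partition, simple slopes."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from fidlmm import (
    ModelSpec,
    ModelTerm,
    SyntheticConfig,
    build_design,
    fit_reml,
    reml_criterion,
    satterthwaite_tests,
    simple_slopes,
    simulate_dataset,
    variance_partition,
)
from fidlmm.frequentist import FitResult
from fidlmm.model_core import DesignRealization, Theta

DATA = Path(__file__).parent / "data"


def balanced_one_way(m=8, k=6, tau=4.0, sigma=1.5, seed=0):
    rng = np.random.default_rng(seed)
    u = np.sqrt(tau) * rng.standard_normal(m)
    y = np.repeat(u, k) + np.sqrt(sigma) * rng.standard_normal(m * k)
    return DesignRealization(y=y, X=np.ones((m * k, 1)),
                             group_index=np.repeat(np.arange(m), k),
                             column_names=["intercept"])


class TestFitReml:
    def test_balanced_anova_closed_form(self):
        """For a balanced one-way layout REML equals the ANOVA
        method-of-moments estimators: sigma2 = MS_within and
        tau00 = (MS_between - MS_within) / k."""
        m, k = 8, 6
        design = balanced_one_way(m, k)
        y = design.y.reshape(m, k)
        gm = y.mean()
        ms_b = k * ((y.mean(axis=1) - gm) ** 2).sum() / (m - 1)
        ms_w = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (m * (k - 1))
        fit = fit_reml(design)
        assert fit.theta_hat.var_resid == pytest.approx(ms_w, rel=1e-6)
        assert fit.theta_hat.var_subject == pytest.approx(max((ms_b - ms_w) / k, 0.0),
                                                          rel=1e-6)

    def test_boundary_zero_variance_when_no_between_effect(self):
        rng = np.random.default_rng(1)
        m, k = 40, 10
        y = rng.standard_normal(m * k)  # no subject effect at all
        design = DesignRealization(y=y, X=np.ones((m * k, 1)),
                                   group_index=np.repeat(np.arange(m), k),
                                   column_names=["intercept"])
        fit = fit_reml(design)
        assert fit.theta_hat.var_subject == pytest.approx(0.0, abs=1e-3)
        assert fit.theta_hat.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_matches_frozen_lmer_benchmark(self):
        """Frozen cross-validation fixture: the same model fitted by R's
        lmerTest (REML + Satterthwaite) on the stored benchmark dataset."""
        table = pd.read_csv(DATA / "lmer_benchmark.csv")
        spec = ModelSpec(response="sbp_r",
                         fixed_terms=("tertile", "sbp_baseline", "cognition",
                                      "cognition:tertile"))
        design = build_design(table, spec)
        fit = satterthwaite_tests(fit_reml(design), design)
        with open(DATA / "lmer_benchmark_expected.json") as fh:
            exp = json.load(fh)
        np.testing.assert_allclose(fit.theta_hat.beta, exp["estimate"], rtol=1e-6)
        np.testing.assert_allclose(fit.se_beta, exp["se"], rtol=1e-5)
        np.testing.assert_allclose(fit.satterthwaite_df, exp["df"], rtol=1e-3)
        np.testing.assert_allclose(fit.p_values, exp["p"], rtol=1e-3)
        assert fit.theta_hat.var_subject == pytest.approx(exp["tau00"][0], rel=1e-4)
        assert fit.theta_hat.var_resid == pytest.approx(exp["sigma2"][0], rel=1e-4)
        assert fit.reml_criterion == pytest.approx(exp["reml_criterion"][0], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, default_dataset, default_config):
        """Runtime cross-check against an independent mixed-model fitter."""
        import statsmodels.formula.api as smf

        table, _ = default_dataset
        t = table.copy()
        t["ct"] = t.cognition * t.tertile
        t["pt"] = t.physical_challenges_w1 * t.tertile
        sm_fit = smf.mixedlm(
            "sbp_r ~ tertile + sbp_baseline + cognition + physical_challenges_w1 + ct + pt",
            t, groups=t["subject_id"]).fit(reml=True)
        design = build_design(table, default_config.model_spec())
        fit = fit_reml(design)
        np.testing.assert_allclose(fit.theta_hat.beta, sm_fit.fe_params.values, rtol=1e-5)
        assert fit.theta_hat.var_subject == pytest.approx(sm_fit.cov_re.values[0, 0],
                                                          rel=1e-3)
        assert fit.theta_hat.var_resid == pytest.approx(sm_fit.scale, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_criterion_at_optimum_beats_truth(self, seed):
        cfg = SyntheticConfig(seed=seed, n_subjects=20)
        table, truth = simulate_dataset(cfg)
        design = build_design(table, cfg.model_spec())
        fit = fit_reml(design)
        at_truth = reml_criterion(truth.var_subject, truth.var_resid, design)
        assert fit.reml_criterion >= at_truth - 1e-8

    def test_deterministic_and_permutation_invariant(self, default_design):
        fit1 = fit_reml(default_design)
        fit2 = fit_reml(default_design)
        np.testing.assert_array_equal(fit1.theta_hat.beta, fit2.theta_hat.beta)
        rng = np.random.default_rng(9)
        perm = rng.permutation(default_design.n)
        permuted = DesignRealization(
            y=default_design.y[perm], X=default_design.X[perm],
            group_index=default_design.group_index[perm],
            column_names=default_design.column_names)
        fit3 = fit_reml(permuted)
        np.testing.assert_allclose(fit3.theta_hat.beta, fit1.theta_hat.beta, rtol=1e-7)

    def test_parameter_recovery_at_large_n(self):
        cfg = SyntheticConfig(seed=77, n_subjects=200, missing_rate=0.0)
        table, truth = simulate_dataset(cfg)
        design = build_design(table, cfg.model_spec())
        fit = fit_reml(design)
        # 3 sigma on the coefficient standard errors
        np.testing.assert_array_less(
            np.abs(fit.theta_hat.beta - truth.beta), 3.5 * fit.se_beta)
        assert fit.theta_hat.var_subject == pytest.approx(truth.var_subject, rel=0.5)
        assert fit.theta_hat.var_resid == pytest.approx(truth.var_resid, rel=0.15)


class TestSatterthwaite:
    def test_no_between_subject_information_gives_residual_df(self):
        """Groups of size 1 carry no between/within split: tau00 hits the
        boundary and the tests collapse to ordinary regression df = n - p."""
        rng = np.random.default_rng(3)
        n = 40
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        design = DesignRealization(y=y, X=np.column_stack([np.ones(n), x]),
                                   group_index=np.arange(n),
                                   column_names=["intercept", "x"])
        fit = satterthwaite_tests(fit_reml(design), design)
        np.testing.assert_allclose(fit.satterthwaite_df, n - 2, rtol=0.15)

    def test_between_subject_covariate_df_near_subject_count(self):
        """Balanced design with a person-level covariate: its df is close to
        n_subjects - (number of between-subject coefficients)."""
        rng = np.random.default_rng(8)
        m, k = 30, 8
        z = rng.standard_normal(m)
        u = 2.0 * rng.standard_normal(m)
        y = (1.0 + 2.0 * np.repeat(z, k) + np.repeat(u, k)
             + 0.8 * rng.standard_normal(m * k))
        design = DesignRealization(
            y=y, X=np.column_stack([np.ones(m * k), np.repeat(z, k)]),
            group_index=np.repeat(np.arange(m), k),
            column_names=["intercept", "z"])
        fit = satterthwaite_tests(fit_reml(design), design)
        assert fit.satterthwaite_df[1] == pytest.approx(m - 2, rel=0.12)

    def test_p_values_in_unit_interval(self, default_design):
        fit = satterthwaite_tests(fit_reml(default_design), default_design)
        assert np.all((fit.p_values > 0) & (fit.p_values < 1))
        assert np.all(fit.satterthwaite_df > 0)


class TestVariancePartition:
    def test_shared_mean_iid_noise_gives_no_between_share(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame({
            "subject_id": np.repeat([f"s{i}" for i in range(30)], 10),
            "sbp_r": rng.standard_normal(300),
        })
        within, between, s2, t00 = variance_partition(table)
        assert between < 10.0
        assert within + between == pytest.approx(100.0)

    def test_equal_components_split_evenly(self):
        cfg = SyntheticConfig(seed=5, n_subjects=150, missing_rate=0.0,
                              beta={"intercept": 0.0}, tau00=50.0, sigma2=50.0)
        table, _ = simulate_dataset(cfg)
        within, between, *_ = variance_partition(table)
        assert within == pytest.approx(50.0, abs=8.0)


class TestSimpleSlopes:
    def _fit_with_beta(self, beta_focal, beta_int):
        """Model-1-like design over a moderator with between-person mean 0,
        SD 1; coefficient values injected to isolate the arithmetic."""
        subjects = [f"s{i}" for i in range(9)]
        mod = np.repeat([-1.0, 0.0, 1.0], 3)  # ddof=1 SD is exactly 1 for 9 values? no
        # use values with exact mean 0, sd(ddof=1)=1
        mod = np.array([-1.0, -1.0, -1.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        mod = mod / mod.std(ddof=1)
        rows = []
        for s, mval in zip(subjects, mod):
            for t in (1, 2, 3):
                rows.append({"subject_id": s, "tertile": t, "m": mval, "y": 0.0})
        table = pd.DataFrame(rows)
        rng = np.random.default_rng(0)
        table["y"] = rng.standard_normal(len(table))
        spec = ModelSpec(response="y", fixed_terms=("tertile", "m", "m:tertile"))
        design = build_design(table, spec)
        fit = satterthwaite_tests(fit_reml(design), design)
        beta = fit.theta_hat.beta.copy()
        beta[design.column_of(ModelTerm("tertile"))] = beta_focal
        beta[design.column_of(ModelTerm(("m", "tertile")))] = beta_int
        fit2 = FitResult(theta_hat=Theta(beta=beta,
                                         var_subject=fit.theta_hat.var_subject,
                                         var_resid=fit.theta_hat.var_resid),
                         cov_beta=fit.cov_beta, se_beta=fit.se_beta,
                         reml_criterion=fit.reml_criterion, converged=True,
                         column_names=fit.column_names, varcomp_cov=fit.varcomp_cov)
        return fit2, design

    def test_published_slope_pair_arithmetic(self):
        """beta_focal = -0.43, beta_int = 0.32, moderator mean 0 / SD 1 gives
        the published conditional-slope pair (-0.75, -0.11)."""
        fit, design = self._fit_with_beta(-0.43, 0.32)
        tbl = simple_slopes(fit, design, "tertile", "m")
        assert tbl.loc[tbl.at_sd == -1.0, "slope"].iloc[0] == pytest.approx(-0.75, abs=1e-9)
        assert tbl.loc[tbl.at_sd == 1.0, "slope"].iloc[0] == pytest.approx(-0.11, abs=1e-9)

    def test_zero_interaction_gives_equal_slopes(self):
        fit, design = self._fit_with_beta(-0.43, 0.0)
        tbl = simple_slopes(fit, design, "tertile", "m")
        np.testing.assert_allclose(tbl["slope"], -0.43)

    def test_missing_interaction_is_configuration_error(self, default_dataset):
        from fidlmm import ConfigurationError

        table, _ = default_dataset
        spec = ModelSpec(response="sbp_r", fixed_terms=("tertile", "cognition"))
        design = build_design(table, spec)
        fit = satterthwaite_tests(fit_reml(design), design)
        with pytest.raises(ConfigurationError):
            simple_slopes(fit, design, "tertile", "cognition")

    def test_sign_pattern_recovered_on_synthetic_interaction(self):
        """A strong generating cross-level interaction flips the conditional
        slope sign between low and high moderator values."""
        cfg = SyntheticConfig(
            seed=31, n_subjects=120, missing_rate=0.0,
            beta={"intercept": 0.0, "tertile": -1.0, "cognition": 0.0,
                  "cognition:tertile": 2.0})
        table, _ = simulate_dataset(cfg)
        design = build_design(table, cfg.model_spec())
        fit = satterthwaite_tests(fit_reml(design), design)
        tbl = simple_slopes(fit, design, "tertile", "cognition")
        low = tbl.loc[tbl.at_sd == -1.0, "slope"].iloc[0]
        high = tbl.loc[tbl.at_sd == 1.0, "slope"].iloc[0]
        assert low < 0 < high
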