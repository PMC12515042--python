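"""VIF screening, mixed-model fitting, AIC selection, bootstrap, partitioning."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cwpsoil as cw
from cwpsoil import drivers
from cwpsoil.stats import anderson_darling_normal


class TestVIF:
    def test_orthogonal_predictors_all_unity(self):
        n = 40
        X = pd.DataFrame(
            {
                "a": np.tile([1.0, -1.0], n // 2),
                "b": np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
                "c": np.tile([1.0, -1.0, -1.0, 1.0], n // 4),
            }
        )
        retained, report = cw.vif_filter(X, threshold=5.0)
        assert retained == ["a", "b", "c"]
        finals = report.dropna(subset=["vif_final"])["vif_final"]
        assert np.allclose(finals, 1.0)

    def test_correlation_09_closed_form(self):
        """r = 0.9 between two predictors: VIF = 1/(1-0.81) > 5, one dropped."""
        rng = np.random.default_rng(0)
        z = rng.normal(size=5000)
        x = z
        y = 0.9 * z + math.sqrt(1 - 0.81) * rng.normal(size=5000)
        X = pd.DataFrame({"x": x, "y": y})
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        vif = 1 / (1 - r2)
        assert vif == pytest.approx(1 / (1 - 0.81), rel=0.05)
        retained, _ = cw.vif_filter(X, threshold=5.0)
        assert len(retained) == 1

    def test_exact_copy_dropped_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"x": x, "copy": x.copy(), "z": rng.normal(size=50)})
        retained, report = cw.vif_filter(X, threshold=5.0)
        assert len(retained) == 2 and "z" in retained
        assert math.isinf(report.iloc[0]["vif"])


class TestFitLMM:
    def test_matches_statsmodels_oracle(self, grouped_regression):
        """Dual route: coefficients, variances and ML loglik vs MixedLM."""
        y, X, g = grouped_regression
        fit = cw.fit_lmm(y, X, g, method="REML")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(y, sm.add_constant(X), groups=g).fit(reml=True)
        assert np.allclose(fit.params.to_numpy(), ref.params.to_numpy()[:4], atol=1e-5)
        assert fit.sigma2_e == pytest.approx(ref.scale, rel=1e-4)
        assert fit.sigma2_u == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )
        fit_ml = cw.fit_lmm(y, X, g, method="ML")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref_ml = sm.MixedLM(y, sm.add_constant(X), groups=g).fit(reml=False)
        assert fit_ml.loglik == pytest.approx(ref_ml.llf, abs=1e-6)

    def test_noise_free_slope_exact(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = pd.Series(2.0 * X["x"].to_numpy())
        g = pd.Series(np.repeat(list("abcdef"), 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cw.fit_lmm(y, X, g)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-8)
        assert fit.r2m == pytest.approx(1.0, abs=1e-8)
        assert fit.r2c == pytest.approx(1.0, abs=1e-8)

    def test_pure_group_offsets(self):
        """No fixed signal: R2m ~ 0, R2c ~ group-variance share."""
        rng = np.random.default_rng(3)
        g = pd.Series(np.repeat([f"g{i}" for i in range(10)], 20))
        offsets = rng.normal(0, 2.0, 10)
        y = pd.Series(offsets[pd.factorize(g)[0]] + rng.normal(0, 0.3, 200))
        X = pd.DataFrame({"x": rng.normal(size=200)})
        fit = cw.fit_lmm(y, X, g)
        assert fit.r2m < 0.02
        assert fit.r2c > 0.9

    def test_slope_recovery_within_3se(self):
        """Planted beta = 0.5 at n = 125 recovered within 3 SE (20 seeds)."""
        hits = 0
        for seed in range(20):
            sites, truth = cw.simulate_sites(125, 10, 4, seed=seed)
            env = cw.simulate_environment(sites, truth, 8, 0.5, 0.0, seed=seed)
            Xs = drivers.standardize(env[["pH"]])
            y = cw.simulate_module_response(
                truth, Xs, sites, {"pH": 0.5}, 0.5, 0.5, seed=seed
            )
            fit = cw.fit_lmm(y, Xs, sites["cwp_species"])
            if abs(fit.params["pH"] - 0.5) <= 3 * fit.se["pH"]:
                hits += 1
        assert hits >= 19

    def test_standardization_invariance_of_r2(self, grouped_regression):
        y, X, g = grouped_regression
        fit_raw = cw.fit_lmm(y, 3.0 * X + 7.0, g)
        fit_std = cw.fit_lmm(y, drivers.standardize(X), g)
        assert fit_raw.r2m == pytest.approx(fit_std.r2m, abs=1e-6)
        assert fit_raw.r2c == pytest.approx(fit_std.r2c, abs=1e-6)


class TestBackwardAIC:
    def test_strong_kept_noise_dropped(self):
        kept_strong, dropped_noise = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            g = pd.Series(np.repeat([f"g{i}" for i in range(10)], 12))
            X = pd.DataFrame(
                {"strong": rng.normal(size=120), "noise": rng.normal(size=120)}
            )
            y = pd.Series(
                1.0 * X["strong"].to_numpy()
                + rng.normal(0, 0.5, 10)[pd.factorize(g)[0]]
                + rng.normal(0, 0.5, 120)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit, _ = cw.backward_aic(y, X, g)
            if "strong" in fit.fixed.columns:
                kept_strong += 1
            if "noise" not in fit.fixed.columns:
                dropped_noise += 1
        assert kept_strong == n_seeds
        # a pure-noise term survives AIC elimination with P(chi2_1 > 2) ~ 0.157,
        # so the expected drop rate is ~84%
        assert dropped_noise >= 0.75 * n_seeds

    def test_null_model_reached_majority(self):
        """All-noise candidates: intercept-only endpoint in most seeds."""
        nulls = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            g = pd.Series(np.repeat([f"g{i}" for i in range(10)], 12))
            X = pd.DataFrame({"a": rng.normal(size=120)})
            y = pd.Series(rng.normal(0, 1.0, 120))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit, trace = cw.backward_aic(y, X, g)
            if len(fit.fixed.columns) == 0:
                nulls += 1
        assert nulls >= 0.8 * n_seeds

    def test_trace_records_monotone_aic(self, grouped_regression):
        y, X, g = grouped_regression
        X = X.copy()
        X["noise"] = np.random.default_rng(9).normal(size=len(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, trace = cw.backward_aic(y, X, g)
        aics = trace["aic"].to_numpy()
        assert (np.diff(aics) < 0).all()
        assert fit.method == "REML"


class TestBootstrap:
    def test_deterministic_given_seed(self, grouped_regression):
        y, X, g = grouped_regression
        fit = cw.fit_lmm(y, X, g)
        a = cw.bootstrap_ci(fit, n_boot=50, seed=5)
        b = cw.bootstrap_ci(fit, n_boot=50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_fit_zero_width(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = pd.Series(1.5 * X["x"].to_numpy())
        g = pd.Series(np.repeat(list("abcd"), 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cw.fit_lmm(y, X, g)
            ci = cw.bootstrap_ci(fit, n_boot=50, seed=0)
        assert ci.loc["x", "ci_upper"] - ci.loc["x", "ci_lower"] < 1e-6

    def test_interval_brackets_estimate(self, grouped_regression):
        y, X, g = grouped_regression
        fit = cw.fit_lmm(y, X, g)
        ci = cw.bootstrap_ci(fit, n_boot=200, seed=7)
        assert (ci["ci_lower"] <= ci["estimate"] + 1e-9).all()
        assert (ci["ci_upper"] >= ci["estimate"] - 1e-9).all()


class TestPartitionR2:
    def test_single_group_total_is_full_r2m(self, grouped_regression):
        y, X, g = grouped_regression
        part = cw.partition_r2(y, X, g, {"all": list(X.columns)})
        assert part.iloc[0]["total"] == pytest.approx(part.attrs["r2m_full"], abs=1e-9)
        assert part.iloc[0]["shared"] == pytest.approx(0.0, abs=1e-9)

    def test_totals_sum_to_full_r2m(self, grouped_regression):
        y, X, g = grouped_regression
        part = cw.partition_r2(
            y, X, g, {"soil": ["pH", "sand"], "climate": ["MAT"]}
        )
        assert part["total"].sum() == pytest.approx(part.attrs["r2m_full"], abs=1e-6)

    def test_orthogonal_groups_share_nothing(self):
        n = 240
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        rng = np.random.default_rng(5)
        g = pd.Series(np.repeat([f"g{i}" for i in range(8)], n // 8))
        X = pd.DataFrame({"a": a, "b": b})
        y = pd.Series(0.8 * a + 0.5 * b + rng.normal(0, 0.5, n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = cw.partition_r2(y, X, g, {"ga": ["a"], "gb": ["b"]})
        assert abs(part.set_index("group").loc["ga", "shared"]) < 0.02
        assert abs(part.set_index("group").loc["gb", "shared"]) < 0.02

    def test_matches_brute_force_ordering_average(self, grouped_regression):
        """3 groups: totals equal the mean increment over all 3! orderings."""
        y, X, g = grouped_regression
        groups = {"g1": ["pH"], "g2": ["MAT"], "g3": ["sand"]}
        part = cw.partition_r2(y, X, g, groups).set_index("group")

        def r2m(cols):
            return cw.fit_lmm(y, X[cols], g).r2m

        names = list(groups)
        totals = {n: 0.0 for n in names}
        orderings = list(itertools.permutations(names))
        for order in orderings:
            have: list[str] = []
            for gname in order:
                before = r2m([c for n in have for c in groups[n]])
                have.append(gname)
                after = r2m([c for n in have for c in groups[n]])
                totals[gname] += (after - before) / len(orderings)
        for n in names:
            assert part.loc[n, "total"] == pytest.approx(totals[n], abs=1e-8)

    def test_unassigned_predictor_rejected(self, grouped_regression):
        y, X, g = grouped_regression
        with pytest.raises(ValueError):
            cw.partition_r2(y, X, g, {"soil": ["pH"]})


class TestResidualNormality:
    def test_statistic_matches_direct_formula(self):
        """A2 on a fixed vector vs the textbook sum, computed independently."""
        x = np.array([1.1, 0.3, -0.8, 2.2, -1.5, 0.9, 0.1, -0.4, 1.7, -2.0])
        a2, p = anderson_darling_normal(x)
        from scipy.stats import norm

        xs = np.sort(x)
        z = (xs - xs.mean()) / xs.std(ddof=1)
        n = len(z)
        s = 0.0
        for i in range(1, n + 1):
            s += (2 * i - 1) * (
                math.log(norm.cdf(z[i - 1])) + math.log(1 - norm.cdf(z[n - i]))
            )
        expected = -n - s / n
        assert a2 == pytest.approx(expected, rel=1e-10)
        assert 0 < p <= 1

    def test_matches_scipy_statistic(self):
        from scipy.stats import anderson

        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        a2, _ = anderson_darling_normal(x)
        assert a2 == pytest.approx(anderson(x, dist="norm").statistic, rel=1e-8)

    def test_heavy_tails_rejected_often(self):
        """t(2) residuals at n=500: rejection in >= 80% of seeds."""
        rejections = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            x = rng.standard_t(2, size=500)
            _, p = anderson_darling_normal(x)
            if p < 0.05:
                rejections += 1
        assert rejections >= 0.8 * n_seeds

    def test_too_few_residuals_rejected(self, grouped_regression):
        y, X, g = grouped_regression
        idx = [0, 1, 2, 3, 12, 13, 14]  # 7 rows across 2 groups
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cw.fit_lmm(
                y.iloc[idx].reset_index(drop=True),
                X.iloc[idx].reset_index(drop=True)[["pH"]],
                g.iloc[idx].reset_index(drop=True),
            )
        with pytest.raises(ValueError):
            cw.residual_normality(fit)
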