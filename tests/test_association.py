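"""OLS, model comparison, Spearman, and PGLS with Pagel's lambda."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sdbias import (
    ComparativeSimSpec,
    compare_models,
    fit_ols,
    pgls_fit,
    simulate_tree_and_traits,
    spearman_correlation,
)


def _series(values, name="x"):
    return pd.Series(values, name=name)


class TestOLS:
    def test_exact_fit_recovers_coefficients(self):
        x = _series(np.arange(10.0))
        y = 2.0 * x + 1.0
        res = fit_ols(y.rename("y"), x.to_frame())
        assert res.coefficients["x"][0] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["const"][0] == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        # x = 0,1,2; y = 0,1,4 → slope 2, intercept −1/3 by normal equations
        res = fit_ols(_series([0.0, 1.0, 4.0], "y"),
                      _series([0.0, 1.0, 2.0], "x").to_frame())
        assert res.coefficients["x"][0] == pytest.approx(2.0, abs=1e-12)
        assert res.coefficients["const"][0] == pytest.approx(-1 / 3, abs=1e-12)

    def test_independent_response_has_null_r2_adj(self):
        rng = np.random.default_rng(0)
        r2s = [
            fit_ols(
                _series(rng.normal(size=1000), "y"),
                _series(rng.normal(size=1000), "x").to_frame(),
            ).r2_adj
            for _ in range(20)
        ]
        assert abs(np.mean(r2s)) < 0.01

    def test_missing_rows_dropped(self):
        y = _series([1.0, 2.0, np.nan, 4.0, 5.0, 6.0], "y")
        x = _series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "x")
        res = fit_ols(y, x.to_frame())
        assert res.n_obs == 5

    def test_collinear_design_rejected(self):
        x = _series(np.arange(10.0), "x")
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_ols((3 * x).rename("y"), X)


class TestModelComparison:
    def _fits(self, seed=1, n=300, beta2=0.0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = pd.Series(x1 + beta2 * x2 + rng.normal(size=n), name="y")
        X = pd.DataFrame({"x1": x1, "x2": x2})
        base = fit_ols(y, X[["x1"]])
        full = fit_ols(y, X)
        return base, full

    def test_identical_models_zero_deltas(self):
        base, _ = self._fits()
        cmp = compare_models(base, base)
        assert cmp.delta_aic == 0 and cmp.delta_bic == 0 and cmp.delta_r2_adj == 0

    def test_noise_predictor_penalized(self):
        worse = 0
        for seed in range(30):
            base, full = self._fits(seed=seed, beta2=0.0)
            if compare_models(base, full).delta_aic > 0:
                worse += 1
        assert worse > 15  # penalty dominates in the majority of null fits

    def test_real_effect_preferred(self):
        base, full = self._fits(seed=3, beta2=0.8)
        cmp = compare_models(base, full)
        assert cmp.delta_aic < 0 and cmp.delta_r2_adj > 0

    def test_nested_equal_rss_larger_model_penalized(self):
        # duplicate-information predictor leaves RSS unchanged up to
        # numerical noise, so AIC/BIC must rise with the extra parameter
        base, full = self._fits(seed=4, beta2=0.0)
        assert full.aic > base.aic - 2.1  # k increased by 1: max gain bounded

    def test_mismatched_observations_refused(self):
        base, _ = self._fits(seed=5)
        other, _ = self._fits(seed=5, n=200)
        with pytest.raises(ValueError, match="different observation sets"):
            compare_models(base, other)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(50.0)
        assert spearman_correlation(x, np.exp(x / 10))[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -x**3)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        rho, _ = spearman_correlation(x, y)
        oracle = np.corrcoef(scipy.stats.rankdata(x), scipy.stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


@pytest.fixture(scope="module")
def sim():
    spec = ComparativeSimSpec(n_tips=40, lambda_true=0.7, slope_true=0.06,
                              seed=12)
    newick, traits = simulate_tree_and_traits(spec)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    t = traits.set_index("species_id")
    return tree, t["log_doubling_time"], t[["b_sd_percent"]]


class TestPGLS:
    def test_lambda_zero_matches_ols(self, sim):
        tree, y, X = sim
        res = pgls_fit(tree, y, X, lambda_value=0.0)
        ols = fit_ols(y, X)
        for name in res.coefficients:
            assert res.coefficients[name][0] == pytest.approx(
                ols.coefficients[name][0], rel=1e-6
            )

    def test_star_tree_matches_ols_any_lambda(self, sim):
        _, y, X = sim
        star = dendropy.Tree.get(
            data="(" + ",".join(f"{t}:1.0" for t in y.index) + ");",
            schema="newick",
        )
        ols = fit_ols(y, X)
        for lam in (0.0, 0.5, 1.0):
            res = pgls_fit(star, y, X, lambda_value=lam)
            assert res.coefficients["b_sd_percent"][0] == pytest.approx(
                ols.coefficients["b_sd_percent"][0], rel=1e-8
            )

    def test_lambda_hat_maximizes_profile_likelihood(self, sim):
        tree, y, X = sim
        res = pgls_fit(tree, y, X)
        assert 0.0 <= res.lambda_hat <= 1.0
        for lam in np.linspace(0, 1, 11):
            fixed = pgls_fit(tree, y, X, lambda_value=float(lam))
            assert res.log_likelihood >= fixed.log_likelihood - 1e-6

    def test_unmatched_taxa_rejected(self, sim):
        tree, y, X = sim
        y2 = y.rename(index={y.index[0]: "NOT_A_TIP"})
        with pytest.raises(ValueError, match="NOT_A_TIP"):
            pgls_fit(tree, y2, X.rename(index={X.index[0]: "NOT_A_TIP"}))

    def test_agrees_with_r_nlme_gls_at_fixed_lambda(self, sim, tmp_path):
        """Dual-route check: same GLS fit via R's ape/nlme corPagel."""
        tree, y, X = sim
        res = pgls_fit(tree, y, X)
        tree_file = tmp_path / "tree.nwk"
        tree_file.write_text(tree.as_string(schema="newick"))
        data = pd.concat([y, X], axis=1)
        data_file = tmp_path / "traits.csv"
        data.rename_axis("species_id").to_csv(data_file)
        script = textwrap.dedent(f"""
            suppressMessages({{library(ape); library(nlme)}})
            tree <- read.tree("{tree_file}")
            tr <- read.csv("{data_file}")
            rownames(tr) <- tr$species_id
            tr <- tr[tree$tip.label,]
            fit <- gls(log_doubling_time ~ b_sd_percent, data=tr,
                       correlation=corPagel({res.lambda_hat}, phy=tree,
                                            form=~1, fixed=TRUE),
                       method="ML")
            cat(coef(fit)[2], as.numeric(logLik(fit)), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True,
            check=True,
        )
        r_slope, r_loglik = (float(v) for v in out.stdout.strip().split())
        assert res.coefficients["b_sd_percent"][0] == pytest.approx(r_slope, rel=1e-5)
        assert res.log_likelihood == pytest.approx(r_loglik, abs=1e-4)
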