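import numpy as np
import pandas as pd
import pytest

from dyadnirs.bayes import (
    LmeDesign,
    McmcSettings,
    build_design,
    check_convergence,
    fit_bivariate_correlation,
    fit_gibbs,
    hdi,
    pmcmc,
    successive_difference_contrasts,
    summarize_effect,
)
from dyadnirs.simulate import crossed_outcome_table, generate_lme_dataset


def _simple_design(n_groups=40, per_group=10, seed=0):
    rng = np.random.default_rng(seed)
    codes = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(codes.size), rng.standard_normal(codes.size)])
    return X, codes


class TestBuildDesign:
    def test_model5_column_count_matches_contrast_combinatorics(self):
        # intercept + phase(2) + difficulty(2) + phase:difficulty(4)
        # + experience treatment dummies(3)
        df = crossed_outcome_table(25, seed=0).assign(value=0.0)
        design = build_design(5, df, "value")
        assert design.X.shape[1] == 1 + 2 + 2 + 4 + 3
        assert set(design.groups) == {"team", "scenario"}

    def test_model1_has_three_random_blocks(self):
        df = crossed_outcome_table(25, seed=0).assign(value=0.0)
        design = build_design(1, df, "value")
        assert set(design.groups) == {"participant", "team", "scenario"}
        # phase(2)+role(1)+difficulty(2), all interactions, + experience
        assert design.X.shape[1] == 1 + (2 + 1 + 2) + (2 + 4 + 2) + 4 + 3

    def test_single_level_factor_collapses_with_warning(self):
        df = crossed_outcome_table(25, seed=0).assign(value=0.0)
        df["difficulty"] = "low"
        with pytest.warns(UserWarning, match="single level"):
            design = build_design(5, df, "value")
        assert not any("difficulty" in n for n in design.coef_names)

    def test_empty_cell_raises_rank_error(self):
        df = crossed_outcome_table(25, seed=0).assign(value=0.0)
        df = df[~((df.phase == "team") & (df.difficulty == "high"))]
        with pytest.raises(ValueError, match="rank"):
            build_design(5, df, "value")

    def test_successive_difference_contrasts_estimate_adjacent_gaps(self):
        C = successive_difference_contrasts(3)
        means = np.array([1.0, 4.0, 9.0])
        # regression of cell means on [1 | C] recovers adjacent differences
        M = np.column_stack([np.ones(3), C])
        coef = np.linalg.solve(M, means)
        assert coef[1] == pytest.approx(3.0)  # level2 - level1
        assert coef[2] == pytest.approx(5.0)  # level3 - level2


class TestGibbs:
    def test_default_settings_retain_exactly_1000_draws(self):
        X, codes = _simple_design(10, 5)
        design = LmeDesign(None, "y", X, ["b0", "b1"], {"g": codes})
        y = np.random.default_rng(0).standard_normal(codes.size)
        samples = fit_gibbs(y, design, McmcSettings(seed=1))
        assert samples.n_draws == 1000

    def test_same_seed_bit_identical(self):
        X, codes = _simple_design(10, 5)
        design = LmeDesign(None, "y", X, ["b0", "b1"], {"g": codes})
        y = np.random.default_rng(0).standard_normal(codes.size)
        s1 = fit_gibbs(y, design, McmcSettings(seed=42))
        s2 = fit_gibbs(y, design, McmcSettings(seed=42))
        np.testing.assert_array_equal(s1.draws.to_numpy(), s2.draws.to_numpy())

    def test_recovers_simulation_truth_and_matches_reml(self):
        import statsmodels.formula.api as smf

        X, codes = _simple_design(40, 10, seed=1)
        data = generate_lme_dataset(X, {"g": codes}, [2.0, -1.0], {"g": 1.0},
                                    1.0, seed=2)
        design = LmeDesign(None, "y", X, ["b0", "b1"], {"g": codes})
        samples = fit_gibbs(data["y"], design, McmcSettings(seed=3))
        for name, truth in [("b0", 2.0), ("b1", -1.0)]:
            d = samples[name]
            assert abs(d.mean() - truth) <= 3 * d.std()

        df = pd.DataFrame({"y": data["y"], "x": X[:, 1], "g": codes})
        reml = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
        assert samples["b0"].mean() == pytest.approx(
            float(reml.params["Intercept"]), rel=0.10)
        assert samples["b1"].mean() == pytest.approx(
            float(reml.params["x"]), rel=0.10)
        assert samples["sigma2_resid"].mean() == pytest.approx(
            float(reml.scale), rel=0.10)

    def test_posterior_mean_approaches_ols_without_random_effects(self):
        rng = np.random.default_rng(5)
        n = 1000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        design = LmeDesign(None, "y", X, ["b0", "b1"], {})
        samples = fit_gibbs(y, design, McmcSettings(seed=6))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert samples["b0"].mean() == pytest.approx(ols[0], rel=0.01)
        assert samples["b1"].mean() == pytest.approx(ols[1], rel=0.01)

    def test_variance_draws_positive(self):
        X, codes = _simple_design(10, 5)
        design = LmeDesign(None, "y", X, ["b0", "b1"], {"g": codes})
        y = np.random.default_rng(0).standard_normal(codes.size)
        samples = fit_gibbs(y, design, McmcSettings(seed=1))
        assert (samples["sigma2_g"] > 0).all()
        assert (samples["sigma2_resid"] > 0).all()

    def test_convergence_diagnostics_pass_on_clean_fit(self):
        X, codes = _simple_design(40, 10, seed=1)
        data = generate_lme_dataset(X, {"g": codes}, [2.0, -1.0], {"g": 1.0},
                                    1.0, seed=2)
        design = LmeDesign(None, "y", X, ["b0", "b1"], {"g": codes})
        samples = fit_gibbs(data["y"], design, McmcSettings(seed=3))
        flags = check_convergence(samples)
        assert flags["b0"] and flags["b1"]


class TestSummaries:
    def test_pmcmc_floored_when_all_draws_share_sign(self):
        assert pmcmc(np.arange(1, 1001, dtype=float)) == pytest.approx(0.002)

    def test_pmcmc_symmetric_draws_not_significant(self, rng):
        draws = np.concatenate([rng.standard_normal(500),
                                -rng.standard_normal(500)])
        assert pmcmc(draws) > 0.9

    def test_hdi_equals_bruteforce_shortest_window(self, rng):
        for draws in [np.arange(1, 1001, dtype=float),
                      rng.standard_normal(500),
                      rng.exponential(size=700)]:
            x = np.sort(draws)
            n = x.size
            m = int(np.ceil(0.95 * n))
            best = min(
                ((x[i + m - 1] - x[i], (x[i], x[i + m - 1]))
                 for i in range(n - m + 1)),
                key=lambda t: t[0],
            )[1]
            lo, hi = hdi(draws)
            assert (lo, hi) == pytest.approx(best)

    def test_effect_summary_significance_rule(self, rng):
        from dyadnirs.bayes import PosteriorSamples

        pos = PosteriorSamples(pd.DataFrame({"b": rng.normal(5, 0.5, 1000)}))
        s = summarize_effect(pos, "b")
        assert s.significant and s.hdi95[0] <= s.b <= s.hdi95[1]
        sym = PosteriorSamples(pd.DataFrame({"b": rng.normal(0, 1, 1000)}))
        assert not summarize_effect(sym, "b").significant


class TestBivariate:
    def _design(self, n=200, n_groups=20):
        codes = np.repeat(np.arange(n_groups), n // n_groups)
        X = np.ones((n, 1))
        return LmeDesign(None, "y", X, ["b0"], {"g": codes}), codes

    def test_identical_responses_give_correlation_one(self, rng):
        design, codes = self._design()
        y = rng.standard_normal(200) + 0.5 * rng.standard_normal(20)[codes]
        out = fit_bivariate_correlation(y, y.copy(), design, McmcSettings(seed=1))
        assert out.r >= 0.99 and out.significant

    def test_recovers_known_residual_correlation(self, rng):
        design, codes = self._design()
        u = rng.standard_normal(20)
        e = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=200)
        y1 = 1.0 + u[codes] + e[:, 0]
        y2 = -0.5 + 0.7 * u[codes] + e[:, 1]
        out = fit_bivariate_correlation(y1, y2, design, McmcSettings(seed=2))
        assert out.hdi95[0] <= 0.6 + 0.12 and out.hdi95[1] >= 0.6 - 0.12

    def test_independent_responses_usually_not_significant(self, rng):
        design, codes = self._design()
        hits = 0
        for k in range(10):
            y1 = rng.standard_normal(200)
            y2 = rng.standard_normal(200)
            out = fit_bivariate_correlation(
                y1, y2, design,
                McmcSettings(iterations=2600, burnin=600, thin=2, seed=k))
            hits += out.significant
        assert hits <= 2

    def test_too_few_pairs_rejected(self):
        design, _ = self._design()
        y = np.full(200, np.nan)
        y[:5] = 1.0
        with pytest.raises(ValueError, match="10 complete"):
            fit_bivariate_correlation(y, y, design)
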