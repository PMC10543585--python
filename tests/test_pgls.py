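"""PGLS engine: GLS core, lambda profiling, effect sizes, AIC ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloconverge import (
    PGLSFit,
    SyntheticScenario,
    bm_covariance,
    effect_size_from_intercept,
    fit_additive_model,
    gls_fit,
    lambda_transform,
    make_synthetic_study,
    profile_lambda_ml,
    rank_models,
    simulate_bm,
    simulate_tree,
)


def _random_instance(rng, n=20, p=3):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n)
    A = rng.standard_normal((n, n))
    C = A @ A.T + n * np.eye(n)
    return y, X, C


class TestGLS:
    def test_identity_covariance_equals_ols(self, rng):
        for _ in range(100):
            y, X, _ = _random_instance(rng)
            fit = gls_fit(y, X, np.eye(len(y)))
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.allclose(fit.coef, beta_ols, rtol=1e-8)

    def test_perfect_line(self):
        fit = gls_fit([1, 2, 3], np.column_stack([np.ones(3), [1, 2, 3]]), np.eye(3))
        assert fit.coef == pytest.approx([0.0, 1.0], abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_whitening_oracle(self, rng):
        """Explicit Cholesky-whitened OLS reproduces coefficients, SEs, loglik."""
        for _ in range(100):
            y, X, C = _random_instance(rng, n=rng.integers(8, 30))
            fit = gls_fit(y, X, C)
            Li = np.linalg.inv(np.linalg.cholesky(C))
            yw, Xw = Li @ y, Li @ X
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            rss = float(((yw - Xw @ beta) ** 2).sum())
            n, p = Xw.shape
            ll = -0.5 * (
                n * (np.log(2 * np.pi * rss / n) + 1) + np.linalg.slogdet(C)[1]
            )
            se = np.sqrt(np.diag(rss / (n - p) * np.linalg.inv(Xw.T @ Xw)))
            assert np.allclose(fit.coef, beta, rtol=1e-8)
            assert np.allclose(fit.se, se, rtol=1e-8)
            assert fit.log_likelihood == pytest.approx(ll, rel=1e-8)

    def test_singular_covariance_diagnostic(self):
        C = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            gls_fit([1.0, 2.0, 3.0], np.ones((3, 1)), C)

    def test_rank_deficient_design(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            gls_fit(np.arange(5.0), X, np.eye(5))


class TestLambdaProfile:
    def test_grid_never_beats_optimum(self, tree17, rng):
        cov = bm_covariance(tree17)
        for _ in range(5):
            y = simulate_bm(tree17, 0.01, seed=rng).to_numpy()
            x = simulate_bm(tree17, 0.01, seed=rng).to_numpy()
            X = np.column_stack([np.ones_like(x), x])
            fit = profile_lambda_ml(y, X, tree17)
            best_grid = max(
                gls_fit(y, X, lambda_transform(cov, g)).log_likelihood
                for g in np.linspace(0, 1, 101)
            )
            assert fit.log_likelihood >= best_grid - 1e-6

    def test_bm_data_recovers_high_lambda(self, tree64):
        lams = []
        for seed in range(60):
            y = simulate_bm(tree64, 1.0, seed=seed).to_numpy()
            x = np.ones((64, 1))
            lams.append(profile_lambda_ml(y, x, tree64).lambda_hat)
        assert np.median(lams) >= 0.9

    def test_permuted_data_drives_lambda_to_zero(self, tree64):
        rng = np.random.default_rng(0)
        lams = []
        for seed in range(60):
            y = simulate_bm(tree64, 1.0, seed=seed).to_numpy()
            rng.shuffle(y)
            lams.append(profile_lambda_ml(y, np.ones((64, 1)), tree64).lambda_hat)
        assert np.median(lams) <= 0.1

    def test_aic_counts_sigma_and_lambda(self, tree17):
        y = simulate_bm(tree17, 0.01, seed=3).to_numpy()
        fit = profile_lambda_ml(y, np.ones((17, 1)), tree17)
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.log_likelihood)


class TestEffectSize:
    def test_zero_delta(self):
        assert effect_size_from_intercept(0.0).effect_pct == 0.0

    def test_positive_shift_backtransform(self):
        eff = effect_size_from_intercept(0.353, 1.0)
        assert eff.effect_pct == pytest.approx(42.34, abs=0.01)

    def test_negative_shift_backtransform(self):
        eff = effect_size_from_intercept(-0.298, 1.0)
        assert eff.effect_pct == pytest.approx(-25.77, abs=0.01)

    def test_max_value_scaling(self):
        eff = effect_size_from_intercept(0.1, 5.0)
        assert eff.adjusted_intercept == pytest.approx(0.5)
        assert eff.effect_pct == pytest.approx(100 * (np.exp(0.5) - 1))

    @settings(max_examples=100, deadline=None)
    @given(
        d1=st.floats(min_value=-2, max_value=2),
        d2=st.floats(min_value=-2, max_value=2),
    )
    def test_strictly_monotone_in_delta(self, d1, d2):
        e1 = effect_size_from_intercept(d1).effect_pct
        e2 = effect_size_from_intercept(d2).effect_pct
        assert (e1 < e2) == (d1 < d2) or d1 == d2

    def test_inverts_multiplicative_inflation(self):
        # a (1+e)-fold volume inflation in focal species appears as
        # delta = log(1+e) and back-transforms to exactly 100*e
        for e in (0.1, 0.42, -0.26):
            eff = effect_size_from_intercept(np.log1p(e))
            assert eff.effect_pct == pytest.approx(100 * e, rel=1e-12)


class TestAdditiveModel:
    def test_constant_group_inestimable(self, table17, tree17):
        table = table17
        bad = table.data.copy()
        bad["elicit_care"] = 0
        bad["cooperative_breeder"] = 0
        from phyloconverge import TraitTable

        with pytest.raises(ValueError, match="constant"):
            fit_additive_model(TraitTable(bad), tree17, "L", "BLA", "elicit_care")

    def test_recovers_injected_shifts(self):
        deltas_l, deltas_b = [], []
        for seed in range(30):
            table, tree = make_synthetic_study(SyntheticScenario(seed=1000 + seed))
            fit_l, _ = fit_additive_model(table, tree, "L", "BLA", "elicit_care")
            fit_b, _ = fit_additive_model(table, tree, "B", "BLA", "elicit_care")
            deltas_l.append(fit_l.intercept_difference)
            deltas_b.append(fit_b.intercept_difference)
        assert np.mean(deltas_l) == pytest.approx(0.353, abs=0.05)
        assert np.mean(deltas_b) == pytest.approx(-0.298, abs=0.05)

    def test_nonsignificant_effect_reported_zero(self):
        table, tree = make_synthetic_study(
            SyntheticScenario(seed=5, shift_l=0.0, shift_b=0.0, sd_resid=0.3,
                              frac_l=0.2, frac_b=0.3)
        )
        fit, eff = fit_additive_model(table, tree, "AB", "BLA", "elicit_care")
        if fit.p_value_group >= 0.05:
            assert eff.effect_pct == 0.0
            assert eff.intercept_difference == pytest.approx(fit.intercept_difference)

    def test_strong_allometry_r_squared(self, table17, tree17):
        fit, _ = fit_additive_model(table17, tree17, "L", "BLA", "elicit_care")
        assert fit.r_squared >= 0.97


class TestRankModels:
    @staticmethod
    def _fit(aic, resp="L"):
        return PGLSFit(resp, "BLA", "g", np.zeros(3), 1.0, 0.0, aic, 0.99, 0.01, 17)

    def test_clear_best(self):
        cmp = rank_models([self._fit(100), self._fit(103), self._fit(104)])
        assert cmp.labels == ["Best", "No", "No"]

    def test_tied(self):
        cmp = rank_models([self._fit(100), self._fit(101.5), self._fit(104)])
        assert cmp.labels == ["Tied", "Tied", "No"]

    def test_single_model(self):
        assert rank_models([self._fit(42)]).labels == ["Best"]

    def test_mixed_responses_rejected(self):
        with pytest.raises(ValueError):
            rank_models([self._fit(1, "L"), self._fit(2, "B")])
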