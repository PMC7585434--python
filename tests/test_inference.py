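import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from stabscale import (
    PathModelSpec,
    anova_effects,
    climate_residualize,
    log_response_ratio,
    meta_combine,
    overlapping_windows,
    slope_with_ar1,
    standardized_path_fit,
    treatment_difference_q,
)
from stabscale.exceptions import DegenerateInputError, ValidationError

from .oracles import normal_equation_fit


def _metrics_frame(rng, n=40):
    richness = rng.normal(10, 2, n)
    beta = rng.normal(1.5, 0.2, n)
    sp_as = 0.4 * richness + rng.normal(0, 1, n)
    sp_st = rng.normal(0, 1, n)
    alpha = 0.5 * sp_st + 0.5 * sp_as + rng.normal(0, 1, n)
    spat = 0.6 * beta + rng.normal(0, 0.3, n)
    gamma = alpha + spat + rng.normal(0, 0.5, n)
    return pd.DataFrame(
        {
            "richness": richness,
            "beta_diversity": beta,
            "species_stability": sp_st,
            "species_asynchrony": sp_as,
            "alpha_stability": alpha,
            "spatial_asynchrony": spat,
            "gamma_stability": gamma,
        }
    )


class TestStandardizedPathFit:
    def test_perfect_single_predictor(self, rng):
        df = _metrics_frame(rng, 10)
        df["species_stability"] = 2.0 * df["richness"]
        fit = standardized_path_fit(df)
        assert fit.coef("richness->species_stability") == pytest.approx(1.0)
        assert fit.r_squared["species_stability"] == pytest.approx(1.0)

    def test_single_predictor_equals_pearson(self, rng):
        df = _metrics_frame(rng)
        fit = standardized_path_fit(df)
        r = scipy.stats.pearsonr(df.richness, df.species_asynchrony).statistic
        assert fit.coef("richness->species_asynchrony") == pytest.approx(
            r, abs=1e-12
        )

    def test_two_predictor_matches_normal_equations(self, rng):
        df = _metrics_frame(rng, 8)
        fit = standardized_path_fit(df)
        coefs, ses = normal_equation_fit(
            df["alpha_stability"],
            [df["species_stability"], df["species_asynchrony"]],
        )
        assert fit.coef("species_stability->alpha_stability") == pytest.approx(
            coefs[0], abs=1e-10
        )
        assert fit.coef("species_asynchrony->alpha_stability") == pytest.approx(
            coefs[1], abs=1e-10
        )
        assert fit.se("species_stability->alpha_stability") == pytest.approx(
            ses[0], abs=1e-10
        )

    def test_zero_variance_names_variable(self, rng):
        df = _metrics_frame(rng)
        df["beta_diversity"] = 1.0
        with pytest.raises(DegenerateInputError, match="beta_diversity"):
            standardized_path_fit(df)

    def test_exogenous_correlation_reported(self, rng):
        df = _metrics_frame(rng)
        fit = standardized_path_fit(df)
        r = scipy.stats.pearsonr(df.richness, df.beta_diversity).statistic
        assert fit.exogenous_correlation == pytest.approx(r, abs=1e-12)

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValidationError):
            PathModelSpec(paths=(("a", ("b",)), ("b", ("a",))))


class TestMetaCombine:
    def test_closed_form_pooling(self):
        me = meta_combine([(0.2, 0.1), (0.4, 0.1)])
        assert me.pooled == pytest.approx(0.3, abs=1e-12)
        assert me.se == pytest.approx(0.070711, abs=1e-6)

    def test_identical_estimates_zero_heterogeneity(self):
        me = meta_combine([(0.25, 0.08)] * 3)
        assert me.pooled == pytest.approx(0.25)
        assert me.q_heterogeneity == pytest.approx(0.0, abs=1e-12)
        assert me.tau_squared == 0.0

    def test_equal_weights_give_mean_and_sqrt_k_shrinkage(self, rng):
        coefs = rng.normal(0.3, 0.02, 6)
        me = meta_combine([(c, 0.1) for c in coefs])
        assert me.pooled == pytest.approx(coefs.mean(), abs=1e-12)
        assert me.se == pytest.approx(0.1 / math.sqrt(6), abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            meta_combine([(0.2, 0.1), (0.4, 0.0)])


class TestTreatmentDifferenceQ:
    def test_closed_form_examples(self):
        q, df, p = treatment_difference_q((0.4, 0.1), (0.1, 0.1))
        assert q == pytest.approx(4.5, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.0339, abs=1e-4)
        q2, _, _ = treatment_difference_q((0.39, 0.05), (0.20, 0.05))
        assert q2 == pytest.approx(7.22, abs=1e-12)

    def test_equal_estimates_give_q_zero_p_one(self):
        q, _, p = treatment_difference_q((0.3, 0.1), (0.3, 0.2))
        assert q == 0.0
        assert p == 1.0

    def test_symmetry_and_shift_invariance(self, rng):
        a, b = (0.42, 0.07), (0.11, 0.09)
        q1, _, _ = treatment_difference_q(a, b)
        q2, _, _ = treatment_difference_q(b, a)
        q3, _, _ = treatment_difference_q((a[0] + 5, a[1]), (b[0] + 5, b[1]))
        assert q1 == pytest.approx(q2, abs=1e-14)
        assert q1 == pytest.approx(q3, abs=1e-9)


class TestSlopeWithAr1:
    def test_rho_zero_reduces_to_ols(self, rng):
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        ols = np.polyfit(x, y, 1)[0]
        # rho forced to 0 must equal OLS exactly
        fit0 = slope_with_ar1(y, x, fixed_rho=0.0)
        assert fit0.slope == pytest.approx(ols, abs=1e-10)
        # independent errors: estimated rho ~ 0, slope ~ OLS
        fit = slope_with_ar1(y, x)
        assert fit.slope == pytest.approx(ols, abs=0.05)

    def test_recovers_known_slope_under_ar1_noise(self):
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(size=n)
        eps = np.zeros(n)
        for t in range(1, n):
            eps[t] = 0.6 * eps[t - 1] + rng.normal(scale=0.5)
        y = 2.0 * x + eps
        fit = slope_with_ar1(y, x)
        assert fit.ci_low < 2.0 < fit.ci_high
        assert fit.rho == pytest.approx(0.6, abs=0.15)
        assert fit.converged

    def test_constant_response_flagged(self, rng):
        with pytest.warns(UserWarning):
            fit = slope_with_ar1(np.ones(10), rng.normal(size=10))
        assert fit.slope == 0.0
        assert not fit.converged


class TestLogResponseRatio:
    @pytest.mark.parametrize(
        "f, c, expected",
        [(10, 5, math.log(2)), (7, 7, 0.0), (5, 10, -math.log(2))],
    )
    def test_values(self, f, c, expected):
        assert log_response_ratio(f, c) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            log_response_ratio(0.0, 5.0)


class TestClimateResidualize:
    def _covariates(self, rng, n=42):
        return pd.DataFrame(
            {"MAP_VAR": rng.uniform(0.1, 0.8, n),
             "MAT_VAR": rng.uniform(0.1, 0.9, n)}
        )

    def test_matches_normal_equation_oracle(self, rng):
        cov = self._covariates(rng)
        y = rng.normal(size=42)
        res = climate_residualize(y, cov)
        X = np.column_stack([np.ones(42), cov.MAP_VAR, cov.MAT_VAR])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res, y - X @ beta, atol=1e-10)
        assert abs(res.mean()) < 1e-10

    def test_exact_linear_dependence_gives_zero_residuals(self, rng):
        cov = self._covariates(rng)
        y = 3.0 + 2.0 * cov.MAP_VAR.to_numpy()
        res = climate_residualize(y, cov)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_collinear_covariates_warn(self, rng):
        cov = self._covariates(rng)
        cov["MAT_VAR"] = 2.0 * cov["MAP_VAR"]
        with pytest.warns(UserWarning, match="collinear"):
            climate_residualize(rng.normal(size=42), cov)


class TestAnovaEffects:
    def _frame(self, rng, treatment_shift=0.0):
        df = pd.DataFrame(
            {
                "trt": np.repeat(["Control", "NPK"], 36),
                "duration": list(np.tile(np.repeat([4, 5, 6], 12), 2)),
                "y": rng.normal(size=72),
            }
        )
        df.loc[df.trt == "NPK", "y"] += treatment_shift
        return df

    def test_strong_treatment_no_duration_effect(self, rng):
        tab = anova_effects(self._frame(rng, treatment_shift=5.0), "y")
        assert tab.loc["trt", "p"] < 1e-3
        assert tab.loc["duration", "p"] > 0.05

    def test_identical_groups_f_near_zero(self):
        # both treatment groups carry the same values (duration leaves
        # residual spread, so the F statistic is well defined)
        block = [1.0, 2.0, 3.0, 1.4, 2.6, 3.2]
        df = pd.DataFrame(
            {
                "trt": np.repeat(["Control", "NPK"], 6),
                "duration": list(np.tile([4, 5, 6], 4)),
                "y": block * 2,
            }
        )
        tab = anova_effects(df, "y")
        assert tab.loc["trt", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_single_level_factor_rejected(self, rng):
        df = self._frame(rng)
        with pytest.raises(DegenerateInputError):
            anova_effects(df[df.trt == "NPK"], "y")


@pytest.mark.parametrize("t, n_windows", [(9, 6), (4, 1)])
def test_overlapping_window_counts(t, n_windows):
    wins = overlapping_windows(t)
    assert len(wins) == n_windows
    assert wins[0] == (1, 4)
    assert all(b - a == 3 for a, b in wins)


def test_overlapping_windows_too_short_warns():
    with pytest.warns(UserWarning):
        assert overlapping_windows(3) == []
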