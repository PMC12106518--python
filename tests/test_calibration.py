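"""Curve fitting, identifiability, bootstrap, PCA and correlations."""

import numpy as np
import pandas as pd
import pytest

from osteodamage.calibration import (
    FitConfig,
    REDUCED_FIELDS,
    bootstrap,
    covariate_correlation,
    expand_reduced,
    fit_curve,
    identifiable_projection,
    pca_parameters,
    pca_scores,
    percentile_intervals,
)
from osteodamage.curves import CurveTable
from osteodamage.energy import DEFAULT_PARAMETERS
from osteodamage.errors import ValidationError
from osteodamage.material_point import strain_at_alpha, uniaxial_monotonic


def make_curve(theta, n=60, alpha_stop=0.5, noise_cv=0.0, seed=0):
    e_max = strain_at_alpha(theta, alpha_stop)
    grid = np.linspace(0.0, e_max, n)
    sigma = uniaxial_monotonic(grid, theta).sigma.copy()
    if noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        sigma[1:] *= np.exp(rng.normal(0.0, noise_cv, n - 1))
    return CurveTable(grid, sigma, "tension")


class TestIdentifiableProjection:
    def test_rho_tau_swap_gives_identical_curves(self, theta):
        swapped = theta.replace(rho2=theta.tau2, tau2=theta.rho2,
                                rho3=theta.tau3, tau3=theta.rho3)
        grid = np.linspace(0.0, 0.012, 40)
        a = uniaxial_monotonic(grid, theta).sigma
        b = uniaxial_monotonic(grid, swapped).sigma
        assert np.max(np.abs(a - b)) < 1e-12 * np.max(np.abs(a))
        assert identifiable_projection(theta) == identifiable_projection(swapped)

    def test_distinct_projections_give_distinct_curves(self, theta):
        other = theta.replace(rho2=theta.rho2 * 1.3)
        grid = np.linspace(0.0, 0.012, 40)
        a = uniaxial_monotonic(grid, theta).sigma
        b = uniaxial_monotonic(grid, other).sigma
        assert np.max(np.abs(a - b)) > 1e-6

    def test_projection_idempotent(self, theta):
        red = identifiable_projection(theta)
        back = expand_reduced({k: red[k] for k in REDUCED_FIELDS}, red["N"])
        assert identifiable_projection(back) == red


class TestFit:
    def test_noiseless_round_trip_recovers_identifiable_parameters(self, theta):
        curve = make_curve(theta, alpha_stop=0.45)
        fit = fit_curve(curve, FitConfig(n_starts=2, n_grid=(theta.N,), seed=0))
        assert fit.converged
        assert fit.r_squared >= 1.0 - 1e-9
        true = identifiable_projection(theta)
        scale3 = abs(true["rho_tau3"])
        for key in ("mu2", "nu2", "rho_tau2", "mu3", "rho_tau3", "beta", "r"):
            assert fit.reduced[key] == pytest.approx(true[key], rel=1e-3), key
        for key in ("nu3", "sigma3"):  # true zeros, ridge-pinned
            assert abs(fit.reduced[key]) <= 1e-3 * scale3

    def test_noisy_fit_keeps_high_r_squared(self, theta):
        curve = make_curve(theta, noise_cv=0.01, seed=3)
        fit = fit_curve(curve, FitConfig(n_starts=2, n_grid=(theta.N,), seed=0))
        assert fit.r_squared >= 0.99

    def test_r_squared_invariant_under_stress_rescaling(self, theta):
        curve = make_curve(theta, noise_cv=0.01, seed=5)
        fit1 = fit_curve(curve, FitConfig(n_starts=1, n_grid=(4,), seed=0))
        scaled = CurveTable(curve.abscissa, curve.ordinate * 3.0, "tension")
        fit2 = fit_curve(scaled, FitConfig(n_starts=1, n_grid=(4,), seed=0))
        assert fit2.r_squared == pytest.approx(fit1.r_squared, abs=1e-6)

    def test_bending_curve_fit(self, theta):
        from osteodamage.material_point import SectionSpec, bending_response

        sec = SectionSpec()
        k_max = strain_at_alpha(theta, 0.5) / (sec.thickness / 2.0)
        curve = bending_response(sec, np.linspace(0.0, k_max, 60), theta)
        rng = np.random.default_rng(0)
        curve.ordinate[1:] *= np.exp(rng.normal(0.0, 0.01, len(curve) - 1))
        fit = fit_curve(curve, FitConfig(n_starts=2, n_grid=(4,), seed=0, section=sec))
        assert fit.r_squared >= 0.99

    def test_short_curve_rejected(self, theta):
        grid = np.linspace(0.0, 0.01, 10)
        curve = CurveTable(grid, uniaxial_monotonic(grid, theta).sigma, "tension")
        with pytest.raises(ValidationError):
            fit_curve(curve)


class TestBootstrap:
    def test_zero_residuals_reproduce_theta_hat(self, theta):
        curve = make_curve(theta)
        fit = fit_curve(curve, FitConfig(n_starts=1, n_grid=(4,), seed=0))
        fit.residuals[:] = 0.0
        samples = bootstrap(fit, curve, b=5, seed=1)
        for key in ("beta", "rho_tau2"):
            assert np.allclose(samples[key], fit.reduced[key], rtol=1e-6)

    def test_deterministic_under_seed(self, theta):
        curve = make_curve(theta, noise_cv=0.01, seed=2)
        fit = fit_curve(curve, FitConfig(n_starts=1, n_grid=(4,), seed=0))
        s1 = bootstrap(fit, curve, b=6, seed=9)
        s2 = bootstrap(fit, curve, b=6, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_intervals_shrink_with_noise(self, theta):
        widths = []
        for cv in (0.01, 0.002):
            curve = make_curve(theta, noise_cv=cv, seed=4)
            fit = fit_curve(curve, FitConfig(n_starts=2, n_grid=(4,), seed=0, fixed_r=2.0))
            samples = bootstrap(fit, curve, b=20, seed=3,
                                config=FitConfig(fixed_r=2.0))
            iv = percentile_intervals(samples)
            widths.append(iv.loc["rho_tau2", "upper"] - iv.loc["rho_tau2", "lower"])
        assert widths[1] < widths[0]


class TestPCA:
    def test_rank_one_matrix_single_component(self, rng):
        base = rng.normal(size=20)
        mat = pd.DataFrame(np.outer(base, [1.0, -2.0, 0.5]), columns=list("abc"))
        with pytest.warns(UserWarning):
            stats_obj = pca_parameters(mat)
        assert stats_obj.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_columns_near_uniform_fractions(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4000, 5)), columns=list("abcde"))
        stats_obj = pca_parameters(mat)
        assert np.all(np.abs(stats_obj.explained_variance_ratio - 0.2) < 0.05)

    def test_fractions_sum_to_one_and_loadings_orthonormal(self, rng):
        mat = pd.DataFrame(rng.normal(size=(40, 6)))
        stats_obj = pca_parameters(mat)
        assert stats_obj.explained_variance_ratio.sum() == pytest.approx(1.0)
        load = stats_obj.loadings.to_numpy()
        assert np.allclose(load @ load.T, np.eye(load.shape[0]), atol=1e-10)

    def test_permutation_invariance_of_fractions(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        f1 = pca_parameters(mat).explained_variance_ratio
        f2 = pca_parameters(mat[["c", "a", "d", "b"]]).explained_variance_ratio
        assert np.allclose(f1, f2)

    def test_constant_column_rejected(self, rng):
        mat = pd.DataFrame({"a": rng.normal(size=15), "b": np.ones(15)})
        with pytest.raises(ValidationError):
            pca_parameters(mat)

    def test_scores_shape(self, rng):
        mat = pd.DataFrame(rng.normal(size=(25, 4)))
        stats_obj = pca_parameters(mat)
        scores = pca_scores(stats_obj)
        assert scores.shape == (25, 4)


class TestCovariateCorrelation:
    def test_perfect_linear_pair(self):
        x = np.linspace(0.0, 1.0, 20)
        out = covariate_correlation(
            pd.DataFrame({"v": 2.0 * x + 1.0}), pd.DataFrame({"c": x})
        )
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] < 1e-20

    def test_null_p_values_approximately_uniform(self, rng):
        # implanted null: independent draws; KS test should not reject at 1%
        from scipy import stats as sps

        pvals = []
        for _ in range(1000):
            v = rng.normal(size=12)
            c = rng.normal(size=12)
            pvals.append(float(sps.pearsonr(v, c).pvalue))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValidationError):
            covariate_correlation(
                pd.DataFrame({"v": rng.normal(size=12)}),
                pd.DataFrame({"c": np.ones(12)}),
            )

    def test_bh_correction_appends_q_values(self, rng):
        out = covariate_correlation(
            pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc")),
            pd.DataFrame({"c": rng.normal(size=15)}),
            bh_correct=True,
        )
        assert "q_value" in out.columns
        assert np.all(out["q_value"] >= out["p_value"] - 1e-12)
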