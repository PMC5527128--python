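import warnings

import numpy as np
import pytest

from trendgam import gam, splines
from trendgam.synthetic import simulate_for_recovery


def _single_smooth_spec(t, family="gaussian", link="identity", k=8):
    basis = splines.apply_centering(splines.build_cr_basis(t, k), t)
    return gam.ModelSpec(
        parametric_terms=(gam.ParametricTerm("intercept", np.ones_like(t)),),
        smooth_terms=(gam.SmoothTerm("s", basis, t),),
        family=family,
        link=link,
    )


class TestPirlsFit:
    def test_gaussian_lambda_zero_equals_ols(self, gaussian_smooth_model):
        for seed in range(5):
            spec, y, X, _, _ = gaussian_smooth_model(seed=seed)
            fit = gam.pirls_fit(spec, y, 0.0)
            beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(fit.coefficients, beta_ols, atol=1e-8)

    def test_gaussian_ridge_closed_form(self, gaussian_smooth_model):
        # generalized-ridge oracle at several fixed lambdas
        for seed in range(5):
            spec, y, X, S, _ = gaussian_smooth_model(seed=10 + seed)
            lam = 10.0 ** np.random.default_rng(seed).uniform(-2, 4)
            fit = gam.pirls_fit(spec, y, lam)
            A = X.T @ X
            A[1:, 1:] += lam * S
            np.testing.assert_allclose(
                fit.coefficients, np.linalg.solve(A, X.T @ y), atol=1e-8
            )

    def test_gamma_fitted_means_positive(self):
        rng = np.random.default_rng(3)
        t = np.repeat(np.arange(1.0, 16.0), 2)
        y = rng.gamma(25.0, np.exp(0.5 + 0.1 * t) / 25.0)
        fit = gam.pirls_fit(_single_smooth_spec(t, "gamma", "log"), y, 1.0)
        assert fit.fitted.min() > 0

    def test_huge_lambda_gives_affine_fit(self, gaussian_smooth_model):
        spec, y, _, _, basis = gaussian_smooth_model(seed=2)
        fit = gam.pirls_fit(spec, y, 1e8)
        t = spec.smooth_terms[0].times
        coef = np.polyfit(t, fit.fitted, 1)
        dev = np.max(np.abs(fit.fitted - np.polyval(coef, t)))
        assert dev < 1e-4 * np.std(y)

    def test_nonpositive_response_rejected_under_gamma(self):
        t = np.arange(1.0, 13.0)
        y = np.ones_like(t)
        y[3] = 0.0
        with pytest.raises(ValueError, match="positive"):
            gam.pirls_fit(_single_smooth_spec(t, "gamma", "log"), y, 1.0)

    def test_wrong_lambda_count_rejected(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model()
        with pytest.raises(ValueError, match="smoothing parameters"):
            gam.pirls_fit(spec, y, np.array([1.0, 2.0]))

    def test_unsupported_family_link_pair(self):
        with pytest.raises(ValueError, match="family/link"):
            gam.ModelSpec(
                parametric_terms=(gam.ParametricTerm("i", np.ones(5)),),
                smooth_terms=(),
                family="gamma",
                link="identity",
            )


class TestOptimizeReml:
    def test_scale_equivariance(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=4)
        f1 = gam.optimize_reml(spec, y)
        f2 = gam.optimize_reml(spec, 10.0 * y)
        np.testing.assert_allclose(10.0 * f1.fitted, f2.fitted, rtol=1e-6, atol=1e-8)
        assert abs(f1.edf["s"] - f2.edf["s"]) < 1e-6

    def test_local_optimality(self, gaussian_smooth_model):
        spec, y, X, S, _ = gaussian_smooth_model(seed=5)
        fit = gam.optimize_reml(spec, y)
        assert fit.reml_criterion is not None
        design = gam._assemble(spec, y.size)
        for factor in (1.05, 1 / 1.05):
            lam = fit.lam * factor
            state = gam._pirls(design, y, lam)
            crit = gam._working_reml(design, lam, state[0], state[4], state[5], state[6])
            assert fit.reml_criterion >= crit - 1e-9

    def test_pure_noise_shrinks_to_linear(self):
        # median smooth e.d.f. under a pure-noise response stays near 1
        edfs = []
        t = np.repeat(np.arange(1.0, 16.0), 2)
        spec = _single_smooth_spec(t)
        for seed in range(30):
            y = np.random.default_rng(seed).normal(size=t.size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                edfs.append(gam.optimize_reml(spec, y).edf["s"])
        assert np.median(edfs) <= 1.5

    def test_lambda_bound_flagged(self):
        t = np.repeat(np.arange(1.0, 16.0), 2)
        spec = _single_smooth_spec(t)
        y = np.random.default_rng(0).normal(0.0, 1.0, t.size)  # no signal at all
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = gam.optimize_reml(spec, y)
        # pure noise drives lambda to the upper bound; the fit must say so
        assert fit.lambda_at_bound == bool(
            np.any(np.log10(fit.lam) >= 8 - 1e-6) | np.any(np.log10(fit.lam) <= -8 + 1e-6)
        )

    def test_permutation_invariance(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=6)
        t = spec.smooth_terms[0].times
        perm = np.random.default_rng(1).permutation(t.size)
        basis = spec.smooth_terms[0].basis
        spec_p = gam.ModelSpec(
            parametric_terms=(gam.ParametricTerm("intercept", np.ones_like(t)),),
            smooth_terms=(gam.SmoothTerm("s", basis, t[perm]),),
            family="gaussian",
            link="identity",
        )
        lam = 3.7
        f1 = gam.pirls_fit(spec, y, lam)
        f2 = gam.pirls_fit(spec_p, y[perm], lam)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-10)
        assert abs(f1.edf["s"] - f2.edf["s"]) < 1e-10
        p1 = gam.approx_pvalue(f1, "s")["p_value"]
        p2 = gam.approx_pvalue(f2, "s")["p_value"]
        assert abs(p1 - p2) < 1e-10
        r1 = gam.optimize_reml(spec, y)
        r2 = gam.optimize_reml(spec_p, y[perm])
        np.testing.assert_allclose(r1.coefficients, r2.coefficients, atol=1e-6)


class TestEdf:
    def test_lambda_zero_edf_is_basis_dimension(self, gaussian_smooth_model):
        spec, y, _, _, basis = gaussian_smooth_model(seed=7)
        fit = gam.pirls_fit(spec, y, 0.0)
        assert abs(fit.edf["s"] - basis.dimension) < 1e-8

    def test_huge_lambda_edf_is_one(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=8)
        fit = gam.pirls_fit(spec, y, 1e8)
        assert abs(fit.edf["s"] - 1.0) < 0.01

    def test_trace_additivity(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=9)
        fit = gam.pirls_fit(spec, y, 2.5)
        assert abs(sum(fit.edf.values()) - fit.total_edf) < 1e-8
        # unpenalized parametric coefficients carry e.d.f. exactly 1
        assert abs(fit.edf["intercept"] - 1.0) < 1e-10

    def test_edf_monotone_in_lambda(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=10)
        lams = 10.0 ** np.arange(-4.0, 6.0)
        edfs = [gam.pirls_fit(spec, y, lam).edf["s"] for lam in lams]
        assert np.all(np.diff(edfs) <= 1e-10)

    def test_edf_within_bounds(self, gaussian_smooth_model):
        spec, y, _, _, basis = gaussian_smooth_model(seed=11)
        for lam in (0.01, 1.0, 100.0):
            fit = gam.pirls_fit(spec, y, lam)
            assert 0.0 < fit.edf["s"] <= basis.dimension + 1e-10


class TestApproxPvalue:
    def test_pvalue_in_unit_interval(self, gaussian_smooth_model):
        for seed in range(5):
            spec, y, _, _, _ = gaussian_smooth_model(seed=seed)
            fit = gam.pirls_fit(spec, y, 1.0)
            p = gam.approx_pvalue(fit, "s")["p_value"]
            assert 0.0 <= p <= 1.0

    def test_strong_signal_highly_significant(self):
        hits = 0
        for seed in range(20):
            g = lambda t: 1.0 / (1.0 + np.exp(-0.6 * (t - 7)))
            d = lambda t: np.log(3.0) * np.clip((t - 9.0) / 4.0, 0.0, 1.0)
            data, _ = simulate_for_recovery(g, d, seed=seed, noise_cv=0.10)
            from trendgam.trend import fit_trend_model

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tf = fit_trend_model(data, "synthetic")
            hits += tf.differential.p_value < 0.001
        assert hits >= 19  # >= 95% of reps

    def test_rank_rule(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=12)
        fit = gam.pirls_fit(spec, y, 1.0)
        res = gam.approx_pvalue(fit, "s")
        assert res["rank"] == max(1, round(fit.edf["s"]))


class TestConfidenceBand:
    def test_band_ordering(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=13)
        fit = gam.optimize_reml(spec, y)
        t = spec.smooth_terms[0].times
        band = gam.confidence_band(fit, "s", np.linspace(t.min(), t.max(), 50))
        assert np.all(band["lower"] <= band["estimate"])
        assert np.all(band["estimate"] <= band["upper"])
        assert not band["extrapolated"].any()

    def test_band_narrows_with_replication(self):
        # quadrupling replicates shrinks the average band width
        g = lambda t: np.sin(t / 3.0)
        wins = 0
        n_pairs = 12
        for seed in range(n_pairs):
            widths = []
            for reps in (3, 12):
                data, _ = simulate_for_recovery(
                    g, None, replicates=reps, seed=seed, noise_cv=0.15
                )
                sub = data[data["group"] == "control"]
                t = sub["day"].to_numpy()
                spec = _single_smooth_spec(t, "gaussian", "identity")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = gam.optimize_reml(spec, np.log(sub["concentration"].to_numpy()))
                band = gam.confidence_band(fit, "s", np.arange(1.0, 21.0))
                widths.append(np.mean(band["upper"] - band["lower"]))
            wins += widths[1] < widths[0]
        assert wins == n_pairs  # strict decrease in every pair, on average width

    def test_extrapolation_flagged(self, gaussian_smooth_model):
        spec, y, _, _, basis = gaussian_smooth_model(seed=14)
        fit = gam.pirls_fit(spec, y, 1.0)
        hi = basis.parent.knots[-1]
        band = gam.confidence_band(fit, "s", np.array([hi / 2.0, hi + 5.0]))
        assert band["extrapolated"].tolist() == [False, True]


class TestResidualDiagnostics:
    def test_gaussian_pearson_residuals_centered(self, gaussian_smooth_model):
        spec, y, _, _, _ = gaussian_smooth_model(seed=15)
        fit = gam.pirls_fit(spec, y, 1.0)
        d = gam.residual_diagnostics(fit)
        assert abs(d["pearson_residuals"].mean()) < 1e-8

    def test_constant_cv_gamma_passes_hetero_screen(self):
        passed = 0
        n_reps = 30
        t = np.repeat(np.arange(1.0, 21.0), 3)
        spec = _single_smooth_spec(t, "gamma", "log", k=10)
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            mu = np.exp(1.0 + 0.8 / (1.0 + np.exp(-(t - 8.0))))
            y = rng.gamma(100.0, mu / 100.0)  # CV = 10%, constant
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = gam.optimize_reml(spec, y)
            passed += gam.residual_diagnostics(fit)["hetero_slope_p"] > 0.05
        assert passed >= 0.8 * n_reps

    def test_saturated_gaussian_deviance_zero(self):
        rng = np.random.default_rng(16)
        t = np.arange(1.0, 11.0)
        y = rng.normal(size=10)
        basis = splines.build_cr_basis(t, 10)  # k = n distinct times, uncentered
        spec = gam.ModelSpec(
            parametric_terms=(),
            smooth_terms=(gam.SmoothTerm("s", _uncentered(basis, t), t),),
            family="gaussian",
            link="identity",
        )
        fit = gam.pirls_fit(spec, y, 0.0)
        assert fit.deviance < 1e-6


def _uncentered(basis, t):
    """Wrap a raw BasisSystem with an identity 'constraint' transform."""
    return splines.ConstrainedBasis(
        parent=basis, transform=np.eye(basis.dimension), design_times=np.asarray(t)
    )
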