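"""Model core: design matrices, joint/Laplace likelihoods, fitting."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize as sopt
import scipy.sparse as sp

from krillspot.glmm import (
    MONTHS,
    ModelSpec,
    TweedieParams,
    build_design,
    design_matrix,
    fit,
    joint_nll,
    laplace_marginal_nll,
    make_obs_projector,
    _obs_derivs,
    _obs_mu_part,
)
from krillspot.spde import FieldParams, precision_from_params, spacetime_precision
from krillspot.tweedie import tweedie_log_density


def _toy_data(n=60, seed=0, years=(2015, 2016)):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x_km": rng.uniform(1, 9, n),
        "y_km": rng.uniform(1, 9, n),
        "year": rng.choice(np.array(years), n),
        "month": rng.choice(np.arange(4, 10), n),
        "biomass_mg_m2": rng.gamma(2.0, 2.0, n) * (rng.random(n) > 0.2),
        "depth": rng.uniform(30, 900, n),
    })
    return df


class TestDesign:
    def test_null_spec_column_count(self):
        # intercept + (n_years-1) dummies + (k-1) month-spline columns
        df = _toy_data(80, years=(2010, 2011, 2012, 2013, 2014))
        X, info = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        assert X.shape[1] == 1 + 4 + 5
        assert info.columns[0] == "intercept"

    def test_full_spec_adds_spline_blocks(self, small_grid):
        df = _toy_data(200)
        cov = small_grid.covariates[4]
        rng = np.random.default_rng(1)
        for c in ("dist_coast", "dist_1000m", "slope", "sst", "chl"):
            df[c] = rng.choice(cov[c].to_numpy(), len(df))
        X0, _ = build_design(df, ModelSpec.for_group("EP_adult", "depth"))
        X1, _ = build_design(df, ModelSpec.for_group("EP_adult", "full"))
        # extra columns: coast 3 + isobar 2 + slope 3 + sst 2 + chl 2 = 12
        assert X1.shape[1] - X0.shape[1] == 12

    def test_unseen_year_level_rejected(self):
        df = _toy_data(60)
        X, info = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        new = df.copy()
        new.loc[0, "year"] = 1999
        with pytest.raises(ValueError, match="unseen year"):
            design_matrix(info, new)

    def test_round_trip_bit_exact(self):
        df = _toy_data(60)
        X, info = build_design(df, ModelSpec.for_group("EP_adult", "depth"))
        np.testing.assert_array_equal(design_matrix(info, df), X)


class TestJointNll:
    def test_reduces_to_glm_at_zero_field(self, tiny_mesh):
        df = _toy_data(40)
        X, _ = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        A = make_obs_projector(tiny_mesh, df)
        tw = TweedieParams(1.5, 1.2)
        Q = spacetime_precision(
            precision_from_params(tiny_mesh, FieldParams(8.0, 1.0, 0.3)),
            0.3, 6)
        beta = np.zeros(X.shape[1])
        beta[0] = 0.7
        u = np.zeros(Q.shape[0])
        val = joint_nll(beta, u, df["biomass_mg_m2"].to_numpy(), X, A, Q, tw)
        glm_nll = -tweedie_log_density(
            df["biomass_mg_m2"].to_numpy(), np.exp(X @ beta), tw.phi, tw.p
        ).sum()
        from krillspot.spde import gmrf_logdet

        const = -0.5 * gmrf_logdet(Q) + 0.5 * Q.shape[0] * np.log(2 * np.pi)
        assert val == pytest.approx(glm_nll + const, rel=1e-10)

    def test_finite_with_zero_responses(self, tiny_mesh):
        df = _toy_data(40)
        df["biomass_mg_m2"] = 0.0
        X, _ = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        A = make_obs_projector(tiny_mesh, df)
        Q = spacetime_precision(
            precision_from_params(tiny_mesh, FieldParams(8.0, 1.0)), 0.0, 6)
        val = joint_nll(np.zeros(X.shape[1]), np.zeros(Q.shape[0]),
                        df["biomass_mg_m2"].to_numpy(), X, A, Q,
                        TweedieParams(1.4, 1.0))
        assert np.isfinite(val)

    def test_analytic_gradient_matches_finite_difference(self, tiny_mesh):
        """The inner Newton's gradient (beta and u blocks) against FD."""
        df = _toy_data(30, seed=3)
        y = df["biomass_mg_m2"].to_numpy()
        X, _ = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        A = make_obs_projector(tiny_mesh, df)
        Qd = spacetime_precision(
            precision_from_params(tiny_mesh, FieldParams(8.0, 1.0, 0.2)),
            0.2, 6).toarray()
        rng = np.random.default_rng(4)
        beta = rng.normal(0, 0.2, X.shape[1])
        u = rng.normal(0, 0.2, Qd.shape[0])
        phi, p = 1.1, 1.5

        def obj(z):
            b, uu = z[: X.shape[1]], z[X.shape[1]:]
            eta = X @ b + A @ uu
            return _obs_mu_part(y, eta, phi, p, "tweedie") + 0.5 * uu @ (Qd @ uu)

        g, w = _obs_derivs(y, X @ beta + A @ u, phi, p, "tweedie")
        grad = np.concatenate([X.T @ g, A.T @ g + Qd @ u])
        z0 = np.concatenate([beta, u])
        fd = sopt.approx_fprime(z0, obj, 1e-7)
        np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-6)


class TestLaplace:
    def test_matches_dense_reference_small_mesh(self, tiny_mesh):
        """Laplace marginal nll against an independent dense implementation
        (scipy trust-region inner optimizer, numpy logdet)."""
        df = _toy_data(25, seed=5)
        y = df["biomass_mg_m2"].to_numpy()
        X, _ = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        A = make_obs_projector(tiny_mesh, df)
        tw = TweedieParams(1.5, 1.0)
        Q = spacetime_precision(
            precision_from_params(tiny_mesh, FieldParams(8.0, 0.8, 0.4)),
            0.4, 6)
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.mean(), 0.1))
        ours, u_hat = laplace_marginal_nll(beta, y, X, A, Q, tw)

        Qd = Q.toarray()
        Ad = A.toarray()
        n_u = Qd.shape[0]

        def f(u):
            eta = X @ beta + Ad @ u
            return float(
                -tweedie_log_density(y, np.exp(eta), tw.phi, tw.p).sum()
                + 0.5 * u @ Qd @ u
            )

        def grad(u):
            eta = X @ beta + Ad @ u
            g, _ = _obs_derivs(y, eta, tw.phi, tw.p, "tweedie")
            return Ad.T @ g + Qd @ u

        def hess(u):
            eta = X @ beta + Ad @ u
            _, w = _obs_derivs(y, eta, tw.phi, tw.p, "tweedie")
            return Qd + (Ad * w[:, None]).T @ Ad

        res = sopt.minimize(f, np.zeros(n_u), jac=grad, hess=hess,
                            method="trust-exact", options={"gtol": 1e-12})
        H = hess(res.x)
        sign, logdet_H = np.linalg.slogdet(H)
        sign_Q, logdet_Q = np.linalg.slogdet(Qd)
        ref = (res.fun - 0.5 * logdet_Q + 0.5 * n_u * np.log(2 * np.pi)
               + 0.5 * logdet_H - 0.5 * n_u * np.log(2 * np.pi))
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_gaussian_analogue_matches_closed_form_lmm(self, tiny_mesh):
        """With a Gaussian response the Laplace approximation is exact and
        must equal the closed-form marginal likelihood of the LMM."""
        df = _toy_data(30, seed=6)
        rng = np.random.default_rng(0)
        df["biomass_mg_m2"] = rng.normal(1.0, 1.0, len(df))
        y = df["biomass_mg_m2"].to_numpy()
        X, _ = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        A = make_obs_projector(tiny_mesh, df)
        phi = 0.8
        tw = TweedieParams(1.5, phi)  # p unused by the gaussian family
        Q = spacetime_precision(
            precision_from_params(tiny_mesh, FieldParams(8.0, 0.7, 0.3)),
            0.3, 6)
        beta = np.zeros(X.shape[1])
        beta[0] = 0.9
        ours, _ = laplace_marginal_nll(beta, y, X, A, Q, tw, family="gaussian")
        # closed form: y ~ N(X beta, A Q^-1 A' + phi I)
        S = (A @ np.linalg.inv(Q.toarray()) @ A.toarray().T
             + phi * np.eye(len(y)))
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(S)
        ref = 0.5 * (r @ np.linalg.solve(S, r) + logdet
                     + len(y) * np.log(2 * np.pi))
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_small_sigma_limit_is_glm(self, tiny_mesh):
        df = _toy_data(30, seed=7)
        y = df["biomass_mg_m2"].to_numpy()
        X, _ = build_design(df, ModelSpec.for_group("EP_adult", "null"))
        A = make_obs_projector(tiny_mesh, df)
        tw = TweedieParams(1.5, 1.0)
        Q = spacetime_precision(
            precision_from_params(tiny_mesh, FieldParams(8.0, 1e-4)), 0.0, 6)
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.mean(), 0.1))
        ours, u_hat = laplace_marginal_nll(beta, y, X, A, Q, tw)
        glm = -tweedie_log_density(y, np.exp(X @ beta), tw.phi, tw.p).sum()
        assert abs(ours - glm) < 1e-4
        assert np.abs(u_hat).max() < 1e-4


@pytest.fixture(scope="module")
def fitted(small_mesh, small_grid):
    from krillspot.synthetic import simulate_glmm_dataset

    data, truth = simulate_glmm_dataset(
        small_mesh, small_grid, n_obs=400, seed=10,
        field_params=FieldParams(25.0, 0.8, 0.5),
        covariate_effects={"depth": (0.2, -0.6)},
    )
    f = fit(data, ModelSpec.for_group("EP_adult", "depth"), small_mesh,
            seed=0)
    return f, data, truth


class TestFit:
    def test_converges_and_is_deterministic(self, fitted, small_mesh):
        f, data, truth = fitted
        assert f.converged
        f2 = fit(data, ModelSpec.for_group("EP_adult", "depth"), small_mesh,
                 seed=0)
        np.testing.assert_allclose(f.theta, f2.theta, atol=1e-8)
        assert f.marginal_nll == pytest.approx(f2.marginal_nll, abs=1e-8)

    def test_reasonable_recovery(self, fitted):
        f, data, truth = fitted
        # loose single-replicate sanity bounds
        assert 0.3 < f.field_params.sigma < 2.0
        assert 1.2 < f.tweedie_params.p < 1.8
        assert 0.5 < f.tweedie_params.phi < 3.0

    def test_standardization_round_trip(self, fitted):
        f, data, _ = fitted
        X = design_matrix(f.info, f.data)
        A = make_obs_projector(f.mesh, f.data, f.months)
        eta = X @ f.beta + A @ f.u.ravel()
        np.testing.assert_array_equal(eta, f.fitted_eta)

    def test_all_zero_response_converges(self, small_mesh, small_grid):
        from krillspot.synthetic import simulate_glmm_dataset

        data, _ = simulate_glmm_dataset(small_mesh, small_grid, n_obs=120,
                                        seed=11)
        data["biomass_mg_m2"] = 0.0
        f = fit(data, ModelSpec.for_group("EP_adult", "null"), small_mesh,
                seed=0)
        mu_hat = np.exp(f.fitted_eta)
        assert np.all(mu_hat < 0.5)

    def test_too_few_observations_rejected(self, small_mesh):
        df = _toy_data(30)
        with pytest.raises(ValueError, match="at least 50"):
            fit(df, ModelSpec.for_group("EP_adult", "null"), small_mesh)


class TestConditionalEffects:
    def test_flat_curve_for_zero_coefficients(self, small_mesh, small_grid):
        from krillspot.glmm import conditional_effects
        from krillspot.synthetic import simulate_glmm_dataset

        data, _ = simulate_glmm_dataset(small_mesh, small_grid, n_obs=200,
                                        seed=12)
        f = fit(data, ModelSpec.for_group("EP_adult", "depth"), small_mesh,
                seed=0)
        # zero out the depth-spline block by hand -> flat curve
        idx = [i for i, c in enumerate(f.info.columns) if c.startswith("s(depth)")]
        f.beta[idx] = 0.0
        curve = conditional_effects(f, "depth")
        assert np.ptp(curve["mean"].to_numpy()) < 1e-10

    def test_recovers_quadratic_depth_optimum(self, small_mesh, small_grid):
        from krillspot.glmm import conditional_effects
        from krillspot.synthetic import simulate_glmm_dataset

        # strong quadratic depth effect peaking mid-depth
        data, truth = simulate_glmm_dataset(
            small_mesh, small_grid, n_obs=600, seed=13,
            field_params=FieldParams(25.0, 0.4, 0.3),
            covariate_effects={"depth": (0.0, -1.2)},
        )
        f = fit(data, ModelSpec.for_group("EP_adult", "depth"), small_mesh,
                seed=0)
        curve = conditional_effects(f, "depth")
        # truth peaks where standardized log depth = 0 (geometric mean depth)
        pooled = np.log(np.concatenate(
            [small_grid.covariates[m]["depth"].to_numpy() for m in MONTHS]))
        peak_true = np.exp(pooled.mean())
        peak_est = curve.loc[curve["mean"].idxmax(), "x"]
        span = data["depth"].max() - data["depth"].min()
        assert abs(peak_est - peak_true) < 0.15 * span
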