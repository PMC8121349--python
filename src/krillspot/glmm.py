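"""Spatiotemporal Tweedie GLMM with SPDE random fields (Laplace method).

The model for biomass y_i at location s_i, year t_i, month m_i:

    y_i ~ Tweedie(mu_i, phi, p),  1 < p < 2
    log mu_i = X_i beta + A(s_i) u_{m_i}

with fixed effects beta = year factor + thin-plate spline terms (month and
covariates), and u a Gaussian Markov random field over mesh knots x months:
Matern (nu = 1) in space via the SPDE precision, stationary AR1 across the
six months (April–September, fields pooled across years as in the survey
analysis this package supports).  Estimation maximises the Laplace-
approximated marginal likelihood: the latent field (and, during the outer
search, beta) is profiled out by an inner damped-Newton solve — the inner
problem is strictly convex under the Tweedie log link — and the outer
quasi-Newton search runs over the five transformed hyperparameters
(log range, log sigma, atanh rho, log phi, scaled-logit p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy.special import expit, logit

from .spde import (
    FieldParams,
    SpdeMesh,
    gmrf_logdet,
    precision_from_params,
    projector,
    spacetime_precision,
)
from .splines import TprsBasis, tprs_basis
from .tweedie import tweedie_eta_derivs, tweedie_log_density, tweedie_nll_mu_part

logger = logging.getLogger(__name__)

MONTHS = (4, 5, 6, 7, 8, 9)

# full-covariate spline terms: (column, basis dimension k, transform)
ADULT_FULL_TERMS = (
    ("depth", 3, "log"),
    ("dist_coast", 4, None),
    ("dist_1000m", 3, None),
    ("slope", 4, None),
    ("sst", 3, None),
    ("chl", 3, "log"),
)
LARVAL_EXTRA_TERMS = (("ep_adult", 4, "log1p"), ("ts_adult", 4, "log1p"))


@dataclass(frozen=True)
class SplineTerm:
    name: str
    k: int
    transform: str | None = None  # None | "log" | "log1p"


@dataclass(frozen=True)
class ModelSpec:
    """Which response group and which fixed-effect formula variant."""

    group: str
    variant: str = "full"            # "null" | "depth" | "full"
    terms: tuple = ()
    month_k: int = 6

    @classmethod
    def for_group(cls, group: str, variant: str = "full") -> "ModelSpec":
        if variant == "null":
            terms: tuple = ()
        elif variant == "depth":
            terms = (SplineTerm("depth", 3, "log"),)
        elif variant == "full":
            terms = tuple(SplineTerm(*t) for t in ADULT_FULL_TERMS)
            if group == "larvae":
                terms += tuple(SplineTerm(*t) for t in LARVAL_EXTRA_TERMS)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        return cls(group=group, variant=variant, terms=terms)


@dataclass
class TweedieParams:
    p: float
    phi: float

    def __post_init__(self):
        if not (1.0 < self.p < 2.0):
            raise ValueError("p must lie strictly in (1, 2)")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


@dataclass
class DesignInfo:
    """Everything needed to rebuild the design matrix bit-exactly."""

    year_levels: tuple
    month_meta: TprsBasis
    term_meta: dict            # name -> (transform, mean, sd, TprsBasis)
    terms: tuple
    columns: tuple

    @property
    def n_cols(self) -> int:
        return len(self.columns)


def _transform(x, transform):
    x = np.asarray(x, float)
    if transform == "log":
        return np.log(x)
    if transform == "log1p":
        return np.log1p(x)
    return x


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, DesignInfo]:
    """Training design: intercept + year dummies + month spline + covariate
    splines.  Covariates are transformed (log depth/chlorophyll, log1p adult
    biomass), centred and scaled; the standardization constants are stored
    so prediction reproduces the design exactly."""
    year_levels = tuple(int(v) for v in sorted(pd.unique(data["year"].astype(int))))
    blocks = [np.ones((len(data), 1))]
    columns = ["intercept"]
    for lev in year_levels[1:]:
        blocks.append((data["year"].astype(int).to_numpy() == lev)[:, None] * 1.0)
        columns.append(f"year_{lev}")
    Bm, month_meta = tprs_basis(data["month"].astype(float).to_numpy(), spec.month_k)
    blocks.append(Bm)
    columns += [f"s(month).{j}" for j in range(Bm.shape[1])]
    term_meta = {}
    for term in spec.terms:
        z = _transform(data[term.name].to_numpy(), term.transform)
        mean, sd = float(z.mean()), float(z.std())
        if sd == 0:
            raise ValueError(f"covariate {term.name} is constant")
        zs = (z - mean) / sd
        B, meta = tprs_basis(zs, term.k)
        term_meta[term.name] = (term.transform, mean, sd, meta)
        blocks.append(B)
        columns += [f"s({term.name}).{j}" for j in range(B.shape[1])]
    info = DesignInfo(year_levels, month_meta, term_meta, spec.terms, tuple(columns))
    return np.hstack(blocks), info


def design_matrix(
    info: DesignInfo, data: pd.DataFrame, year_mode: str = "strict"
) -> np.ndarray:
    """Rebuild a design matrix at new data from stored constants.

    ``year_mode="strict"`` errors on unseen year levels; ``"mean"`` uses the
    average year effect (each dummy at 1/n_levels) for year-free prediction
    surfaces."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    if year_mode == "mean":
        w = 1.0 / len(info.year_levels)
        blocks.append(np.full((n, len(info.year_levels) - 1), w))
    else:
        years = data["year"].astype(int).to_numpy()
        unseen = set(years) - set(info.year_levels)
        if unseen:
            raise ValueError(
                f"unseen year level(s) {sorted(unseen)}; refit including them "
                "or predict with year_mode='mean'"
            )
        for lev in info.year_levels[1:]:
            blocks.append((years == lev)[:, None] * 1.0)
    blocks.append(info.month_meta.evaluate(data["month"].astype(float).to_numpy()))
    for term in info.terms:
        transform, mean, sd, meta = info.term_meta[term.name]
        zs = (_transform(data[term.name].to_numpy(), transform) - mean) / sd
        blocks.append(meta.evaluate(zs))
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# likelihood machinery


def _obs_nll(y, eta, phi, p, family):
    if family == "tweedie":
        return float(np.sum(-tweedie_log_density(y, np.exp(eta), phi, p)))
    # gaussian with identity link (oracle/debug family)
    return float(np.sum(0.5 * ((y - eta) ** 2 / phi + np.log(2 * np.pi * phi))))


def _obs_mu_part(y, eta, phi, p, family):
    if family == "tweedie":
        return float(np.sum(tweedie_nll_mu_part(y, eta, phi, p)))
    return float(np.sum(0.5 * (y - eta) ** 2 / phi))


def _obs_derivs(y, eta, phi, p, family):
    if family == "tweedie":
        return tweedie_eta_derivs(y, eta, phi, p)
    return (eta - y) / phi, np.full_like(eta, 1.0 / phi)


def joint_nll(beta, u, y, X, A, Q_st, tweedie: TweedieParams,
              logdet_Q: float | None = None, family: str = "tweedie") -> float:
    """Joint negative log density of (y, u) at fixed parameters.

    sum_i -log f(y_i | mu_i) + 1/2 u'Qu - 1/2 logdet Q + (n_u/2) log 2pi,
    with log mu_i = X_i beta + (A u)_i.
    """
    u = np.asarray(u, float).ravel()
    eta = X @ beta + A @ u
    if logdet_Q is None:
        logdet_Q = gmrf_logdet(Q_st)
    val = (
        _obs_nll(y, eta, phi=tweedie.phi, p=tweedie.p, family=family)
        + 0.5 * float(u @ (Q_st @ u))
        - 0.5 * logdet_Q
        + 0.5 * u.size * np.log(2 * np.pi)
    )
    if not np.isfinite(val):
        bad = np.where(~np.isfinite(eta))[0]
        raise FloatingPointError(
            f"non-finite joint nll (first bad observation index: "
            f"{bad[0] if bad.size else 'none'})"
        )
    return val


def _inner_newton(y, X, A, Qd, phi, p, family, profile_beta, beta0, u0,
                  tol=1e-8, max_iter=100):
    """Damped Newton for the inner mode.

    ``profile_beta=True`` solves jointly over (beta, u); otherwise beta is
    held at ``beta0`` and only u is optimised.  Returns (beta, u, H_uu
    Cholesky factor, n_iter).  The objective (Tweedie mu-part plus field
    quadratic form) is strictly convex, so Newton with step halving is
    globally convergent.
    """
    n_beta = X.shape[1] if profile_beta else 0
    u = u0.copy()
    beta = beta0.copy()

    def obj(beta_, u_):
        eta = X @ beta_ + A @ u_
        return _obs_mu_part(y, eta, phi, p, family) + 0.5 * float(u_ @ (Qd @ u_))

    f = obj(beta, u)
    for it in range(max_iter):
        eta = X @ beta + A @ u
        g, w = _obs_derivs(y, eta, phi, p, family)
        grad_u = A.T @ g + Qd @ u
        AW = A.multiply(w[:, None]) if sp.issparse(A) else A * w[:, None]
        H_uu = Qd + (A.T @ AW).toarray() if sp.issparse(A) else Qd + A.T @ AW
        if profile_beta:
            grad = np.concatenate([X.T @ g, grad_u])
            Xw = X * w[:, None]
            H_bb = X.T @ Xw
            H_bu = (Xw.T @ A.toarray()) if sp.issparse(A) else Xw.T @ A
            H = np.block([[H_bb, H_bu], [H_bu.T, H_uu]])
        else:
            grad = grad_u
            H = H_uu
        gnorm = np.max(np.abs(grad))
        if gnorm < tol * max(1.0, abs(f)):
            break
        try:
            cf = sla.cho_factor(H, lower=True)
        except sla.LinAlgError:
            H = H + 1e-8 * np.eye(H.shape[0])  # Levenberg fallback
            cf = sla.cho_factor(H, lower=True)
        step = sla.cho_solve(cf, -grad)
        t = 1.0
        for _ in range(40):
            beta_t = beta + t * step[:n_beta] if profile_beta else beta
            u_t = u + t * step[n_beta:]
            f_t = obj(beta_t, u_t)
            if np.isfinite(f_t) and f_t <= f + 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        else:  # pragma: no cover - convex objective
            raise RuntimeError("inner line search failed")
        beta, u, f = beta_t, u_t, f_t
    else:
        raise RuntimeError(
            f"inner Newton did not converge in {max_iter} iterations "
            f"(|grad|={gnorm:.2e})"
        )
    eta = X @ beta + A @ u
    _, w = _obs_derivs(y, eta, phi, p, family)
    AW = A.multiply(w[:, None]) if sp.issparse(A) else A * w[:, None]
    H_uu = Qd + ((A.T @ AW).toarray() if sp.issparse(A) else A.T @ AW)
    cf_uu = sla.cho_factor(H_uu, lower=True)
    return beta, u, cf_uu, it + 1


def laplace_marginal_nll(
    beta, y, X, A, Q_st, tweedie: TweedieParams,
    u0=None, family: str = "tweedie", logdet_Q: float | None = None,
):
    """Laplace-approximated -log marginal likelihood at fixed beta.

    nll = joint_nll(u_hat) + 1/2 logdet H(u_hat) - (n_u/2) log 2pi, where
    u_hat is the inner Newton mode and H the conditional precision of u.
    """
    Qd = Q_st.toarray() if sp.issparse(Q_st) else np.asarray(Q_st, float)
    n_u = Qd.shape[0]
    if u0 is None:
        u0 = np.zeros(n_u)
    beta = np.asarray(beta, float)
    _, u_hat, cf_uu, _ = _inner_newton(
        y, X, A, Qd, tweedie.phi, tweedie.p, family, False, beta, u0
    )
    if logdet_Q is None:
        logdet_Q = gmrf_logdet(Q_st)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cf_uu[0]))))
    return (
        joint_nll(beta, u_hat, y, X, A, Q_st, tweedie, logdet_Q, family)
        + 0.5 * logdet_H
        - 0.5 * n_u * np.log(2 * np.pi)
    ), u_hat


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    spec: ModelSpec
    info: DesignInfo
    mesh: SpdeMesh
    months: tuple
    beta: np.ndarray
    u: np.ndarray                  # (n_time, n_k)
    field_params: FieldParams
    tweedie_params: TweedieParams
    marginal_nll: float
    cov_beta: np.ndarray
    theta: np.ndarray
    data: pd.DataFrame = field(repr=False, default=None)
    fitted_eta: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    n_outer_evals: int = 0
    reml: bool = False
    _sigma_se_log: float | None = None

    @property
    def n_params(self) -> int:
        # fixed effects + (range, sigma, rho, phi, p); random effects excluded
        return self.beta.size + 5

    def predict_linear(self, data: pd.DataFrame, year_mode: str = "strict"):
        return design_matrix(self.info, data, year_mode) @ self.beta


def _theta_pack(fp: FieldParams, tw: TweedieParams) -> np.ndarray:
    return np.array([
        np.log(fp.range_km), np.log(fp.sigma), np.arctanh(fp.rho),
        np.log(tw.phi), logit(tw.p - 1.0),
    ])


def _theta_unpack(theta) -> tuple[FieldParams, TweedieParams]:
    fp = FieldParams(
        range_km=float(np.exp(theta[0])),
        sigma=float(np.exp(theta[1])),
        rho=float(np.tanh(theta[2])),
    )
    tw = TweedieParams(p=1.0 + float(expit(theta[4])), phi=float(np.exp(theta[3])))
    return fp, tw


_THETA_BOUNDS = [(np.log(1.0), np.log(1000.0)), (np.log(1e-3), np.log(20.0)),
                 (-2.7, 2.7), (np.log(1e-3), np.log(100.0)), (-6.0, 6.0)]


def make_obs_projector(mesh: SpdeMesh, data: pd.DataFrame,
                       months: tuple = MONTHS) -> sp.csr_matrix:
    """n_obs x (n_time * n_k) matrix selecting each observation's month slice."""
    A_space = projector(mesh, data[["x_km", "y_km"]].to_numpy())
    n_k = mesh.n_nodes
    n_time = len(months)
    month_idx = {m: i for i, m in enumerate(months)}
    coo = A_space.tocoo()
    t = np.array([month_idx[int(m)] for m in data["month"].to_numpy()])
    cols = coo.col + t[coo.row] * n_k
    return sp.csr_matrix(
        (coo.data, (coo.row, cols)), shape=(A_space.shape[0], n_time * n_k)
    )


def fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    mesh: SpdeMesh,
    init: dict | None = None,
    seed: int = 0,
    months: tuple = MONTHS,
    family: str = "tweedie",
    outer_tol: float = 1e-7,
    reml: bool = False,
) -> FittedModel:
    """Maximum marginal likelihood fit of the spatiotemporal GLMM.

    ``data`` needs columns x_km, y_km, year, month, biomass_mg_m2 and the
    spec's covariates.  beta and the latent field are profiled in the inner
    Newton solve; the outer L-BFGS-B runs on the five transformed
    hyperparameters with finite-difference gradients.  ``reml=True`` adds
    the fixed-effect block of the joint Hessian to the Laplace
    log-determinant (restricted likelihood), which removes most of the
    small-sample downward bias of the range and field-SD estimates; use
    plain ML (the default) when comparing models with different fixed
    effects by AIC.  Deterministic given identical inputs.
    """
    if len(data) < 50:
        raise ValueError("need at least 50 observations")
    present = set(int(m) for m in data["month"].unique())
    if not set(months) <= present:
        raise ValueError(f"months {sorted(set(months) - present)} have no data")

    y = data["biomass_mg_m2"].to_numpy(dtype=float)
    X, info = build_design(data, spec)
    A = make_obs_projector(mesh, data, months)
    n_k, n_time = mesh.n_nodes, len(months)
    n_u = n_k * n_time

    init = init or {}
    fp0 = FieldParams(
        range_km=init.get("range_km", 0.25 * float(
            np.hypot(*(data[["x_km", "y_km"]].max() - data[["x_km", "y_km"]].min()))
        )),
        sigma=init.get("sigma", 0.5),
        rho=init.get("rho", 0.0),
    )
    p0 = init.get("p", 1.5)
    # moment-based dispersion start: var(y)/mean(y)^p overshoots because the
    # latent field owns part of the variance; a third of it starts the outer
    # search on the smooth-field side of the likelihood ridge
    if family == "tweedie" and "phi" not in init and y.mean() > 0:
        phi0 = float(np.clip(y.var() / y.mean() ** p0 / 3.0, 0.3, 50.0))
    else:
        phi0 = init.get("phi", 1.0)
    tw0 = TweedieParams(p=p0, phi=phi0)
    theta0 = _theta_pack(fp0, tw0)

    state = {"beta": np.zeros(X.shape[1]), "u": np.zeros(n_u), "evals": 0}
    if family == "tweedie":
        state["beta"][0] = np.log(max(y.mean(), 1e-6))
    else:
        state["beta"][0] = y.mean()

    def profile_nll(theta):
        fp, tw = _theta_unpack(theta)
        Q_space = precision_from_params(mesh, fp)
        Q_st = spacetime_precision(Q_space, fp.rho, n_time)
        logdet_Q = (
            n_k * float(np.linalg.slogdet(
                np.atleast_2d(_ar1_dense(fp.rho, n_time)))[1])
            + n_time * gmrf_logdet(Q_space)
        )
        Qd = Q_st.toarray()
        try:
            beta, u, cf_uu, _ = _inner_newton(
                y, X, A, Qd, tw.phi, tw.p, family, True,
                state["beta"], state["u"],
            )
        except (RuntimeError, FloatingPointError):
            return 1e12
        state["beta"], state["u"] = beta, u
        state["evals"] += 1
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(cf_uu[0]))))
        if reml:
            eta = X @ beta + A @ u
            _, w = _obs_derivs(y, eta, tw.phi, tw.p, family)
            Xw = X * w[:, None]
            H_bb = X.T @ Xw
            H_bu = Xw.T @ A.toarray()
            schur = H_bb - H_bu @ sla.cho_solve(cf_uu, H_bu.T)
            logdet_H += float(np.linalg.slogdet(schur)[1])
        return (
            _obs_nll(y, X @ beta + A @ u, tw.phi, tw.p, family)
            + 0.5 * float(u @ (Qd @ u))
            - 0.5 * logdet_Q
            + 0.5 * logdet_H
        )

    res = sopt.minimize(
        profile_nll, theta0, method="L-BFGS-B", bounds=_THETA_BOUNDS,
        options={"ftol": outer_tol, "gtol": 1e-6, "eps": 1e-5, "maxiter": 200},
    )
    fp, tw = _theta_unpack(res.x)
    nll = profile_nll(res.x)  # refresh state at the optimum
    beta, u = state["beta"], state["u"]

    # fixed-effect covariance from the joint Hessian's beta Schur complement
    eta = X @ beta + A @ u
    _, w = _obs_derivs(y, eta, tw.phi, tw.p, family)
    Q_st = spacetime_precision(precision_from_params(mesh, fp), fp.rho, n_time)
    Qd = Q_st.toarray()
    AW = A.multiply(w[:, None])
    H_uu = Qd + (A.T @ AW).toarray()
    Xw = X * w[:, None]
    H_bb = X.T @ Xw
    H_bu = Xw.T @ A.toarray()
    cf = sla.cho_factor(H_uu, lower=True)
    schur = H_bb - H_bu @ sla.cho_solve(cf, H_bu.T)
    cov_beta = np.linalg.inv(schur)

    if not res.success:
        logger.warning("outer optimizer flagged non-convergence: %s", res.message)
    return FittedModel(
        spec=spec, info=info, mesh=mesh, months=tuple(months),
        beta=beta, u=u.reshape(n_time, n_k),
        field_params=fp, tweedie_params=tw,
        marginal_nll=float(nll), cov_beta=cov_beta, theta=res.x.copy(),
        data=data.reset_index(drop=True), fitted_eta=eta,
        converged=bool(res.success), n_outer_evals=state["evals"],
        reml=reml,
    )


def _ar1_dense(rho, n_time):
    from .spde import ar1_precision

    return ar1_precision(rho, n_time)


def aic(fitted: FittedModel) -> float:
    """2 * n_params + 2 * marginal nll; random effects are not counted."""
    return 2.0 * fitted.n_params + 2.0 * fitted.marginal_nll


def sigma_ci(fitted: FittedModel, level: float = 0.95) -> tuple[float, float]:
    """Wald CI for the field SD via the delta method on log sigma.

    Uses a finite-difference Hessian of the outer objective; cached."""
    if fitted._sigma_se_log is None:
        fitted._sigma_se_log = _theta_se(fitted)[1]
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    s = fitted.field_params.sigma
    se = fitted._sigma_se_log
    return float(s * np.exp(-z * se)), float(s * np.exp(z * se))


def _theta_se(fitted: FittedModel) -> np.ndarray:
    y = fitted.data["biomass_mg_m2"].to_numpy(dtype=float)
    X = design_matrix(fitted.info, fitted.data)
    A = make_obs_projector(fitted.mesh, fitted.data, fitted.months)
    n_time, n_k = fitted.u.shape

    def f(theta):
        fp, tw = _theta_unpack(theta)
        Q_space = precision_from_params(fitted.mesh, fp)
        Q_st = spacetime_precision(Q_space, fp.rho, n_time)
        Qd = Q_st.toarray()
        beta, u, cf_uu, _ = _inner_newton(
            y, X, A, Qd, tw.phi, tw.p, "tweedie",
            True, fitted.beta, fitted.u.ravel(),
        )
        logdet_Q = (
            n_k * float(np.linalg.slogdet(np.atleast_2d(
                _ar1_dense(fp.rho, n_time)))[1])
            + n_time * gmrf_logdet(Q_space)
        )
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(cf_uu[0]))))
        if fitted.reml:
            eta = X @ beta + A @ u
            _, w = _obs_derivs(y, eta, tw.phi, tw.p, "tweedie")
            Xw = X * w[:, None]
            schur = X.T @ Xw - (Xw.T @ A.toarray()) @ sla.cho_solve(
                cf_uu, (Xw.T @ A.toarray()).T)
            logdet_H += float(np.linalg.slogdet(schur)[1])
        return (
            _obs_nll(y, X @ beta + A @ u, tw.phi, tw.p, "tweedie")
            + 0.5 * float(u @ (Qd @ u)) - 0.5 * logdet_Q + 0.5 * logdet_H
        )

    h = 1e-3
    t0 = fitted.theta
    n = t0.size
    H = np.zeros((n, n))
    f0 = f(t0)
    fp_ = np.array([f(t0 + h * e) for e in np.eye(n)])
    fm_ = np.array([f(t0 - h * e) for e in np.eye(n)])
    for i in range(n):
        H[i, i] = (fp_[i] - 2 * f0 + fm_[i]) / h**2
        for j in range(i + 1, n):
            fpp = f(t0 + h * (np.eye(n)[i] + np.eye(n)[j]))
            H[i, j] = H[j, i] = (
                fpp - fp_[i] - fp_[j] + f0
            ) / h**2
    cov = np.linalg.pinv(0.5 * (H + H.T))
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def conditional_effects(
    fitted: FittedModel, covariate: str, n_grid: int = 50
) -> pd.DataFrame:
    """Predicted biomass along one covariate, others at biomass-weighted
    reference values.

    All other covariates sit at their biomass-weighted means (weights = the
    observed group biomass at each haul), month at the group's peak-biomass
    month, year at its average effect, and the spatiotemporal field at its
    mean (zero).  CIs (50% and 95%) come from the fixed-effect covariance
    by the delta method on the log scale, then exponentiated.
    """
    if covariate not in fitted.info.term_meta:
        raise ValueError(f"covariate {covariate!r} not in the fitted spec")
    data = fitted.data
    wts = data["biomass_mg_m2"].to_numpy(dtype=float)
    if wts.sum() <= 0:
        import warnings

        warnings.warn("all observed biomass is zero; using unweighted means",
                      stacklevel=2)
        wts = np.ones_like(wts)
    wts = wts / wts.sum()

    def ref_cols(term_name, values_std):
        _, _, _, meta = fitted.info.term_meta[term_name]
        return meta.evaluate(np.atleast_1d(values_std))

    # peak month: highest predicted density with all splines at reference
    base = {"intercept": 1.0}
    n_lev = len(fitted.info.year_levels)
    month_rows = fitted.info.month_meta.evaluate(np.array(MONTHS, float))
    refs = {}
    for term in fitted.info.terms:
        transform, mean, sd, _ = fitted.info.term_meta[term.name]
        zs = (_transform(data[term.name].to_numpy(), transform) - mean) / sd
        refs[term.name] = float(np.sum(wts * zs))

    def assemble(month_row, grid_term=None, grid_vals=None):
        n = 1 if grid_vals is None else len(grid_vals)
        cols = [np.ones((n, 1)), np.full((n, n_lev - 1), 1.0 / n_lev),
                np.tile(month_row, (n, 1))]
        for term in fitted.info.terms:
            if term.name == grid_term:
                cols.append(ref_cols(term.name, grid_vals))
            else:
                cols.append(np.tile(ref_cols(term.name, refs[term.name]), (n, 1)))
        return np.hstack(cols)

    etas = np.array([
        (assemble(month_rows[i]) @ fitted.beta).item()
        for i in range(len(MONTHS))
    ])
    peak_month_row = month_rows[int(np.argmax(etas))]

    transform, mean, sd, _ = fitted.info.term_meta[covariate]
    z = _transform(data[covariate].to_numpy(), transform)
    grid_raw = np.linspace(data[covariate].min(), data[covariate].max(), n_grid)
    grid_std = (_transform(grid_raw, transform) - mean) / sd
    B = assemble(peak_month_row, covariate, grid_std)
    eta = B @ fitted.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", B, fitted.cov_beta, B))
    out = pd.DataFrame({
        "x": grid_raw,
        "mean": np.exp(eta),
        "lo50": np.exp(eta - 0.6744897501960817 * se),
        "hi50": np.exp(eta + 0.6744897501960817 * se),
        "lo95": np.exp(eta - 1.959963984540054 * se),
        "hi95": np.exp(eta + 1.959963984540054 * se),
    })
    out.attrs["peak_month"] = int(MONTHS[int(np.argmax(etas))])
    return out
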