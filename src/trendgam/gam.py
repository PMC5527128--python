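"""Penalized-spline GAM fitting for Gaussian/identity and Gamma/log models.

Coefficients are estimated by penalized iteratively reweighted least squares
(PIRLS); smoothing parameters are chosen by maximizing a Laplace-approximate
restricted likelihood evaluated on the converged working model (exact REML in
the Gaussian case, performance-iteration REML for the Gamma family).
Inference uses the Bayesian posterior covariance
``V_beta = phi * (X'WX + S_lambda)^{-1}``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from trendgam.splines import ConstrainedBasis

LOG10_LAMBDA_BOUNDS = (-8.0, 8.0)
_RANK_RTOL = 1e-9


class GamConvergenceError(RuntimeError):
    """PIRLS or the REML optimizer failed to converge.

    Carries the criterion trace accumulated up to the failure.
    """

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = list(trace or [])


# ---------------------------------------------------------------------------
# families


class _Family:
    name: str
    link: str

    @staticmethod
    def validate(y: np.ndarray) -> None: ...

    @staticmethod
    def initialize(y: np.ndarray) -> np.ndarray: ...

    @staticmethod
    def linkfun(mu: np.ndarray) -> np.ndarray: ...

    @staticmethod
    def linkinv(eta: np.ndarray) -> np.ndarray: ...

    @staticmethod
    def mu_eta(eta: np.ndarray) -> np.ndarray: ...

    @staticmethod
    def variance(mu: np.ndarray) -> np.ndarray: ...

    @staticmethod
    def deviance_residuals_sq(y: np.ndarray, mu: np.ndarray) -> np.ndarray: ...


class GaussianIdentity(_Family):
    name = "gaussian"
    link = "identity"

    @staticmethod
    def validate(y):
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")

    @staticmethod
    def initialize(y):
        return np.asarray(y, dtype=float).copy()

    @staticmethod
    def linkfun(mu):
        return mu

    @staticmethod
    def linkinv(eta):
        return eta

    @staticmethod
    def mu_eta(eta):
        return np.ones_like(eta)

    @staticmethod
    def variance(mu):
        return np.ones_like(mu)

    @staticmethod
    def deviance_residuals_sq(y, mu):
        return (y - mu) ** 2


class GammaLog(_Family):
    name = "gamma"
    link = "log"

    @staticmethod
    def validate(y):
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if np.any(y <= 0):
            bad = np.flatnonzero(y <= 0)
            raise ValueError(
                f"gamma family requires strictly positive response; "
                f"non-positive at rows {bad[:20].tolist()}"
            )

    @staticmethod
    def initialize(y):
        return np.asarray(y, dtype=float).copy()

    @staticmethod
    def linkfun(mu):
        return np.log(mu)

    @staticmethod
    def linkinv(eta):
        return np.exp(np.clip(eta, -700, 700))

    @staticmethod
    def mu_eta(eta):
        return np.exp(np.clip(eta, -700, 700))

    @staticmethod
    def variance(mu):
        return mu**2

    @staticmethod
    def deviance_residuals_sq(y, mu):
        return 2.0 * ((y - mu) / mu - np.log(y / mu))


_FAMILIES = {
    ("gaussian", "identity"): GaussianIdentity,
    ("gamma", "log"): GammaLog,
}


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ParametricTerm:
    """A named parametric column (e.g. intercept or a treatment indicator)."""

    name: str
    column: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SmoothTerm:
    """A penalized smooth of time, optionally switched off per observation.

    ``by`` (if given) is a 0/1 indicator of length n; rows with ``by == 0``
    contribute zero to this term (a treatment-specific smoother).
    """

    name: str
    basis: ConstrainedBasis
    times: np.ndarray = field(repr=False)
    by: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class ModelSpec:
    parametric_terms: tuple[ParametricTerm, ...]
    smooth_terms: tuple[SmoothTerm, ...]
    family: str = "gaussian"
    link: str = "identity"

    def __post_init__(self):
        if (self.family, self.link) not in _FAMILIES:
            raise ValueError(
                f"unsupported family/link pair ({self.family}, {self.link}); "
                f"supported: gaussian/identity, gamma/log"
            )
        names = [t.name for t in self.parametric_terms] + [t.name for t in self.smooth_terms]
        if len(set(names)) != len(names):
            raise ValueError("term names must be unique")
        for t in self.smooth_terms:
            if t.by is not None and not np.all(np.isin(np.asarray(t.by), (0, 1))):
                raise ValueError(f"by-indicator of smooth '{t.name}' must be 0/1")

    @property
    def family_obj(self) -> type[_Family]:
        return _FAMILIES[(self.family, self.link)]


@dataclass
class _Design:
    """Assembled numeric design shared by PIRLS and the REML search."""

    X: np.ndarray
    n: int
    p: int
    param_slice: slice
    param_names: list[str]
    smooth_names: list[str]
    smooth_slices: list[slice]
    smooth_penalties: list[np.ndarray]  # block penalties, each (d_j, d_j)
    penalty_ranks: list[int]
    penalty_logdets: list[float]  # sum of log positive eigenvalues per block
    null_dim: int  # dimension of the null space of the total penalty
    family: type[_Family]

    def penalized_matrix(self, XtWX: np.ndarray, lam: np.ndarray) -> np.ndarray:
        A = XtWX.copy()
        for lj, sl, S in zip(lam, self.smooth_slices, self.smooth_penalties):
            A[sl, sl] += lj * S
        return A

    def penalty_quadform(self, beta: np.ndarray, lam: np.ndarray) -> float:
        total = 0.0
        for lj, sl, S in zip(lam, self.smooth_slices, self.smooth_penalties):
            b = beta[sl]
            total += lj * float(b @ S @ b)
        return total

    def log_det_penalty(self, lam: np.ndarray) -> float:
        # penalty blocks are disjoint, so the positive-part log-determinant is
        # additive: sum_j [rank_j * log(lam_j) + logdet+(S_j)]
        return float(
            sum(
                r * math.log(lj) + ld
                for lj, r, ld in zip(lam, self.penalty_ranks, self.penalty_logdets)
            )
        )


def _assemble(spec: ModelSpec, n: int) -> _Design:
    cols: list[np.ndarray] = []
    param_names = []
    for t in spec.parametric_terms:
        c = np.asarray(t.column, dtype=float).ravel()
        if c.size != n:
            raise ValueError(f"parametric term '{t.name}' has length {c.size}, expected {n}")
        cols.append(c[:, None])
        param_names.append(t.name)
    n_param = len(cols)
    smooth_names, smooth_slices, penalties, ranks, logdets = [], [], [], [], []
    offset = n_param
    blocks = []
    for t in spec.smooth_terms:
        times = np.asarray(t.times, dtype=float).ravel()
        if times.size != n:
            raise ValueError(f"smooth term '{t.name}' covariate length mismatch")
        B = t.basis.evaluate(times)
        if t.by is not None:
            B = B * np.asarray(t.by, dtype=float)[:, None]
        d = B.shape[1]
        S = t.basis.penalty
        S = 0.5 * (S + S.T)
        eig = np.linalg.eigvalsh(S)
        tol = max(eig.max(), 0.0) * _RANK_RTOL
        pos = eig[eig > tol]
        smooth_names.append(t.name)
        smooth_slices.append(slice(offset, offset + d))
        penalties.append(S)
        ranks.append(int(pos.size))
        logdets.append(float(np.log(pos).sum()))
        blocks.append(B)
        offset += d
    X = np.hstack(cols + blocks) if (cols or blocks) else np.empty((n, 0))
    p = X.shape[1]
    null_dim = p - sum(ranks)
    return _Design(
        X=X,
        n=n,
        p=p,
        param_slice=slice(0, n_param),
        param_names=param_names,
        smooth_names=smooth_names,
        smooth_slices=smooth_slices,
        smooth_penalties=penalties,
        penalty_ranks=ranks,
        penalty_logdets=logdets,
        null_dim=null_dim,
        family=spec.family_obj,
    )


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedGAM:
    """A converged penalized GAM fit.

    ``edf`` maps each term name to its effective degrees of freedom; smooth
    e.d.f. is the trace of the corresponding diagonal block of
    ``F = (X'WX + S_lambda)^{-1} X'WX``.
    """

    spec: ModelSpec
    y: np.ndarray
    coefficients: np.ndarray
    lam: np.ndarray
    dispersion: float
    covariance: np.ndarray  # posterior V_beta = phi (X'WX + S_lambda)^{-1}
    edf: dict[str, float]
    total_edf: float
    deviance: float
    fitted: np.ndarray
    linear_predictor: np.ndarray
    working_weights: np.ndarray
    iterations: int
    converged: bool
    criterion_trace: list[float]
    reml_criterion: float | None
    lambda_at_bound: bool
    design: _Design = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def residual_dof(self) -> float:
        return self.n - self.total_edf

    def term_slice(self, term: str) -> slice:
        d = self.design
        if term in d.smooth_names:
            return d.smooth_slices[d.smooth_names.index(term)]
        if term in d.param_names:
            i = d.param_names.index(term)
            return slice(i, i + 1)
        raise KeyError(f"unknown term '{term}'")

    def smooth_term(self, term: str) -> SmoothTerm:
        for t in self.spec.smooth_terms:
            if t.name == term:
                return t
        raise KeyError(f"'{term}' is not a smooth term")


def _pirls(design: _Design, y: np.ndarray, lam: np.ndarray, *, max_iter: int = 200,
           tol: float = 1e-8):
    """Inner penalized IRLS loop at fixed smoothing parameters.

    Returns the converged state including the final working response/weights
    (needed by the REML criterion).
    """
    fam = design.family
    X = design.X
    mu = fam.initialize(y)
    eta = fam.linkfun(mu)
    dev = float(fam.deviance_residuals_sq(y, mu).sum())
    trace = [dev]
    beta = np.zeros(design.p)
    z = w = None
    XtWX = XtWz = None
    converged = False
    for it in range(1, max_iter + 1):
        g1 = fam.mu_eta(eta)
        z = eta + (y - mu) / g1
        w = g1**2 / fam.variance(mu)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWz = Xw.T @ z
        A = design.penalized_matrix(XtWX, lam)
        try:
            c, low = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover - degenerate design
            raise GamConvergenceError(f"penalized system not positive definite: {e}", trace)
        beta = cho_solve((c, low), XtWz)
        eta = X @ beta
        mu = fam.linkinv(eta)
        new_dev = float(fam.deviance_residuals_sq(y, mu).sum())
        trace.append(new_dev)
        if abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        raise GamConvergenceError(
            f"PIRLS did not converge in {max_iter} iterations", trace
        )
    return beta, eta, mu, dev, z, w, XtWX, it, trace


def _working_reml(design: _Design, lam: np.ndarray, beta: np.ndarray, z: np.ndarray,
                  w: np.ndarray, XtWX: np.ndarray) -> float:
    """Laplace-approximate restricted log-likelihood of the working model,
    with the scale profiled out.  Larger is better."""
    n = design.n
    r = design.X @ beta - z
    rss_pen = float(r @ (w * r)) + design.penalty_quadform(beta, lam)
    rss_pen = max(rss_pen, 1e-300)
    A = design.penalized_matrix(XtWX, lam)
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    nmp = n - design.null_dim
    phi = rss_pen / nmp
    return float(
        -0.5 * nmp * (math.log(2 * math.pi * phi) + 1.0)
        - 0.5 * logdet_A
        + 0.5 * design.log_det_penalty(lam)
        + 0.5 * design.null_dim * math.log(2 * math.pi)
    )


def _finalize(spec: ModelSpec, design: _Design, y: np.ndarray, lam: np.ndarray,
              state, reml: float | None, criterion_trace: list[float]) -> FittedGAM:
    beta, eta, mu, dev, z, w, XtWX, iters, _ = state
    A = design.penalized_matrix(XtWX, lam)
    Ainv = np.linalg.inv(A)
    F = Ainv @ XtWX
    edf: dict[str, float] = {}
    for name in design.param_names:
        i = design.param_names.index(name)
        edf[name] = float(F[i, i])
    for name, sl in zip(design.smooth_names, design.smooth_slices):
        edf[name] = float(np.trace(F[sl, sl]))
    total_edf = float(np.trace(F))
    fam = design.family
    pearson = (y - mu) / np.sqrt(fam.variance(mu))
    resid_dof = max(design.n - total_edf, 1.0)
    phi = float((pearson**2).sum() / resid_dof)
    if fam is GaussianIdentity:
        # for the gaussian family the Pearson estimator is the usual RSS-based one
        pass
    cov = phi * Ainv
    lo, hi = LOG10_LAMBDA_BOUNDS
    with np.errstate(divide="ignore"):
        log_lam = np.log10(lam) if lam.size else lam
    at_bound = bool(lam.size and np.any((log_lam <= lo + 1e-6) | (log_lam >= hi - 1e-6)))
    return FittedGAM(
        spec=spec,
        y=np.asarray(y, dtype=float),
        coefficients=beta,
        lam=lam.copy(),
        dispersion=phi,
        covariance=cov,
        edf=edf,
        total_edf=total_edf,
        deviance=dev,
        fitted=mu,
        linear_predictor=eta,
        working_weights=w,
        iterations=iters,
        converged=True,
        criterion_trace=criterion_trace,
        reml_criterion=reml,
        lambda_at_bound=at_bound,
        design=design,
    )


def pirls_fit(spec: ModelSpec, y: np.ndarray, lam: np.ndarray | float) -> FittedGAM:
    """Fit the model at fixed smoothing parameters ``lam`` (one per smooth)."""
    y = np.asarray(y, dtype=float).ravel()
    spec.family_obj.validate(y)
    design = _assemble(spec, y.size)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.size != len(design.smooth_names):
        raise ValueError(
            f"expected {len(design.smooth_names)} smoothing parameters, got {lam.size}"
        )
    if np.any(lam < 0):
        raise ValueError("smoothing parameters must be non-negative")
    state = _pirls(design, y, lam)
    return _finalize(spec, design, y, lam, state, None, state[8])


def optimize_reml(spec: ModelSpec, y: np.ndarray) -> FittedGAM:
    """Fit the model with smoothing parameters chosen by REML.

    The search runs a coarse scan plus bounded Brent refinement per
    log10-smoothing-parameter coordinate (two sweeps), then a joint
    Nelder-Mead polish.  Bounds are ``log10 lambda in [-8, 8]``.
    """
    y = np.asarray(y, dtype=float).ravel()
    spec.family_obj.validate(y)
    design = _assemble(spec, y.size)
    m = len(design.smooth_names)
    if m == 0:
        state = _pirls(design, y, np.empty(0))
        return _finalize(spec, design, y, np.empty(0), state, None, state[8])

    trace: list[float] = []

    def neg_criterion(rho: np.ndarray) -> float:
        lam = 10.0 ** np.clip(rho, *LOG10_LAMBDA_BOUNDS)
        try:
            state = _pirls(design, y, lam)
        except GamConvergenceError:
            return np.inf
        val = _working_reml(design, lam, state[0], state[4], state[5], state[6])
        trace.append(val)
        return -val

    lo, hi = LOG10_LAMBDA_BOUNDS
    rho = np.zeros(m)
    coarse = np.arange(lo, hi + 0.5, 1.0)
    for _sweep in range(2):
        for j in range(m):
            def f1(r, j=j):
                rr = rho.copy()
                rr[j] = r
                return neg_criterion(rr)

            vals = [f1(r) for r in coarse]
            best = coarse[int(np.argmin(vals))]
            res = optimize.minimize_scalar(
                f1,
                bounds=(max(lo, best - 1.5), min(hi, best + 1.5)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            rho[j] = float(res.x)
    res = optimize.minimize(
        neg_criterion,
        rho,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200 * m},
    )
    if np.isfinite(res.fun) and res.fun <= neg_criterion(rho):
        rho = np.clip(res.x, lo, hi)
    if not np.isfinite(neg_criterion(rho)):
        raise GamConvergenceError("REML optimization failed to find a finite criterion", trace)
    lam = 10.0 ** rho
    state = _pirls(design, y, lam)
    reml = _working_reml(design, lam, state[0], state[4], state[5], state[6])
    fit = _finalize(spec, design, y, lam, state, reml, trace)
    if fit.lambda_at_bound:
        warnings.warn(
            "a smoothing parameter hit its bound [1e-8, 1e8]", RuntimeWarning, stacklevel=2
        )
    return fit


# ---------------------------------------------------------------------------
# post-fit summaries


def edf_per_term(fit: FittedGAM) -> dict[str, float]:
    """Named effective degrees of freedom, one entry per model term."""
    return dict(fit.edf)


def approx_pvalue(fit: FittedGAM, term: str) -> dict:
    """Approximate Wald-type significance test for a smooth term.

    The statistic is ``f' V_f^- f`` where ``f`` is the term evaluated at its
    design points and ``V_f^-`` is the rank-r pseudo-inverse of its posterior
    covariance, with ``r = max(1, round(e.d.f.))``.  Gaussian fits refer the
    statistic to chi-square(r); gamma fits (estimated dispersion) use
    ``F(r, residual dof)``.  The construction is approximate by design.
    """
    st = fit.smooth_term(term)
    sl = fit.term_slice(term)
    pts = np.unique(st.times if st.by is None else np.asarray(st.times)[np.asarray(st.by) == 1])
    B = st.basis.evaluate(pts)
    f = B @ fit.coefficients[sl]
    Vf = B @ fit.covariance[sl, sl] @ B.T
    Vf = 0.5 * (Vf + Vf.T)
    evals, evecs = np.linalg.eigh(Vf)
    tol = max(evals.max(), 0.0) * 1e-10
    pos = evals > tol
    if not pos.any():
        return {"term": term, "statistic": np.nan, "rank": 0, "p_value": np.nan,
                "degenerate": True}
    r = int(max(1, round(fit.edf[term])))
    r = min(r, int(pos.sum()))
    order = np.argsort(evals)[::-1][:r]
    proj = evecs[:, order].T @ f
    stat = float((proj**2 / evals[order]).sum())
    if fit.spec.family == "gaussian":
        p = float(stats.chi2.sf(stat, r))
    else:
        p = float(stats.f.sf(stat / r, r, max(fit.residual_dof, 1.0)))
    return {"term": term, "statistic": stat, "rank": r, "p_value": p, "degenerate": False}


def confidence_band(fit: FittedGAM, term: str, grid: np.ndarray, level: float = 0.95) -> dict:
    """Pointwise Bayesian credible band for a smooth term on ``grid``.

    Returns estimate, standard error, lower/upper bounds (``est +/- z*SE``)
    and an extrapolation flag per grid point.  Values are on the linear
    predictor (link) scale.
    """
    st = fit.smooth_term(term)
    sl = fit.term_slice(term)
    grid = np.asarray(grid, dtype=float).ravel()
    B = st.basis.evaluate(grid)
    est = B @ fit.coefficients[sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, fit.covariance[sl, sl], B), 0.0))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return {
        "grid": grid,
        "estimate": est,
        "se": se,
        "lower": est - z * se,
        "upper": est + z * se,
        "extrapolated": st.basis.is_extrapolating(grid),
    }


def residual_diagnostics(fit: FittedGAM) -> dict:
    """Residual vectors plus a simple heteroscedasticity screen.

    The screen regresses |Pearson residual| on the fitted values and reports
    the slope with its p-value; a clearly positive slope flags variance
    increasing with the mean.
    """
    fam = fit.spec.family_obj
    y, mu = fit.y, fit.fitted
    d2 = np.maximum(fam.deviance_residuals_sq(y, mu), 0.0)
    dev_res = np.sign(y - mu) * np.sqrt(d2)
    pearson = (y - mu) / np.sqrt(fam.variance(mu))
    n = y.size
    srt = np.sort(dev_res)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_corr = float(np.corrcoef(srt, theo)[0, 1]) if n > 2 else np.nan
    if np.ptp(mu) > 0:
        reg = stats.linregress(mu, np.abs(pearson))
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    else:
        slope, slope_p = 0.0, 1.0
    return {
        "deviance_residuals": dev_res,
        "pearson_residuals": pearson,
        "fitted": mu.copy(),
        "qq_correlation": qq_corr,
        "hetero_slope": slope,
        "hetero_slope_p": slope_p,
    }
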