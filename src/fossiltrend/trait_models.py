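"""Maximum-likelihood trait-evolution models on fossil-tipped time trees.

Seven Gaussian models for a continuous trait (log10 body length) observed at
the tips of a time-calibrated, generally non-ultrametric phylogeny:

==============  ===========================================================
model           process
==============  ===========================================================
BM              unbiased Brownian motion, constant rate sigma^2
OU              single-optimum Ornstein–Uhlenbeck, fixed root at theta
trend           biased random walk (BM + deterministic drift beta per Myr)
ACDC            BM with exponentially time-dependent rate sigma0^2 e^(r t)
rate_shift      BM whose rate switches from sigma2_1 to sigma2_2 at t_shift
env_rate        BM whose rate tracks an environmental curve,
                sigma^2(a) = sigma0^2 e^(b * env(a))
trend_shift     mode shift: unbiased BM until t_shift (Ma), then a trended
                random walk with drift beta; the covariance stays BM and
                tip means gain beta * max(0, t_shift - t_i)
==============  ===========================================================

All models share a multivariate-normal likelihood whose covariance is built
from root-to-MRCA shared path lengths; squared standard errors of the
species means are added to the diagonal to absorb measurement error. The
mean parameters (theta, and the trend coefficient where the mean is linear
in it) are profiled out by generalized least squares; the remaining
parameters are estimated numerically with multi-start bounded optimisation.
`t_shift` in the mode-shift model is found by a mandatory global grid scan
followed by local refinement, because its profile likelihood can contain
saddle points on fossil-poor trees.

Model comparison uses small-sample-corrected AIC (AICc) with n = number of
tips, and Akaike weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import quad
from scipy.interpolate import make_smoothing_spline
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .phylo_core import TimeTree, TreeSample
from .size_data import TraitDataset

__all__ = [
    "MODELS",
    "MODEL_K",
    "ModelFit",
    "EnvCurve",
    "SupportSurface",
    "BootstrapResult",
    "cov_bm",
    "cov_ou",
    "cov_acdc",
    "cov_rate_shift",
    "cov_env_rate",
    "mean_trend",
    "mean_trend_shift",
    "loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "compare_models",
    "support_surface",
    "parametric_bootstrap",
    "fit_over_sample",
    "smooth_env_curve",
]

MODELS = ("BM", "OU", "trend", "ACDC", "rate_shift", "env_rate", "trend_shift")

#: free-parameter counts (mean + variance parameters)
MODEL_K = {
    "BM": 2,
    "OU": 3,
    "trend": 3,
    "ACDC": 3,
    "rate_shift": 4,
    "env_rate": 3,
    "trend_shift": 4,
}

_LOG_S2_BOUNDS = (np.log(1e-10), np.log(1e4))
_LOG2PI = np.log(2.0 * np.pi)


# ======================================================================
# environmental curve
# ======================================================================


@dataclass
class EnvCurve:
    """A smooth proxy curve mapping age (Ma) to an environmental value.

    Evaluation outside ``[age_min, age_max]`` is constant at the boundary
    value (ages are clamped).
    """

    fn: Callable[[np.ndarray], np.ndarray]
    age_min: float
    age_max: float
    df: float | None = None

    def __call__(self, age):
        a = np.clip(np.asarray(age, dtype=float), self.age_min, self.age_max)
        out = self.fn(a)
        return float(out) if np.isscalar(age) else np.asarray(out, dtype=float)

    @classmethod
    def from_function(cls, fn, age_min: float, age_max: float) -> "EnvCurve":
        return cls(fn=fn, age_min=float(age_min), age_max=float(age_max))


def _spline_df(x: np.ndarray, lam: float, probes: np.ndarray | None) -> float:
    """Effective degrees of freedom (trace of the smoother matrix).

    Exact (column by column) for short series; a fixed-probe Hutchinson
    trace estimate for long ones, so the df(lambda) curve stays monotone
    during the bisection.
    """
    n = len(x)
    if probes is None:
        tr = 0.0
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            tr += make_smoothing_spline(x, e, lam=lam)(x[j])
            e[j] = 0.0
        return tr
    acc = 0.0
    for z in probes.T:
        acc += z @ make_smoothing_spline(x, z, lam=lam)(x)
    return acc / probes.shape[1]


def smooth_env_curve(age, value, df: float = 15.0) -> EnvCurve:
    """Cubic smoothing spline through (age, value) with a target effective df.

    Duplicate ages are averaged before fitting. The smoothing penalty is
    chosen by bisection so that the trace of the smoother matrix equals
    ``df`` (to ~0.05). Evaluation is clamped to the data range.
    """
    a = np.asarray(age, dtype=float)
    v = np.asarray(value, dtype=float)
    if a.shape != v.shape or a.ndim != 1:
        raise ValueError("age and value must be 1-D arrays of equal length")
    order = np.argsort(a)
    a, v = a[order], v[order]
    ua, inv = np.unique(a, return_inverse=True)
    if len(ua) != len(a):
        vv = np.zeros(len(ua))
        cnt = np.zeros(len(ua))
        np.add.at(vv, inv, v)
        np.add.at(cnt, inv, 1.0)
        a, v = ua, vv / cnt
    n = len(a)
    if n < df + 1:
        raise ValueError(f"need at least df+1 = {df + 1:g} distinct ages, got {n}")
    if n <= 150:
        probes = None
    else:
        probes = np.random.default_rng(12345).choice([-1.0, 1.0], size=(n, 16))
    lo, hi = -18.0, 25.0  # log lambda bracket; df is decreasing in lambda
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        d = _spline_df(a, float(np.exp(mid)), probes)
        if abs(d - df) < 0.05:
            break
        if d > df:
            lo = mid
        else:
            hi = mid
    spl = make_smoothing_spline(a, v, lam=float(np.exp(0.5 * (lo + hi))))
    return EnvCurve(fn=spl, age_min=float(a[0]), age_max=float(a[-1]), df=df)


# ======================================================================
# covariance and mean constructions
# ======================================================================


def cov_bm(tree: TimeTree, sigma2: float) -> np.ndarray:
    """Brownian-motion covariance: sigma2 times shared root-to-MRCA paths."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return sigma2 * tree.shared_path_matrix()


def cov_ou(tree: TimeTree, sigma2: float, alpha: float) -> np.ndarray:
    """Fixed-root (non-stationary) OU covariance on a possibly fossil tree.

    V_ij = (sigma2 / 2 alpha) e^(-alpha d_ij) (1 - e^(-2 alpha s_ij)) with
    s_ij the shared path from the root and d_ij the non-shared time
    separating tips i and j; continuous BM limit as alpha -> 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    S = tree.shared_path_matrix()
    if alpha < 1e-12:
        return sigma2 * S
    depth = np.diag(S)
    d = depth[:, None] + depth[None, :] - 2.0 * S
    return sigma2 * np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)


def cov_acdc(tree: TimeTree, sigma0_2: float, r: float) -> np.ndarray:
    """Accelerating/decelerating-rate covariance.

    The rate at time t after the root is sigma0^2 e^(r t); integrating along
    shared paths gives V_ij = sigma0^2 (e^(r s_ij) - 1) / r, with the BM
    limit sigma0^2 s_ij as r -> 0.
    """
    S = tree.shared_path_matrix()
    if abs(r) < 1e-12:
        return sigma0_2 * S
    return sigma0_2 * np.expm1(r * S) / r


def cov_rate_shift(
    tree: TimeTree, sigma2_old: float, sigma2_young: float, t_shift: float
) -> np.ndarray:
    """Two-regime BM covariance with a rate switch at age ``t_shift`` (Ma).

    sigma2_old applies to path time older than t_shift, sigma2_young to the
    younger portion.
    """
    if sigma2_old <= 0 or sigma2_young <= 0:
        raise ValueError("rates must be > 0")
    T = tree.root_age
    if not (0.0 <= t_shift <= T + 1e-9):
        raise ValueError(f"t_shift must lie in [0, {T:g}]")
    S = tree.shared_path_matrix()
    older = np.minimum(max(T - t_shift, 0.0), S)
    return sigma2_old * older + sigma2_young * (S - older)


def _env_integral_table(tree: TimeTree, b: float, env) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative integral of e^(b env(age)) over depth-from-root breakpoints."""
    S = tree.shared_path_matrix()
    T = tree.root_age
    breaks = np.unique(np.round(np.concatenate(([0.0], S.ravel())), 9))
    J = np.zeros(len(breaks))
    f = lambda u: np.exp(b * float(env(T - u)))
    for k in range(1, len(breaks)):
        seg, _ = quad(f, breaks[k - 1], breaks[k], limit=200)
        J[k] = J[k - 1] + seg
    return breaks, J


def cov_env_rate(tree: TimeTree, sigma0_2: float, b: float, env) -> np.ndarray:
    """Environment-dependent-rate covariance.

    The instantaneous rate at age a is sigma0^2 e^(b env(a)); entries are the
    integral of that rate over each shared path, evaluated by adaptive
    quadrature accumulated between consecutive node depths.
    """
    T = tree.root_age
    amin = getattr(env, "age_min", None)
    amax = getattr(env, "age_max", None)
    if amin is not None and (amin > 1e-6 + min(tree.tip_ages.values()) or amax < T - 1e-6):
        raise ValueError(
            f"environmental curve [{amin:g}, {amax:g}] Ma does not cover the "
            f"tree span [0, {T:g}] Ma"
        )
    S = tree.shared_path_matrix()
    breaks, J = _env_integral_table(tree, b, env)
    idx = np.searchsorted(breaks, np.round(S, 9))
    return sigma0_2 * J[np.clip(idx, 0, len(J) - 1)]


def mean_trend(tree: TimeTree, theta: float, beta: float) -> np.ndarray:
    """Expected tip values under a biased random walk (trend).

    E(x_i) = theta + beta (T_root - t_i): drift accrues over each lineage's
    full duration. On an ultrametric tree all durations are equal and the
    trend coefficient is confounded with the root state (a warning is
    emitted).
    """
    if beta != 0.0 and tree.is_ultrametric():
        warnings.warn(
            "trend coefficient is unidentifiable on an ultrametric tree "
            "(confounded with the root state)",
            stacklevel=2,
        )
    return theta + beta * (tree.root_age - tree.tip_age_array())


def mean_trend_shift(
    tree: TimeTree, theta: float, beta: float, t_shift: float
) -> np.ndarray:
    """Expected tip values under the mode-shift model.

    Unbiased BM until age ``t_shift`` (Ma before present), then a trended
    walk: E(x_i) = theta + beta max(0, min(t_shift, T_root) - t_i). Tips
    predating the shift keep mean theta; the covariance is the BM one.
    """
    if t_shift < 0:
        raise ValueError("t_shift must be >= 0")
    eff = min(t_shift, tree.root_age)
    return theta + beta * np.clip(eff - tree.tip_age_array(), 0.0, None)


def loglik(mean: np.ndarray, cov: np.ndarray, se: np.ndarray, x: np.ndarray) -> float:
    """Multivariate-normal log density with covariance ``cov + diag(se^2)``.

    Evaluated via Cholesky factorization; returns -inf when the total
    covariance is not positive definite.
    """
    mean = np.asarray(mean, float)
    x = np.asarray(x, float)
    se = np.asarray(se, float)
    n = len(x)
    if mean.shape != (n,) or se.shape != (n,) or cov.shape != (n, n):
        raise ValueError("dimension mismatch")
    V = cov + np.diag(se**2)
    try:
        c = cho_factor(V, lower=True, check_finite=False)
    except LinAlgError:
        return -np.inf
    r = x - mean
    quad_form = float(r @ cho_solve(c, r, check_finite=False))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return -0.5 * (n * _LOG2PI + logdet + quad_form)


# ======================================================================
# GLS profiling machinery
# ======================================================================


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile the mean coefficients out of the MVN likelihood.

    Returns (lnl, beta_hat) at the GLS estimate, or (-inf, None) when V is
    not positive definite. A rank-deficient design raises LinAlgError.
    """
    n = len(y)
    try:
        c = cho_factor(V, lower=True, check_finite=False)
    except LinAlgError:
        return -np.inf, None
    ViX = cho_solve(c, X, check_finite=False)
    Viy = cho_solve(c, y, check_finite=False)
    A = X.T @ ViX
    beta = np.linalg.solve(A, X.T @ Viy)  # LinAlgError if singular
    r = y - X @ beta
    quad_form = float(r @ cho_solve(c, r, check_finite=False))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return -0.5 * (n * _LOG2PI + logdet + quad_form), beta


def _gls_profile_scale(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Profile both the mean coefficients and an overall variance scale.

    For V = s2 * C (no measurement error) the ML scale is the mean GLS
    quadratic form; returns (lnl, beta_hat, s2_hat).
    """
    n = len(y)
    try:
        c = cho_factor(C, lower=True, check_finite=False)
    except LinAlgError:
        return -np.inf, None, np.nan
    ViX = cho_solve(c, X, check_finite=False)
    Viy = cho_solve(c, y, check_finite=False)
    beta = np.linalg.solve(X.T @ ViX, X.T @ Viy)
    r = y - X @ beta
    q = float(r @ cho_solve(c, r, check_finite=False))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    s2 = q / n
    lo, hi = np.exp(_LOG_S2_BOUNDS[0]), np.exp(_LOG_S2_BOUNDS[1])
    s2 = float(np.clip(s2, lo, hi))
    lnl = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + q / s2)
    return lnl, beta, s2


def _trend_shift_design(tree: TimeTree, t_shift: float) -> np.ndarray:
    eff = min(t_shift, tree.root_age)
    g = np.clip(eff - tree.tip_age_array(), 0.0, None)
    return g


# ======================================================================
# model fitting
# ======================================================================


@dataclass
class ModelFit:
    """A maximum-likelihood fit of one trait-evolution model."""

    model: str
    sigma2: float
    theta: float
    params: dict = field(default_factory=dict)
    t_shift: float | None = None
    lnl: float = np.nan
    k: int = 0
    n: int = 0
    aicc: float = np.nan
    delta_aicc: float = np.nan
    weight: float = np.nan
    converged: bool = False
    hessian_pd: bool | None = None
    grad_norm: float = np.nan
    message: str = ""

    @property
    def parameter(self) -> float | None:
        """The single model-specific parameter, Table-report style."""
        key = {
            "OU": "alpha",
            "trend": "beta",
            "ACDC": "r",
            "env_rate": "slope",
            "rate_shift": "sigma2_2",
            "trend_shift": "beta",
        }.get(self.model)
        return None if key is None else self.params.get(key)


def _prepare(tree: TimeTree, dataset: TraitDataset):
    y, se = dataset.align(tree.tip_labels)
    return np.asarray(y, float), np.asarray(se, float)


def _hessian_diagnostics(nll: Callable, p: np.ndarray):
    """Finite-difference gradient norm and Hessian PD flag at the optimum."""
    p = np.asarray(p, float)
    m = len(p)
    h = 1e-4 * np.maximum(np.abs(p), 1e-3)
    f0 = nll(p)
    g = np.zeros(m)
    H = np.zeros((m, m))
    try:
        for i in range(m):
            ei = np.zeros(m)
            ei[i] = h[i]
            fp, fm = nll(p + ei), nll(p - ei)
            g[i] = (fp - fm) / (2 * h[i])
            H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
        for i in range(m):
            for j in range(i + 1, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i] = h[i]
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    nll(p + ei + ej) - nll(p + ei - ej) - nll(p - ei + ej) + nll(p - ei - ej)
                ) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return float(np.linalg.norm(g)), False
        return float(np.linalg.norm(g)), bool(np.min(np.linalg.eigvalsh(H)) > 0)
    except Exception:
        return np.nan, False


def _optimize_profile(
    neg_profile: Callable,
    starts: list[np.ndarray],
    bounds: list[tuple[float, float]],
):
    best = None
    ok = False
    for x0 in starts:
        try:
            res = optimize.minimize(
                neg_profile, x0, method="L-BFGS-B", bounds=bounds
            )
        except (LinAlgError, FloatingPointError):
            continue
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or bool(res.success)
    return best, ok


def fit_model(
    tree: TimeTree,
    dataset: TraitDataset,
    model: str,
    *,
    env: EnvCurve | None = None,
    seed: int = 0,
    n_starts: int = 5,
    t_shift_grid: float = 0.1,
    n_aicc: int | None = None,
    diagnostics: bool = True,
) -> ModelFit:
    """Fit one trait-evolution model by maximum likelihood.

    The mean parameters are profiled analytically by GLS; variance-side
    parameters are optimised numerically (bounded L-BFGS with ``n_starts``
    seeded random multi-starts). For ``trend_shift`` the shift time is
    scanned globally on a grid of spacing ``t_shift_grid`` Myr before local
    refinement. ``n_aicc`` overrides the AICc sample size (default: number
    of tips). Non-convergence is flagged on the returned fit, never raised.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model == "env_rate":
        if env is None:
            raise ValueError("env_rate requires an environmental curve")
        probe = env(np.linspace(0.0, tree.root_age, 64))
        if float(np.ptp(probe)) < 1e-10:
            warnings.warn(
                "environmental curve is constant over the tree span: the "
                "env_rate model degenerates to BM with a rescaled rate",
                stacklevel=2,
            )
    y, se = _prepare(tree, dataset)
    n = tree.n_tips
    S = tree.shared_path_matrix()
    D = np.diag(se**2)
    ones = np.ones((n, 1))
    no_se = bool(np.all(se == 0.0))
    depth_mean = float(np.mean(np.diag(S)))
    ls2_0 = float(np.log(np.clip(np.var(y) / max(depth_mean, 1e-12), 1e-9, None)))
    rng = np.random.default_rng(seed)
    T = tree.root_age

    def design(mdl: str, ts: float | None = None) -> np.ndarray:
        if mdl == "trend":
            return np.column_stack([np.ones(n), T - tree.tip_age_array()])
        if mdl == "trend_shift":
            g = _trend_shift_design(tree, ts)
            if float(np.max(np.abs(g))) < 1e-12:
                return ones
            return np.column_stack([np.ones(n), g])
        return ones

    def profile_bm_like(X: np.ndarray) -> tuple[float, np.ndarray, float]:
        """Profile (coefs, sigma2) for models whose covariance is s2*S + D."""
        if no_se:
            lnl, beta, s2 = _gls_profile_scale(y, X, S)
            return lnl, beta, s2

        def neg(ls2):
            lnl, _ = _gls_profile(y, X, np.exp(ls2) * S + D)
            return -lnl

        res = optimize.minimize_scalar(
            neg, bounds=_LOG_S2_BOUNDS, method="bounded",
            options={"xatol": 1e-9},
        )
        s2 = float(np.exp(res.x))
        lnl, beta = _gls_profile(y, X, s2 * S + D)
        return lnl, beta, s2

    fit = ModelFit(model=model, sigma2=np.nan, theta=np.nan, n=n)
    natural: np.ndarray | None = None
    full_nll: Callable | None = None

    if model in ("BM", "trend"):
        X = design(model)
        try:
            lnl, beta, s2 = profile_bm_like(X)
        except LinAlgError:
            raise ValueError(
                "singular GLS system (trend is unidentifiable here)"
            ) from None
        fit.sigma2, fit.theta, fit.lnl = s2, float(beta[0]), lnl
        fit.converged = np.isfinite(lnl)
        if model == "trend":
            fit.params["beta"] = float(beta[1])
            natural = np.array([s2, beta[0], beta[1]])
            full_nll = lambda p: -loglik(
                mean_trend(tree, p[1], p[2]), p[0] * S, se, y
            )
        else:
            natural = np.array([s2, beta[0]])
            full_nll = lambda p: -loglik(np.full(n, p[1]), p[0] * S, se, y)

    elif model == "trend_shift":
        ts_grid = np.arange(0.0, T + t_shift_grid, t_shift_grid)
        ts_grid[-1] = min(ts_grid[-1], T)

        def profile_ts(ts: float) -> float:
            try:
                lnl, _, _ = profile_bm_like(design("trend_shift", ts))
            except LinAlgError:
                return -np.inf
            return lnl

        lnls = np.array([profile_ts(ts) for ts in ts_grid])
        i0 = int(np.argmax(lnls))
        lo = ts_grid[max(i0 - 1, 0)]
        hi = ts_grid[min(i0 + 1, len(ts_grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda ts: -profile_ts(ts), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            ts_hat = float(res.x) if -res.fun >= lnls[i0] else float(ts_grid[i0])
        else:
            ts_hat = float(ts_grid[i0])
        lnl, beta, s2 = profile_bm_like(design("trend_shift", ts_hat))
        b_hat = float(beta[1]) if len(beta) > 1 else 0.0
        fit.sigma2, fit.theta, fit.lnl = s2, float(beta[0]), lnl
        fit.params["beta"] = b_hat
        fit.t_shift = ts_hat
        fit.converged = np.isfinite(lnl)
        natural = np.array([s2, beta[0], b_hat, ts_hat])
        full_nll = lambda p: -loglik(
            mean_trend_shift(tree, p[1], p[2], p[3]), p[0] * S, se, y
        )

    else:
        # numeric shape parameters with profiled theta and scale
        if model == "OU":
            shape_bounds = [(0.0, 20.0)]
            shape0 = [0.5 / T]
            build_C = lambda sh: cov_ou(tree, 1.0, sh[0])
        elif model == "ACDC":
            rmax = 20.0 / T
            shape_bounds = [(-rmax, rmax)]
            shape0 = [0.0]
            build_C = lambda sh: cov_acdc(tree, 1.0, sh[0])
        elif model == "env_rate":
            shape_bounds = [(-20.0, 20.0)]
            shape0 = [0.0]
            build_C = lambda sh: cov_env_rate(tree, 1.0, sh[0], env)
        elif model == "rate_shift":
            # ratio of old to young rate (log scale) plus the shift age
            shape_bounds = [(-12.0, 12.0), (0.0, T)]
            shape0 = [0.0, T / 2.0]
            build_C = lambda sh: cov_rate_shift(tree, np.exp(sh[0]), 1.0, sh[1])
        else:  # pragma: no cover
            raise AssertionError(model)

        def neg_profile(shape: np.ndarray) -> float:
            try:
                C = build_C(np.asarray(shape, float))
            except (ValueError, FloatingPointError):
                return np.inf
            if no_se:
                lnl, _, _ = _gls_profile_scale(y, ones, C)
                return -lnl

            def neg_inner(ls2):
                lnl, _ = _gls_profile(y, ones, np.exp(ls2) * C + D)
                return -lnl

            res = optimize.minimize_scalar(
                neg_inner, bounds=_LOG_S2_BOUNDS, method="bounded",
                options={"xatol": 1e-8},
            )
            return float(res.fun)

        starts = [np.array(shape0)]
        for _ in range(max(n_starts - 1, 0)):
            starts.append(
                np.array(
                    [rng.uniform(lo_, hi_) for lo_, hi_ in shape_bounds]
                )
            )
        best, ok = _optimize_profile(neg_profile, starts, shape_bounds)
        if best is None or not np.isfinite(best.fun):
            fit.message = "all optimisation starts failed"
            return fit
        shape_hat = np.asarray(best.x, float)
        C = build_C(shape_hat)
        if no_se:
            lnl, beta, s2 = _gls_profile_scale(y, ones, C)
        else:
            res = optimize.minimize_scalar(
                lambda ls2: -_gls_profile(y, ones, np.exp(ls2) * C + D)[0],
                bounds=_LOG_S2_BOUNDS, method="bounded", options={"xatol": 1e-9},
            )
            s2 = float(np.exp(res.x))
            lnl, beta = _gls_profile(y, ones, s2 * C + D)
        fit.theta, fit.lnl = float(beta[0]), lnl
        fit.converged = ok and np.isfinite(lnl)
        if model == "OU":
            fit.sigma2 = s2
            fit.params["alpha"] = float(shape_hat[0])
            natural = np.array([s2, beta[0], shape_hat[0]])
            full_nll = lambda p: -loglik(
                np.full(n, p[1]), cov_ou(tree, p[0], p[2]), se, y
            )
        elif model == "ACDC":
            fit.sigma2 = s2
            fit.params["r"] = float(shape_hat[0])
            natural = np.array([s2, beta[0], shape_hat[0]])
            full_nll = lambda p: -loglik(
                np.full(n, p[1]), cov_acdc(tree, p[0], p[2]), se, y
            )
        elif model == "env_rate":
            fit.sigma2 = s2
            fit.params["slope"] = float(shape_hat[0])
            natural = np.array([s2, beta[0], shape_hat[0]])
            full_nll = lambda p: -loglik(
                np.full(n, p[1]), cov_env_rate(tree, p[0], p[2], env), se, y
            )
        else:  # rate_shift: s2 is the young-regime rate
            s2_old = float(s2 * np.exp(shape_hat[0]))
            fit.sigma2 = s2_old
            fit.params["sigma2_2"] = s2
            fit.t_shift = float(shape_hat[1])
            natural = np.array([s2_old, s2, beta[0], shape_hat[1]])
            full_nll = lambda p: -loglik(
                np.full(n, p[2]), cov_rate_shift(tree, p[0], p[1], p[3]), se, y
            )

    fit.k = MODEL_K[model]
    fit.n = int(n_aicc if n_aicc is not None else n)
    if np.isfinite(fit.lnl):
        fit.aicc = aicc(fit.lnl, fit.k, fit.n)
    if diagnostics and natural is not None and np.isfinite(fit.lnl):
        fit.grad_norm, fit.hessian_pd = _hessian_diagnostics(full_nll, natural)
        if not fit.hessian_pd:
            fit.message = (
                "Hessian at the optimum is not positive definite "
                "(flat direction or saddle point)"
            )
    return fit


# ======================================================================
# information criteria
# ======================================================================


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc list")
    d = a - np.min(a)
    w = np.exp(-0.5 * d)
    return w / np.sum(w)


def compare_models(
    tree: TimeTree,
    dataset: TraitDataset,
    models: Sequence[str] = MODELS,
    *,
    env: EnvCurve | None = None,
    seed: int = 0,
    n_aicc: int | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, list[ModelFit]]:
    """Fit a set of models and assemble an AICc comparison table.

    Returns the table (sorted by AICc) and the underlying fits. A model
    whose fit fails is kept as a flagged row rather than aborting the run.
    """
    fits: list[ModelFit] = []
    for i, m in enumerate(models):
        try:
            fits.append(
                fit_model(
                    tree, dataset, m, env=env, seed=seed + i, n_aicc=n_aicc,
                    **fit_kwargs,
                )
            )
        except Exception as exc:  # keep the table, flag the row
            bad = ModelFit(model=m, sigma2=np.nan, theta=np.nan, n=tree.n_tips)
            bad.message = f"fit failed: {exc}"
            fits.append(bad)
    finite = np.array([f.aicc if np.isfinite(f.aicc) else np.inf for f in fits])
    if np.all(np.isinf(finite)):
        raise RuntimeError("every model fit failed")
    w = akaike_weights(finite[np.isfinite(finite)])
    amin = float(np.min(finite))
    j = 0
    for f in fits:
        if np.isfinite(f.aicc):
            f.delta_aicc = f.aicc - amin
            f.weight = float(w[j])
            j += 1
    rows = [
        {
            "model": f.model,
            "sigma2": f.sigma2,
            "theta": f.theta,
            "parameter": f.parameter,
            "t_shift": f.t_shift,
            "lnL": f.lnl,
            "k": f.k,
            "AICc": f.aicc,
            "dAICc": f.delta_aicc,
            "wA": f.weight,
            "converged": f.converged,
            "message": f.message,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    return table, fits


# ======================================================================
# support surfaces
# ======================================================================


@dataclass
class SupportSurface:
    """Profile log-likelihood over the mode-shift parameters.

    ``dlnl`` holds lnL_max - lnL (>= 0, 0 at the ML point); 1-D over
    t_shift when ``beta`` is None, else 2-D with shape (len(t_shift),
    len(beta)).
    """

    t_shift: np.ndarray
    dlnl: np.ndarray
    lnl_max: float
    beta: np.ndarray | None = None

    def support_region(self, level: float = 2.0) -> np.ndarray:
        """Boolean mask of grid points within ``level`` lnL units of the ML."""
        return self.dlnl <= level

    def support_range(self, level: float = 2.0) -> tuple[float, float]:
        """(min, max) t_shift inside the support region (profile surface)."""
        if self.dlnl.ndim == 1:
            inside = self.t_shift[self.dlnl <= level]
        else:
            inside = self.t_shift[np.any(self.dlnl <= level, axis=1)]
        if inside.size == 0:
            raise ValueError("empty support region at this level")
        return float(inside.min()), float(inside.max())


def support_surface(
    tree: TimeTree,
    dataset: TraitDataset,
    t_shift_values,
    beta_values=None,
) -> SupportSurface:
    """Profile the mode-shift likelihood over t_shift (and optionally beta).

    At each grid point every other parameter (theta, sigma2, and beta when
    not gridded) is re-optimised.
    """
    ts = np.asarray(t_shift_values, dtype=float)
    T = tree.root_age
    if np.any(ts < -1e-9) or np.any(ts > T + 1e-9):
        raise ValueError(f"t_shift grid must lie within [0, {T:g}]")
    y, se = _prepare(tree, dataset)
    n = tree.n_tips
    S = tree.shared_path_matrix()
    D = np.diag(se**2)
    ones = np.ones((n, 1))
    no_se = bool(np.all(se == 0.0))

    def profile(X: np.ndarray, yy: np.ndarray) -> float:
        if no_se:
            lnl, _, _ = _gls_profile_scale(yy, X, S)
            return lnl
        res = optimize.minimize_scalar(
            lambda ls2: -_gls_profile(yy, X, np.exp(ls2) * S + D)[0],
            bounds=_LOG_S2_BOUNDS, method="bounded", options={"xatol": 1e-8},
        )
        return -float(res.fun)

    if beta_values is None:
        lnl = np.empty(len(ts))
        for i, t in enumerate(ts):
            g = _trend_shift_design(tree, t)
            X = ones if float(np.max(np.abs(g))) < 1e-12 else np.column_stack([np.ones(n), g])
            try:
                lnl[i] = profile(X, y)
            except LinAlgError:
                lnl[i] = -np.inf
        mx = float(np.max(lnl))
        return SupportSurface(t_shift=ts, dlnl=mx - lnl, lnl_max=mx)

    bs = np.asarray(beta_values, dtype=float)
    lnl2 = np.empty((len(ts), len(bs)))
    for i, t in enumerate(ts):
        g = _trend_shift_design(tree, t)
        for j, b in enumerate(bs):
            lnl2[i, j] = profile(ones, y - b * g)
    mx = float(np.max(lnl2))
    return SupportSurface(t_shift=ts, dlnl=mx - lnl2, lnl_max=mx, beta=bs)


# ======================================================================
# parametric bootstrap and posterior-sample robustness
# ======================================================================


@dataclass
class BootstrapResult:
    statistic: float
    p_value: float
    null_stats: np.ndarray
    nsim: int

    @property
    def resolution(self) -> float:
        """Smallest attainable nonzero p at this simulation size."""
        return 1.0 / self.nsim


def parametric_bootstrap(
    tree: TimeTree,
    dataset: TraitDataset,
    *,
    null: str = "BM",
    alt: str = "trend_shift",
    nsim: int = 1000,
    seed: int = 0,
    env: EnvCurve | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Likelihood-ratio parametric bootstrap of ``alt`` against ``null``.

    Simulates ``nsim`` datasets under the null ML parameters (trait values
    plus Gaussian measurement noise with the observed SE structure), refits
    both models to each, and reports p = proportion of null statistics
    2 dlnL >= the observed statistic.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    from .synthetic_data import sim_traits  # deferred: avoids an import cycle

    fit_kwargs.setdefault("diagnostics", False)
    fit0 = fit_model(tree, dataset, null, env=env, seed=seed, **fit_kwargs)
    fit1 = fit_model(tree, dataset, alt, env=env, seed=seed, **fit_kwargs)
    obs = max(0.0, 2.0 * (fit1.lnl - fit0.lnl))
    rng = np.random.default_rng(seed)
    _, se = _prepare(tree, dataset)
    params = _null_sim_params(fit0)
    stats = np.empty(nsim)
    for b in range(nsim):
        yb = sim_traits(
            tree, fit0.model, params, seed=int(rng.integers(2**31 - 1)), env=env
        ).to_numpy()
        yb = yb + rng.normal(0.0, se)
        ds = TraitDataset(
            species=list(tree.tip_labels),
            mean=yb,
            n=np.ones(tree.n_tips, int),
            se=se,
        )
        f0 = fit_model(tree, ds, null, env=env, seed=seed + b + 1, **fit_kwargs)
        f1 = fit_model(tree, ds, alt, env=env, seed=seed + b + 1, **fit_kwargs)
        stats[b] = max(0.0, 2.0 * (f1.lnl - f0.lnl))
    p = float(np.mean(stats >= obs))
    return BootstrapResult(statistic=obs, p_value=p, null_stats=stats, nsim=nsim)


def _null_sim_params(fit: ModelFit) -> dict:
    params = {"sigma2": fit.sigma2, "theta": fit.theta}
    params.update(fit.params)
    if fit.t_shift is not None:
        params["t_shift"] = fit.t_shift
    return params


def fit_over_sample(
    trees: TreeSample | Iterable[TimeTree],
    dataset: TraitDataset,
    models: Sequence[str] = MODELS,
    *,
    env: EnvCurve | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit a model set independently to every tree in a posterior sample.

    Returns one row per (tree, model) with per-tree Akaike weights; a tree
    whose fits fail is recorded with an error message and the run continues.
    """
    rows = []
    for ti, tree in enumerate(trees):
        try:
            table, _ = compare_models(
                tree, dataset, models, env=env, seed=seed + 1000 * ti, **fit_kwargs
            )
        except Exception as exc:
            rows.append({"tree": ti, "model": None, "error": str(exc)})
            continue
        for _, r in table.iterrows():
            rec = {"tree": ti, "error": ""}
            rec.update(r.to_dict())
            rows.append(rec)
    return pd.DataFrame(rows)


def summarize_sample_fits(df: pd.DataFrame, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)) -> pd.DataFrame:
    """Quantiles of parameter estimates and weights across a tree sample."""
    good = df[df["model"].notna()]
    out = good.groupby("model")[["sigma2", "theta", "t_shift", "lnL", "wA"]].quantile(
        list(quantiles)
    )
    return out.unstack(level=-1)
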