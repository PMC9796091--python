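"""Maximum-likelihood variance components for direct and indirect genetic effects.

The offspring phenotype vector ``y`` (one entry per trio) is modelled as
Gaussian with mean ``X @ beta`` (intercept and child sex) and covariance

    V = var_o * A_oo + var_m * A_mm + var_p * A_pp
        + cov_om * (A_om + A_om') + cov_op * (A_op + A_op')
        + cov_mp * (A_mp + A_mp') + resid * I,

where the ``A`` matrices are the trio role-blocks of a genomic
relatedness matrix.  Four nested specifications are supported:

``differential``
    all seven parameters free (maternal and paternal effects may differ);
``combined``
    maternal and paternal effects equal and perfectly correlated
    (``var_m = var_p = cov_mp``, ``cov_om = cov_op``), four parameters;
``no_parental``
    direct effects only (GRM-based heritability), two parameters;
``null``
    residual variance only.

Estimation is full maximum likelihood with the fixed effects profiled
out by generalized least squares.  The implied 3x3 genetic covariance
matrix is kept positive semi-definite by a log-Cholesky
parameterization (variance boundaries reachable in the limit, implied
correlations bounded in [-1, 1]); optimization is quasi-Newton with the
analytic gradient, from three deterministic starting points.  Standard
errors come from the inverse expected (Fisher) information on the raw
parameter scale, which is exact in form because ``V`` is linear in the
raw parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, lapack

from .data import ConfigurationError, InputError
from .relatedness import GRMSet

__all__ = [
    "VCSpec",
    "VCFit",
    "FitOptions",
    "StandardizedFit",
    "SPECS",
    "NESTING_ORDER",
    "COMPONENT_NAMES",
    "build_covariance",
    "neg2_loglik",
    "fit_vc",
    "standardize_fit",
    "is_nested",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: expanded component order used throughout reporting
COMPONENT_NAMES = (
    "var_o", "var_m", "var_p", "cov_om", "cov_op", "cov_mp", "resid",
)

#: weights of each expanded component in the phenotypic variance
#: (mother-father covariance does not contribute: mates are unrelated)
_VARIANCE_WEIGHTS = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 1.0])

NESTING_ORDER = ("null", "no_parental", "combined", "differential")


@dataclass(frozen=True)
class VCSpec:
    """A nested model specification: free parameters and their meaning.

    ``expansion`` maps the spec's raw parameter vector to the seven
    expanded components in ``COMPONENT_NAMES`` order.
    """

    name: str
    param_names: tuple[str, ...]
    expansion: np.ndarray

    @property
    def df(self) -> int:
        """Number of free variance parameters."""
        return len(self.param_names)

    @property
    def variance_weights(self) -> np.ndarray:
        """Per-parameter weight in the total phenotypic variance."""
        return _VARIANCE_WEIGHTS @ self.expansion

    def expand(self, theta: np.ndarray) -> np.ndarray:
        """Raw spec parameters -> the seven expanded components."""
        return self.expansion @ np.asarray(theta, dtype=float)


def _make_specs() -> dict[str, VCSpec]:
    e = np.eye(7)
    specs = {}
    specs["differential"] = VCSpec(
        "differential",
        ("var_o", "var_m", "var_p", "cov_om", "cov_op", "cov_mp", "resid"),
        e.copy(),
    )
    exp_c = np.zeros((7, 4))
    exp_c[0, 0] = 1.0                      # var_o
    exp_c[[1, 2, 5], 1] = 1.0              # var_m = var_p = cov_mp = var_par
    exp_c[[3, 4], 2] = 1.0                 # cov_om = cov_op = cov_opar
    exp_c[6, 3] = 1.0                      # resid
    specs["combined"] = VCSpec(
        "combined", ("var_o", "var_par", "cov_opar", "resid"), exp_c
    )
    exp_n = np.zeros((7, 2))
    exp_n[0, 0] = 1.0
    exp_n[6, 1] = 1.0
    specs["no_parental"] = VCSpec("no_parental", ("var_o", "resid"), exp_n)
    exp_0 = np.zeros((7, 1))
    exp_0[6, 0] = 1.0
    specs["null"] = VCSpec("null", ("resid",), exp_0)
    return specs


SPECS = _make_specs()


def get_spec(spec) -> VCSpec:
    if isinstance(spec, VCSpec):
        return spec
    try:
        return SPECS[spec]
    except KeyError:
        raise ConfigurationError(
            f"unknown spec {spec!r}; choose from {sorted(SPECS)}"
        ) from None


def is_nested(inner, outer) -> bool:
    """True when ``inner`` is nested within ``outer`` along the model chain."""
    inner, outer = get_spec(inner), get_spec(outer)
    return NESTING_ORDER.index(inner.name) < NESTING_ORDER.index(outer.name)


def _base_matrices(grms: GRMSet) -> list[np.ndarray]:
    n = grms.n_trios
    return [
        grms.a_oo,
        grms.a_mm,
        grms.a_pp,
        grms.a_om + grms.a_om.T,
        grms.a_op + grms.a_op.T,
        grms.a_mp + grms.a_mp.T,
        np.eye(n),
    ]


def component_matrices(grms: GRMSet, spec) -> list[np.ndarray]:
    """The matrices ``C_j`` such that ``V = sum_j theta_j C_j`` for a spec."""
    spec = get_spec(spec)
    base = _base_matrices(grms)
    out = []
    for j in range(spec.df):
        weights = spec.expansion[:, j]
        c = None
        for w, b in zip(weights, base):
            if w != 0.0:
                c = w * b if c is None else c + w * b
        out.append(c)
    return out


def build_covariance(grms: GRMSet, theta, spec) -> np.ndarray:
    """Assemble the model covariance matrix ``V(theta)`` for a specification."""
    spec = get_spec(spec)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.df,):
        raise ConfigurationError(
            f"spec {spec.name!r} takes {spec.df} parameters, got {theta.shape}"
        )
    v = None
    for t, c in zip(theta, component_matrices(grms, spec)):
        v = t * c if v is None else v + t * c
    if not np.allclose(v, v.T, atol=1e-8 * max(1.0, np.abs(v).max())):
        raise RuntimeError("covariance matrix is not symmetric")
    return v


# ---------------------------------------------------------------------------
# likelihood


def _profile_nll(v: np.ndarray, y: np.ndarray, x: np.ndarray):
    """-2 log-likelihood with GLS-profiled fixed effects; raises on non-PD V."""
    factor = cho_factor(v, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    vi_x = cho_solve(factor, x, check_finite=False)
    vi_y = cho_solve(factor, y, check_finite=False)
    xtvix = x.T @ vi_x
    beta = np.linalg.solve(xtvix, x.T @ vi_y)
    vi_r = vi_y - vi_x @ beta
    r = y - x @ beta
    nll = y.size * LOG2PI + logdet + float(r @ vi_r)
    return nll, beta, vi_r, factor


def _inverse_from_factor(factor) -> np.ndarray:
    c, lower = factor
    inv, info = lapack.dpotri(c, lower=lower)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    tri = np.tril(inv) if lower else np.triu(inv)
    return tri + tri.T - np.diag(np.diag(inv))


_PENALTY = 1e10


def neg2_loglik(theta, y, X, grms: GRMSet, spec) -> float:
    """-2 log-likelihood of ``y`` at raw parameters ``theta``.

    The fixed effects are profiled out by generalized least squares.  A
    non-positive-definite ``V(theta)`` returns a large penalized value
    (optimizer-safe) and increments ``neg2_loglik.n_penalized``.
    """
    spec = get_spec(spec)
    y = np.asarray(y, dtype=float)
    x = np.asarray(X, dtype=float)
    v = build_covariance(grms, theta, spec)
    try:
        nll, _, _, _ = _profile_nll(v, y, x)
    except np.linalg.LinAlgError:
        neg2_loglik.n_penalized += 1
        return _PENALTY + float(np.sum(np.square(theta)))
    return nll


neg2_loglik.n_penalized = 0


# ---------------------------------------------------------------------------
# parameter transforms (log-Cholesky of the implied genetic covariance)


def _theta_from_phi(spec: VCSpec, phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    name = spec.name
    if name == "null":
        return np.array([np.exp(phi[0])])
    if name == "no_parental":
        return np.exp(phi)
    if name == "combined":
        l11, l21, l22 = np.exp(phi[0]), phi[1], np.exp(phi[2])
        return np.array(
            [l11 * l11, l21 * l21 + l22 * l22, l11 * l21, np.exp(phi[3])]
        )
    if name == "differential":
        l = np.zeros((3, 3))
        l[0, 0], l[1, 1], l[2, 2] = np.exp(phi[0]), np.exp(phi[2]), np.exp(phi[5])
        l[1, 0], l[2, 0], l[2, 1] = phi[1], phi[3], phi[4]
        g = l @ l.T
        return np.array(
            [g[0, 0], g[1, 1], g[2, 2], g[0, 1], g[0, 2], g[1, 2], np.exp(phi[6])]
        )
    raise ConfigurationError(f"unknown spec {name!r}")


def _chol_with_jitter(g: np.ndarray) -> np.ndarray:
    scale = max(np.abs(np.diag(g)).max(), 1e-8)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(g + jitter * scale * np.eye(g.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise ConfigurationError("implied genetic covariance is not PSD")


def _phi_from_theta(spec: VCSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    name = spec.name
    floor = 1e-10

    def safelog(x):
        return np.log(np.maximum(x, floor))

    if name == "null":
        return np.array([safelog(theta[0])])
    if name == "no_parental":
        return safelog(theta)
    if name == "combined":
        g = np.array([[theta[0], theta[2]], [theta[2], theta[1]]])
        l = _chol_with_jitter(g)
        return np.array(
            [safelog(l[0, 0]), l[1, 0], safelog(l[1, 1]), safelog(theta[3])]
        )
    if name == "differential":
        vo, vm, vp, com, cop, cmp_, resid = theta
        g = np.array([[vo, com, cop], [com, vm, cmp_], [cop, cmp_, vp]])
        l = _chol_with_jitter(g)
        return np.array(
            [
                safelog(l[0, 0]), l[1, 0], safelog(l[1, 1]),
                l[2, 0], l[2, 1], safelog(l[2, 2]),
                safelog(resid),
            ]
        )
    raise ConfigurationError(f"unknown spec {name!r}")


def _transform_jacobian(spec: VCSpec, phi: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """d theta / d phi by central differences (the transform is cheap)."""
    k = phi.size
    jac = np.empty((spec.df, k))
    for i in range(k):
        step = np.zeros(k)
        step[i] = h
        jac[:, i] = (
            _theta_from_phi(spec, phi + step) - _theta_from_phi(spec, phi - step)
        ) / (2.0 * h)
    return jac


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    Three deterministic starting points are screened by their initial
    -2 log-likelihood and the quasi-Newton run proceeds from the best,
    falling back to the remaining starts if it fails to converge; set
    ``full_multistart`` to optimize from every start and keep the best
    optimum (costlier, identical on well-behaved likelihoods).
    Convergence is a relative -2ll change below ``ftol`` (at most
    ``maxiter`` iterations per start).
    """

    n_starts: int = 3
    maxiter: int = 500
    ftol: float = 1e-8
    gtol: float = 1e-5
    compute_se: bool = True
    full_multistart: bool = False


@dataclass
class StandardizedFit:
    """Estimates rescaled so the sex-conditional phenotypic variance is one."""

    components: pd.Series          # the seven expanded components
    se: pd.Series
    cov: np.ndarray                # covariance of the expanded components
    total_raw_variance: float


@dataclass
class VCFit:
    """A fitted specification: estimates, likelihood and uncertainty."""

    spec: VCSpec
    estimates: np.ndarray          # raw scale, spec parameter order
    fixed_effects: np.ndarray      # [intercept, sex]
    neg2_loglik: float
    df: int
    se: np.ndarray
    cov: np.ndarray                # covariance of raw spec parameters
    converged: bool
    n_trios: int
    n_penalized: int = 0
    standardized: StandardizedFit | None = None

    def expanded(self) -> tuple[pd.Series, pd.Series, np.ndarray]:
        """Raw estimates, SEs and covariance on the seven-component scale."""
        e = self.spec.expansion
        est = pd.Series(self.spec.expand(self.estimates), index=COMPONENT_NAMES)
        cov7 = e @ self.cov @ e.T
        se = pd.Series(np.sqrt(np.clip(np.diag(cov7), 0.0, None)),
                       index=COMPONENT_NAMES)
        return est, se, cov7

    @property
    def total_variance(self) -> float:
        """Model-implied phenotypic variance after conditioning on sex."""
        return float(self.spec.variance_weights @ self.estimates)


def _starting_points(spec: VCSpec, s2: float, n_starts: int) -> list[np.ndarray]:
    """Deterministic raw-scale starts: equal split, direct-heavy, residual-heavy."""
    name = spec.name
    if name == "null":
        raw = [np.array([s2]), np.array([0.5 * s2]), np.array([1.5 * s2])]
    elif name == "no_parental":
        raw = [
            np.array([0.5 * s2, 0.5 * s2]),
            np.array([0.8 * s2, 0.2 * s2]),
            np.array([0.1 * s2, 0.9 * s2]),
        ]
    elif name == "combined":
        raw = [
            np.array([s2 / 6, s2 / 6, 0.0, 0.5 * s2]),
            np.array([0.5 * s2, 0.05 * s2, 0.0, 0.4 * s2]),
            np.array([0.05 * s2, 0.025 * s2, 0.0, 0.9 * s2]),
        ]
    elif name == "differential":
        third = s2 / 6
        raw = [
            np.array([third, third, third, 0, 0, 0, 0.5 * s2]),
            np.array([0.5 * s2, 0.05 * s2, 0.05 * s2, 0, 0, 0, 0.4 * s2]),
            np.array([0.05 * s2, 0.02 * s2, 0.02 * s2, 0, 0, 0, 0.9 * s2]),
        ]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown spec {name!r}")
    return raw[:n_starts]


def fit_vc(
    spec,
    y,
    X,
    grms: GRMSet,
    options: FitOptions | None = None,
) -> VCFit:
    """Maximize the likelihood of a specification over its variance parameters.

    Variances stay non-negative and the implied genetic covariance
    positive semi-definite through the log-Cholesky parameterization;
    the optimizer is L-BFGS with the analytic gradient

        d(-2ll)/d theta_j = tr(V^-1 C_j) - u' C_j u,   u = V^-1 (y - X beta),

    chained through the transform.  The best of the deterministic starts
    is returned; ``converged`` reflects optimizer success at that start.
    """
    spec = get_spec(spec)
    options = options or FitOptions()
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(X, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    n = y.size
    if grms.n_trios != n:
        raise InputError("GRM block size does not match phenotype length")

    cs = component_matrices(grms, spec)
    n_penalized = [0]

    def objective(phi):
        theta = _theta_from_phi(spec, phi)
        v = None
        for t, c in zip(theta, cs):
            v = t * c if v is None else v + t * c
        try:
            nll, _, vi_r, factor = _profile_nll(v, y, x)
            vinv = _inverse_from_factor(factor)
        except np.linalg.LinAlgError:
            n_penalized[0] += 1
            return _PENALTY + float(np.sum(theta**2)), np.zeros_like(phi)
        grad_raw = np.array(
            [float((vinv * c).sum() - vi_r @ c @ vi_r) for c in cs]
        )
        jac = _transform_jacobian(spec, phi)
        return nll, jac.T @ grad_raw

    # ML residual variance of y after the fixed effects (divisor n)
    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    s2 = float(np.sum((y - x @ beta_ols) ** 2) / n)

    def value_only(phi):
        theta = _theta_from_phi(spec, phi)
        v = None
        for t, c in zip(theta, cs):
            v = t * c if v is None else v + t * c
        try:
            return _profile_nll(v, y, x)[0]
        except np.linalg.LinAlgError:
            return _PENALTY + float(np.sum(theta**2))

    log_pos = _log_positions(spec)
    bounds = [
        (-30.0, 12.0) if i in log_pos else (-1e3, 1e3)
        for i in range(len(_phi_from_theta(spec, _starting_points(spec, s2, 1)[0])))
    ]

    def run(phi0):
        return optimize.minimize(
            objective,
            phi0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.maxiter,
                "ftol": options.ftol,
                "gtol": options.gtol,
            },
        )

    starts = [_phi_from_theta(spec, s)
              for s in _starting_points(spec, s2, options.n_starts)]
    best = None
    best_success = False
    if options.full_multistart:
        for phi0 in starts:
            res = run(phi0)
            if best is None or res.fun < best.fun:
                best = res
                best_success = bool(res.success)
    else:
        # screen starts by initial objective, optimize from the best first
        order = np.argsort([value_only(phi0) for phi0 in starts])
        for rank in order:
            res = run(starts[rank])
            if best is None or res.fun < best.fun:
                best = res
                best_success = bool(res.success)
            if best_success:
                break

    theta_hat = _theta_from_phi(spec, best.x)
    v = build_covariance(grms, theta_hat, spec)
    nll, beta, vi_r, factor = _profile_nll(v, y, x)

    if options.compute_se:
        vinv = _inverse_from_factor(factor)
        w = [vinv @ c for c in cs]
        k = spec.df
        info = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                info[i, j] = info[j, i] = 0.5 * float((w[i] * w[j].T).sum())
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        cov = np.full((spec.df, spec.df), np.nan)
        se = np.full(spec.df, np.nan)

    return VCFit(
        spec=spec,
        estimates=theta_hat,
        fixed_effects=beta,
        neg2_loglik=float(nll),
        df=spec.df,
        se=se,
        cov=cov,
        converged=best_success,
        n_trios=n,
        n_penalized=n_penalized[0],
    )


def _log_positions(spec: VCSpec) -> set[int]:
    """Indices of log-scale (diagonal) entries in the transform vector."""
    return {
        "null": {0},
        "no_parental": {0, 1},
        "combined": {0, 2, 3},
        "differential": {0, 2, 5, 6},
    }[spec.name]


class DegenerateFitError(RuntimeError):
    """The fitted model implies a non-positive total phenotypic variance."""


def standardize_fit(fit: VCFit) -> VCFit:
    """Rescale estimates so the model-implied total variance equals one.

    The total is ``var_o + var_m + var_p + cov_om + cov_op + resid``
    (``cov_mp`` contributes nothing because mates are unrelated), so the
    standardized components sum to one by construction.  Standard errors
    map through the delta method.
    """
    total = fit.total_variance
    if not np.isfinite(total) or total <= 0:
        raise DegenerateFitError(
            f"total variance {total!r} is not positive; cannot standardize"
        )
    theta = fit.estimates
    c = fit.spec.variance_weights
    eta = theta / total
    # delta method: d(theta_j / total)/d theta_k
    d = (np.eye(fit.spec.df) * total - np.outer(theta, c)) / total**2
    cov_eta = d @ fit.cov @ d.T
    e = fit.spec.expansion
    eta7 = e @ eta
    cov7 = e @ cov_eta @ e.T
    se7 = np.sqrt(np.clip(np.diag(cov7), 0.0, None))
    standardized = StandardizedFit(
        components=pd.Series(eta7, index=COMPONENT_NAMES),
        se=pd.Series(se7, index=COMPONENT_NAMES),
        cov=cov7,
        total_raw_variance=total,
    )
    return dataclasses.replace(fit, standardized=standardized)
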