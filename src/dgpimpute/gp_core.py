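"""Single zero-mean Gaussian process: fitting and exact prediction.

The model is ``Y ~ N(0, sigma^2 R(X))`` with ``R`` built from a product
correlation kernel plus nugget (see :mod:`dgpimpute.kernels`).  Posterior
prediction at a new point ``x0`` is the standard conditional Gaussian

    mean     = r(x0)^T R(x)^{-1} y
    variance = sigma^2 (1 + eta - r(x0)^T R(x)^{-1} r(x0))

with ``r(x0) = [k(x0, x_1), ..., k(x0, x_n)]``.  Hyperparameters are
estimated by multi-start quasi-Newton maximum likelihood on log-parameters
(log-lengthscales, log-nugget) with the scale ``sigma^2`` profiled out
analytically; an optional weak log-normal lengthscale prior turns this into
MAP estimation, useful as a stability aid inside stochastic-EM loops.

All factorizations are Cholesky with one jitter-escalation retry chain
(x10 per step, up to 1e-4) before failing; escalations are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize

from .kernels import KernelSpec, correlation_matrix, cross_correlation

__all__ = [
    "GPModel",
    "PredictiveMoments",
    "build_gp",
    "fit_gp",
    "predict_gp",
    "log_marginal_likelihood",
]

log = logging.getLogger(__name__)

#: negative predictive variances larger than this are a bug, not round-off
VARIANCE_TOL = 1e-12

#: default lower bound on the nugget during optimization (PD guarantee)
NUGGET_FLOOR = 1e-8

_JITTER_MAX = 1e-4


@dataclass
class PredictiveMoments:
    """Per-query mean and variance — the universal prediction contract."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = clip_variance(np.asarray(self.variance, dtype=float))


def clip_variance(v: np.ndarray, hard_tol: float = 1e-8) -> np.ndarray:
    """Zero out round-off negatives; warn if more negative than ``hard_tol``."""
    v = np.asarray(v, dtype=float)
    if np.any(v < -hard_tol):
        log.warning("predictive variance %.3e below -%g; clipping",
                    float(np.min(v)), hard_tol)
    return np.where(v < 0.0, 0.0, v)


@dataclass
class GPModel:
    """A fitted (or fully specified) GP with a cached Cholesky factor."""

    X: np.ndarray            # (n, D) training inputs
    y: np.ndarray            # (n,) training outputs
    spec: KernelSpec
    L: np.ndarray = field(repr=False, default=None)      # lower Cholesky of R
    alpha: np.ndarray = field(repr=False, default=None)  # R^{-1} y
    jitter: float = 0.0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_dict(self) -> dict:
        return {"X": self.X.tolist(), "y": self.y.tolist(),
                "spec": self.spec.to_dict(), "jitter": self.jitter}

    @classmethod
    def from_dict(cls, d: dict) -> "GPModel":
        return build_gp(np.asarray(d["X"], dtype=float),
                        np.asarray(d["y"], dtype=float),
                        KernelSpec.from_dict(d["spec"]))


def _chol_with_escalation(R: np.ndarray, what: str = "R"):
    """Cholesky with jitter escalation; raises with a condition estimate."""
    jitter = 0.0
    Rj = R
    while True:
        try:
            L = np.linalg.cholesky(Rj)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = 1e-8 if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX:
                cond = np.linalg.cond(R)
                raise np.linalg.LinAlgError(
                    f"Cholesky of {what} failed after jitter escalation to "
                    f"{_JITTER_MAX:g}; condition estimate {cond:.3e}"
                )
            log.info("jitter escalation on %s: %g", what, jitter)
            Rj = R + jitter * np.eye(R.shape[0])


def build_gp(X: np.ndarray, y: np.ndarray, spec: KernelSpec) -> GPModel:
    """Condition a GP with known hyperparameters on training data."""
    X = as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y entries must align")
    if X.shape[1] != spec.ndim:
        raise ValueError("input dimension does not match kernel lengthscales")
    R = correlation_matrix(spec, X)
    L, jitter = _chol_with_escalation(R)
    alpha = cho_solve((L, True), y)
    return GPModel(X=X, y=y, spec=spec, L=L, alpha=alpha, jitter=jitter)


def as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _profiled_nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                       family: str, prior: tuple | None):
    """Negative log marginal likelihood with sigma^2 profiled out, + gradient.

    ``params`` = [log gamma_1 .. log gamma_D, log eta].  The profiled value
    is ``sigma^2_hat = y^T R^{-1} y / n`` and

        nll = n/2 log(2 pi sigma^2_hat) + 1/2 log|R| + n/2

    Gradient (SE family; analytic):
        d nll / d theta = 1/2 tr(R^{-1} dR) - alpha^T dR alpha / (2 sigma^2_hat)
    """
    n, D = X.shape
    gammas = np.exp(params[:D])
    eta = np.exp(params[D])
    spec = KernelSpec(family=family, lengthscales=gammas, scale=1.0, nugget=eta)
    K = cross_correlation(spec, X, X)
    R = K + eta * np.eye(n)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    alpha = cho_solve((L, True), y)
    s2 = float(y @ alpha) / n
    s2 = max(s2, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    nll = 0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)

    Rinv = cho_solve((L, True), np.eye(n))
    grad = np.empty_like(params)
    if family == "squared_exponential":
        for d in range(D):
            H = (X[:, d, None] - X[None, :, d]) ** 2
            dR = K * (2.0 * H / gammas[d] ** 2)  # dR/dlog gamma_d
            grad[d] = 0.5 * np.sum(Rinv * dR) - (alpha @ dR @ alpha) / (2.0 * s2)
    else:
        # finite-difference fallback for Matern lengthscales
        for d in range(D):
            h = 1e-6
            pp = params.copy(); pp[d] += h
            f1, _ = _profiled_nll_value(pp, X, y, family)
            pm = params.copy(); pm[d] -= h
            f0, _ = _profiled_nll_value(pm, X, y, family)
            grad[d] = (f1 - f0) / (2 * h)
    # dR/dlog eta = eta I
    grad[D] = 0.5 * eta * np.trace(Rinv) - eta * float(alpha @ alpha) / (2.0 * s2)

    if prior is not None:
        # weak log-normal prior on lengthscales (MAP aid)
        m, s = prior
        z = (params[:D] - m) / s
        nll += 0.5 * float(z @ z)
        grad[:D] += z / s
    return nll, grad


def _profiled_nll_value(params, X, y, family):
    n, D = X.shape
    spec = KernelSpec(family=family, lengthscales=np.exp(params[:D]),
                      scale=1.0, nugget=np.exp(params[D]))
    R = correlation_matrix(spec, X)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return 1e10, None
    alpha = cho_solve((L, True), y)
    s2 = max(float(y @ alpha) / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return 0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n), s2


def fit_gp(X, y, family: str = "squared_exponential", init=None, seed=0,
           n_restarts: int = 5, nugget_floor: float = NUGGET_FLOOR,
           maxiter: int = 100, lengthscale_prior: tuple | None = None) -> GPModel:
    """Maximum-likelihood (or MAP) fit of a zero-mean GP.

    Parameters
    ----------
    X, y:
        Training inputs (n, D) or (n,) and outputs (n,); ``n >= 2``.
    init:
        Optional ``KernelSpec`` or array ``[log gammas..., log eta]`` used
        as the first optimization start.
    seed:
        Integer or ``numpy.random.SeedSequence`` seeding the restart draws;
        the fit is deterministic given the seed.
    n_restarts:
        Additional random restarts beyond the heuristic start.
    lengthscale_prior:
        Optional ``(mean, sd)`` of a log-normal lengthscale prior (MAP).

    The scale ``sigma^2`` is profiled analytically and recovered at the
    optimum (floored at 1e-12, so an all-zero ``y`` reverts predictions to
    the prior mean 0 with the scale at its floor).
    """
    X = as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y entries must align")
    if X.shape[0] < 2:
        raise ValueError("fitting requires n >= 2 points")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("training data must be finite")
    n, D = X.shape
    rng = np.random.default_rng(seed)

    # heuristic start: median pairwise distance per dim, small nugget
    start = np.empty(D + 1)
    ranges = np.empty(D)
    for d in range(D):
        diffs = np.abs(X[:, d, None] - X[None, :, d])
        pos = diffs[diffs > 0]
        med = np.median(pos) if pos.size else 1.0
        start[d] = np.log(max(med, 1e-6))
        r = float(np.ptp(X[:, d]))
        ranges[d] = r if r > 0 else 1.0
    start[D] = np.log(1e-2)
    if init is not None:
        if isinstance(init, KernelSpec):
            start = np.concatenate([np.log(init.lengthscales),
                                    [np.log(max(init.nugget, nugget_floor))]])
        else:
            start = np.asarray(init, dtype=float).copy()

    bounds = [(np.log(1e-3 * ranges[d]), np.log(1e3 * ranges[d]))
              for d in range(D)] + [(np.log(nugget_floor), np.log(10.0))]
    start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])

    starts = [start]
    for _ in range(n_restarts):
        pert = np.concatenate([
            start[:D] + rng.normal(0.0, 1.0, size=D),
            [np.log(1e-2) + rng.normal(0.0, 1.5)],
        ])
        starts.append(np.clip(pert, [b[0] for b in bounds],
                              [b[1] for b in bounds]))

    best = None
    for s0 in starts:
        res = minimize(_profiled_nll_grad, s0,
                       args=(X, y, family, lengthscale_prior),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter})
        if np.isfinite(res.fun) and res.fun < 1e9 and (
                best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "GP fitting failure: non-finite likelihood at every restart "
            f"(n={n}, D={D}, family={family})")

    params = best.x
    _, s2 = _profiled_nll_value(params, X, y, family)
    s2 = max(s2 if s2 is not None else 1e-12, 1e-12)
    spec = KernelSpec(family=family, lengthscales=np.exp(params[:D]),
                      scale=s2, nugget=np.exp(params[D]))
    return build_gp(X, y, spec)


def predict_gp(model: GPModel, X0) -> PredictiveMoments:
    """Exact posterior predictive mean and variance at query points."""
    X0 = as_2d(X0)
    if X0.shape[1] != model.spec.ndim:
        raise ValueError("query dimension does not match training dimension")
    r = cross_correlation(model.spec, X0, model.X)  # (n0, n)
    mean = r @ model.alpha
    v = solve_triangular(model.L, r.T, lower=True)  # (n, n0)
    quad = np.sum(v * v, axis=0)
    variance = model.spec.scale * (1.0 + model.spec.nugget - quad)
    variance = np.where(np.abs(variance) < VARIANCE_TOL, 0.0, variance)
    return PredictiveMoments(mean=mean, variance=variance)


def log_marginal_likelihood(model: GPModel) -> float:
    """Exact log density of ``y`` under ``N(0, sigma^2 R(x))``."""
    n = model.n
    s2 = model.spec.scale
    quad = float(model.y @ model.alpha) / s2
    logdet = n * np.log(s2) + 2.0 * float(np.sum(np.log(np.diag(model.L))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
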