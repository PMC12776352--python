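"""Deep GP with stochastic imputation (DGP-SI).

A two-layer deep GP shares the linked-GP architecture (time -> covariates
-> output) but treats missing covariate values as latent.  The joint
likelihood integrates the layer-2 density over the missing cells, which is
intractable; stochastic imputation sidesteps the integral by sampling the
latent cells with elliptical slice sampling (ESS) within a Gibbs sweep:

* prior role in ESS: the layer-1 GP conditional of the missing cells of
  covariate p given its observed cells,
* likelihood role: the layer-2 Gaussian density of the output y given the
  completed covariate matrix.

Hyperparameters are estimated by stochastic EM (SEM): alternate (i) ESS
imputation sweeps over all covariates with missing cells and (ii) per-GP
maximum-likelihood re-estimation on the single current completed dataset.
With zero missing cells the procedure collapses exactly to independent
complete-case GP fits and the joint objective equals the complete-case
(linked-GP) likelihood sum.

Prediction follows the stochastic-imputation recipe: each retained/fresh
ESS draw defines a linked GP whose closed-form moments are mixed,

    mu      = (1/N) sum_i mu_i
    sigma^2 = (1/N) sum_i (mu_i^2 + sigma_i^2) - mu^2,

and latent-cell imputation pools the retained chain the same way.
Observed cells are never modified by any operation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve

from .gp_core import (GPModel, PredictiveMoments, as_2d, build_gp,
                      clip_variance, fit_gp, log_marginal_likelihood,
                      predict_gp)
from .kernels import KernelSpec, correlation_matrix
from .linked_gp import LinkedLayer, linked_predict

__all__ = [
    "SEMConfig",
    "DGPHierarchy",
    "ess_update",
    "sem_fit",
    "dgp_predict",
    "impute_missing",
    "dgp_objective",
    "sem_child_seeds",
]

log = logging.getLogger(__name__)


@dataclass
class SEMConfig:
    """Stochastic-EM schedule and fitting options.

    Defaults target thorough desk-scale runs; the benchmark pipeline uses a
    lighter documented schedule (see :mod:`dgpimpute.pipeline`).
    """

    n_sem_iters: int = 100
    ess_steps_per_iter: int = 10
    burn_in: int = 50
    seed: int = 0
    family: str = "squared_exponential"
    n_restarts_init: int = 5
    n_restarts_refit: int = 0       # refits warm-start from current values
    refit_maxiter: int = 40
    init_maxiter: int = 100
    randomize_sweep: bool = False   # Gibbs order over covariates
    init_mode: str = "gp_interp"    # or "random"
    n_imputations: int = 50
    #: extra ESS draws collected after the last M-step, at the final
    #: hyperparameters (the imputation-sampling stage of the algorithm);
    #: appended to the retained chain, `final_thin` sweeps apart
    n_final_draws: int = 0
    final_thin: int = 1


@dataclass
class DGPHierarchy:
    """Two-layer hierarchy state: data, masks, latent values, fitted GPs."""

    x: np.ndarray               # (N, 1) shared time inputs
    w: np.ndarray               # (N, P) completed covariates (latent filled)
    obs_mask: np.ndarray        # (N, P) True where observed
    y: np.ndarray               # (N,) outputs, fully observed
    layer1: list = field(default_factory=list)   # list[GPModel]
    layer2: GPModel = None
    rng: np.random.Generator = None
    chain: list = field(default_factory=list)    # retained (N, P) draws

    @property
    def n_covariates(self) -> int:
        return self.w.shape[1]

    def linked_layer(self) -> LinkedLayer:
        """Linked GP conditioned on the current completed covariates."""
        layer1 = [build_gp(self.x, self.w[:, p], g.spec)
                  for p, g in enumerate(self.layer1)]
        layer2 = build_gp(self.w, self.y, self.layer2.spec)
        return LinkedLayer(layer1=layer1, layer2=layer2)

    def to_dict(self) -> dict:
        return {
            "x": self.x.tolist(),
            "w": self.w.tolist(),
            "obs_mask": self.obs_mask.tolist(),
            "y": self.y.tolist(),
            "layer1_specs": [g.spec.to_dict() for g in self.layer1],
            "layer2_spec": self.layer2.spec.to_dict(),
        }


def sem_child_seeds(seed, n_covariates: int):
    """Deterministic seed split used by :func:`sem_fit`.

    Returns ``(layer1_seeds, layer2_seed, chain_seed)`` spawned from
    ``SeedSequence(seed)`` in a fixed documented order, so independent
    per-GP fits with these seeds are bit-identical to the fits inside
    :func:`sem_fit` when there is nothing to impute.
    """
    children = np.random.SeedSequence(seed).spawn(n_covariates + 2)
    return children[:n_covariates], children[n_covariates], children[n_covariates + 1]


# ---------------------------------------------------------------------------
# elliptical slice sampling
# ---------------------------------------------------------------------------

def _ess_step(f, m, L, loglik, rng, max_shrink: int = 1000):
    """One elliptical slice sampling update for prior N(m, L L^T).

    Rejection-free: shrinks the angle bracket toward the current state, so
    it accepts in finitely many steps with probability 1.
    """
    nu = L @ rng.standard_normal(f.size)
    logy = loglik(f) + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    for _ in range(max_shrink):
        fp = m + (f - m) * np.cos(theta) + nu * np.sin(theta)
        if loglik(fp) > logy:
            return fp
        if theta < 0.0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    raise RuntimeError("ESS bracket shrink did not terminate")


def _gp_density_loglik(spec: KernelSpec, X: np.ndarray, y: np.ndarray) -> float:
    """log N(y; 0, sigma^2 R(X)) for given hyperparameters."""
    n = y.size
    R = correlation_matrix(spec, X)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        R = R + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(R)
    alpha = cho_solve((L, True), y)
    s2 = spec.scale
    quad = float(y @ alpha) / s2
    logdet = n * np.log(s2) + 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def _layer1_conditional(h: DGPHierarchy, p: int):
    """Mean and Cholesky factor of the layer-1 GP conditional of the
    missing cells of covariate ``p`` given its observed cells.

    Fixed while the hyperparameters are fixed, so callers running many
    sweeps at constant hyperparameters should compute it once.
    """
    obs = h.obs_mask[:, p]
    miss = ~obs
    spec = h.layer1[p].spec
    Sigma = spec.scale * correlation_matrix(spec, h.x)
    Soo = Sigma[np.ix_(obs, obs)]
    Smo = Sigma[np.ix_(miss, obs)]
    Smm = Sigma[np.ix_(miss, miss)]
    try:
        Lo = np.linalg.cholesky(Soo)
    except np.linalg.LinAlgError:
        Lo = np.linalg.cholesky(Soo + 1e-8 * np.eye(Soo.shape[0]))
    A = cho_solve((Lo, True), Smo.T).T
    m_c = A @ h.w[obs, p]
    C = Smm - A @ Smo.T
    C = 0.5 * (C + C.T)
    jitter = 0.0
    while True:
        try:
            Lc = np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 100.0
            if jitter > 1e-4:
                raise np.linalg.LinAlgError(
                    f"singular layer-1 conditional for covariate {p}")
    return m_c, Lc


def ess_update(h: DGPHierarchy, p: int, loglik=None,
               conditional=None) -> DGPHierarchy:
    """One ESS update of the missing cells of covariate ``p`` (in place).

    The stationary distribution is the conditional of ``w_{p,m}`` given the
    observed cells, the output y, the other covariates and the current
    hyperparameters.  No-op if covariate ``p`` is fully observed.

    ``loglik`` is a test hook replacing the layer-2 log density; it
    receives the full completed (N, P) covariate matrix.  ``conditional``
    optionally supplies a precomputed :func:`_layer1_conditional`.
    """
    obs = h.obs_mask[:, p]
    miss = ~obs
    if not np.any(miss):
        return h
    m_c, Lc = conditional if conditional is not None \
        else _layer1_conditional(h, p)

    wbuf = h.w  # in-place completion buffer; observed cells untouched

    if loglik is None:
        spec2 = h.layer2.spec

        def _loglik(fm):
            wbuf[miss, p] = fm
            return _gp_density_loglik(spec2, wbuf, h.y)
    else:
        def _loglik(fm):
            wbuf[miss, p] = fm
            return loglik(wbuf)

    f0 = h.w[miss, p].copy()
    f1 = _ess_step(f0, m_c, Lc, _loglik, h.rng)
    wbuf[miss, p] = f1
    return h


# ---------------------------------------------------------------------------
# stochastic EM
# ---------------------------------------------------------------------------

def _validate_inputs(x, w_obs, y):
    x = as_2d(x)
    w_obs = np.asarray(w_obs, dtype=float)
    if w_obs.ndim != 2:
        raise ValueError("w_obs must be (N, P)")
    y = np.asarray(y, dtype=float).ravel()
    if not (x.shape[0] == w_obs.shape[0] == y.size):
        raise ValueError("x, w_obs and y must have the same number of rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be fully observed at all N points")
    for p in range(w_obs.shape[1]):
        if np.isfinite(w_obs[:, p]).sum() < 2:
            raise ValueError(
                f"covariate {p} has fewer than 2 observed values; exclude it "
                "from the model (sparsely measured variables cannot anchor a "
                "layer-1 GP)")
    return x, w_obs, y


def sem_fit(x, w_obs, y, config: SEMConfig | None = None) -> DGPHierarchy:
    """Fit the two-layer hierarchy by stochastic EM.

    ``w_obs`` is (N, P) with NaN marking missing cells; ``y`` must be fully
    observed.  Alternates ESS imputation sweeps with per-GP hyperparameter
    re-estimation on the current completed dataset; retains one latent
    snapshot per post-burn-in sweep.  Deterministic given ``config.seed``.
    """
    cfg = config or SEMConfig()
    x, w_obs, y = _validate_inputs(x, w_obs, y)
    N, P = w_obs.shape
    obs_mask = np.isfinite(w_obs)
    seeds1, seed2, chain_seed = sem_child_seeds(cfg.seed, P)
    rng = np.random.default_rng(chain_seed)

    # latent initialization: layer-1 GP interpolation per covariate
    w = w_obs.copy()
    layer1 = []
    for p in range(P):
        obs = obs_mask[:, p]
        g = fit_gp(x[obs], w_obs[obs, p], family=cfg.family, seed=seeds1[p],
                   n_restarts=cfg.n_restarts_init, maxiter=cfg.init_maxiter)
        if np.any(~obs):
            mom = predict_gp(g, x[~obs])
            if cfg.init_mode == "random":
                w[~obs, p] = mom.mean + np.sqrt(mom.variance) * \
                    rng.standard_normal(int((~obs).sum()))
            else:
                w[~obs, p] = mom.mean
        # recondition on the completed series at the fitted hyperparameters
        layer1.append(build_gp(x, w[:, p], g.spec))
    layer2 = fit_gp(w, y, family=cfg.family, seed=seed2,
                    n_restarts=cfg.n_restarts_init, maxiter=cfg.init_maxiter)

    h = DGPHierarchy(x=x, w=w, obs_mask=obs_mask, y=y,
                     layer1=layer1, layer2=layer2, rng=rng)

    incomplete = [p for p in range(P) if np.any(~obs_mask[:, p])]
    if not incomplete:
        # nothing latent: SEM collapses to independent complete-case fits
        h.chain = [h.w.copy()]
        return h

    def _sweep(conds):
        order = list(incomplete)
        if cfg.randomize_sweep:
            h.rng.shuffle(order)
        for p in order:
            ess_update(h, p, conditional=conds[p])

    for it in range(cfg.n_sem_iters):
        # E-ish step: stochastic imputation sweeps (conditionals are fixed
        # between M-steps, so compute them once per iteration)
        conds = {p: _layer1_conditional(h, p) for p in incomplete}
        for _ in range(cfg.ess_steps_per_iter):
            _sweep(conds)
            if it >= cfg.burn_in:
                h.chain.append(h.w.copy())
        # M step: re-estimate hyperparameters on the completed dataset
        new_layer1 = []
        for p in range(P):
            g = fit_gp(h.x, h.w[:, p], family=cfg.family,
                       init=h.layer1[p].spec, seed=seeds1[p],
                       n_restarts=cfg.n_restarts_refit,
                       maxiter=cfg.refit_maxiter)
            new_layer1.append(g)
        h.layer1 = new_layer1
        h.layer2 = fit_gp(h.w, h.y, family=cfg.family, init=h.layer2.spec,
                          seed=seed2, n_restarts=cfg.n_restarts_refit,
                          maxiter=cfg.refit_maxiter)

    # imputation-sampling stage: extra draws at the final hyperparameters
    if cfg.n_final_draws > 0:
        conds = {p: _layer1_conditional(h, p) for p in incomplete}
        for _ in range(cfg.n_final_draws):
            for _ in range(cfg.final_thin):
                _sweep(conds)
            h.chain.append(h.w.copy())
    if not h.chain:
        h.chain = [h.w.copy()]
    return h


def dgp_objective(h: DGPHierarchy) -> float:
    """Joint training objective at the current completed dataset.

    Sum of the layer-1 log marginal likelihoods on (x, w_p) and the layer-2
    log marginal likelihood on (w, y).  With zero missingness this equals
    the complete-case linked-GP likelihood sum exactly.
    """
    total = log_marginal_likelihood(build_gp(h.w, h.y, h.layer2.spec))
    for p, g in enumerate(h.layer1):
        total += log_marginal_likelihood(build_gp(h.x, h.w[:, p], g.spec))
    return total


# ---------------------------------------------------------------------------
# prediction / imputation
# ---------------------------------------------------------------------------

def dgp_predict(h: DGPHierarchy, x0, n_imputations: int = 50) -> PredictiveMoments:
    """Stochastic-imputation prediction of the output at new times ``x0``.

    Draws ``n_imputations`` fresh ESS sweeps (continuing the chain), builds
    the linked GP for each completed dataset, and mixes the closed-form
    moments.  With no missing cells all draws coincide and the mixture
    reduces to a single linked-GP prediction.
    """
    if n_imputations < 1:
        raise ValueError("n_imputations must be >= 1")
    x0 = as_2d(x0)
    incomplete = [p for p in range(h.n_covariates)
                  if np.any(~h.obs_mask[:, p])]
    means = []
    variances = []
    for _ in range(n_imputations):
        for p in incomplete:
            ess_update(h, p)
        mom = linked_predict(h.linked_layer(), x0)
        means.append(mom.mean)
        variances.append(mom.variance)
        if not incomplete and len(means) == 1:
            # draws are all identical without latent cells
            means = means * n_imputations
            variances = variances * n_imputations
            break
    mu = np.mean(means, axis=0)
    second = np.mean([m * m + v for m, v in zip(means, variances)], axis=0)
    return PredictiveMoments(mean=mu, variance=clip_variance(second - mu * mu))


def impute_missing(h: DGPHierarchy, n_imputations: int | None = None) -> PredictiveMoments:
    """Per-cell posterior moments of every covariate cell from the chain.

    Pools the retained post-burn-in ESS draws mixture-style: per missing
    cell, the mean and (population) variance of the draws.  Observed cells
    are returned verbatim with variance 0.  ``n_imputations`` limits the
    pool to the last draws of the chain.
    """
    if not h.chain:
        raise ValueError("hierarchy has no retained draws; run sem_fit first")
    draws = h.chain if n_imputations is None else h.chain[-int(n_imputations):]
    stack = np.stack(draws)  # (n_draws, N, P)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0)
    mean[h.obs_mask] = h.w[h.obs_mask]
    var[h.obs_mask] = 0.0
    return PredictiveMoments(mean=mean, variance=var)
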