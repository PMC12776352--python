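"""Linked Gaussian process: analytic moment propagation through two layers.

Layer 1 is a bank of P independent GPs mapping a shared input (time) to P
covariates; layer 2 is a GP mapping the P covariates to the output.  The
exact predictive density of the composition,

    p(y0 | x0, data) = integral p(y0 | w0) prod_p p(w0p | x0) dw0,

is intractable, but its first two moments are closed-form because they
reduce to Gaussian expectations of the layer-2 kernel.  With I(x0) (M,)
and J(x0) (M, M) assembled as products over covariates of the
one-dimensional kernel expectations (see :mod:`dgpimpute.kernels`), and
R(w), y the layer-2 correlation matrix and outputs:

    mean     = I^T R(w)^{-1} y
    variance = y^T R(w)^{-1} J R(w)^{-1} y - mean^2
               + sigma^2 (1 + eta - tr(R(w)^{-1} J))

The linked GP is the Gaussian with these moments; it is exact when all
layer-1 predictive variances vanish (I, J collapse to plain kernel values
and the formulas reduce to ordinary GP prediction).  Layer-1 predictive
distributions enter as independent Gaussians per covariate — the factorized
conditional-independence structure of the hierarchy; no cross-covariate
predictive covariance is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve

from .gp_core import (GPModel, PredictiveMoments, as_2d, build_gp,
                      clip_variance, fit_gp, log_marginal_likelihood,
                      predict_gp)
from .kernels import _I_vec, _J_mat

__all__ = [
    "LinkedLayer",
    "build_linked_layer",
    "fit_complete_case_lgp",
    "linked_predict",
    "lgp_log_likelihood",
]


@dataclass
class LinkedLayer:
    """Layer-1 GPs (time -> covariates) feeding a layer-2 GP (covariates -> y)."""

    layer1: list  # list[GPModel], each 1-D input
    layer2: GPModel

    def __post_init__(self) -> None:
        if self.layer2.spec.ndim != len(self.layer1):
            raise ValueError(
                "layer-2 input dimension must equal the number of layer-1 GPs")


def build_linked_layer(x, w, y, layer1_specs, layer2_spec) -> LinkedLayer:
    """Condition a linked layer on complete data with known hyperparameters."""
    x = as_2d(x)
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    layer1 = [build_gp(x, w[:, p], sp) for p, sp in enumerate(layer1_specs)]
    layer2 = build_gp(w, y, layer2_spec)
    return LinkedLayer(layer1=layer1, layer2=layer2)


def fit_complete_case_lgp(x, w_masked, y, family: str = "squared_exponential",
                          seed=0, n_restarts: int = 5) -> LinkedLayer:
    """Fit a linked GP by complete-case analysis.

    Each layer-1 GP is trained on the rows where its covariate is observed;
    the layer-2 GP is trained on the rows where *all* covariates are
    observed.  Raises if no complete rows exist (complete-case analysis
    impossible).
    """
    x = as_2d(x)
    w_masked = np.asarray(w_masked, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    P = w_masked.shape[1]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(P + 1)
    layer1 = []
    for p in range(P):
        obs = np.isfinite(w_masked[:, p])
        if obs.sum() < 2:
            raise ValueError(f"covariate {p} has fewer than 2 observed values")
        layer1.append(fit_gp(x[obs], w_masked[obs, p], family=family,
                             seed=children[p], n_restarts=n_restarts))
    complete = np.all(np.isfinite(w_masked), axis=1)
    if not np.any(complete):
        raise ValueError("no complete cases: complete-case analysis impossible")
    layer2 = fit_gp(w_masked[complete], y[complete], family=family,
                    seed=children[P], n_restarts=n_restarts)
    return LinkedLayer(layer1=layer1, layer2=layer2)


def linked_predict(layer: LinkedLayer, x0) -> PredictiveMoments:
    """Closed-form linked-GP mean and variance at query times ``x0``."""
    x0 = as_2d(x0)
    g2 = layer.layer2
    P = len(layer.layer1)
    M = g2.n
    mom1 = [predict_gp(g, x0) for g in layer.layer1]
    mus = np.stack([m.mean for m in mom1])        # (P, n0)
    vars_ = np.stack([m.variance for m in mom1])  # (P, n0)

    s2 = g2.spec.scale
    eta = g2.spec.nugget
    n0 = x0.shape[0]
    mean = np.empty(n0)
    variance = np.empty(n0)
    for j in range(n0):
        I = np.ones(M)
        J = np.ones((M, M))
        for p in range(P):
            I *= _I_vec(g2.spec, p, mus[p, j], vars_[p, j], g2.X[:, p])
            J *= _J_mat(g2.spec, p, mus[p, j], vars_[p, j], g2.X[:, p])
        mu = float(I @ g2.alpha)
        RinvJ = cho_solve((g2.L, True), J)
        var = (float(g2.alpha @ J @ g2.alpha) - mu * mu
               + s2 * (1.0 + eta - float(np.trace(RinvJ))))
        mean[j] = mu
        variance[j] = var
    return PredictiveMoments(mean=mean, variance=clip_variance(variance))


def lgp_log_likelihood(layer: LinkedLayer) -> float:
    """Complete-case likelihood: sum of the P+1 GP log marginal likelihoods.

    Each GP in the layer carries its own (complete-case) training set, so
    the joint complete-case log likelihood factorizes as the layer-2 log
    density of y given w plus the per-covariate layer-1 log densities.
    """
    return (log_marginal_likelihood(layer.layer2)
            + sum(log_marginal_likelihood(g) for g in layer.layer1))
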