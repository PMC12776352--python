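"""Baseline imputers: LOCF, chained equations (MICE), per-covariate GPs.

All three operate on a wide table (rows = timestamps, columns = variables,
NaN = missing) and never modify observed cells.

* LOCF carries the last observed value forward; series heads before the
  first observation stay missing and are flagged.  No uncertainty.
* Chained equations ("norm" flavour): each incomplete column is imputed by
  Bayesian linear regression on the other columns with posterior draws of
  the coefficients and noise, cycled for several iterations, repeated for
  m draws; per-cell moments are pooled by Rubin's rules
  (total = within + (1 + 1/m) * between).  Rows are treated as
  exchangeable — time enters only if supplied as an ordinary column.
* GP interpolation fits an independent GP per covariate on (time, observed
  values) and predicts the missing timestamps; no cross-covariate
  information is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp_core import fit_gp, predict_gp

__all__ = [
    "BaselineResult",
    "locf_impute",
    "locf_table",
    "chained_impute",
    "gp_interp_impute",
]

log = logging.getLogger(__name__)


@dataclass
class BaselineResult:
    """Completed table plus per-cell uncertainty where the method has one.

    ``variance`` is None for LOCF (no uncertainty quantification, so LOCF
    is excluded from likelihood-based evaluation by construction).
    ``unimputable`` flags cells the method could not fill (LOCF heads).
    """

    method: str
    mean: pd.DataFrame
    variance: pd.DataFrame | None = None
    n_draws: int | None = None
    unimputable: pd.DataFrame | None = None
    #: per-column multiple-imputation draws, {col: (values (m, n_mis),
    #: within-draw variances (m, n_mis), missing row index)}; lets the
    #: pooled variance be recomputed from first principles
    draws: dict | None = None


# ---------------------------------------------------------------------------
# LOCF
# ---------------------------------------------------------------------------

def locf_impute(series: pd.Series):
    """Last observation carried forward on one time-ordered series.

    Returns ``(filled, head_mask)`` where ``head_mask`` flags entries
    before the first observation, which remain missing.  Idempotent; an
    all-missing series is an error.
    """
    if series.notna().sum() == 0:
        raise ValueError("cannot LOCF-impute an all-missing series")
    filled = series.ffill()
    head_mask = filled.isna()
    return filled, head_mask


def locf_table(table: pd.DataFrame) -> BaselineResult:
    """Column-wise LOCF over a wide table."""
    mean = table.copy()
    heads = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col in table.columns:
        mean[col], heads[col] = locf_impute(table[col])
    return BaselineResult(method="locf", mean=mean, variance=None,
                          unimputable=heads)


# ---------------------------------------------------------------------------
# chained equations
# ---------------------------------------------------------------------------

def _bayes_lm_draw(Xo, yo, Xm, rng):
    """Posterior draw of a linear model and stochastic imputations.

    Classical "norm" step: sigma^2 from the scaled inverse chi-square,
    beta from its conditional Gaussian, then y_mis = Xm beta + noise.
    Returns (imputed values, per-cell predictive variances).
    """
    n, k = Xo.shape
    XtX = Xo.T @ Xo
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - k, 1)
    s2 = float(resid @ resid) / df
    s2 = max(s2, 1e-12)
    sigma2 = s2 * df / rng.chisquare(df)
    cov = sigma2 * XtX_inv
    cov = 0.5 * (cov + cov.T)
    # eigen-based root tolerates the rank-deficient pinv covariance
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    beta = beta_hat + root @ rng.standard_normal(k)
    hat = np.einsum("ij,jk,ik->i", Xm, XtX_inv, Xm)
    var = sigma2 * (1.0 + hat)
    values = Xm @ beta + rng.standard_normal(Xm.shape[0]) * np.sqrt(sigma2)
    return values, var


def chained_impute(table: pd.DataFrame, n_iters: int = 10, n_draws: int = 20,
                   seed: int = 0, predictors=None) -> BaselineResult:
    """Multiple imputation by chained equations (Bayesian linear "norm").

    ``predictors`` optionally restricts the regressor columns used for
    every incomplete column (itself always excluded); by default all other
    columns are used.  Each of the ``n_draws`` completed tables is produced
    by ``n_iters`` column-wise cycles; per-cell mean and variance are
    pooled across draws by the standard multiple-imputation combination.
    Constant columns are skipped with a warning.  Each column needs at
    least 2 observed values.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cols = list(table.columns)
    targets = [c for c in cols if table[c].isna().any()]
    for c in targets:
        if table[c].notna().sum() < 2:
            raise ValueError(f"column {c!r} has fewer than 2 observed values")
    skipped = [c for c in targets
               if table[c].dropna().nunique() <= 1]
    for c in skipped:
        log.warning("chained_impute: skipping constant column %r", c)
    targets = [c for c in targets if c not in skipped]

    mean = table.copy()
    if not targets:
        zero_var = table.notna().astype(float) * 0.0
        return BaselineResult(method="mice", mean=mean, variance=zero_var,
                              n_draws=n_draws)

    values = {c: np.empty((n_draws, int(table[c].isna().sum())))
              for c in targets}
    within = {c: np.empty_like(values[c]) for c in targets}
    miss_idx = {c: table.index[table[c].isna()] for c in targets}

    base = table.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(cols)}
    for d in range(n_draws):
        work = base.copy()
        # start from observed column means
        for c in targets:
            j = col_pos[c]
            m = np.isnan(work[:, j])
            work[m, j] = np.nanmean(base[:, j])
        for _ in range(n_iters):
            for c in targets:
                j = col_pos[c]
                pred_cols = ([col_pos[p] for p in predictors if p != c]
                             if predictors is not None
                             else [col_pos[p] for p in cols if p != c])
                X = np.column_stack([np.ones(len(work)),
                                     work[:, pred_cols]])
                obs = ~np.isnan(base[:, j])
                vals, var = _bayes_lm_draw(X[obs], base[obs, j], X[~obs], rng)
                work[~obs, j] = vals
                values[c][d] = vals
                within[c][d] = var
    variance = table.notna().astype(float) * 0.0
    for c in targets:
        m = n_draws
        q_bar = values[c].mean(axis=0)
        w_bar = within[c].mean(axis=0)
        b = values[c].var(axis=0, ddof=1) if m > 1 else np.zeros_like(q_bar)
        total = w_bar + (1.0 + 1.0 / m) * b
        mean.loc[miss_idx[c], c] = q_bar
        variance.loc[miss_idx[c], c] = total
    return BaselineResult(method="mice", mean=mean, variance=variance,
                          n_draws=n_draws,
                          draws={c: (values[c], within[c], miss_idx[c])
                                 for c in targets})


# ---------------------------------------------------------------------------
# per-covariate GP interpolation
# ---------------------------------------------------------------------------

def gp_interp_impute(table: pd.DataFrame, time=None,
                     family: str = "squared_exponential", seed: int = 0,
                     n_restarts: int = 2) -> BaselineResult:
    """Independent GP regression per column over time.

    ``time`` defaults to the table index.  Each incomplete column gets its
    own squared-exponential GP fitted on the observed (time, value) pairs
    and evaluated at the missing timestamps; no other column is consulted.
    """
    t = np.asarray(table.index if time is None else time, dtype=float)
    mean = table.copy()
    variance = table.notna().astype(float) * 0.0
    ss = np.random.SeedSequence(seed).spawn(len(table.columns))
    for i, col in enumerate(table.columns):
        obs = table[col].notna().to_numpy()
        if not obs.any() or obs.all():
            continue
        if obs.sum() < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        g = fit_gp(t[obs], table[col].to_numpy(dtype=float)[obs],
                   family=family, seed=ss[i], n_restarts=n_restarts)
        mom = predict_gp(g, t[~obs])
        idx = table.index[~obs]
        mean.loc[idx, col] = mom.mean
        variance.loc[idx, col] = mom.variance
    return BaselineResult(method="gp_interp", mean=mean, variance=variance)
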