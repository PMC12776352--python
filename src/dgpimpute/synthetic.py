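"""Synthetic clinical-style admissions and the masking protocol.

Emulates the structure the hierarchy assumes: per admission a shared
hourly time grid of 19-115 points, three smooth covariate trajectories
(pCO2, SID and lactate analogues, each drawn from its own GP over time on
the standardized scale) and an output (pH analogue) generated as a noisy
nonlinear function of the covariates.  The default link

    pH* = -0.6 pCO2* + 0.5 SID* - 0.3 lactate* - 0.2 (pCO2* x lactate*) + eps

carries the acid-base directionality (CO2 and lactate acidify, the strong
ion difference alkalinizes) plus a mild interaction so a joint model can
detectably beat covariate-wise interpolation; it makes no clinical claim.

Masking modes: MCAR cell masking at a given proportion of the observed
target cells, a contiguous interval shared across the targeted variables
(the cross-covariate-uncertainty protocol), and an optional MNAR mode in
which masking probability increases where the output sits near its median
(emulating clinicians sampling less when a patient looks stable); MNAR is
provided for exploration and not used by the default benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admission import COVARIATES, OUTPUT_VAR, AdmissionTable
from .kernels import KernelSpec, correlation_matrix

__all__ = [
    "SyntheticConfig",
    "MaskSpec",
    "generate_admission",
    "generate_dataset",
    "apply_mask",
]

#: default per-covariate generating kernel: smooth over ~10 h, unit signal
#: variance, a small nugget for measurement noise
def _default_kernels() -> dict:
    return {v: KernelSpec("squared_exponential", [10.0], scale=1.0,
                          nugget=0.01) for v in COVARIATES}


DEFAULT_COEFFS = (-0.6, 0.5, -0.3, -0.2)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    n_admissions: int = 14
    hours_range: tuple = (19, 115)
    covariate_kernels: dict = field(default_factory=_default_kernels)
    link: str = "interaction"          # linear | quadratic | interaction
    coefficients: tuple = DEFAULT_COEFFS
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hours_range
        if not (1 <= lo <= hi):
            raise ValueError("hours_range must satisfy 1 <= min <= max")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.link not in ("linear", "quadratic", "interaction"):
            raise ValueError(f"unknown link {self.link!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "covariate_kernels" in d:
            d["covariate_kernels"] = {
                k: KernelSpec.from_dict(v)
                for k, v in d["covariate_kernels"].items()}
        if "hours_range" in d:
            d["hours_range"] = tuple(d["hours_range"])
        if "coefficients" in d:
            d["coefficients"] = tuple(d["coefficients"])
        return cls(**d)


@dataclass
class MaskSpec:
    """Masking protocol for one experiment run."""

    proportion: float
    mode: str = "mcar"                 # mcar | interval | mnar
    target: str = "covariates"         # covariates | output
    variables: tuple | None = None     # subset of target variables
    seed: int | tuple = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.proportion < 1.0):
            raise ValueError("proportion must lie in (0, 1)")
        if self.mode not in ("mcar", "interval", "mnar"):
            raise ValueError(f"unknown mask mode {self.mode!r}")
        if self.target not in ("covariates", "output"):
            raise ValueError(f"unknown mask target {self.target!r}")


def _link_output(link: str, coeffs, w: np.ndarray) -> np.ndarray:
    a, b, c, d = coeffs
    p, s, l = w[:, 0], w[:, 1], w[:, 2]
    out = a * p + b * s + c * l
    if link == "quadratic":
        out = out + d * p * p
    elif link == "interaction":
        out = out + d * p * l
    return out


def generate_admission(cfg: SyntheticConfig, admission_index: int) -> AdmissionTable:
    """Draw one fully observed admission; deterministic in (seed, index)."""
    rng = np.random.default_rng([cfg.seed, admission_index])
    lo, hi = cfg.hours_range
    n = int(rng.integers(lo, hi + 1))
    t = np.arange(n, dtype=float)[:, None]
    w = np.empty((n, len(COVARIATES)))
    for j, var in enumerate(COVARIATES):
        spec = cfg.covariate_kernels[var]
        Sigma = spec.scale * correlation_matrix(spec, t)
        L = np.linalg.cholesky(Sigma)
        w[:, j] = L @ rng.standard_normal(n)
    y = _link_output(cfg.link, cfg.coefficients, w) \
        + rng.normal(0.0, cfg.noise_sd, size=n)
    frame = pd.DataFrame({OUTPUT_VAR: y}, index=pd.RangeIndex(n, name="hour"))
    for j, var in enumerate(COVARIATES):
        frame[var] = w[:, j]
    return AdmissionTable(f"synth-{admission_index:03d}", frame)


def generate_dataset(cfg: SyntheticConfig) -> list:
    """The full synthetic cohort."""
    return [generate_admission(cfg, i) for i in range(cfg.n_admissions)]


def apply_mask(table: AdmissionTable, mask: MaskSpec):
    """Blank cells per the masking protocol; return the held-out truth.

    Returns ``(masked_table, truth)`` where ``truth`` is a tidy frame with
    columns ``hour, variable, value`` of exactly the blanked cells.
    Already-missing cells are never selected; revealing the truth restores
    the original table exactly.
    """
    rng = np.random.default_rng(mask.seed)
    if mask.target == "covariates":
        variables = list(mask.variables or table.covariates)
    else:
        variables = [table.output_var]
    out = table.copy()
    frame = out.frame
    records = []

    if mask.mode == "interval":
        n = table.n_hours
        width = int(np.ceil(mask.proportion * n))
        if width < 1:
            raise ValueError("proportion rounds to an empty interval")
        start = int(rng.integers(0, n - width + 1))
        window = frame.index[start:start + width]
        for var in variables:
            sel = frame.loc[window, var].dropna()
            for h, v in sel.items():
                records.append((h, var, v))
                frame.loc[h, var] = np.nan
    else:
        cells = [(h, var, frame.loc[h, var])
                 for var in variables
                 for h in frame.index[frame[var].notna()]]
        k = int(np.floor(mask.proportion * len(cells)))
        if k < 1:
            raise ValueError("proportion rounds to zero cells to mask")
        if mask.mode == "mcar":
            chosen = rng.choice(len(cells), size=k, replace=False)
        else:  # mnar: mask preferentially where the output is near its median
            ph = frame[table.output_var]
            med = float(ph.median())
            scale = float(ph.std()) or 1.0
            wts = np.array([np.exp(-abs(frame.loc[h, table.output_var] - med)
                                   / scale)
                            if np.isfinite(frame.loc[h, table.output_var])
                            else 1.0
                            for h, _, _ in cells])
            wts = wts / wts.sum()
            chosen = rng.choice(len(cells), size=k, replace=False, p=wts)
        for i in chosen:
            h, var, v = cells[i]
            records.append((h, var, v))
            frame.loc[h, var] = np.nan

    truth = pd.DataFrame(records, columns=["hour", "variable", "value"])
    truth = truth.sort_values(["variable", "hour"]).reset_index(drop=True)
    return out, truth
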