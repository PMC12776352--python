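# Methods

## The model

`dgpimpute` imputes missing values in irregularly sampled multivariate
clinical time series with a two-layer Gaussian-process hierarchy.  One
admission window is one independent time series on a unit-spaced hourly
grid.  Layer 1 is a bank of P independent zero-mean GPs over time, one per
covariate (the default cohort mimics a blood-gas panel: pCO₂, strong ion
difference, lactate).  Layer 2 is a GP from the P covariates to the output
variable (a pH analogue).  All GPs use product-form correlation kernels

    k(a, b) = ∏_d k_d(|a_d − b_d|),      k_d(h) = exp(−h²/γ_d²)

with scale σ² and nugget η applied at the matrix level
(R_ij = k(x_i, x_j) + η·1{i = j}).  Note the squared-exponential
parametrization has no factor of 2; the closed-form Gaussian kernel
expectations below depend on it.  A Matérn-2.5 family is available; its
kernel expectations fall back to kink-split Gauss–Legendre quadrature
(the kernel's derivative kink at each training value defeats plain
Gauss–Hermite rules, so the integral is split at the kinks, after which
64 nodes per segment reach machine accuracy).

### Linked-GP prediction

Feeding layer-1 predictive Gaussians through layer 2 has no closed-form
density, but its first two moments do:

    μ̃₀ = I(x₀)ᵀ R(w)⁻¹ y
    σ̃₀² = yᵀR(w)⁻¹ J(x₀) R(w)⁻¹ y − μ̃₀² + σ²(1 + η − tr[R(w)⁻¹J(x₀)])

where I_i and J_ij are products over covariates of the Gaussian
expectations E[k_p(W₀p, w_ip)] and E[k_p(W₀p, w_ip) k_p(W₀p, w_jp)], with
W₀p the layer-1 predictive at x₀.  For the squared exponential these are

    I = (1 + 2v/γ²)^(−1/2) exp(−(μ−w)²/(γ² + 2v))
    J = exp(−(w_i−w_j)²/(2γ²)) (1 + 4v/γ²)^(−1/2)
        exp(−(μ−w̄)²/(γ²/2 + 2v)),   w̄ = (w_i+w_j)/2.

Layer-1 predictives enter as independent Gaussians per covariate — the
factorized conditional-independence structure of the hierarchy; no
cross-covariate predictive covariance is modelled.  The trace term is
evaluated through the Cholesky factor of R(w), never an explicit inverse.
The Gaussian with moments (μ̃₀, σ̃₀²) is the linked-GP approximation; its
adequacy is verified empirically against Monte-Carlo evaluation of the
exact integral (three-standard-error agreement at 10⁵ samples on small
randomized instances) rather than asserted analytically.

### Stochastic imputation and training

Missing covariate cells are latent.  The joint likelihood integrates the
layer-2 density over them, which is intractable, so the sampler works with
completed datasets:

* **ESS-within-Gibbs.**  For covariate p, the prior is the layer-1 GP
  conditional of the missing cells given the observed cells; the
  likelihood is the layer-2 density of y given the completed covariate
  matrix.  Elliptical slice sampling makes the update rejection-free and
  tuning-free.  Observed cells are never modified.
* **Stochastic EM.**  Alternate (i) ESS sweeps over all covariates with
  missing cells and (ii) maximum-likelihood re-estimation of each GP on
  the *single* current completed dataset (stochastic EM proper, not an
  average over draws).  With zero missing cells this collapses exactly to
  independent complete-case fits, and the joint objective equals the sum
  of the per-GP complete-case log likelihoods.
* **Prediction / imputation.**  Each retained (or fresh) draw defines a
  linked GP; predictions mix the draws' moments
  (μ = N⁻¹Σμ̃ᵢ, σ² = N⁻¹Σ(μ̃ᵢ² + σ̃ᵢ²) − μ²).  Latent-cell imputation pools
  the retained chain the same way: per missing cell, mean and population
  variance across draws; observed cells are returned verbatim with
  variance 0.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| lengthscales γ | fitted (start: median pairwise distance) | smoothness, in input units (hours for layer 1, z-units for layer 2) |
| scale σ² | profiled analytically | signal variance; floored at 1e−12 |
| nugget η | fitted, floor 1e−8 | observation noise + PD guarantee |
| SEM iterations | 100 (library default) | E/M alternations |
| ESS sweeps per iteration | 10 | latent mixing per M-step |
| burn-in | 50 iterations | discarded before pooling |
| imputations N | 50 | mixture size for prediction |

Fitting is multi-start L-BFGS on (log γ, log η) with the scale profiled
out; the gradient is analytic for the squared-exponential family.  An
optional weak log-normal lengthscale prior (MAP) is available as a
stability aid.  Cholesky failures escalate jitter ×10 from 1e−8 up to
1e−4 before raising; escalations are logged.

The *benchmark* pipeline uses a documented desk-scale SEM schedule —
10 SEM iterations, 3 ESS sweeps each, burn-in 5, warm-started single-start
refits capped at 25 optimizer iterations, followed by an
imputation-sampling stage of 35 extra ESS draws at the final
hyperparameters (50 pooled draws in total) — chosen so a full sweep
(14 admissions × 4 missingness levels × 10 mask replicates × 4 methods)
is a desk-scale, single-CPU computation.  The sampling stage matters for
calibration: pooling only the few draws retained while hyperparameters
are still moving underestimates posterior variance, whereas draws at the
final hyperparameters estimate it consistently.  The warm-started refits
converge in a few steps because hyperparameters move little between SEM
iterations.

## Baselines

* **LOCF** carries the last observation forward; heads of series stay
  missing, are flagged, and are excluded from every method's scoring in a
  run so denominators match.  LOCF has no predictive distribution and is
  never scored by NLL.
* **MICE** is chained equations with Bayesian linear regression
  ("norm"): per incomplete column, draw σ² from its scaled inverse
  chi-square, β from its conditional Gaussian, impute with noise; 10
  cycles, 20 draws, Rubin-pooled per cell
  (total = within + (1 + 1/m)·between).  The pooled Gaussian is used for
  NLL; the draws are retained on the result for direct recomputation.
  In the benchmark MICE regresses covariates on time and the output only
  (both fully observed there), preserving its cross-sectional,
  temporally blind character.
* **GP interpolation** fits an independent squared-exponential GP per
  covariate over time — the complete-case, longitudinal-only ablation of
  the hierarchy.

## Evaluation

MAE = (1/(N×D)) ΣΣ |Y_id − Ŷ_id| over masked cells (GP-based methods are
scored at their predictive means), and NLL = −Σ log p(Y_i) with p the
per-cell Gaussian predictive, both on the per-admission z-scored scale
(population SD) used for modelling.  NLL is a sum, so it grows both with
miscalibration and with the number of masked cells.  Aggregation is
per-admission scores first, then mean ± standard error across admissions.

## The synthetic cohort

No public version of the motivating clinical dataset exists, so the
generator emulates its structure: 14 admissions, lengths uniform on
[19, 115] hourly points; three covariate trajectories drawn from
squared-exponential GPs (lengthscale 10 h, scale 1, nugget 0.01 — smooth
over several hours with mild measurement noise); output
y = −0.6·pCO₂* + 0.5·SID* − 0.3·lactate* − 0.2·(pCO₂*·lactate*) + ε,
ε ~ N(0, 0.1²), on standardized scales.  The signs mimic acid-base
directionality (CO₂ and lactate acidify, SID alkalinizes) and the
interaction gives layer 2 a mild non-linearity; no clinical claim is
attached.  Masking is MCAR over the admission's observed covariate cells
at 10/20/30/40%, or a contiguous interval shared across targeted
variables; an MNAR mode (masking preferentially where the output sits
near its median, imitating informative sampling) exists but is not part
of the default benchmark.

Because the generator satisfies the model's own assumptions (smooth GP
covariates, a low-noise link, MCAR masking), passing benchmarks show that
the machinery recovers structure it is designed for — they do not show
robustness to model misspecification, MNAR missingness, regime changes,
or the measurement artefacts of real monitoring data.

## Numerical and design choices

* Predictive variances are clipped to 0 below round-off tolerance
  (1e−12); a raw linked variance below −1e−8 triggers a warning since it
  signals a bug, not round-off.
* The nugget indicator is on training-point *index* equality, so
  duplicated measurement values do not couple through the nugget;
  duplicate inputs with η = 0 surface as factorization errors rather than
  being silently regularized.
* Gibbs sweeps visit covariates in ascending index order by default;
  randomized order is available as a mixing aid.
* Latent cells initialize at the layer-1 GP interpolant (warm start);
  random initialization from the predictive is available.
* Missingness proportion is interpreted per admission (a fraction of all
  observed covariate cells), not per variable.
* z-scoring is per admission, matching the independence of admission
  windows.
* A covariate with fewer than 2 observed values is rejected with advice
  to exclude it, mirroring the practice of dropping variables measured
  once or twice per stay.

## Known limitations

* Two layers, one-dimensional output; no deeper hierarchies.
* No sparse/inducing-point approximations: cost is O(N³) per likelihood
  evaluation, acceptable for admission windows of ~100 points, not for
  long high-frequency records.
* Hyperparameters are point estimates (SEM), not posteriors; imputation
  uncertainty does not include hyperparameter uncertainty.
* The chained-equations baseline is the "norm" flavour only; predictive
  mean matching and tree-based variants are out of scope.
* MNAR missingness is generated but not modelled; the sampler assumes
  the missingness mechanism is ignorable given the observed data.
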