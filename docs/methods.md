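# Methods

This note documents the models implemented in `semisoft`, the numerical
choices behind them, the synthetic benchmark they are validated on, and
the limitations of both.

## Base learner: ELM and its negative-correlation ensemble

An extreme learning machine (ELM) is a single-hidden-layer network with
sigmoid activation `g(x) = 1/(1+e^(−x))` whose input weights and biases
are drawn i.i.d. uniform on [−1, 1] (seedable) and frozen; only the
output weights are estimated, as the minimum-norm least-squares solution
of `Hβ = y` with `H` the hidden-layer response matrix.  Inputs are always
standardized to zero mean / unit variance using the statistics of the
labeled ∪ unlabeled training inputs (sigmoid saturation and kernel
distances need comparable scales); the label stays on its original
scale.

NCLELM trains `N_ELM` such members jointly.  Member *n* minimizes
`e_n(β_n) = ½(‖H_nβ_n − y‖² − λ‖H_nβ_n − f_ens‖²)` with `f_ens` the member
average.  Substituting `f_ens` and setting every `∂e_n/∂β_n = 0` yields a
symmetric block system `Gβ = T` with diagonal blocks
`[1 − λ((N−1)/N)²]·H_nᵀH_n` and off-diagonal blocks `λ(N−1)/N²·H_nᵀH_m`;
these coefficients were re-derived from the stationarity condition and
are verified in the test suite by a central-finite-difference gradient
oracle (‖∂e_n/∂β_n‖ < 10⁻⁵ on random instances).  At `λ = 0` the system
decouples into independent member fits; at `N_ELM = 1` the penalty
vanishes.

**Linear solves.**  `G` is frequently rank-deficient (the training set is
smaller than the combined node count whenever pseudo-labeled subsets are
small), so all solves use a truncated pseudo-inverse with a relative
singular-value cutoff of 10⁻⁸; a warning is logged when the retained
spectrum still has condition number above 10¹².  Diagonal jitter was
rejected: inverting near-null directions at `1/ε` amplifies numerical
null-space noise and made independently computed objective values
disagree at the 10⁻⁷ level.

Defaults `{N_ELM, N_node, λ} = {5, 20, 0.6}` follow the reference
fermentation operating point.

## GPR-derived search bounds

Before pseudo labels are optimized, a squared-exponential GPR with
additive noise is fitted to the labeled data and its predictive interval
at each unlabeled input becomes that label's search box:
`[μ − z·σ, μ + z·σ]` with `z` the two-sided normal quantile of the
confidence level (default 0.95, giving z ≈ 1.960).  Hyperparameters use
a fixed deterministic heuristic — lengthscale = median pairwise training
distance, signal variance = var(y), noise variance = 0.1·var(y).  The
predictive variance includes the observation noise, because the bracketed
quantity is a noisy label; far from the data the interval therefore
reverts to `±z·√(σ_f² + σ_n²)`.  A marginal-likelihood refinement
(L-BFGS-B on the log hyperparameters, deterministic) is available via
`fit_gpr(..., optimize=True)` but is not the default: on small
high-dimensional labeled sets it collapses the noise term and the
near-interpolating posterior extrapolates poorly.  Degenerate intervals
(σ = 0) are widened by `10⁻⁶·max(1, |μ|)`; constant inputs fall back to a
prior-only model with a warning.

## Pseudo-label optimization

The labels of a `U′`-row unlabeled subsample (drawn without replacement)
are the decision vector, partitioned subset-major into `M` equal blocks
of `P = U′/M` (chromosome layout `y₁,₁ … y₁,P, …, y_M,P`; a non-divisible
`U′` is rejected with instructions to truncate, since silently resizing
would change `P` invisibly).  Four terms score a candidate:

* **O1** — Σᵢ labeled-set MSE of learner *i* refit on subset *i* alone;
* **O2** — the same with learner *i* refit on labeled ∪ subset *i*;
* **O3** — `yᵀLy` over the joint `[y_l; y_u]` vector, with
  `w_ij = exp(−‖x_i−x_j‖²/(2δ²))` and `L = D − W`;
* **O4** — labeled-set MSE of the simple average of the M subset-refit
  learners.

Combined: `F = O1 + γ₁O2 + γ₂O3 + γ₃O4`, fitness `1/(F + 10⁻¹²)`.

**Graph bandwidth δ.**  The default is the mean distance to the 7 nearest
neighbours over the standardized labeled ∪ subsample inputs.  A global
median-distance bandwidth connects every pair with weight ≈ 0.5, which
puts `yᵀLy` three to four orders of magnitude above the MSE terms — at
that scale any positive γ₂ from the usual candidate grid simply flattens
the labels.  The neighbour-scale bandwidth keeps the graph effectively
local, so the smoothness term acts as the label-propagation pull it is
intended to be ("median" remains selectable).  The graph is dense by
construction; cost is O((L+U′)²), so keep `L + U′ ≤` a few thousand.

**Caching.**  With frozen input layers every refit is a linear solve, so
the refit model's predictions on the labeled set are a *linear map* of
the candidate labels.  The problem object precomputes these maps (one
truncated pseudo-inverse per learner per training set), reducing each GA
evaluation to a few small matrix-vector products; the subset refits are
shared between O1 and O4.  Tests compare against an uncached
refit-per-call implementation at 10⁻⁸.

**Genetic algorithm.**  Population initialized uniformly inside the
bounds; per generation: binary tournament selection, BLX-α crossover
(α = 0.5, probability 0.9), per-gene Gaussian mutation
(σ = 0.1 × box width, probability 1/U′), clipping to the bounds, elitism
of 1.  The best-so-far history is therefore non-increasing, and every
candidate ever evaluated is feasible.  Defaults npop = ngen = 50.  All
randomness flows from a single seed.

**Scale-balanced trade-off weights.**  For single-run studies,
`scale_balanced_gammas` sets `γ_i = O1(mid)/O_i(mid)` at the box-midpoint
candidate so each weighted term starts at the same magnitude — a standard
scalarization heuristic for objectives on heterogeneous scales.  The
ensemble pipeline instead enumerates a candidate grid (below) and lets
pruning discard badly weighted settings.

## Ensemble pipeline

`K = k₁k₂k₃` perturbation settings enumerate the Cartesian product of
three γ candidate lists (default {0, 0.01, 0.1, 0.5, 1} each, giving 125
settings and, with M = 3, 375 base models).  Each setting carries fresh
model seeds, a fresh unlabeled subsample and its own GA seed, all derived
deterministically from the master seed.  Per setting, the M learners are
refit on labeled ∪ pseudo-labeled data (semi-supervised model) and on the
labeled data alone (supervised counterpart, identical input layers).
Failed settings are logged and skipped.

**Pruning.**  `PIR = (RMSE_init − RMSE_ss)/RMSE_init` on an independent
validation set; retained iff PIR ≥ threshold (default 0, inclusive).
`PIR` at `RMSE_init = 0` is defined as 0 when the semi-supervised model
is also exact, −∞ otherwise.  If nothing survives, the single best-PIR
model is kept with a warning.

**Stacking.**  The retained models' validation predictions form the
second-level design matrix for a PLS regression on the validation labels.
The component count is chosen by 5-fold cross-validation over
1…min(S, 10, effective rank) with the one-standard-error rule; the
CV-minimum alone overfits a 40-sample validation set (it chose 4–6
components whose coefficients generalized worse than a simple average).
Coefficients are stored in affine form `β₀ + Σβᵢŷᵢ`.  The supervised
counterparts of the retained models are stacked the same way for
reference.  Validation predictions are computed once and reused for
pruning and stacking.

## Synthetic benchmark

The generator emulates the statistical shape of multi-batch fed-batch
fermentation data, not its mechanistic kinetics.  Twelve input variables
follow four smooth trajectory styles (logistic feed-up, linear ramp,
exponential decay, slow oscillation) whose parameters are drawn once per
process; each batch perturbs them mildly (±10% amplitude, small phase
shifts) plus a small smooth wobble, so all batches are draws from one
distribution — the assumption the semi-supervised method rests on.  The
batch-variation level is calibrated so a supervised single ELM on the
scarce labeled set reaches R² ≈ 0.9 on held-out batches, the difficulty
regime where label scarcity matters.  The label is the fixed nonlinear
function `2σ(2x₁) + sin x₂ + 0.5x₃x₄ + 0.3x₅² − 0.4x₆` of the first six
inputs (the rest are nuisance variables) plus N(0, 0.05²) noise.

The packaged benchmark simulates 20 batches × 60 samples, holds out 8
whole batches as the test set (480 samples), spreads 40 validation
samples over ≥ 3 further held-out batches, labels 22 training samples
(~3% labeled fraction, comparable to industrial practice) and leaves the
rest as the unlabeled pool.  Study conditions: γ grids {0, 0.1}³ (K = 8),
M = 2, U′ = 60, GA 50×50 — the full-grid workflow at workstation scale.
Single-model baselines (ELM, NCLELM) are reported as the mean over 20
random initializations, since a single random draw is an unreliable
estimate for an interpolation-unstable model.

## What the tests do and do not show

The suite verifies the algebra (solver stationarity, λ = 0 decoupling,
Laplacian identities, cached-vs-plain objective equality at 10⁻⁸), the
behavioural contracts (GA monotonicity and feasibility, PIR arithmetic,
byte-identical reruns under one seed, serialization round trips) and two
stochastic end-to-end properties on the benchmark:

* **Method ordering** — test RMSE of the semi-supervised stacked
  ensemble ≤ supervised stacked ensemble ≤ NCLELM ≤ ELM.  This holds in
  the large majority of replicates, but the first inequality is thin:
  both stacked ensembles operate near the information ceiling of the
  smooth synthetic process, so individual replicates can invert it.
* **Pseudo-label recovery vs. the box midpoint** — this check *fails* by
  design honesty.  The midpoint of the GPR-derived box is exactly the GPR
  posterior mean, which on smooth same-distribution data is already a
  near-optimal label estimate.  The combined objective is quadratic in
  the candidate labels under frozen hidden layers, and even its exact
  box-constrained minimizer only ties the midpoint's label RMSE: the
  objective measures consistency with the labeled set, a quantity the
  GPR-mean labels maximize essentially by construction, and with P = 10
  pseudo-labels per learner the multi-learner signal is weak.  Optimized
  pseudo labels here are *good* (RMSE ≈ 2× the noise floor) — they are
  just not systematically better than the GPR mean that seeds their
  bounds.

Passing tests on this generator demonstrate internal correctness and the
qualitative benefit structure of the method on smooth, replicate-batch,
same-distribution data.  They do not demonstrate robustness to process
drift, non-replicate batches, input sensor noise, missing data or
distribution shift between unlabeled and labeled samples — all common in
industrial historians and all outside the generator's scope.

## Known limitations

* Dense graph and cached maps give O((L+U′)²) memory per problem.
* The GA handles a few hundred decision variables; much larger `U′`
  turns the problem into large-scale black-box optimization.
* The stacking and pruning decisions ride on a small validation set;
  with fewer than ~20 validation samples they become noisy.
* Determinism is guaranteed for a fixed BLAS/numpy stack; bitwise
  reproducibility across different linear-algebra backends is not.
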