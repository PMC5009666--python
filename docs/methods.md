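# Methods

## The model

`bregnmf` factorizes a non-negative data matrix M (d × n, e.g. patients ×
gene-expression values) that may contain missing entries and gross
outliers.  Let Ω be the set of observed positions.  The package solves

    min_{Y, S, U≥0, V≥0}   ½ Σ_{(i,j)∈Ω} (Y_ij − (UV^t)_ij)²  +  λ ‖S‖₁
    subject to             M = Y + S   on Ω,

where Y is the denoised/completed matrix, S a sparse matrix absorbing
outliers, and U (d × r), V (n × r) strictly positive low-rank factors.
Off Ω there is no constraint, so the completion on missing entries is
driven entirely by the low-rank fit; the value exposed to users on
missing entries is Y, which there equals (UV^t).

The assumptions are the usual low-rank-plus-sparse ones: the uncorrupted
signal has few degrees of freedom (r ≪ min(d, n)), corruptions are sparse
and large, and missingness is unrelated to the signal.  Columns of U act
as interpretable features; each sample is a non-negative mixture of them,
and the dominant factor per sample (`cluster_index`) serves as a cluster
label.

## The entropic Bregman-proximal factor updates

Minimization in U (and symmetrically V) is regularized by the Bregman
divergence of the negative entropy h(x) = x ln x,

    D(U, U_prev) = Σ_ij [ U ln(U/U_prev) − U + U_prev ],

which is finite only for positive U, so positivity needs no projection.
The proximal subproblem

    argmin_U  ½‖Y − UV^t‖²_F + ρ D(U, U_prev)

has the stationarity condition (Y − UV^t)V = ρ ln(U/U_prev), solved by the
fixed-point iteration  U ← exp(G(U)/ρ + ln U_prev)  with G(U) = (Y − UV^t)V,
stopped when the max absolute entrywise change drops below `inner_tol`
(default 1e-3).

**Damping.**  The raw map has a negative Jacobian of magnitude roughly
‖V^tV‖·U/ρ.  When that approaches 1 — which already happens at d, n in the
tens with the default ρ = 100 — the iteration oscillates with period 2 and
diverges.  The implementation therefore iterates the log-domain damped map

    ln U ← (1 − α) ln U + α (G(U)/ρ + ln U_prev),      α = `inner_damping`,

with α = ½ by default, plus two safeguards: the log-step per sweep is
capped at one e-fold, and α is halved (down to 0.05) whenever the
iterate-to-iterate change grows.  None of these change the fixed points:
on exit with the tolerance met, the stationarity equation above holds (the
inner solver agrees with an L-BFGS-B solve of the subproblem to ~1e-8; see
the test suite).  α = 1 recovers the undamped map.

**Convergence speed.**  Each converged prox step satisfies
ln U^{k+1} = ln U^k + G(U^{k+1})/ρ — an *implicit* mirror-descent step of
size 1/ρ.  With ρ = 100 the factors therefore move slowly: on the 50 × 70
rank-8 toy problem the Frobenius error after 100 alternating iterations is
about 30 % of its starting value, reaching 5 % only after roughly 1300
iterations.  This is a property of the scheme, not of the inner solver
(solving the subproblems exactly changes the 100-iteration figure by under
two percentage points).  Larger ρ buys stability and monotonicity at the
price of progress per iteration.

## The ADMM for the masked, robust problem

The augmented Lagrangian adds ρ_aug/2 · Σ_Ω (M − Y − S)² to the Lagrangian
with multipliers Λ (supported on Ω).  One outer sweep performs, in order:

1. **Y-update** (closed form): Y = ((UV^t) + Λ + ρ_aug(M − S)) / (1 + ρ_aug)
   on Ω, Y = (UV^t) off Ω.
2. **S-update** (entrywise soft-thresholding):
   S = soft_threshold(M − Y + Λ/ρ_aug, λ/ρ_aug) on Ω, S = 0 off Ω.
   The dead zone is closed: |input| ≤ threshold maps to exactly 0.
3. **U-update**, 4. **V-update**: the damped fixed-point solves above,
   fitting the *current Y* (M itself has holes and outliers; Y carries the
   data into the factor subproblems through the coupling terms).
5. **Dual ascent**: Λ ← Λ + step·(M − Y − S) on Ω.  The step is 1 by
   default; `dual_step_scaled=True` uses ρ_aug (the standard pairing).

Initialization: U, V i.i.d. Uniform(`positivity_floor`, 1] (seeded),
S = Λ = 0, and Y = M on Ω with missing entries imputed by their row mean
of observed values.  A row with no observed entry falls back to the global
observed mean, with a warning.

Termination: both the primal residual max_Ω |M − Y − S| and the Frobenius
distance between successive Λ iterates below `admm_tol` (default 1e-5), or
`admm_max_iter` sweeps (default 2000).  The cap is deliberately high
because the factor updates advance O(1/ρ_prox) per sweep; each sweep is a
handful of small matrix products, so 2000 sweeps complete in well under a
second at the problem sizes treated here.

**Why ρ_aug defaults to 1, not 100.**  The two ρ's play different roles
and are deliberately separate parameters.  Substituting the Y-update into
the S-update shows the S-iterates relax toward their per-entry optimum at
rate ρ_aug/(1 + ρ_aug) per sweep.  At ρ_aug = 100 that is 0.99: outlier
mass migrates into S over hundreds of sweeps, while the factors keep
moving every sweep.  The factors then win the race and absorb spikes into
the low-rank part — a self-consistent stationary point in which the
l1 term is avoided entirely (S = 0 at true spikes, fit ≈ M there) and the
decomposition fails at its main task.  At ρ_aug = 1 the transfer happens
within a few sweeps and the spikes land in S.  Note also that at
ρ_aug = 1 the unit dual step *is* the standard scaled step, and the
S-update's Λ/ρ term reduces to Λ.  Measured on a 60 × 40 rank-4 instance
with 5 % spikes at 10× data RMS: support precision/recall 1.00/0.99 and
clean-fit RMSE 0.03 at ρ_aug = 1, versus 0.89/0.85 and RMSE 0.74 at
ρ_aug = 100.

## Choosing λ

`lambda_grid` builds a log-spaced grid (default 20 points) from
λ_max/1000 to λ_max, with λ_max = max_Ω |M − (U⁰V⁰^t)|, the largest
initial fit residual.  This bound serves twice: the residual entering the
very first S-update is (M − U⁰V⁰^t)/(1 + ρ_aug), so every λ ≥ λ_max zeroes
that update entirely (the soft-threshold dead-zone condition) for any
ρ_aug; and the stationarity condition for S ≡ 0 at a solution is
λ ≥ max|Λ*| with Λ* = M − (UV^t)*, whose entries do not exceed the initial
residuals in practice, so the top of the grid keeps S identically zero
through the whole run — the regime of pure low-rank completion.

`select_lambda` holds out s observed entries (default 5 %), declared
missing, runs the full solver per grid point on the reduced mask, and
scores the mean squared error of the completed Y on the held-out entries
(err_λ).  One split is shared across the grid so the per-λ errors are
paired and comparable; `repeats=R` averages over R independent splits
(default 1).  The minimizing λ is selected; exact ties break to the
smaller λ.

**Behaviour of the err_λ curve.**  On data whose clean part is exactly
low rank, every λ below the point where outliers start leaking into the
completion predicts held-out entries essentially equally well (the small-λ
limit is a least-absolute-deviations fit, which is also consistent), so
the curve is a flat floor followed by a steep rise; the floor's argmin can
then wander with the holdout draw.  Averaging over repeated splits
(repeats ≥ 3) stabilizes it; the recovery experiments in this package use
repeats = 3.  On noisy data the floor is additionally tilted by the noise
variance of the held-out entries.

## The synthetic generator

`make_toy(d=50, n=70, r=8)` draws U₀, V₀ with i.i.d. Uniform[0, 1] entries
and sets M = U₀V₀^t — exactly low rank, fully observed, noiseless.
Corruptions are applied in one canonical order (outliers → missingness →
noise; enforced, since permuting the order changes the instance):

- `inject_outliers(fraction, magnitude=10)`: ⌈fraction·d·n⌉ positions get
  spikes of size magnitude × data RMS with random signs.  Because the
  observed matrix must stay non-negative, corrupted entries are clipped at
  0 and S_true records the *realized* delta, so M_obs − S_true reproduces
  the previous matrix exactly.  Consequence: a negative spike on a small
  entry becomes a small corruption (the entry is floored at 0) that no
  method can flag from the data — this bounds attainable recall and is the
  main reason measured recall sits near rather than at 1.
- `inject_missing(fraction)`: uniform mask without replacement; a draw
  that would empty a row is redrawn once, then allowed with a warning
  (exercising the initializer's fallback).  A `protected` set is never
  masked.
- `add_noise(sigma)`: centered Gaussian with SD sigma × data RMS on
  observed entries, clipped at 0 (clip count reported).

Every instance's `metadata` suffices to regenerate it bit-exactly
(`from_metadata`).  What the generator does *not* emulate: realistic
qPCR/microarray noise physics, correlated missingness, heteroscedastic
noise, or approximately-low-rank signal.  Passing tests on these instances
demonstrates the solver's mechanics (support recovery, completion,
convergence), not performance on real expression data.

## Defaults and numerical choices

| parameter | default | meaning |
|---|---|---|
| `rho_prox` | 100 | Bregman proximal weight in the factor updates |
| `rho_aug` | 1 | augmented-Lagrangian penalty (see above) |
| `lam` | 1 | outlier sparsity weight (select via `select_lambda`) |
| `inner_tol` / `inner_max_iter` | 1e-3 / 50 | inner fixed-point stop (max-norm of change) |
| `inner_damping` | 0.5 | log-domain damping of the inner map |
| `outer_max_iter` / `outer_tol` | 100 / 1e-6 | plain NMF: cap and relative error change |
| `admm_max_iter` / `admm_tol` | 2000 / 1e-5 | ADMM: cap; primal and dual tolerance |
| `positivity_floor` | 1e-6 | lower end of the Uniform factor initialization |
| `dual_step_scaled` | False | dual ascent step 1 vs ρ_aug |

- Exponents in the factor update are clamped to ±50 before
  exponentiation (with a warning) so a pathological gradient cannot
  overflow; positivity is preserved and the outer loop can recover.
- The inner-loop stopping distance is the max absolute entrywise change
  between successive iterates, matching the per-entry derivation of the
  update.
- Soft-threshold ties (|y| = t) map to 0; argmax ties in `cluster_index`
  take the smallest index; err_λ ties take the smallest λ.
- All-zero input to `nmf_bregman` returns factors at the positivity floor
  with a warning; degenerate zero rows/columns are fitted with small
  positive values without special-casing.
- All randomness flows through seeded `numpy` generators; identical seeds
  give bit-identical runs, and matrices serialize with 12 significant
  digits so repeated CLI runs produce byte-identical files.

## Known limitations

- The alternating Bregman-proximal scheme is slow at large `rho_prox` (an
  implicit mirror step of size 1/ρ per iteration); no convergence theory
  is provided, and the error trace is only empirically monotone.
- The λ-selection criterion (held-out MSE) barely discriminates within the
  flat region of the err_λ curve on noiseless exactly-low-rank data; the
  support of S at the selected λ is then sensitive to the holdout draw
  unless splits are repeated.
- S is identified only where corruption exceeds the soft-threshold dead
  zone λ/ρ_aug; corruptions comparable to the fit residuals are
  indistinguishable from them.
- The observed data must be non-negative; outliers that would drive an
  entry negative are only representable through the clipping convention
  described above.
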