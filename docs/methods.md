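# Methods

## The estimation problem

`effconn` estimates *directed, signed* effective connectivity between nodes
(e.g. parcellated brain regions) from nothing but the zero-lag covariance of
their activity.  The model is a stationary linear consistency equation

    x = G x + v,

where `G` is the coupling matrix (entry `(i, j)` is the influence of node
`j` on node `i`) and the external drives `v` are pairwise independent with
unit variance.  Under this model the precision matrix factorizes exactly:

    C⁻¹ = (1 − G)ᵀ (1 − G) = B*B,   B = 1 − G.

The covariance alone cannot identify `B`: for any unitary `U`, `UB` is an
equally valid factor.  The method resolves the ambiguity by assuming the
network is sparse and selecting the factor of minimal off-diagonal L1 norm,

    Γ(U) = Σ_{i≠j} |(U B₀)_{ij}|  →  min over U unitary,

where `B₀` is the unique positive-definite square root of `C⁻¹`.  What makes
directionality recoverable at all is collider structure: the term `GᵀG` in
the precision creates an entry between every pair of nodes that share a
common *target*, and those entries break the symmetry between a motif and
its edge-reversal.  The diagonal of both the cost and the final estimate is
excluded throughout — self-couplings are not identifiable in this model.

## Optimizer

`Γ` is piecewise linear in the entries of `UB`, so its minimization over
the orthogonal/unitary group is a *nonsmooth* manifold problem.  The
optimizer follows geodesics generated by the skew-Hermitian direction
`a = ½(dU* − Ud*)` with `d = phase(UB)·B*` (the entrywise subgradient,
diagonal zeroed, zero chosen at kinks), taking steps

    U ← exp(−δ a) U,   δ = 2π / (|λ_max(a)| · κ),

i.e. a `1/κ` fraction of the spectral period of the direction (κ = 500 by
default).  Two facts shape the implementation:

1. **Subgradient steps must not be forced monotone.**  The raw cost
   oscillates around a slowly decreasing level; rejecting uphill steps
   freezes the iteration at the first kink far above the optimum (verified
   empirically).  The optimizer therefore steps unconditionally, tracks the
   best iterate seen, and *anneals*: when `patience` iterations bring no
   new best, the step is halved (κ doubled) and the search resumes from the
   best point.  This is the standard diminishing-step schedule under which
   subgradient methods converge; the reported cost sequence (best-so-far)
   is monotone by construction.
2. **Convergence tests live at phase boundaries.**  The gradient-residual
   test `‖d − Ud*U‖_F < gtol` runs every iteration; the iterate-change and
   relative cost-change tests (`xtol`, `ftol`) are evaluated when an
   annealing phase ends, where the oscillation has been reduced to its best
   representative.  Tolerances default to `xtol = gtol = 0.7·10⁻²`,
   `ftol = 0.7·10⁻⁴`.

Unitarity is maintained by re-orthonormalizing (polar projection) every 100
steps; `exp(−δa)` is computed by scaling-and-squaring and `|λ_max|` by a
warm-started power iteration, which keeps an iteration at ~1 ms for
100-node problems.

Two polish stages run after convergence: a line search over one spectral
period of the last direction (coarse grid + golden-section), and a
coordinate descent over planar Givens rotations.  A left rotation in the
`(i, j)` plane only mixes rows `i` and `j` of `UB`, so each 1-D problem
costs O(N); sweeps repeat until stable, with a few seeded random-direction
line searches used to step over kinks that block every single-plane move.
Both stages are deterministic and never increase the cost.

The minimizer is defined only up to row sign flips and permutations of the
factor.  `canonicalize` fixes this gauge by a linear assignment that
maximizes the absolute diagonal, then flips row signs to make the diagonal
nonnegative — the form `1 − G` takes for a sparse `G`.  The estimate is
`G_est = 1 − canonicalize(U B₀)` with the diagonal zeroed.

### What the optimizer does and does not achieve

An edge whose endpoints share no collider has both orientations at *exactly
equal* cost, so the global minimizer is non-unique and at least one edge is
misassigned (error `|J|`) for almost every sparse Erdős-Rényi realization.
Elementwise-exact recovery is therefore not a property of the method at any
network size; what it delivers — and what the tests assert — is
detection-level recovery: AUC/average-precision near 1, correct signs for
essentially all detected edges, and misclassification fractions of a
percent or less in the sparse regime.  On very small dense-strength
networks (N ≲ 20) even the global minimum can lie away from the truth, and
bare 3-node motifs can converge to the reversed-orientation local minimum;
larger networks funnel reliably.

## Random networks

Ground-truth networks are Erdős-Rényi digraphs: each ordered off-diagonal
pair carries an edge independently with probability `p`; all edges have the
same magnitude `|J|` and are negative (inhibitory) with probability 0.5
(i.i.d. by default; an exact-half option exists).  The magnitude is set
from the target bulk spectral radius via `ρ² = J² p (1−p) N`, an asymptotic
relation — sampled radii scatter around `ρ`, and an exact-rescale option is
available for sweeps that need the radius pinned.  Skeleton-plus-background
experiments superimpose an independent denser network whose radius is a
fraction (20% in the standard setup) of the skeleton's.

## Surrogate recordings

Activity is an Ornstein-Uhlenbeck process `dx = Ax dt + dW` with drift
`A = (G − 1)/τ`, stable iff every eigenvalue of `A` has negative real part.
The stationary covariance solves the Lyapunov equation `AΣ + ΣAᵀ = −1`
(unit-intensity drive; the sign convention that makes `Σ` positive definite
for stable `A`).  Sampling uses the exact discretization

    x(t+Δt) = e^{AΔt} x(t) + n(t),   n ~ N(0, Σ − e^{AΔt} Σ e^{AᵀΔt}),

with `x(0) ~ N(0, Σ)`, so every marginal is exactly stationary and no
burn-in is needed.  A `noise_mode="stationary"` variant draws the update
noise from `N(0, Σ)` instead; it inflates the marginal variance by ~40% at
`Δt = τ` and exists only for comparison.

BOLD-like observations are produced by convolving each node with the
canonical double-gamma haemodynamic response (positive lobe shape 6, scale
1 s, mode 5 s; undershoot shape 16, ratio 1/6; 32 s support; unit peak),
then optionally adding i.i.d. Gaussian observation noise, with
`SNR = σ²_signal / σ²_obs` recorded.  Defaults follow the reference
simulation table: N = 100, p = 0.1, ρ = 0.3, τ = Δt = 0.1 s, T = 350 000 s.
The accompanying prose states ρ = 0.74 instead of 0.3; the two settings
give sharply different functional-connectivity baselines, and only ρ = 0.3
reproduces the reference worked-example numbers (see below), so the table
value is the default and both are exposed as presets (`ou-default`,
`ou-strong-coupling`), plus a tenfold-shorter `ou-short` preset for quick
experiments.

The simulator emulates the second-order statistics of resting-state
recordings under a *linear* model with homogeneous time constants and a
single noise-free HRF.  It does not model nonlinear neural dynamics,
balloon-model haemodynamics, regionally varying HRFs, scanner drift or
physiological noise — so passing tests show the estimator recovers networks
whose data actually follow the model class, not that it is robust to those
real-data deviations.

## Estimation pipeline and conventions

Time series are standardized per node (population convention, mean 0,
variance 1) before the covariance `C = (1/M) Σ_t x xᵀ` is formed, so `C` is
a correlation matrix; accumulation is chunked in float64, letting long runs
be stored in float32.  `C` must be positive definite with condition number
below 10¹⁰ (an optional ridge exists but is off by default).  Thresholding
to the strongest fraction of connections counts over the full N² grid —
a 90-node estimate at 10% keeps exactly 810 entries — with ties broken by
row-major order.

Metrics operate on off-diagonal entries: AUC and average precision (PRS)
score `|G_est|` against binary edge existence; the Pearson coefficient
(PCC) compares signed weights.  Thresholded confusion reports give both the
ROC-convention rates (miss rate FN/(TP+FN), false-alarm rate FP/(FP+TN))
and the *entry fractions* FN/N_offdiag, FP/N_offdiag; the reference
dense-network percentages are only self-consistent as entry fractions, and
the reference functional-connectivity PCC is only reproducible when
computed over the full matrix including its unit diagonal, so those
conventions are used where those quantities are reported.  The default
confusion threshold is half the ground-truth edge magnitude.

## Problem sizes used in validation

The validation suite uses the reference study conditions directly: 20
realizations at N = 100 for the noise-free default (`p = 0.1, ρ = 0.7`) and
dense (`p = 0.21`) regimes, one full-length (T = 350 000 s, 3.5 million
samples) OU recording for the worked example, three repetitions per point
for the qualitative structural sweeps, and 20 short OU runs for the
latent-driver check.  A full validation pass takes a few minutes on one
CPU; a single 100-node estimation takes seconds.

## Known limitations

- Orientation of collider-free edges is unidentifiable in principle; the
  optimizer picks one orientation of the tied pair.
- Dense networks (`p ≳ 0.2` at equal edge strength) are beyond the sparse
  regime the L1 selection assumes; misses rise to roughly one in seven of
  all possible connections.
- The estimator consumes zero-lag covariances only; lagged structure is
  used nowhere, and frequency-resolved estimation (the optimizer accepts
  complex Hermitian input) has no spectral-estimation front end here.
- Permutation equivariance of the full pipeline holds only up to optimizer
  path effects (the Givens sweep order is index-dependent).
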