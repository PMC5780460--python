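# Methods

This note documents the models implemented in `spectralmap`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Model

### Individual spectral mapping

Given a subject's symmetric structural adjacency matrix `S` (non-negative,
streamline-derived weights, `n` parcels) and functional correlation matrix
`F`, the mapping class is

    F̂ = R f(S) Rᵀ,   f(S) = Σ_{i=0..k} aᵢ Sⁱ,   RRᵀ = RᵀR = I.

`f(S)` aggregates anatomical walks: `[Sˡ]ᵢⱼ` is the sum over all walks of
length `l` from `i` to `j` of the product of traversed edge weights, so
the polynomial weights the contribution of walks up to length `k`.  The
rotation `R` re-expresses that walk structure in the functional eigenmode
coordinates.

The parameters minimize the squared Frobenius norm `‖F̂ − F‖²_F`
(diagonal included).  With `S = V Λ Vᵀ` and `F = U Φ Uᵀ`, eigenvalues
sorted descending in both, the minimizer is closed-form:

- coefficients: the least-squares solution of the Vandermonde system
  `L a = φ`, where row `i` of `L` is `(1, λᵢ, λᵢ², …, λᵢᵏ)`;
- rotation: the orthogonal Procrustes alignment `R* = U Vᵀ`.

On the training matrix this gives `F̂ = U f(Λ) Uᵀ`: the functional
eigenvectors with polynomially transformed structural eigenvalues.  The
orthogonality constraint admits reflections; `det R` is not restricted,
since `U Vᵀ` may have either sign.

Reported quality uses `ucorr` (Pearson correlation of strict
upper-triangular entries, diagonal excluded); the *fitting* objective is
the full Frobenius norm.  The two play distinct roles and are kept
separate throughout.

### Rank-constrained rotation

To probe overfitting from the rotation's `n(n−1)/2` degrees of freedom,
the rank-`m` variant aligns only the leading `m` eigenmode pairs:

    R_m = U_m V_mᵀ + Ū V̄ᵀ,

with `U_m`, `V_m` the first `m` columns of `U`, `V`.  The completion is
deterministic and uses no functional information beyond `span(U_m)`:
`V̄ = V[:, m:]` (trailing structural eigenvectors) and `Ū` is the
QR-orthonormalization of `(I − U_m U_mᵀ) V[:, m:]`, taken in
descending-eigenvalue order with QR signs fixed.  Had the completion used
`U`'s own trailing eigenvectors, `R_m` would equal `U Vᵀ` for every `m`
and the constraint would never bind.  At `m = n` the construction reduces
exactly to the unconstrained solution.  `R_m` is orthogonal by
construction (a product of two orthogonal matrices).  With this
completion the unaligned modes default to a structural alignment; mapping
quality grows with `m` on a coarse grid (`1, n/4, n/2, n`), though
per-step monotonicity in `m` is not a theorem and small local dips can
occur on fine grids.

### Group spectral mapping

For a cohort `{(Sⱼ, Fⱼ)}` of `N` subjects, the group model shares one
orthogonal eigenmode basis `Q` and one coefficient vector `c`:

    F̂ⱼ = Q g(Λⱼ) Qᵀ,   g(x) = Σ_{r=0..k} c_r x^r,

where `Λⱼ` holds subject `j`'s structural eigenvalues (descending); the
subject's structural eigen*vectors* are deliberately unused.  The
objective is `Σⱼ ‖F̂ⱼ − Fⱼ‖²_F` over orthogonal `Q` — a joint approximate
diagonalization problem with no closed form.  The solver alternates:

- **c-step (exact).**  `‖Q D Qᵀ − Fⱼ‖²_F = ‖D − QᵀFⱼQ‖²_F`, and the
  off-diagonal entries of `QᵀFⱼQ` do not depend on `c`; the minimization
  reduces exactly to a stacked `(N·n) × (k+1)` Vandermonde least squares
  of `diag(QᵀFⱼQ)` against each subject's eigenvalues.
- **Q-step (monotone descent).**  Euclidean gradient
  `4 Σⱼ (Q Dⱼ Qᵀ − Fⱼ) Q Dⱼ`, projected to the tangent space of the
  orthogonal manifold, followed by a QR retraction and Armijo
  backtracking line search.  The step is accepted only on sufficient
  decrease, so the recorded objective trace is non-increasing by
  construction; the retraction re-orthogonalizes `Q` every iteration.

Initialization is deterministic: `Q₀` = eigenvectors of the cohort-mean
functional matrix (descending), `c` from the c-step at `Q₀`.  For a
noiseless shared-basis cohort this start is already exact (the mean
functional matrix shares the planted basis), so convergence is immediate;
seeded Haar random restarts (`n_starts > 1`) are available for rugged
instances.  Convergence is declared when the relative objective decrease
falls below `tol` (default `1e-8`) or after `max_iter` (default 500)
iterations; hitting `max_iter` raises a warning and marks the results
object `converged = False` — never silent.

## Conventions and numerics

- **Eigenvalue order** is descending for both matrices; the polynomial
  fit pairs spectra by sorted position.  A strictly increasing `f` on the
  spectrum makes this pairing the identifiable one.
- **Eigenvector signs**: each column is flipped so its largest-magnitude
  entry is positive (ties broken at the lowest index).  `F̂` is
  sign-invariant, but `R` and the weight matrix `W = VᵀRV` are not; the
  convention makes them reproducible.  Eigenvector-correlation tables in
  the spectral-similarity report use absolute values for the same reason.
- **Degenerate eigenvalues** (gap ≤ `1e-10` relative) trigger a warning;
  pairing stays positional, no re-pairing search.  Note that small sparse
  random graphs often have *exactly* degenerate spectra (automorphisms):
  `F̂` is unaffected, but `W` becomes basis-dependent within a cluster.
- **Conditioning**: eigenvalues are divided by the spectral radius before
  powering (`PolynomialMap.eigenvalue_scale`), and coefficients map back
  analytically (`aᵢ = cᵢ / sⁱ`).  Raw Vandermonde systems at `k = 10` are
  severely ill-conditioned; the rescaling is an exact reparameterization.
  Least squares uses orthogonal factorization (`lstsq`), never the
  normal-equations inverse.
- **Underdetermined designs** (`n < k + 1`) are rejected; there is no
  regularization on the coefficients.
- **Asymmetric inputs** are symmetrized as `(X + Xᵀ)/2` only when the
  maximum asymmetry is ≤ `1e-8` relative; larger asymmetry is an error
  (silent correction would mask upstream data problems).
- **Degenerate sweep cells**: at `k = 0` the mapped matrix is a multiple
  of the identity and its off-diagonal triangle is rounding noise;
  `sweep_order` flags such cells as NaN rather than correlating noise.
- **Model files** are JSON with floats at `repr` precision, so round
  trips are bit-exact.

## Evaluation apparatus

- **Time-sample split**: one index set of size `⌊L/2⌋` drawn uniformly
  without replacement, *shared across regions*, complement as the second
  set; Pearson matrices of the two sub-series are the in/out-of-sample
  `F⁽¹⁾, F⁽²⁾`.  A per-region independent split would destroy the
  temporal alignment that inter-regional correlation requires, so the
  shared split is the only well-defined construction.
- **Perturbation model**: `[Š]ᵢⱼ = (1 + Δᵢⱼ)[S]ᵢⱼ` with `Δ` uniform on
  `(−ρ, ρ)`, drawn on the upper triangle and mirrored.  Sparsity is
  preserved and perturbations are proportional to entry size.  Robustness
  is `ucorr(F̂, F̌)` with `F̌` computed from the *original* fitted
  parameters applied to `Š`.
- **Null models**: six `ucorr` families over a cohort — structural vs
  functional (same and crossed subjects), functional–functional,
  structural–structural, and the swapped mapping `F̂ᵢʲ` (subject `i`'s
  parameters applied to subject `j`'s structure) against both `Fᵢ` and
  `Fⱼ` — plus the self-mapped reference.  Self-pairs are excluded from
  cross tables (`N(N−1)` or `N(N−1)/2` entries as appropriate).
- **Spectral similarity**: per-rank eigenvalue quartiles across subjects
  and all-pairs absolute correlations of the first and second
  eigenvectors, both modalities.

## Synthetic generators

All generators are pure functions of (spec, seed).

- `make_structural`: Erdős–Rényi-style weighted graph, uniform(0.1, 1) or
  lognormal weights, density 0.3 by default, zero diagonal,
  max-normalized.  Default size `n = 60`.
- `make_planted_pair`: `F = R₀ f(Λ) …` built from a Haar-random `R₀` and
  a planted polynomial *strictly increasing* on the conditioned spectrum
  `[−1, 1]` — the linear coefficient is set above `Σ i·|cᵢ|`, so
  monotonicity (the exact-recovery identifiability condition) holds by
  construction rather than by rejection sampling.  Functional matrices
  are rescaled into `[−1, 1]` with the planted coefficients rescaled
  identically, so ground truth stays exact.  Optional additive symmetric
  spectral noise (`noise_sigma`, default 0).
- `make_cohort`: subjects share a base graph with ±30% multiplicative
  entry jitter (similar but distinct spectra, as observed across real
  subjects).  `heterogeneity` interpolates the functional basis between
  one shared orthogonal basis (0: exact planted group model) and
  independent Haar bases with independent coefficients (1: independent
  individual mappings); a single cohort-wide rescale keeps shared
  coefficients shared.
- `make_bold_series`: first-order vector autoregression
  `x_t = A x_{t−1} + ε_t` with `A ∝ S` rescaled so the spectral radius of
  `A` equals `coupling` (default 0.9 in the CLI; stationarity requires
  `< 1`).  The stationary covariance `Σ_k Aᵏ(Aᵏ)ᵀ` makes population
  correlations an increasing function of walk-weighted proximity.  200
  burn-in steps precede sampling.

What the generators *do not* emulate: hemodynamics, bandpass filtering,
physiological noise regression, realistic degree distributions or spatial
embedding of parcellations.  Passing tests therefore demonstrate the
estimators' mathematical correctness (recovery, optimality, monotonicity,
robustness) on data realizing the model class and an AR surrogate of
BOLD — not performance on empirical connectomes.

## Problem sizes and defaults

Fits at the design point (`n ≤ ~400`) are dense `eigh` + small least
squares, milliseconds per subject.  Test and acceptance runs use
`n = 10–60`, cohorts of 6–12, series of 300–4800 samples, and 50-seed
Monte-Carlo medians for perturbation curves — sizes at which every
stochastic check is stable across seeds while the whole suite runs in
well under a minute.

## Known limitations

- In-sample Frobenius residual is provably non-increasing in `k` (nested
  model classes minimize exactly that functional); in-sample `ucorr` is
  *not* covered by that argument.  It is monotone to ~1e-15 on noiseless
  planted subjects, but can dip by ~1e-7 under spectral noise.
- The group solver is a local method for a non-convex problem: the
  monotone trace and the planted/degenerate recoveries are guaranteed
  surfaces, the global optimum is not.  Multi-start is available but off
  by default (deterministic single start).
- The rank-`m` completion is one principled choice among several; other
  deterministic completions would satisfy the same orthogonality and
  `m = n` contracts while differing at intermediate `m`.
- With exactly degenerate spectra, eigenmode-resolved outputs (`W`,
  eigenvector-correlation tables) depend on the eigensolver's basis
  choice within clusters, although mapped matrices do not.
- Structural self-loops (a nonzero diagonal of `S`) are accepted by the
  loaders and handled by the theory; the synthetic generator emits zero
  diagonals.
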