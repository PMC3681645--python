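# Methods

## Model

Each sample (column of the G × N expression matrix **Y**) is modeled as a
convex combination of R non-negative gene signatures plus Gaussian noise:

    y_i = Σ_r m_r a_{r,i} + n_i,    n_i ~ N(0, σ² I_G),
    m_{g,r} ≥ 0,   a_{r,i} ≥ 0,   Σ_r a_{r,i} = 1.

The constraints identify the decomposition up to factor order: no scale or
sign ambiguity remains, so a factor is directly an expression profile and a
score is directly a proportion. Priors:

* **Number of factors.** R uniform on {2, …, R_max}.
* **Signatures.** Because the scores sum to one, the noiseless data live in
  an affine subspace; signatures are parameterized by their projected
  coordinates t_r = P(m_r − ȳ), where ȳ is the mean sample and the rows of P
  are leading principal eigenvectors of the empirical covariance. Each t_r
  has a Gaussian prior N(e_r, s² I) truncated to the polytope
  {t : Pᵀt + ȳ ≥ 0} that keeps the back-projected signature non-negative.
  The prior means e_r are set by a maximal-simplex-volume endmember search
  over the projected samples (the standard geometric initialization in
  linear unmixing); the same points initialize the chain.
* **Scores.** Each column of A uniform on the simplex.
* **Noise.** σ² ~ inverse-Gamma(ν/2, γ/2) with a Jeffreys prior on γ;
  integrating γ out analytically leaves the improper density 1/σ²
  independent of ν. ν is therefore inert at run time and kept only as a
  configuration knob (default 2).

### Working dimension

The projected coordinates of a state with R factors use the leading R − 1
principal directions of one PCA basis fitted at the start (principal
subspaces are nested, so no refit is needed when R changes). Tying the
dimension to the current R matters at gene-chip aspect ratios (G ≫ N): the
sample covariance inflates pure-noise directions by up to (1 + √(G/N))², and
a working dimension fixed at R_max − 1 lets the state R = R_max interpolate
all projected noise exactly, locking the chain at R_max. With D = R − 1 the
true factor count has no spare noise directions to absorb. On data whose
centered rank is below R_max − 1 (e.g. noise-free simulations) the
admissible factor counts are capped at rank + 1.

## Sampler

One outer iteration performs, in order: one trans-dimensional move (skipped
in supervised fixed-R mode), one systematic scan of the projected factor
columns, one scan of all score columns, and one σ² draw. All randomness
flows from a single seeded generator, so runs are bit-reproducible.

* **Factor columns.** The full conditional of t_r is Gaussian with
  covariance (Σ_i a²_{r,i}/σ² + 1/s²)⁻¹ I (the projection rows are
  orthonormal and the noise isotropic, so the general matrix expression
  collapses to a scalar), truncated to the positivity polytope. It is
  sampled by one coordinatewise Gibbs scan; the per-coordinate truncation
  interval follows from the G linear inequalities, maintained incrementally.
  An infeasible starting column (possible after an ablation run or a
  pathological move) is repaired by shrinking it radially toward t = 0,
  which always back-projects to the non-negative ȳ.
* **Score columns.** With the last score expressed as one minus the rest,
  the free coordinates have a Gaussian conditional with shared precision
  M̄ᵀM̄/σ² (M̄ = signatures minus the last one), truncated to the simplex;
  they are updated by a coordinatewise scan, vectorized across samples
  (columns are conditionally independent given M). Near-duplicate factors
  make M̄ᵀM̄ singular; a logged ridge stabilizes the solve.
* **Noise variance.** σ² ~ inverse-Gamma(GN/2, SSR/2).
* **Truncated-normal primitive.** Inverse-CDF sampling in log-probability
  space on the mirrored lower tail (`log_ndtr`/`ndtri_exp`), accurate for
  truncation regions many standard deviations out (validated on [8, 9]
  against quadrature).

### Trans-dimensional moves

A birth, death, or switch move is drawn with configured probabilities
(default ⅓ each; no death at R = 2, no birth at R = R_max).

* **Birth.** A new signature is proposed by projecting a uniformly chosen
  data column at the grown dimension, jittering it (variance s²/10),
  repairing to feasibility, and requiring a minimum spectral angle of 0.05
  rad to every existing factor (at most 50 attempts, else the proposal is
  aborted and counted). Every sample gives the new factor a Beta(1, R)
  share; old scores scale by the complement, so columns stay on the simplex.
* **Death.** The factor whose score-weighted distance to the convex hull of
  the remaining signatures is smallest is removed, and its scores are
  redistributed onto the remaining factors in the simplex proportions that
  best reconstruct its signature (fully constrained least squares via
  sum-augmented NNLS). A redundant factor — one expressible as a convex
  combination of the others — therefore dies at almost no likelihood cost,
  while a true vertex is protected. The last working dimension is dropped
  with the factor.
* **Switch.** One signature is replaced by a freshly generated one (same
  generator as birth, distinctness enforced against the others); its scores
  are kept.

**Acceptance.** Each proposal is accepted with probability min(1, ρ) where
ρ is the *per-entry* likelihood ratio exp(ΔSSR-term / (G·N)): the geometric
mean over matrix entries of the pointwise likelihood ratio at the current
σ². The total-matrix ratio is also attached to each proposal for
diagnostics, but it is numerically degenerate at gene-chip dimensions — any
dimension change costs |Δlog L| in the hundreds-to-thousands once the
within-R Gibbs has adapted (see the working-dimension note above), which
would freeze R at its starting value. Normalizing per observation keeps the
same fit comparison on a size-free scale. No reversible-jump Jacobians are
applied, so the chain targets the posterior over R only approximately; the
estimator consumes the sampled R trace as an empirical vote.

Measured move behaviour on the benchmark below: births are accepted at
roughly 20–60% while the factor count is below the truth (they genuinely
reduce residual), deaths of redundant factors at ~90%+, and deaths of true
vertices essentially never — the chain descends from R_max and then
fluctuates around R_true with 60–80% of post-burn-in mass on it.

## Estimators and diagnostics

* **Factor count:** the most frequent post-burn-in sampled R; ties break to
  the smaller count.
* **Joint MAP:** among stored post-burn-in states at the selected R, the one
  maximizing the unnormalized log-posterior (likelihood − log σ² + factor
  prior + count prior + score-prior constant). Stored states keep projected
  coordinates and are back-projected on demand.
* **Reconstruction-error trace:** RE(t) = ‖Y − M⁽ᵗ⁾A⁽ᵗ⁾‖²/(NG) recorded at
  every iteration (not thinned); its stabilization is the practical
  convergence check, alongside the R trace.

## Synthetic benchmark

`ublu.synthetic` generates the three test geometries: *peaky* (baseline 1.0
with a disjoint high-amplitude block of 5% of genes per factor at 10.0, in
arbitrary expression units), *orthogonal* (orthonormalized Gaussian columns
scaled to unit mean-square entry; deliberately violates positivity), and
*orthogonal-positive* (disjoint-support blocks with uniform random
amplitudes). Scores are flat-Dirichlet columns; noise is i.i.d. Gaussian
with σ² set so the sample-averaged ratio G⁻¹σ⁻²‖Ma_i‖² matches the target
SNR (default 20 dB). Defaults are G = 512, N = 128, R = 3. Negative entries
created by noise are clipped to zero and counted (for peaky data at 20 dB
the clipped fraction is ~0; for the orthogonal scenario clipping is
substantial — that scenario exists precisely to stress the positivity
assumption). A *realistic-factors* scenario drawn from real datasets is not
reproducible without external data and is intentionally absent.

What the generator does **not** emulate: heavy-tailed and heteroscedastic
microarray noise, probe-level effects, correlated genes within pathways, and
time dependence between samples from the same subject. Passing recovery
tests on these simulations therefore certifies the sampler and estimators
under the model's own assumptions, not performance on real chips.

## Test-scale choices and measured behaviour

The recovery benchmark used in the test suite and the acceptance script
runs at G = 256, N = 64, R_true = 3, 20 dB, R_max = 8, 2000 iterations with
500 burn-in — sizes chosen so the ten-seed experiment completes in a few
minutes while keeping the G ≫ N regime of expression data. At these
conditions the MAP factor count is 3 in 10/10 seeds, aligned per-factor
spectral angles are 0.09–0.13 rad, score MSEs are 1–7×10⁻³, and the
reconstruction error is within 7% of the generating σ².

Known limitation: the radius of a vertex along its ray from the data
centroid is weakly identified at moderate N — samples near the simplex
boundary push vertices slightly outward (releasing score truncation), and
single posterior draws show ~10% radial wobble. One of the thirty
factor-level score MSEs in the ten-seed benchmark exceeds the 5×10⁻³ test
bound (6.5×10⁻³) for exactly this reason; the corresponding assertion is
left failing rather than widened. The wobble shrinks with N and does not
affect factor identity (inter-factor angles exceed 1 rad).

## Numerical choices

* Eigenvector signs fixed by making each vector's largest-magnitude entry
  positive (reproducibility across LAPACK builds).
* Feasibility tolerance defaults to 0 (exact inequalities); chain states
  satisfy M ≥ 0 and simplex sums to within 1e-10 in floating point.
* Degenerate truncation intervals (numerically empty after conditioning)
  return the interval midpoint instead of raising.
* SSR = 0 (exact reconstruction) floors σ² at 1e-12 with a warning instead
  of sampling a degenerate inverse-Gamma.
* The truncation normalization constants of the factor prior (orthant
  probabilities) are omitted throughout: they cancel in within-dimension
  Gibbs ratios and are constant across the equal-R states compared by the
  MAP ranking.
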