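# Methods

## Model and scope

The package constructs *second-order* group knockoffs: given a correlation
matrix `Σ` for `p` features and a partition into `g` groups, it chooses a
group-block-diagonal matrix `S` so that the joint covariance `G_S` of the
originals and `m` knockoff copies (diagonal blocks `Σ`, off-diagonal blocks
`Σ − S`) is a valid covariance, i.e. `S ⪰ 0` and `D = ((m+1)/m)Σ − S ⪰ 0`.
Exchangeability then holds for the first two moments of any group swap,
which is exact for Gaussian features and an approximation otherwise. All
samplers here are Gaussian; discrete genotypes are covered only insofar as
their second moments are well approximated by a Gaussian, which is the
standard working assumption for summary-statistic (Z-score) analyses.

Useful identities, used throughout the solver and verified in the test
suite: writing `J` for the all-ones `(m+1)×(m+1)` matrix,
`G_S = J ⊗ (Σ−S) + I ⊗ S`, hence

* `det G_S = m^p · det D · det S^m`, so the entropy objective is
  `L_ME(S) = −[m·logdet S + logdet D]` up to the constant `p·log m`;
* `Tr(G_S⁻¹) = (1/m)·Tr(D⁻¹) + m·Tr(S⁻¹)` (the MVR objective).

## Objectives and solvers

Four constructions are available:

| method  | objective                                             | algorithm |
|---------|-------------------------------------------------------|-----------|
| `equi`  | `S_γ = τ Σ_γ`, largest feasible τ                     | closed form |
| `sdp`   | `Σ_γ |A_γ|⁻² Σ_{ij∈γ} |S_ij − Σ_ij|`                  | coordinate descent + PCA |
| `maxent`| `−[m logdet S + logdet D]`                            | coordinate descent + PCA |
| `mvr`   | `(1/m)Tr(D⁻¹) + m Tr(S⁻¹)`                            | coordinate descent + PCA |

`equi` computes `τ = min{1, ((m+1)/m)·λ_min(BΣB)}` with
`B = diag(Σ_γ^{−1/2})`; for `m = 1` this is the classical bound
`min{1, 2λ_min(BΣB)}`, and the `m > 1` form is the direct generalization of
the constraint `((m+1)/m)Σ − S ⪰ 0`. The returned `S` is shrunk by
`(1 − ε)` to stay strictly interior; the pre-shrink τ is reported.

The iterative methods start from the strictly feasible interior point
`S⁰ = (τ_equi/2)·Σ_block` and alternate, per round:

1. **a full coordinate sweep** — groups in index order; within each group
   diagonal entries first, then the upper triangle row-major.  For each
   entry the feasible step interval is computed from quadratic forms
   `e_i'S⁻¹e_j`, `e_i'D⁻¹e_j` obtained by triangular solves on the
   maintained Cholesky factors;
2. **a full PCA sweep** — rank-1 steps `S ← S + δ·vv'` along each
   eigenvector of `Σ_block = diag(Σ_1, ..., Σ_g)` (outer products respect
   the block pattern).  These coarser moves let the iterate escape the
   slow-mixing regime of pure coordinate descent near the PD boundary.

Step sizes: ME diagonal and PCA steps have closed forms
(`δ = (m·s − d)/((m+1)·s·d)` with `s = v'S⁻¹v`, `d = v'D⁻¹v`, always
interior); ME off-diagonal steps maximize the rank-2 determinant-ratio
objective by bounded scalar search; SDP steps are exact 1-D minimizers of
the piecewise-linear restriction (breakpoint enumeration); MVR steps
minimize the exact low-rank trace-update formulas by bounded scalar search.
Every step is accepted only if it does not increase the objective, making
the per-round objective trace non-increasing by construction.

### Feasible intervals: printed form vs exact form

For diagonal entries the step region
`(−1/(S⁻¹)_jj, 1/(D⁻¹)_jj)` is exact. For off-diagonal entries the
commonly quoted region built from the same quadratic forms
(`−2/[(S⁻¹)_ii + 2(S⁻¹)_ij + (S⁻¹)_jj]` below, the analogous `D` expression
above) is a relaxation, not an exact feasibility region: each bound is
conservative for one matrix but ignores the other matrix's cap on that
side. Example: `Σ = I₂, S = 0.5·I, m = 1` gives the quoted region
`(−0.5, 1.5)`, yet `S + δ(e₁e₂' + e₂e₁')` loses positive definiteness at
`δ = 0.5`. `feasible_interval` exposes the quoted form (and its diagonal
exact form); internally every candidate step is clamped to the *exact*
region obtained from the roots of the rank-2 determinant ratios
`(1 + δa_ij)² − δ²a_ii a_jj` (and the `D` analogue). For ME this is belt
and braces — the log objective diverges at the true boundary — but for
SDP/MVR the clamp is required for correctness.

### Cholesky maintenance

Factors `C` (of `S`) and `L` (of `D`) are kept in sync under every step via
rank-1 update/downdate (a symmetric off-diagonal step decomposes as
`δ(xx' − yy')` with `x, y = (e_i ± e_j)/√2`). The sequential kernel is
numba-jitted with a pure-NumPy fallback. A downdate that loses positive
definiteness (possible only within rounding of the feasibility boundary)
triggers a full refactorization and a warning. The test suite checks
`‖CC' − S‖_max ≤ 1e−8` after 100 random updates.

### Stopping and defaults

`eps_boundary = 1e−6` is removed from both ends of every step interval.
Iteration stops when the relative objective change per round falls below
`tol_obj` (default `1e−4`) or after `max_sweeps = 100` rounds. The default
tolerance targets the statistical use case, where `S` errors of order
`1e−3` are immaterial; the analytic-recovery tests (identity and
single-group regimes, oracle comparison) tighten `tol_obj` to `1e−10`
because they assert numerical agreement, not statistical adequacy.
Convergence is linear, so the extra cost is a handful of rounds.

## Sampling

From Gaussian conditioning on `G_S`, the knockoff copies given `X = x` are
`X̃_k = Px + ε_k` with

* `P = I − SΣ⁻¹`,
* `Cov(ε_k, ε_k) = 2S − SΣ⁻¹S`, `Cov(ε_k, ε_l) = S − SΣ⁻¹S` (k ≠ l).

The implied joint covariance reproduces `G_S` exactly; this identity is an
explicit test contract. The `mp × mp` noise covariance is factored by
symmetric eigendecomposition with negative eigenvalues (≥ −1e−8, arising
only at the feasibility boundary) clipped to zero. Ghost knockoffs apply
the same law directly to a Z-score vector. Columns are laid out
copy-major: copy k occupies columns `[(k−1)p, kp)`.

## Group-key conditional independence

Within each group a key subset `A_γ⋆` may be selected so that the remaining
members are (approximately) independent of everything outside the group
given the keys. Keys are chosen by greedy forward selection: starting from
the variable with the largest explained within-group variance
`EV(K) = Tr(Σ_{γ,K} Σ_{KK}⁻¹ Σ_{K,γ})` (a sum of per-variable R² values
under unit variances), variables are added — ties to the lowest index —
until `EV/|A_γ| ≥ c`. The greedy EV criterion is computed over *all* group
members, keys included; `c = 1` makes every variable a key and disables the
construction. Knockoffs are then solved and sampled for the keys only, and
non-key knockoffs regenerated as `B·X̃⋆ + N(0, R)` from the within-group
conditional regression (`B = Σ_{†⋆}Σ_{⋆⋆}⁻¹`, `R` the Schur complement).
For the entropy objective this two-stage construction provably yields the
same distribution as solving on the full `Σ` whenever the conditional
independence holds exactly; the suite verifies the equivalence empirically
(joint second moments at n = 200 000) on a covariance constructed to
satisfy the property, and `ci_implied_sigma` provides the projection of an
arbitrary `Σ` onto the exactly-conditionally-independent structure for
diagnostics.

## Grouping

Groups come from average-linkage hierarchical clustering with dissimilarity
`1 − |r|` (absolute correlation — the sign of LD correlation is an artifact
of allele coding) and a strict cut at height `1 − cutoff`, so pairs with
`|r|` exactly equal to the cutoff do not merge; this makes the partition
deterministic. Default cutoff 0.5.

## Selection filter

Group importance is `Z_γ = Σ_{i∈A_γ}|β̂_i|` from a Lasso on the augmented
design `[X, X̃_1, ..., X̃_m]`, with the penalty chosen by 10-fold
cross-validation on a 100-point logarithmic grid with seeded fold
assignment (determinism). For summary statistics a deliberately simple
ridge surrogate `β̂ = (G_S + εI)⁻¹[z; z̃]` stands in for penalized
summary-statistic regression; it is plumbing for the pipeline, not a
power-optimized statistic. Scores per group: the winner index `κ` (0 when
the original ties or beats all m copies — ties favor the original,
matching the `≥` in the W indicator), the margin `τ` = largest value minus
the median of the remaining m, and `W = τ·1(κ = 0)`, which on winning
groups equals `(Z − median(Z̃^(1..m)))·1(Z ≥ max Z̃)`. The selection
threshold is the smallest positive `τ` value at which the FDP estimate
`(1/m + (1/m)·#{κ ≥ 1, τ_γ ≥ t}) / #{κ = 0, τ_γ ≥ t}` drops below `q`;
with `m = 1` this is the classic knockoff+ filter. The margin-based `τ`
convention was fixed by requiring consistency between the `(κ, τ)` filter
and the printed `W`; the end-to-end FDR simulation guards the choice.

## Synthetic covariance families and the simulation harness

Five generators emulate canonical dependence structures (defaults chosen
once as representative of the knockoff simulation literature):

* `block` — equicorrelated blocks of size `b = 5`, within-block correlation
  `ρ_b ~ U(0.3, 0.9)` per block (or fixed);
* `er_cov` / `er_prec` — Erdős–Rényi sparse symmetric matrix (edge
  probability 0.1, weights `U(0.2, 0.6)` with random sign, diagonal loaded
  for positive definiteness) used as covariance, or as precision and then
  inverted;
* `ar1` — `Σ_ij = ρ^|i−j|`, default `ρ = 0.5`;
* `ar1_corr` — AR(1) with per-adjacent-pair `ρ_j ~ U(0.2, 0.8)`.

All outputs are rescaled to unit diagonal; `regularize` then shifts toward
the identity on a 0.01 grid until `λ_min ≥ 0.01` (the smallest such shift,
recorded in the model; idempotent).

Each simulation replicate: draw `Σ`, draw `X ~ N(0, Σ)` (n rows,
standardized), draw `k` causal coefficients `~ N(0, effect_sd²)` at uniform
positions with unit Gaussian noise, cluster groups from the *sample*
correlation of `X` (as an analyst without oracle knowledge would), solve
`S` on the generator `Σ` (both choices configurable), sample `m` knockoffs,
fit the Lasso, filter at level `q`. Power counts discovered causal groups
(a group is causal if it contains ≥ 1 causal feature); FDP counts
discoveries containing none; empty denominators are defined as 0. Per-rep
seeds are spawned deterministically from the master seed.

The headline experiment uses the AR(1) family at `p = 200`, `n = 750`,
`k = 10`, `m = 5`, `q = 0.1`, 40 replicates — a problem size chosen so the
whole experiment, solver included, completes in minutes while leaving the
Monte-Carlo error of the FDR estimate a few percent. What these simulations
emulate is the *Gaussian idealization* of LD: they do not capture discrete
genotypes, allele-frequency spectra, population structure, or mismatch
between the LD panel and the study sample, so passing them demonstrates
correctness of the machinery under its own model assumptions, not
robustness to real-data violations of those assumptions.

## Known limitations

* Dense linear algebra throughout: `p` is bounded by memory and `O(p³)`
  factorizations; the intended usage solves LD blocks of ~10²–10³ variants
  separately, block by block, not a whole chromosome at once.
* The summary-statistic importance is a ridge surrogate, weaker than a
  proper penalized pseudo-regression with tuned penalty.
* Low-rank (`Σ = D + UU'`) accelerations and HMM-based discrete knockoffs
  are out of scope.
* FDR control holds at the group level for the *given* `Σ`; a badly
  misestimated LD matrix degrades the guarantee.
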