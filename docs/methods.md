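# Methods

## Model

The working object is a `p`-dimensional mixture of `J` Gaussian components
grouped into `C ≤ J` subpopulations,

    g(x) = Σ_{c=1}^C α_c f_c(x),

where each subpopulation density `f_c` is the weight-renormalized mixture of
its member Gaussians. With the identity partition this is an ordinary
Gaussian mixture; after component aggregation the `f_c` can be arbitrarily
non-Gaussian while `g` itself is unchanged. All densities are evaluated in
log space (per-component Cholesky factorizations, log-sum-exp combination),
so tail evaluations far below the linear floating-point range remain usable.
Covariances with condition number above 1e12 are rejected with a diagnostic
rather than silently regularized. Variable indices are 1-based in every
public signature and 0-based internally.

## Discriminative measures

Concordance between two densities is `δ_{a,b} = ∫ f_a f_b dx`. For
Gaussians this is the normal density `N(μ_a; μ_b, Σ_a + Σ_b)`, computed with
the exponent kept explicit in log space; for subpopulations it expands
bilinearly over member-Gaussian pairs with renormalized weights (a
log-sum-exp over pair terms). From the concordances:

* DIME values `Δ_c = δ_{c,−c}/δ_{c,c}` and `Δ_{−c} = δ_{c,−c}/δ_{−c,−c}`.
  By Cauchy–Schwarz `δ_{c,−c} ≤ √(δ_{c,c} δ_{−c,−c})`, hence
  `Δ_c Δ_{−c} ≤ 1` always.
* Threshold probabilities `τ_{c+} = α_c/(α_c + (1−α_c)Δ_c)` and
  `τ_{c−} = α_c Δ_{−c}/(1−α_c + α_c Δ_{−c})`.
* Aggregate accuracy `A_c = α_c τ_{c+} + (1−α_c)(1−τ_{c−})`.

All of these are invariant under invertible affine maps of the variables
(each concordance picks up the same Jacobian factor, which cancels in the
ratios), so standardizing data cannot change any conclusion; this is tested
to 1e-8.

`τ_{c±}` are first-order (ratio-of-expectations) approximations to the
expected posterior classification probabilities
`α_{c+} = E[α_c*(x) | x∼f_c]` and `α_{c−} = E[α_c*(x) | x∼f_{−c}]`. A
stratified Monte Carlo oracle (`mc_classification_rates`, exact-allocation
stratification over member Gaussians, mandatory seed) estimates the true
rates for comparison. **Known limitation:** the approximation is accurate
when components are well separated (small Δ) or balanced, but degrades
badly for rare components at moderate overlap — by exact quadrature the
error in `τ_{c+}` reaches ≈ 0.24 for a two-component 1-D model with
α_c = 0.1 and 2σ separation, and ≈ 0.05 at α_c = 0.3 and 3σ. The
corresponding grid test in the acceptance suite documents this honestly and
fails for those regimes; in the discriminative-selection setting the
quantities of interest are small-Δ subsets, where the approximation is
good (errors below 0.01 for Δ ≤ 0.05).

Ties at the classification boundary (`α_c*(x) = τ`, i.e. V = 0) are
classified as "not c": the positive decision requires strict inequality.

## Subset search

Marginalizing the fitted mixture to a subset `h` is exact (sub-vectors and
sub-matrices), so any subset can be scored without refitting. Exhaustive
enumeration is allowed up to p = 20 (with an optional `max_size` cap);
forward search greedily adds the variable maximizing `A_c`, with ties broken
to the smallest variable index for reproducibility. The trace records two
markers without truncating by default: the first step whose accuracy
increment is below 0.01 (dagger) and the first step reaching `A_c ≥ 0.95`
(star). Accuracy-based greedy ordering is the default; by construction the
greedy accuracy path is non-decreasing, and adding a variable that is
independent of the rest with identical distribution across components leaves
every DIME quantity exactly unchanged, so such variables are never
preferred. When a set of aligned posterior draws is supplied instead of one
mixture, each candidate subset is scored by the posterior mean of `A_c`
(per-draw functional evaluation, then averaging); running a separate search
per draw would be combinatorially unstable.

## Fitting

The truncated Dirichlet-process mixture fixes a large truncation `J`, puts
stick-breaking weights `v_j ∼ Beta(1, a)` (concentration `a = 1` by default,
`v_J ≡ 1`) and conjugate normal-inverse-Wishart priors on each component.
Default NIW hyperparameters are data-driven and overridable: prior mean =
sample mean, `κ = 0.01`, `ν = p + 2`, scale matrix = sample covariance
× `J^{−2/p}`, shrinking prior component volumes as the truncation grows.
Data are standardized per variable before fitting and the fitted parameters
mapped back to original units; the DIME functionals are affine-invariant, so
this is purely numerical hygiene.

**Bayesian EM (posterior mode).** Standard responsibilities in the E-step;
in the M-step the stick fractions have the closed-form MAP update
`v_j = n_j/(n_j + m_j + a − 1)` (`n_j` expected counts, `m_j` tail counts),
and means/covariances the standard NIW MAP updates with the covariance
denominator `ν + n_j + p + 2`. The full log posterior (likelihood +
stick-breaking + NIW, constants included) is computed every iteration and is
non-decreasing; this is asserted in tests. Components that lose all
responsibility fall back smoothly to their prior mode — regularization, not
a crash. Defaults: up to 2000 iterations at relative tolerance 1e-8
(convergence near overlapping-component modes is slow), 10 random restarts
(means initialized at randomly chosen data points), best log posterior wins,
ties to the first.

**Blocked Gibbs.** Cycles allocations | parameters (categorical),
sticks | allocations (`Beta(1 + n_j, a + m_j)`), and
(mean, covariance) | allocations from the conjugate NIW posterior
(inverse-Wishart then normal). With no data the sampler reproduces the
prior — tested against the analytic stick moments `E[w_j] = 2^{−j}` at
a = 1 — and on single-component problems it matches the conjugate
closed-form posterior. Seeds are explicit everywhere.

**Relabeling.** Label switching across draws is removed by hard-classifying
a fixed anchor sample under a reference model (typically the EM mode) and
under each draw, then permuting each draw's components by the optimal
assignment (Hungarian algorithm on the agreement table). The contract —
identity on aligned draws, inverse permutation on permuted copies, unimodal
per-slot traces after injected switching — is tested directly.

**Aggregation by modes of attraction.** From each fitted component mean a
fixed-point density ascent of `g` is run (the Gaussian-mixture mean-shift
iteration `x ← (Σ_j w_j N_j(x) Σ_j^{-1})^{-1} Σ_j w_j N_j(x) Σ_j^{-1} μ_j`,
up to 500 steps at relative tolerance 1e-8; non-convergent ascents are
assigned to the nearest located mode with a warning). Components whose modes
coincide — single-linkage, distance below `merge_tol·√p` in per-variable
pooled-standard-deviation units, `merge_tol = 0.1` — share a subpopulation.
Aggregation only relabels components: `g(x)` is exactly unchanged, which the
tests assert pointwise. Subpopulations are labeled 1..C in decreasing
aggregate weight; "effective" subpopulations are those with aggregate weight
above 0.01 (configurable).

## Synthetic generators

`four_component_example()` is the benchmark: 8 variables, 4 components with
proportions (0.3, 0.3, 0.3, 0.1); component 1 shifted on variables 1 and 8
(variance 1 on variable 1), components 2 and 3 shifted to 5 on the
correlated blocks {1,2,3} and {4,5,6} with fixed 3×3 covariance blocks,
component 4 spherical at the origin; all remaining coordinates independent
with variance 5; n = 6000 by default, default seed 20150603. Each dominant
component thus has its own small discriminative variable set and variable 7
is informative for nothing — the structure the selection machinery should
recover. `make_scenario` provides parametric families with closed-form 1-D
answers: an overlap grid (`Δ = exp(−d²/4v)` for an equal-variance pair at
separation d), an exactly-irrelevant appended variable, and a
nested-information diagonal model.

These generators emulate Gaussian or mixture-of-Gaussian subpopulations
only. Real flow-cytometry channels show skew, heavy tails, and boundary
pile-ups that the generators do not imitate, so passing tests demonstrate
correctness of the measures and the fitting/search machinery under the
model's own assumptions, not robustness to real-instrument artifacts.

## Problem sizes and numerical choices

The benchmark pipeline (tests and the acceptance script) uses the full
n = 6000 and J = 16 with 4 EM restarts — enough, in practice, to land the
dominant mode while keeping a full run under a minute. Unit tests use
smaller configurations (n of a few hundred to 2000, J ≤ 6). Monte Carlo
oracles use 1e5 draws with stratified allocation. Quadrature oracles
(adaptive 1-D and 2-D) are trusted to 1e-8 and used only in tests. Weight
floors (1e-10) keep empty sticks off exact zero; covariance symmetrization
`(A + Aᵀ)/2` is applied after every update.

## Design choices made where the design was open

* Posterior summaries average per-draw functionals rather than evaluating
  functionals at averaged parameters; published per-step tables produced
  this way are therefore only approximately internally consistent, and
  consistency checks against printed values use ±0.0015.
* Uncertainty intervals are central 95% draw quantiles.
* The greedy criterion is `A_c`; DIME-based ordering can be derived from the
  same tables but is not the default.
* DP concentration is fixed at 1 rather than given a hyperprior; for the
  discriminative questions addressed here the truncation level, not the
  concentration, is the binding choice.
* The model JSON schema is versioned (`schema_version: 1`); draws are stored
  as JSON lines with a header record.
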