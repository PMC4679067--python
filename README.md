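# dimix

Discriminative variable-subset evaluation for Bayesian Gaussian mixture
models.

## The problem

In mixture-model analyses of multivariate data — the motivating case being
flow cytometry, where each of 10–20 markers is measured on very large numbers
of single cells and mixture components represent cell subpopulations — a
recurring question is *which variables discriminate a given subpopulation
from everything else*. Different subpopulations are typically characterized
by different, small variable subsets, so a single global variable ranking is
not enough: the assessment has to be per component, and it should be cheap
enough to evaluate many subsets against an already-fitted model without
refitting.

`dimix` is for statisticians and computational biologists who fit Bayesian
Gaussian mixtures (or aggregate them into non-Gaussian subpopulations) and
want a principled, fast ranking of variable subsets per subpopulation.

## The measures

For a mixture `g(x) = Σ_c α_c f_c(x)` and a component (or set of components)
`c` with complement `−c`, discrimination is built on the *concordance*
between densities,

    δ_{a,b} = ∫ f_a(x) f_b(x) dx,

which for Gaussians has the closed form `δ_{a,b} = N(μ_a; μ_b, Σ_a + Σ_b)`
and extends bilinearly to mixture-of-Gaussian components. The *discriminative
information measures of evidence* (DIME) are the standardized, directional
concordances

    Δ_c = δ_{c,−c} / δ_{c,c},    Δ_{−c} = δ_{c,−c} / δ_{−c,−c},

Bayes-factor-scale quantities — small values mean strong discrimination.
They map, with the prior probability α_c, to *discriminative threshold
probabilities*

    τ_{c+} = α_c / (α_c + (1 − α_c) Δ_c),
    τ_{c−} = α_c Δ_{−c} / (1 − α_c + α_c Δ_{−c}),

first-order approximations to the expected true-positive and false-positive
posterior classification probabilities, and to the *aggregate discriminative
accuracy*

    A_c(h) = α_c τ_{c+}(h) + (1 − α_c)(1 − τ_{c−}(h))

for any variable subset `h ⊆ {1..p}`, obtained by simply marginalizing the
fitted mixture to `h`. Subsets are then ranked per component by exhaustive
enumeration (small `p`) or greedy forward selection on `A_c`.

The package also provides the model-fitting side: truncated Dirichlet-process
Gaussian mixtures fit by a Bayesian EM (posterior-mode) algorithm and by
blocked Gibbs sampling, MCMC relabeling, and aggregation of Gaussian
components into non-Gaussian subpopulations via modes of attraction.

## Worked example

```python
from dimix import GaussianComponent, StructuredMixture, concordance, dime_summary

mix = StructuredMixture([
    GaussianComponent([0.0], [[1.0]], 0.3),
    GaussianComponent([3.0], [[1.0]], 0.7),
])
s = dime_summary(mix, 1)
print(round(concordance(mix, 1, 1), 4), round(concordance(mix, 1, 2), 4))
print(f"{s.delta_c:.4f} {s.tau_plus:.4f} {s.tau_minus:.4f} {s.accuracy:.4f}")
```

prints

```
0.2821 0.0297
0.1054 0.8026 0.0432 0.9105
```

— the two unit-variance normals separated by 3σ have self-concordance 0.2821
and cross-concordance 0.0297, giving Δ₁ ≈ 0.105 (about 10:1 evidence against
component-1 membership at a typical component-1 point is needed before
mislabeling); a threshold classifier for component 1 has expected posterior
true-positive probability ≈ 0.80, false-positive ≈ 0.04, and prior-weighted
accuracy A₁ ≈ 0.91.

The scripts in `examples/` each demonstrate one capability end to end:
`dime_basics.py` (the numbers above plus a Monte Carlo check),
`forward_search_benchmark.py` (per-component forward variable ranking with
the stop markers), `fit_and_aggregate.py` (EM fit, mode-based aggregation,
matching to ground truth), and `posterior_uncertainty.py` (Gibbs draws and
95% posterior intervals for DIME functionals). A thin CLI wraps the same
workflow: `dimix simulate | fit | aggregate | dime | search | report`.

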