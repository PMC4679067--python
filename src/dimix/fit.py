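"""Truncated Dirichlet-process Gaussian mixture fitting.

The model is a finite mixture with a fixed large truncation level J whose
weights follow a truncated stick-breaking prior, v_j ~ Beta(1, a) for j < J
with w_j = v_j prod_{l<j} (1 - v_l) and v_J = 1, approximating a Dirichlet
process mixture; each component carries a conjugate normal-inverse-Wishart
(NIW) prior on (mean, covariance).

Two fitters share this model:

* ``bayes_em_fit`` — an EM algorithm for the posterior mode (MAP).  The
  E-step computes responsibilities; the M-step maximizes the expected
  complete-data log posterior, with closed-form stick updates
  v_j = n_j / (n_j + m_j + a - 1) (n_j expected counts, m_j tail counts)
  and standard NIW MAP updates for means and covariances.  The log posterior
  is non-decreasing across iterations; the best of several random restarts is
  returned.

* ``gibbs_fit`` — a blocked Gibbs sampler cycling allocations | parameters,
  stick weights | allocations, and (mean, covariance) | allocations from the
  conjugate NIW posterior.

Data are standardized (per-variable center/scale) internally before fitting
and the fitted model is mapped back to the original units; the DIME
functionals are affine invariant, so this is purely numerical hygiene.

``aggregate_components`` merges fitted Gaussians into non-Gaussian
subpopulations by modes of attraction: a density (mean-shift) ascent of the
overall mixture density is run from each component mean, and components whose
ascents settle on the same mode share a subpopulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import invwishart

from .mixture import GaussianComponent, StructuredMixture

__all__ = [
    "NIWPrior",
    "FitConfig",
    "FitResult",
    "PosteriorDraws",
    "bayes_em_fit",
    "gibbs_fit",
    "relabel",
    "aggregate_components",
    "effective_components",
    "match_subpopulations",
]

_LOG2PI = float(np.log(2.0 * np.pi))
# Weight floor: keeps empty sticks off exact zero so log-weights stay finite.
_WEIGHT_FLOOR = 1e-10


@dataclass
class NIWPrior:
    """Normal-inverse-Wishart hyperparameters for one component.

    mean ~ N(m0, cov / kappa), cov ~ IW(nu, psi).  Defaults are data-driven
    (see ``FitConfig.resolve_prior``).
    """

    m0: np.ndarray
    kappa: float
    nu: float
    psi: np.ndarray

    def validate(self, p: int):
        if self.nu <= p - 1:
            raise ValueError(f"nu must exceed p-1={p - 1}, got {self.nu}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class FitConfig:
    """Settings for EM and Gibbs fitting of the truncated-DP mixture.

    truncation
        Upper bound J on the number of Gaussian components (J >= 2).
    dp_concentration
        Stick-breaking concentration a > 0 (fixed; default 1).
    prior
        Optional explicit NIW prior; by default resolved from the data as
        m0 = sample mean, kappa = 0.01, nu = p + 2, psi = sample covariance
        scaled by J**(-2/p) so that prior component volumes shrink as the
        truncation grows.
    em_max_iter, em_rel_tol, em_restarts
        EM iteration cap, relative log-posterior tolerance, and number of
        random restarts (best log posterior wins, ties to the first).
    mcmc_iter, mcmc_burn, mcmc_thin
        Gibbs sampler length, burn-in, and thinning.
    """

    truncation: int = 16
    dp_concentration: float = 1.0
    prior: Optional[NIWPrior] = None
    em_max_iter: int = 2000
    em_rel_tol: float = 1e-8
    em_restarts: int = 10
    mcmc_iter: int = 1000
    mcmc_burn: int = 200
    mcmc_thin: int = 1
    standardize: bool = True

    def __post_init__(self):
        if self.truncation < 2:
            raise ValueError("truncation J must be at least 2")
        if self.dp_concentration <= 0:
            raise ValueError("dp_concentration must be positive")
        if self.em_restarts < 1:
            raise ValueError("em_restarts must be at least 1")

    def resolve_prior(self, x: np.ndarray) -> NIWPrior:
        if self.prior is not None:
            self.prior.validate(x.shape[1])
            return self.prior
        p = x.shape[1]
        scale = self.truncation ** (-2.0 / p)
        prior = NIWPrior(
            m0=x.mean(axis=0),
            kappa=0.01,
            nu=float(p + 2),
            psi=np.cov(x, rowvar=False) * scale + 1e-8 * np.eye(p),
        )
        prior.validate(p)
        return prior


@dataclass
class FitResult:
    """Posterior-mode fit: the mixture (identity partition), its log posterior,
    the per-iteration trace of the winning restart, and a convergence flag."""

    mixture: StructuredMixture
    log_posterior: float
    trace: np.ndarray
    converged: bool


@dataclass
class PosteriorDraws:
    """Aligned (or raw) MCMC draws of the mixture.

    Iterating yields StructuredMixture draws, so the DIME posterior-summary
    machinery can consume this directly.
    """

    draws: list[StructuredMixture]
    aligned: bool = False
    log_posterior_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __iter__(self):
        return iter(self.draws)

    def __len__(self):
        return len(self.draws)


# ---------------------------------------------------------------------------
# internals shared by EM and Gibbs


def _standardizer(x: np.ndarray, on: bool):
    center = x.mean(axis=0) if on else np.zeros(x.shape[1])
    scale = x.std(axis=0, ddof=1) if on else np.ones(x.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def _destandardize_params(means, covs, center, scale):
    out_means = [m * scale + center for m in means]
    d = np.diag(scale)
    out_covs = [d @ c @ d for c in covs]
    return out_means, out_covs


def _component_log_pdfs(x, means, covs):
    """(n, J) matrix of Gaussian log pdfs from explicit parameter lists."""
    n, p = x.shape
    out = np.empty((n, len(means)))
    for j, (m, c) in enumerate(zip(means, covs)):
        chol = np.linalg.cholesky(c)
        dev = (x - m) @ np.linalg.inv(chol).T
        maha = np.einsum("ij,ij->i", dev, dev)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, j] = -0.5 * (p * _LOG2PI + logdet + maha)
    return out


def _sticks_to_weights(v: np.ndarray) -> np.ndarray:
    """Map J-1 stick fractions to J weights (last stick implicitly 1)."""
    j = v.size + 1
    w = np.empty(j)
    rest = 1.0
    for i in range(j - 1):
        w[i] = v[i] * rest
        rest *= 1.0 - v[i]
    w[-1] = rest
    return np.maximum(w, _WEIGHT_FLOOR)


def _weights_to_sticks(w: np.ndarray) -> np.ndarray:
    j = w.size
    v = np.empty(j - 1)
    rest = 1.0
    for i in range(j - 1):
        v[i] = min(max(w[i] / rest, 1e-12), 1.0 - 1e-12)
        rest *= 1.0 - v[i]
    return v


def _log_prior(weights, means, covs, prior: NIWPrior, a: float) -> float:
    """Log prior density: truncated stick-breaking + NIW per component.

    Constant terms in the NIW normalizer are included so that log-posterior
    values are comparable across restarts and between EM and Gibbs.
    """
    p = means[0].size
    v = _weights_to_sticks(np.asarray(weights))
    lp = float(np.sum((a - 1.0) * np.log1p(-v))) + (v.size) * np.log(a)
    nu, kappa, psi, m0 = prior.nu, prior.kappa, prior.psi, prior.m0
    sign, logdet_psi = np.linalg.slogdet(psi)
    from scipy.special import multigammaln

    niw_const = (
        0.5 * nu * logdet_psi
        - 0.5 * nu * p * np.log(2.0)
        - multigammaln(0.5 * nu, p)
        + 0.5 * p * np.log(kappa)
        - 0.5 * p * _LOG2PI
    )
    for m, c in zip(means, covs):
        chol = np.linalg.cholesky(c)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        cinv_dev = np.linalg.solve(c, m - m0)
        quad = kappa * float((m - m0) @ cinv_dev)
        trace_term = float(np.trace(np.linalg.solve(c, psi)))
        lp += niw_const - 0.5 * (nu + p + 2.0) * logdet - 0.5 * (trace_term + quad)
    return lp


def _log_posterior(x, weights, means, covs, prior, a) -> float:
    lp = _component_log_pdfs(x, means, covs)
    loglik = float(np.sum(logsumexp(lp + np.log(weights), axis=1)))
    return loglik + _log_prior(weights, means, covs, prior, a)


def _as_mixture(weights, means, covs) -> StructuredMixture:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    comps = [GaussianComponent(m, c, wi) for m, c, wi in zip(means, covs, w)]
    return StructuredMixture(comps)


# ---------------------------------------------------------------------------
# Bayesian EM


def _em_once(x, config: FitConfig, prior: NIWPrior, rng) -> tuple:
    n, p = x.shape
    j = config.truncation
    a = config.dp_concentration
    # init: means at randomly chosen data points, covariances at the prior mode
    means = [x[i].copy() for i in rng.choice(n, size=j, replace=False)]
    cov0 = prior.psi / (prior.nu + p + 2.0) + 1e-6 * np.eye(p)
    covs = [cov0.copy() for _ in range(j)]
    weights = np.full(j, 1.0 / j)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(config.em_max_iter):
        # E-step
        logr = _component_log_pdfs(x, means, covs) + np.log(weights)
        logr -= logsumexp(logr, axis=1, keepdims=True)
        r = np.exp(logr)
        nj = r.sum(axis=0)
        # M-step: sticks
        tail = np.concatenate([np.cumsum(nj[::-1])[::-1][1:], [0.0]])[: j - 1]
        denom = nj[: j - 1] + tail + a - 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(denom > 0, nj[: j - 1] / np.maximum(denom, 1e-300), 0.0)
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        weights = _sticks_to_weights(v)
        # M-step: NIW MAP per component
        for k in range(j):
            rk = r[:, k]
            nk = nj[k]
            xbar = (rk @ x) / nk if nk > 1e-12 else prior.m0
            mean_k = (prior.kappa * prior.m0 + nk * xbar) / (prior.kappa + nk)
            dev = x - xbar
            s = (rk[:, None] * dev).T @ dev
            d0 = (xbar - prior.m0)[:, None]
            psi_post = (
                prior.psi + s + (prior.kappa * nk / (prior.kappa + nk)) * (d0 @ d0.T)
            )
            cov_k = psi_post / (prior.nu + nk + p + 2.0)
            means[k] = mean_k
            covs[k] = 0.5 * (cov_k + cov_k.T)
        lpost = _log_posterior(x, weights, means, covs, prior, a)
        trace.append(lpost)
        if np.isfinite(prev) and abs(lpost - prev) <= config.em_rel_tol * (abs(prev) + 1.0):
            converged = True
            prev = lpost
            break
        prev = lpost
    return weights, means, covs, np.array(trace), converged


def bayes_em_fit(x: np.ndarray, config: FitConfig, seed=0) -> FitResult:
    """MAP fit of the truncated-DP Gaussian mixture by Bayesian EM.

    Runs ``config.em_restarts`` random initializations and returns the fit
    with the highest log posterior.  The returned mixture has the identity
    partition (one subpopulation per Gaussian); follow with
    ``aggregate_components`` to form non-Gaussian subpopulations.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    if np.isnan(x).any():
        raise ValueError("data contains missing values")
    center, scale = _standardizer(x, config.standardize)
    z = (x - center) / scale
    prior = config.resolve_prior(z)
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(config.em_restarts):
        weights, means, covs, trace, converged = _em_once(z, config, prior, rng)
        any_converged = any_converged or converged
        if best is None or trace[-1] > best[3][-1]:
            best = (weights, means, covs, trace, converged)
    weights, means, covs, trace, converged = best
    if not converged:
        warnings.warn(
            "Bayesian EM did not meet the relative tolerance within "
            f"{config.em_max_iter} iterations; returning the best fit found",
            RuntimeWarning,
        )
    means, covs = _destandardize_params(means, covs, center, scale)
    return FitResult(
        mixture=_as_mixture(weights, means, covs),
        log_posterior=float(trace[-1]),
        trace=trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# blocked Gibbs


def gibbs_fit(
    x: np.ndarray,
    config: FitConfig,
    init: Optional[StructuredMixture] = None,
    seed=0,
) -> PosteriorDraws:
    """Blocked Gibbs sampler for the truncated-DP Gaussian mixture.

    Cycles z | (w, theta), sticks v | z, and (mean, cov) | z with conjugate
    Beta and NIW full conditionals.  With an empty data matrix (n = 0) the
    sampler draws from the prior, which the tests use as a correctness check.
    ``init`` (typically the EM posterior mode) sets the starting parameters.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    n, p = x.shape
    j = config.truncation
    a = config.dp_concentration
    rng = np.random.default_rng(seed)
    center, scale = _standardizer(x, config.standardize and n > 1)
    z = (x - center) / scale
    if n > 1:
        prior = config.resolve_prior(z)
    else:
        if config.prior is None:
            raise ValueError("an explicit prior is required when fitting without data")
        prior = config.prior
    if init is not None:
        if init.n_components != j:
            raise ValueError("init mixture truncation does not match config")
        weights = init.weights.copy()
        means = [(c.mean - center) / scale for c in init.components]
        d_inv = np.diag(1.0 / scale)
        covs = [d_inv @ c.cov @ d_inv for c in init.components]
    else:
        weights = np.full(j, 1.0 / j)
        means = [prior.m0 + 0.01 * rng.standard_normal(p) for _ in range(j)]
        covs = [prior.psi / max(prior.nu - p - 1.0, 1.0) for _ in range(j)]
    draws: list[StructuredMixture] = []
    lp_trace = []
    for it in range(config.mcmc_iter):
        # allocations
        if n > 0:
            logr = _component_log_pdfs(z, means, covs) + np.log(weights)
            logr -= logsumexp(logr, axis=1, keepdims=True)
            u = rng.random(n)
            alloc = (np.cumsum(np.exp(logr), axis=1) < u[:, None]).sum(axis=1)
            alloc = np.minimum(alloc, j - 1)
            nj = np.bincount(alloc, minlength=j).astype(float)
        else:
            alloc = np.empty(0, dtype=int)
            nj = np.zeros(j)
        # sticks
        tail = np.concatenate([np.cumsum(nj[::-1])[::-1][1:], [0.0]])[: j - 1]
        v = rng.beta(1.0 + nj[: j - 1], a + tail)
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        weights = _sticks_to_weights(v)
        # component parameters from the conjugate NIW posterior
        for k in range(j):
            rows = z[alloc == k] if n > 0 else z[:0]
            nk = rows.shape[0]
            if nk > 0:
                xbar = rows.mean(axis=0)
                dev = rows - xbar
                s = dev.T @ dev
            else:
                xbar = prior.m0
                s = np.zeros((p, p))
            kappa_n = prior.kappa + nk
            nu_n = prior.nu + nk
            m_n = (prior.kappa * prior.m0 + nk * xbar) / kappa_n
            d0 = (xbar - prior.m0)[:, None]
            psi_n = prior.psi + s + (prior.kappa * nk / kappa_n) * (d0 @ d0.T)
            psi_n = 0.5 * (psi_n + psi_n.T)
            cov_k = invwishart.rvs(df=nu_n, scale=psi_n, random_state=rng)
            cov_k = np.atleast_2d(cov_k)
            mean_k = rng.multivariate_normal(m_n, cov_k / kappa_n)
            means[k] = mean_k
            covs[k] = 0.5 * (cov_k + cov_k.T)
        if it >= config.mcmc_burn and (it - config.mcmc_burn) % config.mcmc_thin == 0:
            om, oc = _destandardize_params(means, covs, center, scale)
            draws.append(_as_mixture(weights, om, oc))
            if n > 0:
                lp_trace.append(_log_posterior(z, weights, means, covs, prior, a))
    return PosteriorDraws(draws=draws, aligned=False, log_posterior_trace=np.array(lp_trace))


def relabel(
    draws: PosteriorDraws,
    reference: StructuredMixture,
    anchor: np.ndarray,
) -> PosteriorDraws:
    """Align component labels of each draw to a reference mixture.

    Both the reference and each draw hard-classify a fixed anchor sample to
    their J Gaussian components; each draw's components are then permuted by
    the optimal assignment (Hungarian algorithm) that minimizes disagreement
    with the reference classification.  Deterministic given the draws.
    """
    anchor = np.atleast_2d(np.asarray(anchor, dtype=float))
    j = reference.n_components
    ref_alloc = np.argmax(
        reference.component_log_pdfs(anchor) + np.log(reference.weights), axis=1
    )
    aligned = []
    for mix in draws:
        if mix.n_components != j:
            raise ValueError("draw truncation differs from reference")
        alloc = np.argmax(mix.component_log_pdfs(anchor) + np.log(mix.weights), axis=1)
        agree = np.zeros((j, j))
        np.add.at(agree, (ref_alloc, alloc), 1.0)
        row, col = linear_sum_assignment(-agree)
        perm = np.empty(j, dtype=int)
        perm[row] = col  # reference slot r holds draw component perm[r]
        comps = [mix.components[perm[r]] for r in range(j)]
        aligned.append(StructuredMixture(comps))
    return PosteriorDraws(
        draws=aligned, aligned=True, log_posterior_trace=draws.log_posterior_trace
    )


# ---------------------------------------------------------------------------
# component aggregation by modes of attraction


def _mean_shift(mix: StructuredMixture, start: np.ndarray, max_steps=500, tol=1e-8):
    """Fixed-point density ascent of the mixture density from ``start``.

    x <- (sum_j w_j N_j(x) S_j^-1)^-1 sum_j w_j N_j(x) S_j^-1 mu_j,
    the stationary-point iteration of grad g = 0 for Gaussian mixtures.
    Returns (mode, converged).
    """
    p = mix.dim
    invs = [np.linalg.inv(c.cov) for c in mix.components]
    x = np.asarray(start, dtype=float).copy()
    for _ in range(max_steps):
        logw = mix.component_log_pdfs(x[None, :])[0] + np.log(mix.weights)
        logw -= logsumexp(logw)
        w = np.exp(logw)
        num = np.zeros(p)
        den = np.zeros((p, p))
        for wj, inv, comp in zip(w, invs, mix.components):
            den += wj * inv
            num += wj * (inv @ comp.mean)
        x_new = np.linalg.solve(den, num)
        if np.linalg.norm(x_new - x) < tol * (1.0 + np.linalg.norm(x)):
            return x_new, True
        x = x_new
    return x, False


def aggregate_components(
    mix: StructuredMixture, merge_tol: float = 0.1
) -> StructuredMixture:
    """Group Gaussian components into subpopulations by modes of attraction.

    A density ascent is started from each component mean; components whose
    ascents reach the same mode of the overall density g share a
    subpopulation.  Two modes are "the same" when their distance, measured in
    per-variable standardized units (pooled mixture standard deviations), is
    below ``merge_tol * sqrt(p)``.  Aggregation only changes the partition:
    the mixture density g is exactly unchanged.  Subpopulations are labeled
    1..C in decreasing aggregate weight.
    """
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    p = mix.dim
    w = mix.weights
    mu_bar = sum(wi * c.mean for wi, c in zip(w, mix.components))
    second = sum(
        wi * (c.cov + np.outer(c.mean, c.mean)) for wi, c in zip(w, mix.components)
    )
    pooled_sd = np.sqrt(np.maximum(np.diag(second - np.outer(mu_bar, mu_bar)), 1e-12))
    modes = []
    non_converged = 0
    for comp in mix.components:
        mode, ok = _mean_shift(mix, comp.mean)
        if not ok:
            non_converged += 1
        modes.append(mode / pooled_sd)
    if non_converged:
        warnings.warn(
            f"density ascent did not converge for {non_converged} component(s); "
            "they were assigned to the nearest located mode",
            RuntimeWarning,
        )
    # single-linkage merge of modes within the tolerance radius
    j = len(modes)
    parent = list(range(j))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    thr = merge_tol * np.sqrt(p)
    for i in range(j):
        for k in range(i + 1, j):
            if np.linalg.norm(modes[i] - modes[k]) < thr:
                parent[find(i)] = find(k)
    roots = [find(i) for i in range(j)]
    # label groups 1..C by decreasing aggregate weight; ties by first member
    group_weight: dict[int, float] = {}
    group_first: dict[int, int] = {}
    for i, r in enumerate(roots):
        group_weight[r] = group_weight.get(r, 0.0) + mix.components[i].weight
        group_first.setdefault(r, i)
    ordered = sorted(group_weight, key=lambda r: (-group_weight[r], group_first[r]))
    label_of = {r: c for c, r in enumerate(ordered, start=1)}
    partition = tuple(label_of[r] for r in roots)
    return StructuredMixture(mix.components, partition)


def effective_components(mix: StructuredMixture, threshold: float = 0.01) -> list[int]:
    """Subpopulation labels whose aggregate weight exceeds ``threshold``."""
    return [c for c in mix.labels if mix.alpha(c) > threshold]


def match_subpopulations(
    mix: StructuredMixture, x: np.ndarray, true_labels: np.ndarray
) -> dict[int, int]:
    """Match fitted subpopulations to true labels by maximal overlap.

    Classifies ``x`` to the fitted subpopulation with the highest posterior
    probability, cross-tabulates against ``true_labels``, and solves the
    optimal assignment.  Returns {fitted label -> true label} for the matched
    pairs (extra fitted subpopulations are left unmatched).
    """
    from .mixture import component_posterior

    fitted_labels = list(mix.labels)
    post = np.column_stack([component_posterior(mix, x, c) for c in fitted_labels])
    hard = np.asarray(fitted_labels)[np.argmax(post, axis=1)]
    true_vals = sorted(set(int(t) for t in true_labels))
    table = np.zeros((len(fitted_labels), len(true_vals)))
    for i, fl in enumerate(fitted_labels):
        for k, tv in enumerate(true_vals):
            table[i, k] = np.sum((hard == fl) & (true_labels == tv))
    row, col = linear_sum_assignment(-table)
    return {int(fitted_labels[r]): int(true_vals[c]) for r, c in zip(row, col)}
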