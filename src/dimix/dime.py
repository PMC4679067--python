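"""Discriminative information measures for mixture components.

Given a structured mixture g = sum_c alpha_c f_c, discrimination of one
subpopulation c from its complement -c is summarized through the concordance

    delta_{a,b} = integral f_a(x) f_b(x) dx,

a symmetric overlap measure between two densities.  For Gaussians it has the
closed form delta_{a,b} = N(mu_a; mu_b, Sigma_a + Sigma_b); for the sub-mixture
densities f_c it expands bilinearly over member Gaussian pairs.  From the
concordances we form the DIME values

    Delta_c  = delta_{c,-c} / delta_{c,c}    (true-positive direction)
    Delta_-c = delta_{c,-c} / delta_{-c,-c}  (true-negative direction),

Bayes-factor-scale quantities where small values mean good discrimination, and
the discriminative threshold probabilities

    tau_c+ = alpha_c / (alpha_c + (1 - alpha_c) Delta_c)
    tau_c- = alpha_c Delta_-c / (1 - alpha_c + alpha_c Delta_-c),

first-order approximations to the expected true- and false-positive posterior
classification probabilities.  The aggregate accuracy

    A_c = alpha_c tau_c+ + (1 - alpha_c)(1 - tau_c-)

puts discrimination for a variable subset h on an absolute probability scale.
All concordance work is carried out in log space so that extreme component
separations produce tiny Delta values rather than underflowing to 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .mixture import (
    GaussianComponent,
    StructuredMixture,
    marginalize,
    validate_subset,
)

__all__ = [
    "DimeSummary",
    "RateEstimate",
    "PosteriorDimeSummary",
    "log_gaussian_concordance",
    "gaussian_concordance",
    "concordance",
    "dime_values",
    "thresholds",
    "accuracy",
    "dime_summary",
    "mc_classification_rates",
    "posterior_summary",
]


@dataclass(frozen=True)
class DimeSummary:
    """DIME quintet for one (component set, variable subset) pair."""

    component: object
    subset: tuple[int, ...]
    delta_c: float
    delta_neg_c: float
    tau_plus: float
    tau_minus: float
    accuracy: float
    alpha_c: float

    def as_dict(self) -> dict:
        return {
            "component": self.component,
            "subset": self.subset,
            "delta_c": self.delta_c,
            "delta_neg_c": self.delta_neg_c,
            "tau_plus": self.tau_plus,
            "tau_minus": self.tau_minus,
            "accuracy": self.accuracy,
            "alpha_c": self.alpha_c,
        }


@dataclass(frozen=True)
class RateEstimate:
    """Monte Carlo estimates of expected classification rates.

    ``alpha_plus_hat`` estimates E[alpha_c*(x) | x ~ f_c] (true-positive rate)
    and ``alpha_minus_hat`` estimates E[alpha_c*(x) | x ~ f_-c] (false-positive
    rate), each with its Monte Carlo standard error.
    """

    alpha_plus_hat: float
    alpha_minus_hat: float
    se_plus: float
    se_minus: float
    n_draws: int


def log_gaussian_concordance(a: GaussianComponent, b: GaussianComponent) -> float:
    """log of integral N(x; mu_a, S_a) N(x; mu_b, S_b) dx.

    Equals the log density of N(mu_a - mu_b; 0, S_a + S_b); computed through a
    Cholesky factor with the exponent kept explicit, so extreme separations
    give large negative logs instead of zero.
    """
    if a.dim != b.dim:
        raise ValueError("components have different dimensions")
    s = a.cov + b.cov
    try:
        chol = np.linalg.cholesky(s)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - SPD sum of SPDs
        raise ValueError("sum of covariances is not positive definite") from exc
    dev = a.mean - b.mean
    z = np.linalg.solve(chol, dev)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (a.dim * np.log(2.0 * np.pi) + logdet + float(z @ z))


def gaussian_concordance(a: GaussianComponent, b: GaussianComponent) -> float:
    """Closed-form concordance between two Gaussian densities (weights ignored)."""
    return float(np.exp(log_gaussian_concordance(a, b)))


def _log_concordance_parts(
    mix: StructuredMixture, part_a, part_b, h: Optional[Iterable[int]] = None
) -> float:
    """log delta between the sub-mixture densities of two label sets.

    Bilinear expansion over member Gaussian pairs with weights renormalized
    within each part; evaluated as a logsumexp over pair terms.
    """
    if h is not None:
        mix = marginalize(mix, h)
    ia = mix.member_indices(part_a)
    ib = mix.member_indices(part_b)
    log_wa = np.log([mix.components[j].weight for j in ia]) - np.log(mix.alpha(part_a))
    log_wb = np.log([mix.components[j].weight for j in ib]) - np.log(mix.alpha(part_b))
    terms = np.empty((len(ia), len(ib)))
    for r, j in enumerate(ia):
        for s, k in enumerate(ib):
            terms[r, s] = (
                log_wa[r] + log_wb[s]
                + log_gaussian_concordance(mix.components[j], mix.components[k])
            )
    return float(logsumexp(terms))


def concordance(
    mix: StructuredMixture, part_a, part_b, h: Optional[Iterable[int]] = None
) -> float:
    """Concordance delta between the densities of two subpopulation label sets.

    ``h`` optionally marginalizes to a 1-based variable subset first.
    """
    return float(np.exp(_log_concordance_parts(mix, part_a, part_b, h)))


def dime_values(
    mix: StructuredMixture, c, h: Optional[Iterable[int]] = None
) -> tuple[float, float]:
    """(Delta_c, Delta_-c) for label set ``c`` on variable subset ``h``."""
    neg = mix.complement_labels(c)
    if h is not None:
        mix = marginalize(mix, h)
    log_cross = _log_concordance_parts(mix, c, neg)
    log_cc = _log_concordance_parts(mix, c, c)
    log_nn = _log_concordance_parts(mix, neg, neg)
    return float(np.exp(log_cross - log_cc)), float(np.exp(log_cross - log_nn))


def thresholds(alpha_c: float, delta_c: float, delta_neg_c: float) -> tuple[float, float]:
    """Discriminative threshold probabilities (tau_c+, tau_c-)."""
    if not 0.0 < alpha_c < 1.0:
        raise ValueError(f"alpha_c must lie in (0, 1), got {alpha_c}")
    if delta_c < 0.0 or delta_neg_c < 0.0:
        raise ValueError("DIME values must be non-negative")
    tau_plus = alpha_c / (alpha_c + (1.0 - alpha_c) * delta_c)
    tau_minus = alpha_c * delta_neg_c / (1.0 - alpha_c + alpha_c * delta_neg_c)
    return float(tau_plus), float(tau_minus)


def accuracy(alpha_c: float, tau_plus: float, tau_minus: float) -> float:
    """Aggregate discriminative accuracy A_c = a tau+ + (1-a)(1-tau-)."""
    if not 0.0 < alpha_c < 1.0:
        raise ValueError(f"alpha_c must lie in (0, 1), got {alpha_c}")
    return float(alpha_c * tau_plus + (1.0 - alpha_c) * (1.0 - tau_minus))


def dime_summary(mix: StructuredMixture, c, h: Optional[Iterable[int]] = None) -> DimeSummary:
    """Full DIME quintet (Delta_c, Delta_-c, tau+, tau-, A_c) for (c, h)."""
    if h is None:
        h = tuple(range(1, mix.dim + 1))
    subset = tuple(int(v) for v in h)
    validate_subset(subset, mix.dim)
    d_c, d_nc = dime_values(mix, c, subset)
    a = mix.alpha(c)
    tp, tm = thresholds(a, d_c, d_nc)
    return DimeSummary(
        component=c if isinstance(c, (int, np.integer)) else tuple(sorted(c)),
        subset=subset,
        delta_c=d_c,
        delta_neg_c=d_nc,
        tau_plus=tp,
        tau_minus=tm,
        accuracy=accuracy(a, tp, tm),
        alpha_c=a,
    )


def _stratified_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n draws across mixture members."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def _stratified_sample(mix: StructuredMixture, c, n: int, rng) -> np.ndarray:
    """Sample n rows from f_c with per-member-Gaussian stratification."""
    idx = mix.member_indices(c)
    w = np.array([mix.components[j].weight for j in idx])
    counts = _stratified_counts(w / w.sum(), n)
    chunks = []
    for j, nj in zip(idx, counts):
        if nj > 0:
            comp = mix.components[j]
            chunks.append(rng.multivariate_normal(comp.mean, comp.cov, size=nj))
    return np.vstack(chunks)


def mc_classification_rates(
    mix: StructuredMixture,
    c,
    h: Optional[Iterable[int]] = None,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> RateEstimate:
    """Monte Carlo oracle for the expected classification rates.

    Estimates alpha_c+ = E[alpha_c*(x) | x ~ f_c] and alpha_c- under f_-c by
    stratified sampling from the member Gaussians of each side (marginalized
    to ``h``), giving an exact-allocation variance reduction over plain
    ancestral sampling.  ``seed`` is mandatory for reproducibility.
    """
    if n < 1000:
        raise ValueError("n must be at least 1000 for a usable Monte Carlo estimate")
    rng = np.random.default_rng(seed)
    m = marginalize(mix, h) if h is not None else mix
    neg = m.complement_labels(c)
    from .mixture import component_posterior

    x_pos = _stratified_sample(m, c, n, rng)
    x_neg = _stratified_sample(m, neg, n, rng)
    post_pos = component_posterior(m, x_pos, c)
    post_neg = component_posterior(m, x_neg, c)
    return RateEstimate(
        alpha_plus_hat=float(post_pos.mean()),
        alpha_minus_hat=float(post_neg.mean()),
        se_plus=float(post_pos.std(ddof=1) / np.sqrt(n)),
        se_minus=float(post_neg.std(ddof=1) / np.sqrt(n)),
        n_draws=n,
    )


@dataclass(frozen=True)
class PosteriorDimeSummary:
    """Posterior mean and central 95% interval for each DIME functional.

    Each functional is evaluated per posterior draw and then averaged;
    intervals are 2.5%/97.5% draw quantiles.
    """

    component: object
    subset: tuple[int, ...]
    mean: DimeSummary
    lower: DimeSummary
    upper: DimeSummary
    n_draws: int


def posterior_summary(draws, c, h: Optional[Iterable[int]] = None) -> PosteriorDimeSummary:
    """Summarize DIME functionals over aligned posterior draws.

    ``draws`` is any sequence of StructuredMixture (e.g. ``PosteriorDraws``
    from the fitting module, after relabeling).
    """
    mixes: Sequence[StructuredMixture] = list(draws)
    if not mixes:
        raise ValueError("empty draw set")
    per_draw = [dime_summary(m, c, h) for m in mixes]
    fields = ["delta_c", "delta_neg_c", "tau_plus", "tau_minus", "accuracy", "alpha_c"]
    arr = np.array([[getattr(s, f) for f in fields] for s in per_draw])
    mean = arr.mean(axis=0)
    lo = np.quantile(arr, 0.025, axis=0)
    hi = np.quantile(arr, 0.975, axis=0)
    subset = per_draw[0].subset
    comp = per_draw[0].component

    def pack(vals):
        kw = dict(zip(fields, (float(v) for v in vals)))
        return DimeSummary(component=comp, subset=subset, **kw)

    return PosteriorDimeSummary(
        component=comp,
        subset=subset,
        mean=pack(mean),
        lower=pack(lo),
        upper=pack(hi),
        n_draws=len(mixes),
    )
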