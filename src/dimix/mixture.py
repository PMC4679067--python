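"""Gaussian mixtures with structured (possibly non-Gaussian) subpopulations.

The central object is a mixture of ``J`` multivariate Gaussian components
partitioned into ``C`` subpopulations.  Each subpopulation density ``f_c`` is
itself a (re-weighted) mixture of its member Gaussians, so the model

    g(x) = sum_c alpha_c f_c(x)

covers both plain Gaussian mixtures (identity partition, C = J) and the
aggregated, non-Gaussian subpopulations produced by mode-based component
merging.  All density work is done in log space; covariance factorizations are
cached per component.

Variable subsets are 1-based in every public signature (``h = (1, 3, 8)``
refers to the first, third and eighth variable); conversion to 0-based NumPy
indexing happens internally.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

__all__ = [
    "GaussianComponent",
    "StructuredMixture",
    "ClassifierSpec",
    "validate_subset",
    "marginalize",
    "density",
    "log_density",
    "component_posterior",
    "classifier_value",
    "sample",
]

_LOG2PI = float(np.log(2.0 * np.pi))

# Covariances worse conditioned than this are treated as numerically singular.
MAX_CONDITION = 1e12


class GaussianComponent:
    """One weighted multivariate normal: ``weight * N(mean, cov)``.

    Parameters
    ----------
    mean : array-like, shape (p,)
    cov : array-like, shape (p, p)
        Symmetric positive definite.  A condition number above
        ``MAX_CONDITION`` raises ``ValueError`` rather than being silently
        regularized.
    weight : float in (0, 1]
    """

    __slots__ = ("mean", "cov", "weight", "_chol", "_logdet")

    def __init__(self, mean, cov, weight):
        mean = np.asarray(mean, dtype=float).ravel()
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError(
                f"covariance shape {cov.shape} incompatible with mean of length {mean.size}"
            )
        if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        cov = 0.5 * (cov + cov.T)
        eig = np.linalg.eigvalsh(cov)
        if eig[0] <= 0.0:
            raise ValueError(f"covariance is not positive definite (min eigenvalue {eig[0]:.3g})")
        if eig[-1] / eig[0] > MAX_CONDITION:
            raise ValueError(
                f"covariance condition number {eig[-1] / eig[0]:.3g} exceeds {MAX_CONDITION:.0e}; "
                "the component is numerically singular"
            )
        weight = float(weight)
        if not 0.0 < weight <= 1.0:
            raise ValueError(f"weight must lie in (0, 1], got {weight}")
        self.mean = mean
        self.cov = cov
        self.weight = weight
        self._chol = None
        self._logdet = None

    @property
    def dim(self) -> int:
        return self.mean.size

    def _factor(self):
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.cov)
            self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))
        return self._chol, self._logdet

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        """Log N(x; mean, cov) for each row of ``x`` (shape (n, p))."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        chol, logdet = self._factor()
        dev = x - self.mean
        z = solve_triangular(chol, dev.T, lower=True)
        maha = np.sum(z * z, axis=0)
        return -0.5 * (self.dim * _LOG2PI + logdet + maha)

    def __repr__(self):
        return f"GaussianComponent(dim={self.dim}, weight={self.weight:.4g})"


class StructuredMixture:
    """A Gaussian mixture whose components are grouped into subpopulations.

    Parameters
    ----------
    components : sequence of GaussianComponent
        Weights must sum to one.
    partition : sequence of int, optional
        Subpopulation label for each component.  Defaults to the identity
        partition ``(1, 2, ..., J)``.  Labels may be any hashable ints; the
        subpopulation probability ``alpha_c`` is the sum of member component
        weights.
    """

    def __init__(self, components: Sequence[GaussianComponent], partition=None):
        components = tuple(components)
        if not components:
            raise ValueError("mixture needs at least one component")
        p = components[0].dim
        for comp in components:
            if comp.dim != p:
                raise ValueError("components have inconsistent dimensions")
        total = sum(comp.weight for comp in components)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"component weights sum to {total:.8f}, expected 1")
        if partition is None:
            partition = tuple(range(1, len(components) + 1))
        else:
            partition = tuple(int(c) for c in partition)
            if len(partition) != len(components):
                raise ValueError("partition length does not match number of components")
        self.components = components
        self.partition = partition

    # -- basic structure ---------------------------------------------------

    @property
    def dim(self) -> int:
        return self.components[0].dim

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> tuple[int, ...]:
        """Subpopulation labels, sorted."""
        return tuple(sorted(set(self.partition)))

    @property
    def n_subpopulations(self) -> int:
        return len(set(self.partition))

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def alpha(self, c) -> float:
        """Subpopulation probability alpha_c for label (or set of labels) c."""
        cset = self._label_set(c)
        return float(sum(comp.weight for comp, lab in zip(self.components, self.partition) if lab in cset))

    @property
    def alphas(self) -> dict[int, float]:
        return {lab: self.alpha(lab) for lab in self.labels}

    def _label_set(self, c) -> frozenset[int]:
        if isinstance(c, (int, np.integer)):
            cset = frozenset([int(c)])
        else:
            cset = frozenset(int(v) for v in c)
        if not cset:
            raise ValueError("empty label set")
        unknown = cset - set(self.partition)
        if unknown:
            raise ValueError(f"unknown subpopulation labels {sorted(unknown)}")
        return cset

    def member_indices(self, c) -> list[int]:
        cset = self._label_set(c)
        return [j for j, lab in enumerate(self.partition) if lab in cset]

    def complement_labels(self, c) -> frozenset[int]:
        comp = frozenset(self.partition) - self._label_set(c)
        if not comp:
            raise ValueError("no complement: the label set covers every subpopulation")
        return comp

    def relabeled(self, mapping: dict[int, int]) -> "StructuredMixture":
        """Return a copy with subpopulation labels mapped through ``mapping``."""
        return StructuredMixture(self.components, tuple(mapping.get(c, c) for c in self.partition))

    # -- log-density machinery --------------------------------------------

    def component_log_pdfs(self, x: np.ndarray) -> np.ndarray:
        """Matrix of per-Gaussian log pdfs, shape (n, J)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim:
            raise ValueError(f"data has {x.shape[1]} columns, mixture has dimension {self.dim}")
        return np.column_stack([comp.log_pdf(x) for comp in self.components])

    def log_density(self, x: np.ndarray) -> np.ndarray:
        lp = self.component_log_pdfs(x)
        return logsumexp(lp + np.log(self.weights), axis=1)

    def density(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(x))

    def subpop_log_density(self, x: np.ndarray, c) -> np.ndarray:
        """log f_c(x): the renormalized mixture of the members of c."""
        idx = self.member_indices(c)
        a = self.alpha(c)
        lp = np.column_stack([self.components[j].log_pdf(np.atleast_2d(x)) for j in idx])
        logw = np.log(np.array([self.components[j].weight for j in idx]) / a)
        return logsumexp(lp + logw, axis=1)

    def __repr__(self):
        return (
            f"StructuredMixture(J={self.n_components}, C={self.n_subpopulations}, p={self.dim})"
        )


class ClassifierSpec:
    """Threshold classifier for one subpopulation (or set of subpopulations).

    ``V_{c,tau}(x) = alpha_c f_c(x) - tau g(x)`` is positive exactly when the
    posterior classification probability alpha_c*(x) exceeds ``tau``.
    """

    def __init__(self, component, threshold: float):
        threshold = float(threshold)
        if not 0.0 < threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
        self.component = component
        self.threshold = threshold


def validate_subset(h: Iterable[int], p: int) -> np.ndarray:
    """Validate a 1-based variable subset; return 0-based index array.

    Order is preserved; duplicates and out-of-range indices are rejected.
    """
    idx = [int(v) for v in h]
    if not idx:
        raise ValueError("variable subset is empty")
    if len(set(idx)) != len(idx):
        raise ValueError(f"variable subset has repeated indices: {idx}")
    for v in idx:
        if not 1 <= v <= p:
            raise ValueError(f"variable index {v} out of range 1..{p}")
    return np.array(idx, dtype=int) - 1


def marginalize(mix: StructuredMixture, h: Iterable[int]) -> StructuredMixture:
    """Restrict the mixture to the variable subset ``h`` (1-based).

    The marginal of a Gaussian mixture is the mixture of marginals: each
    component keeps its weight and subpopulation label, with mean and
    covariance indexed down to ``h``.
    """
    idx = validate_subset(h, mix.dim)
    comps = [
        GaussianComponent(c.mean[idx], c.cov[np.ix_(idx, idx)], c.weight)
        for c in mix.components
    ]
    return StructuredMixture(comps, mix.partition)


def log_density(mix: StructuredMixture, x: np.ndarray) -> np.ndarray:
    return mix.log_density(x)


def density(mix: StructuredMixture, x: np.ndarray) -> np.ndarray:
    return mix.density(x)


def component_posterior(mix: StructuredMixture, x: np.ndarray, c) -> np.ndarray:
    """Posterior classification probability alpha_c*(x) = alpha_c f_c(x) / g(x)."""
    a = mix.alpha(c)
    log_num = np.log(a) + mix.subpop_log_density(x, c)
    return np.exp(log_num - mix.log_density(x))


def classifier_value(mix: StructuredMixture, spec: ClassifierSpec, x: np.ndarray) -> np.ndarray:
    """Evaluate V_{c,tau}(x) = alpha_c f_c(x) - tau g(x).

    Computed as ``g(x) * (alpha_c*(x) - tau)`` so that the sign is decided by
    the well-scaled posterior probability even where both densities underflow
    the linear scale.
    """
    a = mix.alpha(spec.component)
    logg = mix.log_density(x)
    log_num = np.log(a) + mix.subpop_log_density(x, spec.component)
    post = np.exp(log_num - logg)
    return np.exp(logg) * (post - spec.threshold)


def sample(mix: StructuredMixture, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` rows from the mixture; labels are subpopulation labels.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(mix.n_components, size=n, p=mix.weights)
    x = np.empty((n, mix.dim))
    for j, comp in enumerate(mix.components):
        rows = np.flatnonzero(which == j)
        if rows.size:
            x[rows] = rng.multivariate_normal(comp.mean, comp.cov, size=rows.size)
    labels = np.array([mix.partition[j] for j in which])
    return x, labels
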