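"""Synthetic Gaussian-mixture generators with known discriminative structure.

Includes the benchmark 8-dimensional, 4-component mixture used throughout the
tests (each component carries its own small set of informative variables) and
parametric scenario families with closed-form DIME values in one dimension,
so every downstream stage can be verified without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mixture import GaussianComponent, StructuredMixture, sample

__all__ = [
    "SyntheticSpec",
    "four_component_example",
    "generate",
    "make_scenario",
]

DEFAULT_SEED = 20150603


@dataclass
class SyntheticSpec:
    """A fully specified finite Gaussian mixture plus sampling settings."""

    weights: np.ndarray
    means: list[np.ndarray]
    covariances: list[np.ndarray]
    n: int = 6000
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = [np.asarray(m, dtype=float) for m in self.means]
        self.covariances = [np.asarray(c, dtype=float) for c in self.covariances]
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        if not (len(self.weights) == len(self.means) == len(self.covariances)):
            raise ValueError("weights, means and covariances must have equal length")

    @property
    def dim(self) -> int:
        return self.means[0].size

    def to_mixture(self) -> StructuredMixture:
        """One subpopulation per Gaussian component (identity partition)."""
        comps = [
            GaussianComponent(m, c, w)
            for m, c, w in zip(self.means, self.covariances, self.weights)
        ]
        return StructuredMixture(comps)


def four_component_example(n: int = 6000, seed: int = DEFAULT_SEED) -> SyntheticSpec:
    """The 8-dimensional, 4-component benchmark mixture.

    Component proportions (0.3, 0.3, 0.3, 0.1).  Component 1 is shifted on
    variables 1 and 8 (mean 7 and 5) and tight on variable 1 (variance 1);
    components 2 and 3 are shifted to 5 on the correlated variable blocks
    {1,2,3} and {4,5,6} respectively, with the printed 3x3 covariance blocks;
    component 4 sits at the origin with covariance 5I.  All remaining
    coordinates are independent with variance 5, so each of the first three
    components has its own small discriminative variable set (8 for component
    1, the {1,2,3} block for 2, the {4,5,6} block for 3) while variable 7 is
    irrelevant everywhere.
    """
    p = 8
    weights = np.array([0.3, 0.3, 0.3, 0.1])
    means = [
        np.array([7.0, 0, 0, 0, 0, 0, 0, 5.0]),
        np.array([5.0, 5.0, 5.0, 0, 0, 0, 0, 0]),
        np.array([0, 0, 0, 5.0, 5.0, 5.0, 0, 0]),
        np.zeros(p),
    ]
    cov1 = np.diag([1.0, 5, 5, 5, 5, 5, 5, 5])
    block2 = np.array([[1.5, 0.6, 0.9], [0.6, 1.0, 0.3], [0.9, 0.3, 0.8]])
    block3 = np.array([[1.0, 0.7, 0.9], [0.7, 1.5, 0.3], [0.9, 0.3, 2.0]])
    cov2 = 5.0 * np.eye(p)
    cov2[np.ix_([0, 1, 2], [0, 1, 2])] = block2
    cov3 = 5.0 * np.eye(p)
    cov3[np.ix_([3, 4, 5], [3, 4, 5])] = block3
    cov4 = 5.0 * np.eye(p)
    return SyntheticSpec(weights, means, [cov1, cov2, cov3, cov4], n=n, seed=seed)


def generate(spec: SyntheticSpec, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (data, true subpopulation labels) from the spec's mixture."""
    return sample(spec.to_mixture(), spec.n, spec.seed if seed is None else seed)


def make_scenario(kind: str, **params) -> SyntheticSpec:
    """Parametric test families with known discriminative structure.

    kind="overlap-grid": two equal-variance 1-D components with means 0 and
        ``separation`` and common variance ``variance`` (default 1), weights
        (``alpha``, 1-alpha).  Closed form: Delta_1 = exp(-d^2 / (4 v)).
    kind="irrelevant-variable": appends to a base two-component 1-D model an
        extra dimension that is independent with an identical distribution in
        both components, so it carries no discriminative information.
    kind="nested-information": diagonal p-variable model in which variable k
        separates the two components by ``base_sep / 2**(k-1)``, giving a
        strictly nested ordering of informative variables.
    """
    if kind == "overlap-grid":
        d = float(params.get("separation", 3.0))
        v = float(params.get("variance", 1.0))
        a = float(params.get("alpha", 0.5))
        return SyntheticSpec(
            weights=[a, 1.0 - a],
            means=[np.array([0.0]), np.array([d])],
            covariances=[np.array([[v]]), np.array([[v]])],
            n=int(params.get("n", 2000)),
            seed=int(params.get("seed", DEFAULT_SEED)),
        )
    if kind == "irrelevant-variable":
        base = make_scenario("overlap-grid", **params)
        v_extra = float(params.get("extra_variance", 1.0))
        means = [np.append(m, 0.0) for m in base.means]
        covs = []
        for c in base.covariances:
            cc = np.zeros((2, 2))
            cc[0, 0] = c[0, 0]
            cc[1, 1] = v_extra
            covs.append(cc)
        return SyntheticSpec(base.weights, means, covs, n=base.n, seed=base.seed)
    if kind == "nested-information":
        p = int(params.get("p", 4))
        base_sep = float(params.get("base_sep", 8.0))
        a = float(params.get("alpha", 0.5))
        seps = np.array([base_sep / 2**k for k in range(p)])
        return SyntheticSpec(
            weights=[a, 1.0 - a],
            means=[np.zeros(p), seps],
            covariances=[np.eye(p), np.eye(p)],
            n=int(params.get("n", 2000)),
            seed=int(params.get("seed", DEFAULT_SEED)),
        )
    raise ValueError(f"unknown scenario kind {kind!r}")
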