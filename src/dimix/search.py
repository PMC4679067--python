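"""Variable-subset search ranked by discriminative accuracy.

Two strategies: exhaustive enumeration of all non-empty subsets (feasible for
small p) and greedy forward selection that at each step adds the variable
giving the largest aggregate accuracy A_c.  The forward trace records the two
conventional stopping markers without actually truncating the search by
default: the dagger step (first step whose accuracy increment falls below
``stop_increment``, default 0.01) and the star step (first step reaching the
absolute accuracy ``absolute_target``, default 0.95).

When handed a set of aligned posterior draws instead of a single mixture, the
search criterion is the posterior mean of A_c per candidate subset
(per-draw searches would be combinatorially unstable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dime import DimeSummary, dime_summary, posterior_summary
from .mixture import StructuredMixture

__all__ = [
    "SearchTrace",
    "exhaustive_search",
    "best_per_size",
    "forward_search",
    "fixed_subset_report",
    "trace_table",
]

EXHAUSTIVE_P_LIMIT = 20


@dataclass
class SearchTrace:
    """Forward-search result for one component.

    ``order[k]`` is the 1-based variable entered at step k+1; ``summaries[k]``
    the DIME quintet for the first k+1 variables.  ``dagger_step`` and
    ``star_step`` are 1-based step numbers (or None).
    """

    component: object
    order: list[int] = field(default_factory=list)
    summaries: list[DimeSummary] = field(default_factory=list)
    dagger_step: Optional[int] = None
    star_step: Optional[int] = None

    @property
    def accuracies(self) -> list[float]:
        return [s.accuracy for s in self.summaries]


def _is_draws(model) -> bool:
    return not isinstance(model, StructuredMixture)


def _summarize(model, c, h) -> DimeSummary:
    """DIME quintet for (c, h): plug-in on a mixture, posterior mean on draws."""
    if _is_draws(model):
        return posterior_summary(model, c, h).mean
    return dime_summary(model, c, h)


def _dim(model) -> int:
    if _is_draws(model):
        return next(iter(model)).dim
    return model.dim


def exhaustive_search(model, c, max_size: Optional[int] = None) -> pd.DataFrame:
    """Evaluate the DIME quintet on every non-empty subset of size <= max_size.

    Rows are ordered by subset size then lexicographically.  Raises for
    p > 20 without an explicit ``max_size`` (2^p subsets is infeasible).
    """
    p = _dim(model)
    if max_size is None:
        if p > EXHAUSTIVE_P_LIMIT:
            raise ValueError(
                f"p={p} variables means 2^{p} subsets; pass max_size to bound the "
                "enumeration or use forward_search"
            )
        max_size = p
    if max_size < 1 or max_size > p:
        raise ValueError(f"max_size must lie in 1..{p}")
    rows = []
    for size in range(1, max_size + 1):
        for subset in combinations(range(1, p + 1), size):
            s = _summarize(model, c, subset)
            row = s.as_dict()
            row["size"] = size
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[
        ["component", "subset", "size", "accuracy", "tau_plus", "tau_minus", "delta_c", "delta_neg_c", "alpha_c"]
    ]


def best_per_size(table: pd.DataFrame) -> pd.DataFrame:
    """Most accurate subset at each size, from an exhaustive_search table."""
    idx = table.groupby("size")["accuracy"].idxmax()
    return table.loc[idx].reset_index(drop=True)


def forward_search(
    model,
    c,
    stop_increment: float = 0.01,
    absolute_target: float = 0.95,
    run_to_completion: bool = True,
) -> SearchTrace:
    """Greedy forward selection maximizing aggregate accuracy A_c.

    At each step the variable with the largest A_c(h + {j}) enters; ties go to
    the smallest variable index.  With ``run_to_completion`` (default) all p
    variables are ranked and the dagger/star markers are merely recorded;
    otherwise the search stops at the dagger step.
    """
    p = _dim(model)
    trace = SearchTrace(component=c)
    current: list[int] = []
    prev_acc = None
    for step in range(1, p + 1):
        candidates = [j for j in range(1, p + 1) if j not in current]
        best_j, best_s = None, None
        for j in candidates:  # ascending order => ties keep the smallest index
            s = _summarize(model, c, tuple(current + [j]))
            if best_s is None or s.accuracy > best_s.accuracy + 1e-15:
                best_j, best_s = j, s
        current.append(best_j)
        trace.order.append(best_j)
        trace.summaries.append(best_s)
        increment = best_s.accuracy - prev_acc if prev_acc is not None else None
        if (
            trace.dagger_step is None
            and increment is not None
            and increment < stop_increment
        ):
            trace.dagger_step = step
        if trace.star_step is None and best_s.accuracy >= absolute_target:
            trace.star_step = step
        prev_acc = best_s.accuracy
        if not run_to_completion and trace.dagger_step is not None:
            break
    return trace


def fixed_subset_report(model, c, h=None, drop: Optional[int] = None) -> DimeSummary:
    """DIME quintet for a named subset, or for "all variables minus one".

    ``drop=j`` evaluates the complement subset {1..p} \\ {j}, the usual
    question of how much accuracy is lost when one variable is deleted.
    """
    p = _dim(model)
    if drop is not None:
        if h is not None:
            raise ValueError("pass either h or drop, not both")
        h = tuple(j for j in range(1, p + 1) if j != int(drop))
    if h is None:
        h = tuple(range(1, p + 1))
    return _summarize(model, c, tuple(h))


def trace_table(trace: SearchTrace) -> pd.DataFrame:
    """Wide report for a forward trace: one column per step.

    Rows are Variable (with the star/dagger markers attached), the accuracy
    A_c, the thresholds tau_c+/tau_c-, and the DIME pair.
    """
    steps = list(range(1, len(trace.order) + 1))
    var_row = []
    for k, j in zip(steps, trace.order):
        label = str(j)
        if trace.star_step == k:
            label += "*"
        if trace.dagger_step == k:
            label += "†"
        var_row.append(label)
    data = {
        "Variable": var_row,
        "A_c": [round(s.accuracy, 3) for s in trace.summaries],
        "tau_c+": [round(s.tau_plus, 3) for s in trace.summaries],
        "tau_c-": [round(s.tau_minus, 3) for s in trace.summaries],
        "Delta_c": [round(s.delta_c, 3) for s in trace.summaries],
        "Delta_-c": [round(s.delta_neg_c, 3) for s in trace.summaries],
    }
    df = pd.DataFrame(data, index=steps).T
    df.columns = [f"step{k}" for k in steps]
    return df
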