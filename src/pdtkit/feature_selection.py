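"""Wrapper feature selection by best-first search over feature subsets.

The wrapper approach scores a candidate subset by the cross-validated
accuracy of the very classifier that will use it, so the selection criterion
is "usefulness to this classifier" rather than any filter statistic.  The
subset space is traversed best-first: an open list ordered by merit, each
expansion generating the single-feature additions (and deletions, in the
default bidirectional mode) of the most promising unexpanded node.  The
search stops after ``patience`` consecutive non-improving expansions, when
the open list is exhausted, or when the incumbent reaches merit 1.0 (which
no expansion can beat).

Merit is LOOCV accuracy by default.  For the random forest the default is
its out-of-bag accuracy — the ensemble's built-in leave-out estimate — which
costs one fit per subset instead of n; exact LOOCV remains available with
``merit="loocv"``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import POSITIVE, ClassifierSpec, LabeledDataset, RFClassifier
from .errors import ContractError, ParameterError

__all__ = [
    "FeatureSubset",
    "SearchTrace",
    "evaluate_subset",
    "best_first_select",
    "exhaustive_select",
    "selection_report",
]


@dataclass(frozen=True)
class FeatureSubset:
    """A sorted tuple of feature-column indices with its wrapper merit."""

    indices: tuple[int, ...]
    merit: float
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.indices))) != self.indices:
            raise ContractError("indices must be unique and sorted")
        if not (0.0 <= self.merit <= 1.0):
            raise ContractError(f"merit must lie in [0, 1], got {self.merit}")


@dataclass
class SearchTrace:
    """Audit trail of a best-first run."""

    visited: dict[tuple[int, ...], float] = field(default_factory=dict)
    expansions: list[tuple[int, ...]] = field(default_factory=list)
    stopping_reason: str = ""

    @property
    def n_evaluated(self) -> int:
        return len(self.visited)


def _majority_proportion(data: LabeledDataset) -> float:
    pos = float(np.mean(data.y == POSITIVE))
    return max(pos, 1.0 - pos)


def evaluate_subset(
    data: LabeledDataset,
    subset: Sequence[int],
    spec: ClassifierSpec,
    *,
    merit: str = "auto",
) -> float:
    """Wrapper merit of one feature subset.

    The empty subset gets the majority-class proportion (the no-information
    baseline) rather than raising.  ``merit`` is ``"loocv"``, ``"oob"``
    (random forest only) or ``"auto"`` (oob for rf, loocv otherwise).
    """
    cols = tuple(sorted(set(subset)))
    if len(cols) == 0:
        return _majority_proportion(data)
    if merit == "auto":
        merit = "oob" if spec.family == "rf" else "loocv"
    sub = data.subset(cols)
    if merit == "loocv":
        from .evaluation import loocv

        folds = loocv(sub, spec)
        return float(np.mean([f.predicted == f.actual for f in folds]))
    if merit == "oob":
        if spec.family != "rf":
            raise ParameterError("merit='oob' is only defined for the random forest")
        model = RFClassifier(n_trees=spec.n_trees, seed=spec.seed)
        model.fit(sub, oob=True)
        return model.oob_accuracy
    raise ParameterError(f"unknown merit method {merit!r}")


def _order_key(merit: float, node: tuple[int, ...]):
    # higher merit first; ties -> smaller subset, then lexicographic
    return (-merit, len(node), node)


def best_first_select(
    data: LabeledDataset,
    spec: ClassifierSpec,
    *,
    patience: int = 5,
    direction: str = "bidirectional",
    merit: str = "auto",
    max_evaluations: int | None = None,
) -> tuple[FeatureSubset, SearchTrace]:
    """Best-first wrapper search starting from the empty subset.

    Returns the best subset found (possibly empty when no feature beats the
    majority baseline) and the search trace.  Merit ties are broken toward
    the smaller, then lexicographically earlier subset.  Every subset is
    evaluated at most once.
    """
    if data.m < 1:
        raise ParameterError("need at least one feature")
    if direction not in ("bidirectional", "forward"):
        raise ParameterError(f"direction must be bidirectional|forward, got {direction!r}")
    if patience < 1:
        raise ParameterError(f"patience must be >= 1, got {patience}")

    trace = SearchTrace()

    def evaluate(node: tuple[int, ...]) -> float:
        val = evaluate_subset(data, node, spec, merit=merit)
        trace.visited[node] = val
        return val

    empty: tuple[int, ...] = ()
    best_node, best_merit = empty, evaluate(empty)
    open_heap: list = []
    heapq.heappush(open_heap, (*_order_key(best_merit, empty), empty))
    stalls = 0
    eps = 1e-12

    while open_heap:
        if best_merit >= 1.0 - eps:
            trace.stopping_reason = "perfect merit"
            break
        if stalls >= patience:
            trace.stopping_reason = f"{patience} non-improving expansions"
            break
        if max_evaluations is not None and trace.n_evaluated >= max_evaluations:
            trace.stopping_reason = "evaluation budget exhausted"
            break
        *_, node = heapq.heappop(open_heap)
        trace.expansions.append(node)
        improved = False
        in_node = set(node)
        neighbors = [tuple(sorted(in_node | {j})) for j in range(data.m) if j not in in_node]
        if direction == "bidirectional":
            neighbors += [tuple(sorted(in_node - {j})) for j in node]
        for nb in neighbors:
            if nb in trace.visited:
                continue
            val = evaluate(nb)
            heapq.heappush(open_heap, (*_order_key(val, nb), nb))
            if val > best_merit + eps:
                best_node, best_merit = nb, val
                improved = True
            elif abs(val - best_merit) <= eps and _order_key(val, nb) < _order_key(
                best_merit, best_node
            ):
                best_node = nb  # tie-break only; does not reset patience
        stalls = 0 if improved else stalls + 1
    else:
        trace.stopping_reason = "search space exhausted"
    if not trace.stopping_reason:
        trace.stopping_reason = "search space exhausted"

    chosen = FeatureSubset(
        indices=best_node,
        merit=best_merit,
        names=tuple(data.feature_names[j] for j in best_node),
    )
    return chosen, trace


def exhaustive_select(
    data: LabeledDataset, spec: ClassifierSpec, *, merit: str = "auto"
) -> FeatureSubset:
    """Brute-force optimum over all 2^m subsets (oracle; small m only)."""
    if data.m > 16:
        raise ParameterError("exhaustive search is limited to m <= 16 features")
    best: FeatureSubset | None = None
    for mask in range(2**data.m):
        node = tuple(j for j in range(data.m) if mask >> j & 1)
        val = evaluate_subset(data, node, spec, merit=merit)
        if best is None or _order_key(val, node) < _order_key(best.merit, best.indices):
            best = FeatureSubset(
                indices=node,
                merit=val,
                names=tuple(data.feature_names[j] for j in node),
            )
    assert best is not None
    return best


def selection_report(selections: dict[str, FeatureSubset]) -> pd.DataFrame:
    """Summary of which features each classifier selected.

    One row per feature selected by at least one classifier; one column per
    classifier ("X" marks selection) plus the count of classifiers that
    selected the feature.
    """
    if not selections:
        raise ContractError("no selections to report")
    names: list[str] = []
    for subset in selections.values():
        for name in subset.names:
            if name not in names:
                names.append(name)
    rows = []
    for name in names:
        row: dict[str, object] = {"feature": name}
        count = 0
        for clf, subset in selections.items():
            hit = name in subset.names
            row[clf] = "X" if hit else ""
            count += hit
        row["n_classifiers"] = count
        rows.append(row)
    return pd.DataFrame(rows, columns=["feature", *selections.keys(), "n_classifiers"])
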