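"""Rough-set machinery: indiscernibility, approximations, dependency degree,
and three reduct-search strategies (greedy dependency, entropy, discernibility
matrix with greedy set cover)."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_ENTROPY_TOL = 1e-10


@dataclass
class DecisionTable:
    """Discrete decision system: objects x condition attributes plus a decision.

    ``cells[i, j]`` is the integer code of attribute ``j`` on object ``i``.
    """

    cells: np.ndarray
    decision: np.ndarray
    attribute_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.decision = np.asarray(self.decision, dtype=np.int64)
        if self.cells.ndim != 2:
            raise ValueError("cells must be 2-D")
        if self.decision.shape != (self.cells.shape[0],):
            raise ValueError("decision length must equal object count")
        if self.attribute_names is not None and len(self.attribute_names) != self.cells.shape[1]:
            raise ValueError("attribute_names length must equal attribute count")

    @property
    def n_objects(self) -> int:
        return self.cells.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.cells.shape[1]

    @property
    def attributes(self) -> list[int]:
        return list(range(self.n_attributes))


@dataclass(frozen=True)
class Partition:
    """Disjoint blocks of object indices covering the universe."""

    blocks: tuple[frozenset[int], ...]

    def __iter__(self):
        return iter(self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class ReductResult:
    """Attribute subset preserving the full table's dependency degree."""

    selected: list[int]
    dependency_trace: list[float]
    gamma_full: float
    reduction_rate: float
    method: str = ""
    selected_names: list[str] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "selected": self.selected,
                "selected_names": self.selected_names,
                "trace": self.dependency_trace,
                "gamma_full": self.gamma_full,
                "reduction_rate_pct": self.reduction_rate,
            },
            indent=2,
        )


@dataclass
class DiscernibilityMatrix:
    """For each decision-discordant object pair, the attributes that tell
    the pair apart.  Pairs indiscernible on every attribute (inconsistent
    table) carry an empty entry."""

    entries: dict[tuple[int, int], frozenset[int]] = field(default_factory=dict)

    @property
    def inconsistent_pairs(self) -> list[tuple[int, int]]:
        return [p for p, attrs in self.entries.items() if not attrs]


# ---------------------------------------------------------------------------
# discretization

def discretize(values: np.ndarray, n_bins: int = 3, method: str = "equal-frequency",
               attribute_names: Sequence[str] | None = None,
               decision: np.ndarray | None = None,
               edges: list[np.ndarray] | None = None) -> DecisionTable | tuple[DecisionTable, list[np.ndarray]]:
    """Map continuous columns to integer bin codes.

    ``method`` is ``equal-frequency`` (quantile edges) or ``equal-width``.
    Codes are monotone in the raw values.  Constant columns collapse to a
    single code 0.  When ``edges`` is given (from a previous call on
    training data) those edges are applied instead of being re-fit.

    Returns the table, and the fitted edges when ``decision`` is provided
    alongside a fresh fit (so CV callers can re-apply them).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if method not in ("equal-frequency", "equal-width"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, m = x.shape
    codes = np.zeros((n, m), dtype=np.int64)
    fitted: list[np.ndarray] = []
    for j in range(m):
        col = x[:, j]
        if edges is not None:
            cut = edges[j]
        elif col.min() == col.max():
            cut = np.array([])
        elif method == "equal-frequency":
            qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
            cut = np.unique(qs)
        else:
            cut = np.linspace(col.min(), col.max(), n_bins + 1)[1:-1]
        fitted.append(cut)
        codes[:, j] = np.searchsorted(cut, col, side="left") if cut.size else 0
    names = list(attribute_names) if attribute_names is not None else None
    if decision is None:
        table = DecisionTable(cells=codes, decision=np.zeros(n, dtype=np.int64),
                              attribute_names=names)
        return table, fitted
    table = DecisionTable(cells=codes, decision=np.asarray(decision),
                          attribute_names=names)
    return table, fitted


# ---------------------------------------------------------------------------
# core rough-set operations

def indiscernibility_partition(table: DecisionTable, B: Iterable[int]) -> Partition:
    """Partition objects into blocks agreeing on every attribute in ``B``."""
    attrs = sorted(set(B))
    if not attrs:
        raise ValueError("attribute subset must be nonempty")
    if not set(attrs) <= set(table.attributes):
        raise ValueError("attribute subset not contained in the table")
    groups: dict[tuple, list[int]] = {}
    sub = table.cells[:, attrs]
    for i in range(table.n_objects):
        groups.setdefault(tuple(sub[i]), []).append(i)
    return Partition(blocks=tuple(frozenset(v) for v in groups.values()))


def lower_upper_approximation(partition: Partition, X: Iterable[int]) -> tuple[frozenset[int], frozenset[int]]:
    """Blockwise lower/upper approximation of a target object set."""
    target = frozenset(X)
    lower: set[int] = set()
    upper: set[int] = set()
    for block in partition:
        if block & target:
            upper |= block
            if block <= target:
                lower |= block
    return frozenset(lower), frozenset(upper)


def positive_region(table: DecisionTable, P: Iterable[int]) -> frozenset[int]:
    """Objects whose P-block is pure in the decision."""
    partition = indiscernibility_partition(table, P)
    pos: set[int] = set()
    for block in partition:
        decisions = {int(table.decision[i]) for i in block}
        if len(decisions) == 1:
            pos |= block
    return frozenset(pos)


def dependency_degree(table: DecisionTable, P: Iterable[int]) -> float:
    """gamma_P(d) = |POS_P(d)| / |U|."""
    if table.n_objects == 0:
        raise ValueError("empty table")
    return len(positive_region(table, P)) / table.n_objects


def decision_entropy(table: DecisionTable) -> float:
    """Marginal entropy of the decision, base 2."""
    _, counts = np.unique(table.decision, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(table: DecisionTable, P: Iterable[int]) -> float:
    """H(d | P) = sum over P-blocks of (|block|/|U|) * H(d within block)."""
    partition = indiscernibility_partition(table, P)
    n = table.n_objects
    h = 0.0
    for block in partition:
        dec = table.decision[list(block)]
        _, counts = np.unique(dec, return_counts=True)
        p = counts / counts.sum()
        h += (len(block) / n) * float(-(p * np.log2(p)).sum())
    return max(h, 0.0)


# ---------------------------------------------------------------------------
# reduct searches

def gamma_of(table: DecisionTable, subset: Iterable[int]) -> float:
    """Dependency degree extended to the empty subset: the trivial one-block
    partition is pure iff the decision is constant."""
    subset = list(subset)
    if subset:
        return dependency_degree(table, subset)
    return 1.0 if len(np.unique(table.decision)) == 1 else 0.0


def _minimality_pass(table: DecisionTable, selected: list[int], gamma_full: float) -> list[int]:
    # Backward elimination: drop any attribute whose removal keeps gamma intact.
    result = list(selected)
    changed = True
    while changed:
        changed = False
        for a in list(result):
            trial = [b for b in result if b != a]
            if gamma_of(table, trial) == gamma_full:
                result.remove(a)
                changed = True
    return result


def _finalize(table: DecisionTable, selected: list[int], trace: list[float],
              gamma_full: float, method: str) -> ReductResult:
    rate = 100.0 * (1.0 - len(selected) / table.n_attributes) if table.n_attributes else 0.0
    names = None
    if table.attribute_names is not None:
        names = [table.attribute_names[a] for a in selected]
    return ReductResult(selected=selected, dependency_trace=trace,
                        gamma_full=gamma_full, reduction_rate=rate,
                        method=method, selected_names=names)


def quick_reduct(table: DecisionTable) -> ReductResult:
    """Greedy forward selection on the dependency degree, then a backward
    minimality pass.  Ties break toward the lowest attribute index."""
    all_attrs = table.attributes
    gamma_full = dependency_degree(table, all_attrs)
    selected: list[int] = []
    trace: list[float] = []
    current = gamma_of(table, [])
    while current < gamma_full:
        best_a, best_gamma = None, current
        for a in all_attrs:
            if a in selected:
                continue
            g = dependency_degree(table, selected + [a])
            if g > best_gamma:
                best_a, best_gamma = a, g
        if best_a is None:
            # no single attribute helps (e.g. parity interactions): take the
            # lowest-index leftover so the loop still reaches gamma_full;
            # the minimality pass prunes any excess afterwards
            best_a = min(a for a in all_attrs if a not in selected)
            best_gamma = dependency_degree(table, selected + [best_a])
        selected.append(best_a)
        current = best_gamma
        trace.append(current)
    selected = _minimality_pass(table, selected, gamma_full) if selected else selected
    return _finalize(table, selected, trace, gamma_full, "qrfs")


def entropy_reduct(table: DecisionTable) -> ReductResult:
    """Greedy forward selection minimising conditional entropy H(d|R),
    stopping at H(d|A); backward minimality pass on the dependency degree."""
    all_attrs = table.attributes
    h_full = conditional_entropy(table, all_attrs)
    gamma_full = dependency_degree(table, all_attrs)
    selected: list[int] = []
    trace: list[float] = []
    current = decision_entropy(table)
    while current - h_full > _ENTROPY_TOL:
        best_a, best_h = None, current
        for a in all_attrs:
            if a in selected:
                continue
            h = conditional_entropy(table, selected + [a])
            if h < best_h - _ENTROPY_TOL:
                best_a, best_h = a, h
        if best_a is None:
            remaining = [a for a in all_attrs if a not in selected]
            if not remaining:
                break
            # same stall fallback as the dependency-based search
            best_a = min(remaining)
            best_h = conditional_entropy(table, selected + [best_a])
        selected.append(best_a)
        current = best_h
        trace.append(current)
    if not selected and decision_entropy(table) > 0:
        warnings.warn("no informative attributes; empty selection")
    selected = _minimality_pass(table, selected, gamma_full) if selected else selected
    return _finalize(table, selected, trace, gamma_full, "ebfs")


def discernibility_matrix(table: DecisionTable) -> DiscernibilityMatrix:
    """Attribute-difference sets for every pair of objects with differing
    decisions."""
    entries: dict[tuple[int, int], frozenset[int]] = {}
    cells, dec = table.cells, table.decision
    for i in range(table.n_objects):
        for j in range(i + 1, table.n_objects):
            if dec[i] == dec[j]:
                continue
            differing = frozenset(np.flatnonzero(cells[i] != cells[j]).tolist())
            entries[(i, j)] = differing
    return DiscernibilityMatrix(entries=entries)


def discernibility_reduct(table: DecisionTable) -> ReductResult:
    """Greedy set cover (most-frequent attribute first) over the nonempty
    discernibility-matrix entries, then the backward minimality pass.

    Pairs with empty entries (table inconsistency) are excluded from the
    cover with a warning.
    """
    matrix = discernibility_matrix(table)
    if matrix.inconsistent_pairs:
        warnings.warn(
            f"{len(matrix.inconsistent_pairs)} indiscernible pair(s) with differing "
            "decisions excluded from the cover"
        )
    uncovered = [attrs for attrs in matrix.entries.values() if attrs]
    gamma_full = dependency_degree(table, table.attributes) if table.n_attributes else 0.0
    selected: list[int] = []
    trace: list[float] = []
    while uncovered:
        counts = np.zeros(table.n_attributes, dtype=np.int64)
        for attrs in uncovered:
            for a in attrs:
                counts[a] += 1
        best_a = int(np.argmax(counts))  # argmax takes the lowest index on ties
        selected.append(best_a)
        uncovered = [attrs for attrs in uncovered if best_a not in attrs]
        trace.append(dependency_degree(table, selected))
    selected = _minimality_pass(table, selected, gamma_full) if selected else selected
    return _finalize(table, selected, trace, gamma_full, "dmfs")


REDUCT_METHODS = {
    "qrfs": quick_reduct,
    "ebfs": entropy_reduct,
    "dmfs": discernibility_reduct,
}
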