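import numpy as np
import pytest

from toxbalance.data import DESCRIPTOR_NAMES, DescriptorTable
from toxbalance.roughset import DecisionTable
from toxbalance.sampling import SamplePool
from toxbalance.synthetic import GeneratorSpec, generate


@pytest.fixture
def small_table() -> DescriptorTable:
    rng = np.random.default_rng(42)
    values = rng.normal(size=(4, 31))
    return DescriptorTable(
        sample_ids=[f"s{i}" for i in range(4)],
        feature_names=list(DESCRIPTOR_NAMES),
        values=values,
        labels={"mutagenic": np.array([1, 0, 0, 1])},
    )


@pytest.fixture
def toy_decision_table() -> DecisionTable:
    # 8 objects, 4 attributes; attribute 0 alone does not determine the
    # decision, {0, 1} does
    cells = np.array([
        [0, 0, 1, 0],
        [0, 1, 1, 1],
        [1, 0, 0, 0],
        [1, 1, 0, 1],
        [0, 0, 0, 1],
        [0, 1, 1, 0],
        [1, 0, 1, 1],
        [1, 1, 0, 0],
    ])
    decision = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    return DecisionTable(cells=cells, decision=decision)


@pytest.fixture
def overlap_pool() -> SamplePool:
    """Imbalanced 2-class pool with deliberate class overlap."""
    _, pool = generate(GeneratorSpec(n_minority=30, n_majority=120,
                                     n_features=5, separation=1.0,
                                     overlap_fraction=0.4, seed=7))
    return pool


@pytest.fixture
def separated_pool() -> SamplePool:
    _, pool = generate(GeneratorSpec(n_minority=20, n_majority=60,
                                     n_features=4, separation=12.0,
                                     overlap_fraction=0.0, seed=5))
    return pool


def brute_force_reducts(table: DecisionTable):
    """All minimal attribute subsets preserving the full dependency degree,
    by exhaustive enumeration (oracle)."""
    from itertools import combinations

    from toxbalance.roughset import dependency_degree, gamma_of

    attrs = table.attributes
    gamma_full = dependency_degree(table, attrs)
    preserving = []
    if gamma_of(table, []) == gamma_full:
        preserving.append(frozenset())
    for r in range(1, len(attrs) + 1):
        for subset in combinations(attrs, r):
            if dependency_degree(table, list(subset)) == gamma_full:
                preserving.append(frozenset(subset))
    reducts = [s for s in preserving
               if not any(t < s for t in preserving)]
    return gamma_full, reducts


def is_valid_reduct(table: DecisionTable, selected) -> bool:
    """Reduct check independent of the search path: gamma preserved and no
    single attribute removable."""
    from toxbalance.roughset import dependency_degree, gamma_of

    gamma_full = dependency_degree(table, table.attributes)
    sel = list(selected)
    if not sel:
        return gamma_of(table, []) == gamma_full
    if dependency_degree(table, sel) != gamma_full:
        return False
    return all(
        gamma_of(table, [b for b in sel if b != a]) < gamma_full
        for a in sel
    )


def brute_force_tomek_links(pool: SamplePool):
    """O(n^3) direct transcription of the Tomek-link definition (oracle)."""
    from toxbalance.sampling import standardize

    z, _, _ = standardize(pool.features)
    n = z.shape[0]
    d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    links = []
    for i in range(n):
        for j in range(i + 1, n):
            if pool.labels[i] == pool.labels[j]:
                continue
            dij = d[i, j]
            blocked = any(
                e not in (i, j) and (d[i, e] < dij or d[j, e] < dij)
                for e in range(n)
            )
            if not blocked:
                links.append((i, j))
    return links


def auc_pairwise_oracle(labels, scores) -> float:
    """AUC as the probability a random positive outranks a random negative,
    ties counted half (oracle)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
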