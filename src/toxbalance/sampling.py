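"""Class rebalancing: random under/over-sampling, SMOTE, and iterative
Danger-based sampling with Tomek-link cleaning.

All neighbor and link computations use Euclidean distance on z-score
standardized features; the standardization is fit once on the pool being
resampled (descriptors live on wildly different scales, so unstandardized
distances would be dominated by the largest-magnitude column).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


class DegeneratePoolError(ValueError):
    """Raised when an operation needs both classes and one is empty."""


@dataclass
class SamplePool:
    """Feature matrix + binary labels with minority/majority bookkeeping.

    Minority and majority roles are derived from class counts, never from
    label polarity; on an exact tie the positive class (label 1) is treated
    as the minority.
    """

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must match feature rows")
        if not set(np.unique(self.labels).tolist()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def minority_label(self) -> int:
        n_pos = int(np.sum(self.labels == 1))
        n_neg = self.n_samples - n_pos
        return 1 if n_pos <= n_neg else 0

    @property
    def majority_label(self) -> int:
        return 1 - self.minority_label

    @property
    def minority_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == self.minority_label)

    @property
    def majority_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == self.majority_label)

    @property
    def n_minority(self) -> int:
        return self.minority_indices.size

    @property
    def n_majority(self) -> int:
        return self.majority_indices.size

    def require_both_classes(self) -> None:
        if self.n_minority == 0 or self.n_majority == 0:
            raise DegeneratePoolError("pool must contain both classes")


@dataclass(frozen=True)
class TomekLink:
    """Cross-class pair of mutually nearest neighbors."""

    i: int
    j: int
    distance: float


@dataclass
class ItsTrace:
    """Per-iteration accounting of the iterative sampling + cleaning run."""

    iterations: list[dict] = field(default_factory=list)
    cleaning: dict = field(default_factory=dict)
    forced_balance: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {"iterations": self.iterations, "cleaning": self.cleaning,
             "forced_balance": self.forced_balance},
            indent=2,
        )


def standardize(features: np.ndarray, mean: np.ndarray | None = None,
                std: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each column; constant columns get unit scale."""
    x = np.asarray(features, dtype=float)
    if mean is None:
        mean = x.mean(axis=0)
    if std is None:
        std = x.std(axis=0)
        std = np.where(std == 0, 1.0, std)
    return (x - mean) / std, mean, std


# ---------------------------------------------------------------------------
# random sampling

def random_undersample(pool: SamplePool, seed: int = 0) -> SamplePool:
    """Shrink the majority class to the minority size by uniform sampling
    without replacement; the minority class is untouched."""
    pool.require_both_classes()
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(pool.majority_indices, size=pool.n_minority, replace=False)
    keep = np.sort(np.concatenate([pool.minority_indices, keep_maj]))
    return SamplePool(features=pool.features[keep], labels=pool.labels[keep])


def random_oversample(pool: SamplePool, seed: int = 0) -> SamplePool:
    """Replicate minority samples with replacement until the classes match;
    the majority class is untouched."""
    pool.require_both_classes()
    rng = np.random.default_rng(seed)
    deficit = pool.n_majority - pool.n_minority
    extra = rng.choice(pool.minority_indices, size=deficit, replace=True)
    keep = np.concatenate([np.arange(pool.n_samples), extra])
    return SamplePool(features=pool.features[keep], labels=pool.labels[keep])


@dataclass(frozen=True)
class SmoteRecord:
    """Provenance of one synthetic sample: x_new = base + delta*(neighbor - base)."""

    base_index: int
    neighbor_index: int
    delta: float


def smote(pool: SamplePool, k_neighbors: int = 5, seed: int = 0,
          return_records: bool = False):
    """Synthesize minority samples by interpolation between minority
    neighbors until the classes are equal.

    Each synthetic point is ``x_i + delta * (x_hat - x_i)`` with ``x_hat``
    one of the ``k_neighbors`` nearest minority samples to ``x_i`` and
    ``delta`` drawn uniformly on [0, 1] once per synthetic sample.  Base
    samples are cycled round-robin so every minority sample contributes
    near-equally.  With a single minority sample, falls back to replication
    with a warning.
    """
    pool.require_both_classes()
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)
    deficit = pool.n_majority - pool.n_minority
    if deficit == 0:
        return (SamplePool(pool.features.copy(), pool.labels.copy()), []) if return_records \
            else SamplePool(pool.features.copy(), pool.labels.copy())

    min_idx = pool.minority_indices
    if min_idx.size < 2:
        warnings.warn("single minority sample: falling back to replication")
        out = random_oversample(pool, seed=seed)
        return (out, []) if return_records else out

    z, _, _ = standardize(pool.features)
    z_min = z[min_idx]
    dist = cdist(z_min, z_min)
    np.fill_diagonal(dist, np.inf)
    k_eff = min(k_neighbors, min_idx.size - 1)
    neighbor_order = np.argsort(dist, axis=1)[:, :k_eff]

    synth = np.empty((deficit, pool.features.shape[1]))
    records: list[SmoteRecord] = []
    for t in range(deficit):
        b = t % min_idx.size
        nb = neighbor_order[b, rng.integers(0, k_eff)]
        delta = float(rng.uniform(0.0, 1.0))
        base = pool.features[min_idx[b]]
        neigh = pool.features[min_idx[nb]]
        synth[t] = base + delta * (neigh - base)
        records.append(SmoteRecord(int(min_idx[b]), int(min_idx[nb]), delta))

    features = np.vstack([pool.features, synth])
    labels = np.concatenate([pool.labels,
                             np.full(deficit, pool.minority_label, dtype=np.int64)])
    out = SamplePool(features=features, labels=labels)
    return (out, records) if return_records else out


# ---------------------------------------------------------------------------
# Danger detection and the iterative sampling step

def _danger_flags(z: np.ndarray, labels: np.ndarray, minority_label: int,
                  k: int) -> np.ndarray:
    """Vectorized Danger test for all samples.

    A sample is Danger iff a strict majority of its k nearest neighbors
    (self excluded, Euclidean on the standardized coordinates) belongs to
    the minority class.  Ties (even k, split vote) are NOT Danger.
    """
    n = z.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the pool size {n}")
    dist = cdist(z, z)
    np.fill_diagonal(dist, np.inf)
    neighbor_idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
    minority_votes = (labels[neighbor_idx] == minority_label).sum(axis=1)
    return minority_votes * 2 > k


def is_danger(pool: SamplePool, index: int, k: int) -> bool:
    """Danger test for a single sample (see :func:`_danger_flags`)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    z, _, _ = standardize(pool.features)
    return bool(_danger_flags(z, pool.labels, pool.minority_label, k)[index])


def its_sampling_step(pool: SamplePool, k_init: int = 15,
                      seed: int = 0) -> tuple[SamplePool, ItsTrace]:
    """Iterative rebalancing: per iteration, remove Danger majority samples
    and replicate once each non-Danger minority sample, decrementing k from
    ``k_init``; stops exactly at class equality (the final iteration's
    actions are trimmed by seeded subsampling to avoid overshoot).

    If k runs out before equality, balance is forced by random minority
    oversampling with a warning.  Standardization is fixed at entry.
    """
    pool.require_both_classes()
    if k_init < 1:
        raise ValueError("k_init must be >= 1")
    return _its_sampling_impl(pool, k_init, seed)


def _its_sampling_impl(pool: SamplePool, k_init: int, seed: int) -> tuple[SamplePool, ItsTrace]:
    rng = np.random.default_rng(seed)
    trace = ItsTrace()
    _, mean, std = standardize(pool.features)
    features = pool.features.copy()
    labels = pool.labels.copy()
    minority_label = pool.minority_label

    for k in range(k_init, 0, -1):
        n_min = int(np.sum(labels == minority_label))
        n_maj = labels.size - n_min
        gap = n_maj - n_min
        if gap == 0:
            break
        k_eff = min(k, labels.size - 1)
        z = (features - mean) / std
        # One predicate drives both actions: a minority-dominated
        # neighborhood marks a majority sample as Danger (remove) and a
        # minority sample as safely inside its class (replicate).
        minority_dominated = _danger_flags(z, labels, minority_label, k_eff)
        removals = np.flatnonzero((labels != minority_label) & minority_dominated)
        replications = np.flatnonzero((labels == minority_label) & minority_dominated)

        if removals.size + replications.size > gap:
            # Trim the final iteration: pick a seeded random subset of the
            # combined action list so the step lands exactly on equality.
            action_is_removal = np.concatenate([
                np.ones(removals.size, dtype=bool),
                np.zeros(replications.size, dtype=bool),
            ])
            action_idx = np.concatenate([removals, replications])
            pick = rng.choice(action_idx.size, size=gap, replace=False)
            removals = action_idx[pick[action_is_removal[pick]]]
            replications = action_idx[pick[~action_is_removal[pick]]]

        trace.iterations.append({
            "k": k,
            "n_majority_before": n_maj,
            "n_minority_before": n_min,
            "removed": int(removals.size),
            "replicated": int(replications.size),
        })
        if removals.size == 0 and replications.size == 0:
            continue
        keep = np.setdiff1d(np.arange(labels.size), removals)
        features = np.vstack([features[keep], features[replications]])
        labels = np.concatenate([labels[keep], labels[replications]])

    n_min = int(np.sum(labels == minority_label))
    n_maj = labels.size - n_min
    if n_maj != n_min:
        warnings.warn("k schedule exhausted before equality; forcing balance "
                      "by random oversampling of the minority class")
        trace.forced_balance = True
        interim = SamplePool(features=features, labels=labels)
        balanced = random_oversample(interim, seed=int(rng.integers(0, 2**31)))
        features, labels = balanced.features, balanced.labels

    return SamplePool(features=features, labels=labels), trace


# ---------------------------------------------------------------------------
# Tomek links

def find_tomek_links(pool: SamplePool) -> list[TomekLink]:
    """All cross-class pairs (i, j) such that no third sample is strictly
    closer to either endpoint than they are to each other."""
    n = pool.n_samples
    if n < 2 or pool.n_minority == 0 or pool.n_majority == 0:
        return []
    z, _, _ = standardize(pool.features)
    dist = cdist(z, z)
    np.fill_diagonal(dist, np.inf)
    min_other = dist.min(axis=1)
    cross = pool.labels[:, None] != pool.labels[None, :]
    mutual = (dist <= min_other[:, None]) & (dist <= min_other[None, :])
    ii, jj = np.nonzero(cross & mutual & np.triu(np.ones((n, n), dtype=bool), k=1))
    return [TomekLink(i=int(i), j=int(j), distance=float(dist[i, j]))
            for i, j in zip(ii, jj)]


def tomek_clean(pool: SamplePool) -> tuple[SamplePool, dict[int, int]]:
    """Repeatedly remove BOTH endpoints of every Tomek link until none
    remain; link-disjoint removal keeps per-class removal counts equal.

    Stops early with a warning if further removal would empty a class.
    Idempotent: a cleaned pool passes through unchanged.
    """
    features = pool.features.copy()
    labels = pool.labels.copy()
    removed = {0: 0, 1: 0}
    while True:
        current = SamplePool(features=features, labels=labels)
        links = find_tomek_links(current)
        if not links:
            break
        marked: set[int] = set()
        counts = {c: int(np.sum(labels == c)) for c in (0, 1)}
        for link in links:
            if link.i in marked or link.j in marked:
                continue
            li, lj = int(labels[link.i]), int(labels[link.j])
            if counts[li] <= 1 or counts[lj] <= 1:
                warnings.warn("Tomek cleaning stopped early: class would be emptied")
                break
            marked.add(link.i)
            marked.add(link.j)
            counts[li] -= 1
            counts[lj] -= 1
        if not marked:
            break
        for m in marked:
            removed[int(labels[m])] += 1
        keep = np.array([i for i in range(labels.size) if i not in marked])
        features = features[keep]
        labels = labels[keep]
    return SamplePool(features=features, labels=labels), removed


def its(pool: SamplePool, k_init: int = 15, seed: int = 0) -> tuple[SamplePool, ItsTrace]:
    """Full iterative sampling: Danger-based rebalancing then Tomek-link
    cleaning.  Class counts are equal after both phases."""
    balanced, trace = its_sampling_step(pool, k_init=k_init, seed=seed)
    cleaned, removed = tomek_clean(balanced)
    trace.cleaning = {
        "removed_minority": removed[balanced.minority_label],
        "removed_majority": removed[balanced.majority_label],
        "n_after_cleaning": cleaned.n_samples,
    }
    return cleaned, trace


SAMPLING_METHODS = {
    "rus": lambda pool, seed, **kw: random_undersample(pool, seed=seed),
    "ros": lambda pool, seed, **kw: random_oversample(pool, seed=seed),
    "smote": lambda pool, seed, **kw: smote(pool, k_neighbors=kw.get("k_neighbors", 5), seed=seed),
    "its": lambda pool, seed, **kw: its(pool, k_init=kw.get("k_init", 15), seed=seed)[0],
}
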