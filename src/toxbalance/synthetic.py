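"""Synthetic imbalanced two-class descriptor tables with controllable
separation, overlap and label noise, shaped like the benchmark endpoints."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from toxbalance.data import DESCRIPTOR_NAMES, DescriptorTable
from toxbalance.sampling import SamplePool

#: Printed per-endpoint class counts (positive, negative).
ENDPOINT_COUNTS: dict[str, tuple[int, int]] = {
    "mutagenic": (90, 463),
    "tumorigenic": (90, 463),
    "irritant": (67, 486),
    "reproductive": (187, 366),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for an imbalanced Gaussian two-class table.

    separation is the Euclidean distance between class means in units of
    the (unit) per-class standard deviation; overlap_fraction places that
    share of minority samples at the majority mode, manufacturing
    borderline ("Danger") samples; noise_fraction swaps the labels of
    matched cross-class pairs, preserving the exact class counts.
    """

    n_minority: int
    n_majority: int
    n_features: int = 31
    separation: float = 2.0
    overlap_fraction: float = 0.0
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_minority < 1 or self.n_majority < 1:
            raise ValueError("class counts must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        for name in ("overlap_fraction", "noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _feature_names(n: int) -> list[str]:
    names = list(DESCRIPTOR_NAMES[:n])
    names += [f"Descriptor {i + 1}" for i in range(len(names), n)]
    return names


def generate(spec: GeneratorSpec, endpoint: str = "mutagenic") -> tuple[DescriptorTable, SamplePool]:
    """Draw the table: majority at the origin, minority displaced by
    ``separation`` along the diagonal direction, unit isotropic noise.

    Exact class counts, deterministic given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_features
    # concentrate the shift on the first two features so axis-aligned
    # learners can exploit it; Euclidean distance between means stays equal
    # to the separation parameter
    n_info = min(2, m)
    shift = np.zeros(m)
    shift[:n_info] = spec.separation / np.sqrt(n_info)

    maj = rng.standard_normal((spec.n_majority, m))
    n_overlap = int(round(spec.overlap_fraction * spec.n_minority))
    n_core = spec.n_minority - n_overlap
    minority_parts = []
    if n_core:
        minority_parts.append(rng.standard_normal((n_core, m)) + shift)
    if n_overlap:
        # borderline subpopulation drawn from the majority mode itself
        minority_parts.append(rng.standard_normal((n_overlap, m)))
    mino = np.vstack(minority_parts)

    features = np.vstack([mino, maj])
    labels = np.concatenate([
        np.ones(spec.n_minority, dtype=np.int64),
        np.zeros(spec.n_majority, dtype=np.int64),
    ])
    perm = rng.permutation(features.shape[0])
    features, labels = features[perm], labels[perm]

    n_flip_pairs = int(round(spec.noise_fraction * features.shape[0])) // 2
    if n_flip_pairs:
        pos = rng.choice(np.flatnonzero(labels == 1),
                         size=min(n_flip_pairs, int(labels.sum())), replace=False)
        neg = rng.choice(np.flatnonzero(labels == 0), size=pos.size, replace=False)
        labels[pos] = 0
        labels[neg] = 1

    table = DescriptorTable(
        sample_ids=[f"synth-{i}" for i in range(features.shape[0])],
        feature_names=_feature_names(m),
        values=features,
        labels={endpoint: labels},
    )
    return table, SamplePool(features=features, labels=labels)


def table2_fixture(endpoint: str, separation: float = 2.0,
                   overlap_fraction: float = 0.2, seed: int = 0) -> SamplePool:
    """Pool with the printed class counts of the named endpoint."""
    if endpoint not in ENDPOINT_COUNTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    n_pos, n_neg = ENDPOINT_COUNTS[endpoint]
    spec = GeneratorSpec(n_minority=n_pos, n_majority=n_neg,
                         separation=separation,
                         overlap_fraction=overlap_fraction, seed=seed)
    _, pool = generate(spec, endpoint=endpoint)
    return pool
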