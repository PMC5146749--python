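"""Dataset representation, CSV I/O, class-distribution accounting and CV folds."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

#: Canonical descriptor vocabulary, in canonical column order.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Total Molecular Weight",
    "Molecular Weight",
    "Absolute Weight",
    "cLogP",
    "cLogS",
    "H-Acceptors",
    "H-Donors",
    "Total Surface Area",
    "Polar Surface Area",
    "Druglikeness",
    "Molecular Shape Index",
    "Molecular Flexibility",
    "Molecular Complexity",
    "Non Hydrogen Atoms",
    "Non-Carbon/Hydrogen Atoms",
    "Metal Atoms",
    "Electron Negative Atoms",
    "Stereo Centers",
    "Rotatable Bonds",
    "Rings",
    "Aromatic Rings",
    "Aromatic Atoms",
    "sp3-Atoms",
    "Symmetric atoms",
    "Amides",
    "Amines",
    "AlkylAmines",
    "Aromatic Amines",
    "Aromatic Nitrogen",
    "Basic Nitrogen",
    "Acidic Oxygen",
)

#: Recognised toxicity endpoints.
ENDPOINTS: tuple[str, ...] = ("mutagenic", "tumorigenic", "irritant", "reproductive")


class SchemaError(ValueError):
    """Raised when a CSV does not expose the expected descriptor columns."""


class LabelError(ValueError):
    """Raised when an endpoint column is not binary-codable."""


class DegenerateDistributionError(ValueError):
    """Raised when a label vector contains a single class."""


class FoldError(ValueError):
    """Raised when a fold plan cannot satisfy its contract."""


@dataclass
class DescriptorTable:
    """Compounds-by-descriptors matrix with per-endpoint binary labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique row identifiers, order preserved from the source.
    feature_names : list of str
        Descriptor column names.
    values : ndarray of shape (n_samples, n_features)
        Real-valued descriptor matrix.
    labels : dict mapping endpoint name to ndarray of {0, 1}
        1 encodes the toxic (positive) class.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match column count")
        if np.isnan(self.values).any():
            raise ValueError("descriptor matrix contains missing values")
        clean = {}
        for endpoint, vec in self.labels.items():
            arr = np.asarray(vec)
            if arr.shape != (n,):
                raise ValueError(f"label vector for {endpoint!r} has wrong length")
            uniq = set(np.unique(arr).tolist())
            if not uniq <= {0, 1}:
                raise LabelError(f"label vector for {endpoint!r} is not binary: {sorted(uniq)}")
            clean[endpoint] = arr.astype(np.int64)
        self.labels = clean

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, names: Sequence[str]) -> "DescriptorTable":
        """Return a new table restricted to the named feature columns."""
        idx = [self.feature_names.index(n) for n in names]
        return DescriptorTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            labels={k: v.copy() for k, v in self.labels.items()},
        )


def round2(x: float) -> float:
    """Round to 2 decimals, half-up, via an intermediate 3-decimal step.

    The two-stage quantisation reproduces the printing convention of the
    reference distribution table (e.g. 16.2749 -> 16.275 -> 16.28); for
    values not sitting inside a half-unit of the third decimal it agrees
    with plain half-up rounding.
    """
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    d = d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class ClassDistribution:
    """Counts, percentages and imbalance ratio of a binary label vector."""

    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float
    imbalance_ratio: float

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def class_distribution(labels: np.ndarray) -> ClassDistribution:
    """Summarise a binary label vector.

    Percentages and the majority/minority imbalance ratio are reported to
    2 decimals (see :func:`round2`); raw counts stay exact.

    Raises
    ------
    DegenerateDistributionError
        If only one class is present.
    """
    arr = np.asarray(labels)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise LabelError(f"labels must be binary 0/1, got {sorted(uniq)}")
    n_pos = int(np.sum(arr == 1))
    n_neg = int(np.sum(arr == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDistributionError("both classes must be represented")
    total = n_pos + n_neg
    ratio = max(n_pos, n_neg) / min(n_pos, n_neg)
    return ClassDistribution(
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=round2(100.0 * n_pos / total),
        pct_negative=round2(100.0 * n_neg / total),
        imbalance_ratio=round2(ratio),
    )


@dataclass(frozen=True)
class FoldPlan:
    """Cross-validation assignment: one test-fold index per sample."""

    k: int
    assignments: np.ndarray
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "stratified": self.stratified,
             "assignments": self.assignments.tolist()},
            indent=2,
        )


def make_folds(labels: np.ndarray, k: int, stratified: bool = True,
               seed: int = 0) -> FoldPlan:
    """Build a k-fold plan, stratified by default.

    Deterministic given ``seed``; fold sizes differ by at most one.
    """
    arr = np.asarray(labels)
    n = arr.shape[0]
    if k < 2:
        raise FoldError("k must be at least 2")
    if n < k:
        raise FoldError(f"cannot split {n} samples into {k} folds")
    if stratified:
        counts = np.bincount(arr.astype(int), minlength=2)
        small = int(counts[counts > 0].min())
        if small < k:
            raise FoldError(
                f"stratified folds need >= {k} samples per class, smallest class has {small}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)), arr)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)))
    assignments = np.full(n, -1, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splits):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, stratified=stratified)


def load_descriptor_csv(path, endpoint_columns: Sequence[str] | Mapping[str, str] | None = None,
                        feature_names: Sequence[str] | None = None,
                        impute_median: bool = False) -> DescriptorTable:
    """Load a descriptor table from CSV.

    Parameters
    ----------
    path : str or Path
        CSV with a header row; an optional ``sample_id`` column is used for
        row identifiers, otherwise row numbers are assigned.
    endpoint_columns : sequence of column names, or mapping endpoint->column
        Columns to interpret as binary toxicity labels.
    feature_names : sequence of str, "infer", or None
        Expected descriptor columns; defaults to :data:`DESCRIPTOR_NAMES`.
        Pass ``"infer"`` to treat every non-id, non-endpoint column as a
        descriptor (useful for reduced or generated tables).
    impute_median : bool
        Replace missing descriptor cells with the column median instead of
        rejecting the file.
    """
    frame = pd.read_csv(path, float_precision="round_trip")

    if isinstance(endpoint_columns, Mapping):
        endpoint_map = dict(endpoint_columns)
    elif endpoint_columns is None:
        endpoint_map = {e: e for e in ENDPOINTS if e in frame.columns}
    else:
        endpoint_map = {c: c for c in endpoint_columns}
    for col in endpoint_map.values():
        if col not in frame.columns:
            raise SchemaError(f"missing endpoint column: {col!r}")

    if feature_names == "infer":
        non_feature = set(endpoint_map.values()) | {"sample_id"}
        expected = [c for c in frame.columns if c not in non_feature]
        if not expected:
            raise SchemaError("no descriptor columns found")
    else:
        expected = list(feature_names) if feature_names is not None \
            else list(DESCRIPTOR_NAMES)
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing descriptor columns: {missing}")

    if "sample_id" in frame.columns:
        sample_ids = [str(v) for v in frame["sample_id"]]
    else:
        sample_ids = [str(i) for i in range(len(frame))]

    values = frame[expected].to_numpy(dtype=float)
    if np.isnan(values).any():
        if impute_median:
            med = np.nanmedian(values, axis=0)
            rows, cols = np.nonzero(np.isnan(values))
            values[rows, cols] = med[cols]
        else:
            bad = sorted(set(np.nonzero(np.isnan(values))[0].tolist()))
            raise ValueError(f"missing descriptor values in rows {bad}")

    labels = {}
    for endpoint, col in endpoint_map.items():
        raw = frame[col].to_numpy()
        uniq = set(pd.unique(frame[col]).tolist())
        if not uniq <= {0, 1, 0.0, 1.0, True, False}:
            bad_rows = frame.index[~frame[col].isin([0, 1])].tolist()
            raise LabelError(f"non-binary values in {col!r} at rows {bad_rows}")
        labels[endpoint] = raw.astype(np.int64)

    return DescriptorTable(sample_ids=sample_ids, feature_names=expected,
                           values=values, labels=labels)


def write_descriptor_csv(table: DescriptorTable, path) -> None:
    """Write a table to CSV at full float precision (round-trip safe)."""
    frame = pd.DataFrame(table.values, columns=table.feature_names)
    frame.insert(0, "sample_id", table.sample_ids)
    for endpoint, vec in table.labels.items():
        frame[endpoint] = vec
    frame.to_csv(path, index=False, float_format="%.17g")
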