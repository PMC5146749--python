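"""Bagging over pluggable weak learners with majority-vote prediction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from toxbalance.sampling import SamplePool


class TrainingError(ValueError):
    pass


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    """Weak-learner kind + hyperparameters.

    The default is a depth-limited binary decision tree; any object exposing
    ``fit(X, y)`` / ``predict(X)`` can be substituted through ``factory``.
    """

    kind: str = "decision_tree"
    max_depth: int | None = 5
    criterion: str = "gini"

    def build(self, seed: int):
        if self.kind != "decision_tree":
            raise ValueError(f"unknown weak learner {self.kind!r}")
        return DecisionTreeClassifier(max_depth=self.max_depth,
                                      criterion=self.criterion,
                                      random_state=seed)


@dataclass(frozen=True)
class Prediction:
    label: int
    score: float


@dataclass
class BaggingModel:
    learners: list = field(default_factory=list)
    bootstrap_seeds: list[int] = field(default_factory=list)
    learner_spec: LearnerSpec = field(default_factory=LearnerSpec)
    n_features: int = 0
    vote_threshold: float = 0.5

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def train_bagging(pool: SamplePool, T: int = 3,
                  learner_spec: LearnerSpec | None = None, seed: int = 0,
                  bootstrap: bool = True,
                  vote_threshold: float = 0.5) -> BaggingModel:
    """Train ``T`` weak learners, each on a with-replacement bootstrap of the
    pool (same size as the pool); deterministic given ``seed``.

    ``bootstrap=False`` is a test hook that trains every learner on the
    pool itself.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if len(np.unique(pool.labels)) < 2:
        raise TrainingError("training pool must contain both classes")
    spec = learner_spec or LearnerSpec()
    rng = np.random.default_rng(seed)
    n = pool.n_samples
    learners, seeds = [], []
    for t in range(T):
        learner_seed = int(rng.integers(0, 2**31))
        seeds.append(learner_seed)
        if bootstrap:
            # redraw until the bootstrap holds both classes, so every weak
            # learner is trainable
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(pool.labels[idx])) == 2:
                    break
        else:
            idx = np.arange(n)
        learner = spec.build(learner_seed)
        learner.fit(pool.features[idx], pool.labels[idx])
        learners.append(learner)
    return BaggingModel(learners=learners, bootstrap_seeds=seeds,
                        learner_spec=spec, n_features=pool.features.shape[1],
                        vote_threshold=vote_threshold)


def predict(model: BaggingModel, samples: np.ndarray) -> list[Prediction]:
    """Majority-vote aggregation; score is the positive-vote fraction.

    Label 1 iff score strictly exceeds the vote threshold, so an even split
    resolves to the negative class.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[1] != model.n_features:
        raise PredictionError(
            f"expected {model.n_features} features, got {x.shape[1]}")
    votes = np.vstack([learner.predict(x) for learner in model.learners])
    scores = votes.mean(axis=0)
    return [Prediction(label=int(s > model.vote_threshold), score=float(s))
            for s in scores]


def predict_labels(model: BaggingModel, samples: np.ndarray) -> np.ndarray:
    return np.array([p.label for p in predict(model, samples)], dtype=np.int64)


def predict_scores(model: BaggingModel, samples: np.ndarray) -> np.ndarray:
    return np.array([p.score for p in predict(model, samples)], dtype=float)
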