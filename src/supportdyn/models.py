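"""Construct-measurement models.

Seven epsilon-insensitive *linear* support-vector regressions map language
features to the 1-7 construct scale (one model per machine-coded
construct), and a logistic classifier provides the binary story-telling
flag.  Features are standardized before fitting so the signed weights are
comparable across features; hyperparameters are tuned on a development
split, never on the held-out test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DomainError, FitError, SchemaError

DEFAULT_GRID = tuple((C, eps) for C in (0.1, 1.0, 10.0) for eps in (0.01, 0.1, 0.3))


@dataclass
class DatasetSplit:
    """Disjoint train/dev/test message-id lists (80/10/10 by default)."""

    train: list
    dev: list
    test: list
    seed: int


def split_dataset(
    ids: Sequence, proportions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> DatasetSplit:
    """Uniform random 80/10/10 partition, reproducible under ``seed``."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigError(f"proportions {proportions} do not sum to 1")
    if len(ids) < 10:
        raise DomainError(f"need at least 10 ids to split, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    perm = rng.permutation(len(order))
    n = len(order)
    n_dev = int(round(n * proportions[1]))
    n_test = int(round(n * proportions[2]))
    shuffled = [order[i] for i in perm]
    return DatasetSplit(
        train=shuffled[: n - n_dev - n_test],
        dev=shuffled[n - n_dev - n_test : n - n_test],
        test=shuffled[n - n_test :],
        seed=seed,
    )


@dataclass
class ConstructModel:
    """A fitted linear SVR: standardized-scale weights plus scaling params."""

    construct: str
    feature_names: list[str]
    weights: dict[str, float]
    intercept: float
    C: float
    epsilon: float
    scale_mean: dict[str, float]
    scale_sd: dict[str, float]

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise SchemaError(f"feature matrix missing column(s): {', '.join(missing)}")
        X = features[self.feature_names].to_numpy(dtype=float)
        mu = np.array([self.scale_mean[f] for f in self.feature_names])
        sd = np.array([self.scale_sd[f] for f in self.feature_names])
        return (X - mu) / sd

    def predict(self, features: pd.DataFrame, clip: bool = False) -> np.ndarray:
        w = np.array([self.weights[f] for f in self.feature_names])
        pred = self._matrix(features) @ w + self.intercept
        if clip:
            pred = np.clip(pred, 1.0, 7.0)
        return pred

    def to_json(self) -> dict:
        return {
            "construct": self.construct,
            "feature_names": self.feature_names,
            "weights": self.weights,
            "intercept": self.intercept,
            "C": self.C,
            "epsilon": self.epsilon,
            "scale_mean": self.scale_mean,
            "scale_sd": self.scale_sd,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ConstructModel":
        return cls(**obj)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ConstructModel":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class AccuracyReport:
    construct: str
    pearson_r: float
    n_test: int


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _fit_svr(Xs: np.ndarray, y: np.ndarray, C: float, epsilon: float):
    from sklearn.svm import LinearSVR

    svr = LinearSVR(
        C=C,
        epsilon=epsilon,
        loss="epsilon_insensitive",
        fit_intercept=True,
        max_iter=50000,
        tol=1e-6,
        random_state=0,
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        svr.fit(Xs, y)
    return svr


def train_construct_model(
    features: pd.DataFrame,
    targets: Sequence[float],
    construct: str = "",
    C: float = 1.0,
    epsilon: float = 0.1,
    dev_features: Optional[pd.DataFrame] = None,
    dev_targets: Optional[Sequence[float]] = None,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
) -> ConstructModel:
    """Fit a linear epsilon-insensitive SVR after feature standardization.

    If a development split is supplied, (C, epsilon) are chosen from
    ``grid`` by held-out Pearson correlation on that split; otherwise the
    given values are used directly.
    """
    y = np.asarray(targets, dtype=float)
    if len(features) != len(y):
        raise SchemaError("features and targets length mismatch")
    if len(y) < 20:
        raise DomainError(f"need at least 20 training rows, got {len(y)}")
    if np.std(y) == 0:
        raise FitError(f"degenerate fit for {construct!r}: constant target")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise SchemaError("missing values in features or targets")
    Xs, mu, sd = _standardize(X)

    if dev_features is not None and dev_targets is not None:
        ydev = np.asarray(dev_targets, dtype=float)
        Xdev = (dev_features[names].to_numpy(dtype=float) - mu) / sd
        best, best_r = None, -np.inf
        for C_try, eps_try in grid:
            svr = _fit_svr(Xs, y, C_try, eps_try)
            pred = Xdev @ svr.coef_.ravel() + float(np.ravel(svr.intercept_)[0])
            if np.std(pred) == 0 or np.std(ydev) == 0:
                r = -np.inf
            else:
                r = float(np.corrcoef(pred, ydev)[0, 1])
            if r > best_r:
                best, best_r = (C_try, eps_try), r
        C, epsilon = best

    svr = _fit_svr(Xs, y, C, epsilon)
    coef = svr.coef_.ravel()
    return ConstructModel(
        construct=construct,
        feature_names=names,
        weights={n: float(w) for n, w in zip(names, coef)},
        intercept=float(np.ravel(svr.intercept_)[0]),
        C=C,
        epsilon=epsilon,
        scale_mean={n: float(m) for n, m in zip(names, mu)},
        scale_sd={n: float(s) for n, s in zip(names, sd)},
    )


def evaluate_model(
    model: ConstructModel, features: pd.DataFrame, targets: Sequence[float]
) -> AccuracyReport:
    """Pearson r between model predictions and held-out human scores."""
    y = np.asarray(targets, dtype=float)
    pred = model.predict(features)
    if np.std(pred) == 0:
        raise FitError(
            f"model {model.construct!r} produced zero-variance predictions on "
            f"{len(y)} rows; Pearson r undefined"
        )
    if np.std(y) == 0:
        raise DomainError("held-out targets are constant; Pearson r undefined")
    return AccuracyReport(
        construct=model.construct,
        pearson_r=float(np.corrcoef(pred, y)[0, 1]),
        n_test=len(y),
    )


def top_features(model: ConstructModel, k: int = 10) -> list[tuple[str, float]]:
    """The k features with the largest |weight|, signed; ties by name."""
    ranked = sorted(model.weights.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return ranked[: min(k, len(ranked))]


@dataclass
class StoryModel:
    """Logistic story/not-story classifier thresholded at 0.5."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray


def train_story_classifier(features: pd.DataFrame, labels: Sequence[int]) -> StoryModel:
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise FitError("story classifier needs both classes in training data")
    X = features.to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)
    clf = LogisticRegression(max_iter=5000, C=1.0)
    clf.fit(Xs, y)
    return StoryModel(
        feature_names=list(features.columns),
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        scale_mean=mu,
        scale_sd=sd,
    )


def score_story(model: StoryModel, features: pd.DataFrame) -> np.ndarray:
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise SchemaError(f"feature matrix missing column(s): {', '.join(missing)}")
    X = features[model.feature_names].to_numpy(dtype=float)
    z = ((X - model.scale_mean) / model.scale_sd) @ model.weights + model.intercept
    prob = 1.0 / (1.0 + np.exp(-z))
    return (prob >= 0.5).astype(int)


def score_corpus(models: dict[str, ConstructModel], features: pd.DataFrame) -> pd.DataFrame:
    """Apply every construct model to a feature matrix; scores clipped to [1, 7]."""
    out = {}
    for construct, model in models.items():
        out[construct] = model.predict(features, clip=True)
    return pd.DataFrame(out, index=features.index)
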