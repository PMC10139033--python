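"""Model-agnostic training/validation harness for QSAR regressors.

Learners are consumed through a two-method interface (``fit(X, y)`` /
``predict(X)``); adapters map the six conventional QSAR algorithm names to
scikit-learn implementations, and trivial reference models (mean, ordinary
least squares, 1-NN) are provided for testing the harness itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .datatypes import FingerprintDataset, PredictionSet

__all__ = [
    "Regressor",
    "ModelSpec",
    "make_model",
    "cross_validate",
    "fit_predict_external",
    "select_best_model",
    "MeanRegressor",
    "LeastSquaresRegressor",
    "OneNearestNeighbor",
]


@runtime_checkable
class Regressor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Regressor": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class ModelSpec:
    """Named learner plus hyperparameters, resolved by :func:`make_model`."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("model name must be non-empty")


class MeanRegressor:
    """Predicts the training mean; the null model for Q² ≈ 0 checks."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class LeastSquaresRegressor:
    """Ordinary least squares with intercept via ``numpy.linalg.lstsq``."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        A = np.column_stack([np.ones(X.shape[0]), X])
        self.coef_, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([np.ones(X.shape[0]), X]) @ self.coef_


class OneNearestNeighbor:
    """Returns the activity of the closest training row (Euclidean)."""

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        return self.y_[np.argmin(d2, axis=1)]


def make_model(spec: ModelSpec, random_state: int | None = 0) -> Regressor:
    """Resolve a :class:`ModelSpec` to a scikit-learn regressor.

    Supported names: ``rf``, ``svm``, ``rbf`` (kernel ridge with RBF kernel),
    ``adaboost``, ``mlp``, ``knn``, plus the reference models ``mean``,
    ``ols`` and ``1nn``.  Hyperparameters default to the library's defaults.
    """
    name = spec.name.lower()
    hp = dict(spec.hyperparameters)
    if name == "mean":
        return MeanRegressor()
    if name == "ols":
        return LeastSquaresRegressor()
    if name == "1nn":
        return OneNearestNeighbor()

    if name == "rf":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(random_state=random_state, **hp)
    if name == "svm":
        from sklearn.svm import SVR

        return SVR(**hp)
    if name == "rbf":
        from sklearn.kernel_ridge import KernelRidge

        hp.setdefault("kernel", "rbf")
        return KernelRidge(**hp)
    if name == "adaboost":
        from sklearn.ensemble import AdaBoostRegressor

        return AdaBoostRegressor(random_state=random_state, **hp)
    if name == "mlp":
        from sklearn.neural_network import MLPRegressor

        return MLPRegressor(random_state=random_state, **hp)
    if name == "knn":
        from sklearn.neighbors import KNeighborsRegressor

        return KNeighborsRegressor(**hp)
    raise ValueError(f"unknown model name {spec.name!r}")


def _train_moments(activity: np.ndarray) -> tuple[float, int, float]:
    mean = float(activity.mean())
    return mean, activity.size, float(np.sum((activity - mean) ** 2))


def cross_validate(ds: FingerprintDataset, folds: np.ndarray, model: Regressor) -> PredictionSet:
    """Out-of-fold predictions: each row is predicted exactly once by the
    model refit on the complement of its fold.  ``kind`` is ``"loo"`` when
    there are as many folds as rows, else ``"cv"``."""
    folds = np.asarray(folds, dtype=int)
    if folds.shape != (ds.n_compounds,):
        raise ValueError("fold vector must assign every row")
    predicted = np.empty(ds.n_compounds, dtype=float)
    for f in np.unique(folds):
        out = folds == f
        try:
            fitted = model.fit(ds.bits[~out], ds.activity[~out])
            predicted[out] = np.asarray(fitted.predict(ds.bits[out]), dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise RuntimeError(f"model failed on fold {f}") from exc
    mean, n_train, ss = _train_moments(ds.activity)
    kind = "loo" if np.unique(folds).size == ds.n_compounds else "cv"
    return PredictionSet(
        observed=ds.activity,
        predicted=predicted,
        kind=kind,
        train_mean=mean,
        n_train=n_train,
        train_ss=ss,
        ids=list(ds.ids),
    )


def fit_predict_external(
    train: FingerprintDataset, test: FingerprintDataset, model: Regressor
) -> PredictionSet:
    """Fit on the full training set, predict the external test set, carrying
    the training-set moments needed by Q²F1/Q²F3."""
    if train.n_bits != test.n_bits:
        raise ValueError("train/test fingerprint column mismatch")
    fitted = model.fit(train.bits, train.activity)
    predicted = np.asarray(fitted.predict(test.bits), dtype=float)
    mean, n_train, ss = _train_moments(train.activity)
    return PredictionSet(
        observed=test.activity,
        predicted=predicted,
        kind="external",
        train_mean=mean,
        n_train=n_train,
        train_ss=ss,
        ids=list(test.ids),
    )


def select_best_model(reports: dict[str, tuple[float, float]]) -> list[str]:
    """Rank models by descending cross-validated Q², ties broken by
    ascending MAE, then alphabetically by name.

    ``reports`` maps model name → ``(q2_cv, mae)``.
    """
    if not reports:
        raise ValueError("no model reports to rank")
    for name, pair in reports.items():
        if len(pair) != 2 or any(v is None or not np.isfinite(v) for v in pair):
            raise ValueError(f"model {name!r} is missing Q2/MAE")
    return sorted(reports, key=lambda name: (-reports[name][0], reports[name][1], name))
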