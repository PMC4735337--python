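"""Subtype classifiers behind a single train/tune/predict contract.

Three families: ``elastic_net`` (multinomial logistic regression with an
L1/L2 mixture penalty), ``random_forest`` (bagged decision-tree ensemble),
and ``nsc`` (nearest shrunken centroids).  The first two delegate to
scikit-learn solvers; NSC is implemented here from the published
shrunken-centroid construction:

    d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

with the standardized contrasts ``d_ik`` soft-thresholded by the shrinkage
parameter, class centroids rebuilt from the shrunken contrasts, and samples
assigned by minimum standardized squared distance minus twice the log class
prior.  ``s_i`` is the pooled within-class standard deviation of gene i and
``s0`` the median of the ``s_i`` (a guard against near-zero denominators).

Feature matrices are samples x genes (rows are observations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError, TrainingError

FAMILIES = ("elastic_net", "random_forest", "nsc")

#: Desk-scale default hyperparameter grids per family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "elastic_net": {
        "alpha": [round(0.1 * k, 1) for k in range(1, 11)],
        "lambda": list(np.logspace(-4, 1, 20)),
    },
    "random_forest": {
        "n_trees": [500],
        "max_features": ["sqrt", 0.25],
    },
    "nsc": {
        "threshold": list(np.linspace(0.0, 7.0, 15)),
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter search grid."""

    family: str
    grid: Mapping[str, Sequence] = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"invalid ClassifierSpec.family: {self.family!r} not in {FAMILIES}")
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
        grid = {k: list(v) for k, v in grid.items()}
        for name, values in grid.items():
            if len(values) == 0:
                raise ConfigurationError(
                    f"invalid ClassifierSpec.grid: empty candidate list for {name!r}")
        object.__setattr__(self, "grid", grid)

    def grid_points(self) -> list[dict[str, Any]]:
        """The grid as an ordered list of parameter dicts (product order)."""
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# nearest shrunken centroids
# ---------------------------------------------------------------------------

@dataclass
class NSCModel:
    """Parameters of a fitted (possibly shrunken) nearest-centroid rule."""

    classes: np.ndarray          # fixed label order
    overall_centroid: np.ndarray  # (p,)
    centroids: np.ndarray         # (p, K) shrunken class centroids
    s: np.ndarray                 # (p,) pooled within-class SD
    s0: float
    priors: np.ndarray            # (K,)
    threshold: float

    def discriminant(self, X: np.ndarray) -> np.ndarray:
        """delta_k(x) = sum_i (x_i - c_ik)^2 / (s_i+s0)^2 - 2 log pi_k."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        denom = (self.s + self.s0) ** 2
        diffs = X[:, :, None] - self.centroids[None, :, :]
        dist = (diffs ** 2 / denom[None, :, None]).sum(axis=1)
        return dist - 2.0 * np.log(self.priors)[None, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        delta = self.discriminant(X)
        return self.classes[np.argmin(delta, axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        delta = self.discriminant(X)
        z = -0.5 * (delta - delta.min(axis=1, keepdims=True))
        w = np.exp(z)
        return w / w.sum(axis=1, keepdims=True)

    def n_active_genes(self) -> int:
        """Genes whose shrunken contrast is nonzero for at least one class."""
        contrast = self.centroids - self.overall_centroid[:, None]
        return int((np.abs(contrast) > 1e-12).any(axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "overall_centroid": self.overall_centroid.tolist(),
            "centroids": self.centroids.tolist(),
            "s": self.s.tolist(),
            "s0": self.s0,
            "priors": self.priors.tolist(),
            "threshold": self.threshold,
        }


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def train_nsc(X, y, threshold: float, priors: np.ndarray | None = None) -> NSCModel:
    """Fit a nearest shrunken centroid model.

    Requires at least two classes, each with at least two training samples
    (the pooled within-class variance is undefined otherwise).  ``priors``
    defaults to the empirical class proportions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if threshold < 0:
        raise ConfigurationError(f"invalid threshold: {threshold} < 0")
    classes, y_idx = np.unique(y, return_inverse=True)
    n, p = X.shape
    K = len(classes)
    if K < 2:
        raise TrainingError("need at least two classes to train NSC")
    counts = np.bincount(y_idx, minlength=K)
    for k, cls in enumerate(classes):
        if counts[k] < 2:
            raise TrainingError(f"class {cls!r} has fewer than 2 training samples")

    overall = X.mean(axis=0)
    centroids = np.empty((p, K))
    within_ss = np.zeros(p)
    for k in range(K):
        Xk = X[y_idx == k]
        centroids[:, k] = Xk.mean(axis=0)
        within_ss += ((Xk - centroids[:, k]) ** 2).sum(axis=0)
    s = np.sqrt(within_ss / (n - K))
    s0 = float(np.median(s))
    m = np.sqrt(1.0 / counts - 1.0 / n)

    denom = m[None, :] * (s + s0)[:, None]
    d = (centroids - overall[:, None]) / denom
    d_shrunk = _soft_threshold(d, threshold)
    shrunken_centroids = overall[:, None] + denom * d_shrunk

    if priors is None:
        priors = counts / n
    return NSCModel(classes=classes, overall_centroid=overall,
                    centroids=shrunken_centroids, s=s, s0=s0,
                    priors=np.asarray(priors, dtype=float), threshold=float(threshold))


def nsc_threshold_path(X, y, n_points: int = 15) -> list[float]:
    """Evenly spaced shrinkage thresholds from 0 to the largest |contrast|."""
    X = np.asarray(X, dtype=float)
    classes, y_idx = np.unique(np.asarray(y), return_inverse=True)
    n, K = len(y_idx), len(classes)
    counts = np.bincount(y_idx, minlength=K)
    overall = X.mean(axis=0)
    centroids = np.stack([X[y_idx == k].mean(axis=0) for k in range(K)], axis=1)
    within = sum((((X[y_idx == k] - centroids[:, k]) ** 2).sum(axis=0))
                 for k in range(K))
    s = np.sqrt(within / (n - K))
    s0 = float(np.median(s))
    m = np.sqrt(1.0 / counts - 1.0 / n)
    d = (centroids - overall[:, None]) / (m[None, :] * (s + s0)[:, None])
    return list(np.linspace(0.0, float(np.abs(d).max()), n_points))


# ---------------------------------------------------------------------------
# uniform contract
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained classifier: family, chosen hyperparameters, predictor."""

    family: str
    hyperparameters: dict
    classes: np.ndarray
    _predict: Any = field(repr=False)
    _predict_proba: Any = field(repr=False)

    def predict(self, X) -> np.ndarray:
        return self._predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return self._predict_proba(np.asarray(X, dtype=float))


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def fit(spec: ClassifierSpec, params: Mapping[str, Any], X, y) -> FittedModel:
    """Fit one family at fixed hyperparameters; deterministic under the seed."""
    X, _ = _as_matrix(X)
    y = np.asarray(y)
    classes = np.unique(y)

    if len(classes) == 1:
        only = classes[0]
        return FittedModel(
            spec.family, dict(params), classes,
            _predict=lambda Xt: np.full(len(np.atleast_2d(Xt)), only, dtype=object),
            _predict_proba=lambda Xt: np.ones((len(np.atleast_2d(Xt)), 1)))

    if spec.family == "nsc":
        model = train_nsc(X, y, threshold=params["threshold"])
        return FittedModel(spec.family, dict(params), model.classes,
                           _predict=model.predict, _predict_proba=model.predict_proba)

    if spec.family == "elastic_net":
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(X)
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=float(params["alpha"]), C=1.0 / float(params["lambda"]),
            max_iter=2000, tol=1e-3, random_state=spec.seed)
        clf.fit(scaler.transform(X), y)
        return FittedModel(
            spec.family, dict(params), clf.classes_,
            _predict=lambda Xt: clf.predict(scaler.transform(Xt)),
            _predict_proba=lambda Xt: clf.predict_proba(scaler.transform(Xt)))

    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=int(params["n_trees"]),
            max_features=params["max_features"],
            random_state=spec.seed, n_jobs=1)
        clf.fit(X, y)
        return FittedModel(spec.family, dict(params), clf.classes_,
                           _predict=clf.predict, _predict_proba=clf.predict_proba)

    raise ConfigurationError(f"unknown family {spec.family!r}")


def tune(spec: ClassifierSpec, X, y, inner_folds: int = 5,
         seed: int | None = None) -> dict[str, Any]:
    """Choose hyperparameters by stratified inner cross-validation.

    Returns the grid point with maximal mean inner-fold accuracy; ties are
    broken by first occurrence in grid (product) order.  A single-point grid
    is returned without fitting anything.
    """
    points = spec.grid_points()
    if len(points) == 1:
        return points[0]
    if inner_folds < 2:
        raise ConfigurationError(f"invalid inner_folds: {inner_folds} < 2")
    from sklearn.model_selection import StratifiedKFold

    X, _ = _as_matrix(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < inner_folds]
    if len(small):
        raise TrainingError(
            f"class {small[0]!r} has fewer samples than inner_folds={inner_folds}")
    seed = spec.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best_params, best_score = None, -np.inf
    for params in points:
        scores = []
        for train_idx, val_idx in folds:
            model = fit(spec, params, X[train_idx], y[train_idx])
            scores.append(float(np.mean(model.predict(X[val_idx]) == y[val_idx])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params


def train_predict(spec: ClassifierSpec, X_train, y_train, X_test,
                  params: Mapping[str, Any] | None = None,
                  inner_folds: int = 5,
                  seed: int | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Tune (if needed), fit, and predict in one call.

    Returns ``(labels, scores, chosen_params)`` where ``scores`` rows sum to
    one.  Train and test must share an identical, identically ordered gene
    set (checked when both are DataFrames).
    """
    Xtr, train_genes = _as_matrix(X_train)
    Xte, test_genes = _as_matrix(X_test)
    if train_genes is not None and test_genes is not None and train_genes != test_genes:
        raise StructuralError("train/test gene sets differ or are ordered differently")
    if Xtr.shape[1] != Xte.shape[1]:
        raise StructuralError(
            f"train has {Xtr.shape[1]} features but test has {Xte.shape[1]}")
    if params is None:
        params = tune(spec, Xtr, y_train, inner_folds=inner_folds, seed=seed)
    model = fit(spec, params, Xtr, y_train)
    return model.predict(Xte), model.predict_proba(Xte), dict(params)
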