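"""Receptor-status (ER/PR/Her2) prediction from single marker genes.

The clinical status is modelled by univariate logistic regression on the
marker gene's log2 expression (ESR1 for ER, PGR for PR, ERBB2 for Her2).
An operating cutpoint is chosen on the *training* scores by maximizing
Youden's index J = sensitivity + specificity - 1 over an exhaustive ROC,
then applied unchanged to the held-out test scores.  Learning curves repeat
this over stratified holdout rounds and training sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing
from .errors import ConfigurationError, StructuralError, TrainingError
from .simulate import MARKER_GENES, Cohort
from .supervised import (CurveConfig, _seed, stratified_split,
                         stratified_subsample, summarize_records)

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "pos", "neg"


@dataclass
class ROCResult:
    """An exhaustive ROC: cutpoints with sensitivity/specificity and Youden J.

    Cutpoints are the midpoints between adjacent distinct sorted scores,
    bracketed by -inf/+inf sentinels, so every achievable classification of
    the score vector appears exactly once.  A sample is called positive when
    its score >= cutpoint.
    """

    cutpoints: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    @property
    def auc(self) -> float:
        # trapezoid over the (FPR, sensitivity) staircase
        fpr = 1.0 - self.specificity
        order = np.lexsort((self.sensitivity, fpr))
        return float(np.trapezoid(self.sensitivity[order], fpr[order]))


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all distinct cutpoints of the scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise StructuralError("scores and labels differ in length")
    if len(scores) == 0:
        raise StructuralError("empty score vector")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutpoints = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    sens = np.array([(scores[labels] >= c).sum() / n_pos if n_pos else 0.0
                     for c in cutpoints])
    spec = np.array([(scores[~labels] < c).sum() / n_neg if n_neg else 0.0
                     for c in cutpoints])
    return ROCResult(cutpoints=cutpoints, sensitivity=sens, specificity=spec)


def youden_cutoff(roc: ROCResult) -> float:
    """The cutpoint maximizing J; ties broken toward higher specificity.

    Residual ties (identical J and specificity) resolve to the larger
    cutpoint, which is deterministic because cutpoints are strictly ordered.
    """
    if len(roc.cutpoints) == 0:
        raise StructuralError("empty ROC")
    j = roc.youden
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    spec = roc.specificity[candidates]
    best = candidates[spec >= spec.max() - 1e-12]
    return float(roc.cutpoints[best[-1]])


def fit_receptor_model(expression, labels):
    """Univariate logistic regression; returns a score function.

    ``expression`` is the marker gene's per-sample expression, ``labels``
    booleans (positive status).  The returned callable maps expression to
    positive-class probability, monotone in the predictor.
    """
    x = np.asarray(expression, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise TrainingError("both receptor statuses must be present for training")
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect separation is legitimate here
        clf.fit(x, y)

    positive_col = int(np.flatnonzero(clf.classes_ == True)[0])

    def score(values) -> np.ndarray:
        v = np.asarray(values, dtype=float).reshape(-1, 1)
        return clf.predict_proba(v)[:, positive_col]

    return score


def run_receptor_curve(cohort: Cohort, receptor: str,
                       config: CurveConfig) -> pd.DataFrame:
    """Learning curve of receptor-status prediction accuracy.

    Per round: stratified (by status) holdout of ``test_fraction``; for each
    training size, fit the logistic model on the marker gene, choose the
    Youden cutoff on the training ROC, and score binary accuracy (plus
    sensitivity/specificity) on the test set.  Returns a tidy per-round
    table; aggregate with :func:`summarize_receptor_curve`.
    """
    if receptor not in MARKER_GENES:
        raise ConfigurationError(
            f"invalid receptor: {receptor!r} not in {tuple(MARKER_GENES)}")
    marker = MARKER_GENES[receptor]
    if marker not in cohort.counts.index:
        raise StructuralError(f"marker gene {marker!r} missing from cohort")
    status = cohort.annotation[receptor]
    if set(status.unique()) != {POSITIVE, NEGATIVE}:
        if len(status.unique()) < 2:
            raise StructuralError(f"receptor {receptor}: only one status present")

    expr, _ = preprocessing.normalize_counts(cohort.counts)
    marker_expr = expr.loc[marker]
    labels_bool = status == POSITIVE
    master = int(config.master_seed) & 0x7FFFFFFF

    records = []
    for r in range(config.n_rounds):
        pool, test_ids = stratified_split(status, config.test_fraction,
                                          _seed(master, 11, r))
        for size in config.training_sizes:
            if size > len(pool):
                warnings.warn(f"training size {size} infeasible; skipped")
                continue
            train_ids = stratified_subsample(pool, status, size,
                                             _seed(master, 12, r, size))
            y_train = labels_bool.loc[train_ids].to_numpy()
            if y_train.all() or (~y_train).all():
                warnings.warn(f"round {r}, size {size}: a status stratum is "
                              f"empty; round skipped")
                continue
            x_train = marker_expr.loc[train_ids].to_numpy()
            score = fit_receptor_model(x_train, y_train)
            roc = roc_curve(score(x_train), y_train)
            cutoff = youden_cutoff(roc)

            x_test = marker_expr.loc[test_ids].to_numpy()
            y_test = labels_bool.loc[test_ids].to_numpy()
            pred = score(x_test) >= cutoff
            tp = (pred & y_test).sum()
            tn = (~pred & ~y_test).sum()
            records.append({
                "receptor": receptor, "size": size, "round": r,
                "accuracy": float((pred == y_test).mean()),
                "sensitivity": float(tp / y_test.sum()) if y_test.sum() else np.nan,
                "specificity": float(tn / (~y_test).sum()) if (~y_test).sum() else np.nan,
                "auc_train": roc.auc,
                "cutoff": cutoff,
            })
    return pd.DataFrame(records)


def summarize_receptor_curve(records: pd.DataFrame) -> pd.DataFrame:
    return summarize_records(records, value_cols=("accuracy",),
                             by=("receptor", "size"))
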