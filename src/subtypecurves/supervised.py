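"""Nested cross-validation learning curves for subtype classification.

One cross-validation *round*: draw a stratified 10% outer test set, draw a
stratified training subset of the requested size from the remainder, tune
hyperparameters by stratified inner cross-validation on that training set
only, fit, and score on the outer test set.  Rounds are repeated (default
100) and aggregated as mean with the standard error of the cross-validation
mean (SEM).  The factorial design spans training sizes, classifier families,
feature sets (gene panel / top-variance), and optional read depths (counts
binomially thinned and renormalized before analysis).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocessing
from .classifiers import ClassifierSpec, fit, tune
from .errors import ConfigurationError, StructuralError
from .simulate import REPORT_ORDER, SUBTYPES, Cohort, allocate_class_counts, informative_panel

logger = logging.getLogger(__name__)


def _seed(*entropy: int) -> int:
    """A 31-bit seed derived deterministically from integer entropy."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0]) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# stratified sampling
# ---------------------------------------------------------------------------

def stratified_split(labels: pd.Series, test_fraction: float,
                     seed: int) -> tuple[list, list]:
    """Class-balanced outer train/test split.

    The test set holds round(test_fraction * N) samples (half-up rounding),
    apportioned over classes by largest remainder so test class proportions
    match the cohort's.  Returns ``(train_ids, test_ids)`` in original
    sample order; the two are disjoint and exhaustive.
    """
    if len(labels) == 0:
        raise StructuralError("empty annotation")
    classes, counts = np.unique(labels.to_numpy(), return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 1:
            raise StructuralError(f"class {cls!r} is empty")
    n = len(labels)
    test_total = int(np.floor(test_fraction * n + 0.5))
    per_class = allocate_class_counts(test_total, counts / n)
    rng = np.random.default_rng(seed)
    test_ids: set = set()
    for cls, k in zip(classes, per_class):
        ids = labels.index[labels.to_numpy() == cls]
        chosen = rng.choice(len(ids), size=k, replace=False)
        test_ids.update(ids[chosen])
    train = [s for s in labels.index if s not in test_ids]
    test = [s for s in labels.index if s in test_ids]
    return train, test


def stratified_subsample(pool: Sequence, labels: pd.Series, n: int,
                         seed: int) -> list:
    """Stratified subset of ``n`` samples from ``pool``.

    Class composition follows the pool's composition by largest-remainder
    apportionment; members are drawn without replacement per class.
    """
    pool = list(pool)
    if n > len(pool):
        raise ConfigurationError(f"cannot subsample {n} from a pool of {len(pool)}")
    sub = labels.loc[pool]
    classes, counts = np.unique(sub.to_numpy(), return_counts=True)
    per_class = allocate_class_counts(n, counts / counts.sum())
    rng = np.random.default_rng(seed)
    chosen: set = set()
    for cls, k in zip(classes, per_class):
        ids = sub.index[sub.to_numpy() == cls]
        picked = rng.choice(len(ids), size=k, replace=False)
        chosen.update(ids[picked])
    return [s for s in pool if s in chosen]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Row-normalized confusion rates plus the raw counts (true x predicted)."""

    classes: tuple
    counts: pd.DataFrame
    rates: pd.DataFrame


@dataclass
class Metrics:
    accuracy: float
    balanced_accuracy: float
    per_class_accuracy: pd.Series
    confusion: ConfusionMatrix


def metrics(y_true, y_pred, classes: Sequence | None = None) -> Metrics:
    """Overall accuracy, balanced accuracy, class-wise recall, confusion.

    Balanced accuracy is the unweighted mean of per-class accuracies
    (recall) over the classes actually present in ``y_true`` — the
    imbalance-robust summary used throughout the learning curves.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise StructuralError("label vectors differ in length")
    if classes is None:
        observed = set(y_true) | set(y_pred)
        classes = tuple(c for c in REPORT_ORDER if c in observed) \
            if observed <= set(SUBTYPES) else tuple(sorted(observed))
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise StructuralError(f"unknown labels: {sorted(unknown)!r}")

    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    row_totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(row_totals[:, None] > 0,
                         counts / np.maximum(row_totals, 1)[:, None], 0.0)
    accuracy = float(np.trace(counts) / len(y_true))
    present = row_totals > 0
    per_class = pd.Series(np.diag(rates), index=list(classes))
    balanced = float(per_class[present].mean())
    labels = pd.Index(list(classes), name="true")
    cm = ConfusionMatrix(
        classes=classes,
        counts=pd.DataFrame(counts, index=labels, columns=list(classes)),
        rates=pd.DataFrame(rates, index=labels, columns=list(classes)))
    return Metrics(accuracy, balanced, per_class, cm)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetDef:
    """A feature set derived from the cohort expression matrix.

    kind "panel": an explicit gene list; "top_variance": the top ``fraction``
    of genes by variance; "informative_panel": the synthetic stand-in for a
    curated subtype panel (first ``panel_size`` informative genes); "all":
    every gene.
    """

    kind: str = "top_variance"
    genes: tuple | None = None
    fraction: float | None = 0.25
    panel_size: int = 50

    def resolve(self, expr: pd.DataFrame, cohort: Cohort | None = None) -> pd.DataFrame:
        if self.kind == "all":
            return expr
        if self.kind == "top_variance":
            return preprocessing.variance_filter(expr, self.fraction)
        if self.kind == "panel":
            matrix, missing = preprocessing.subset_panel(expr, list(self.genes))
            if missing:
                logger.warning("panel genes missing from matrix: %s", missing)
            return matrix
        if self.kind == "informative_panel":
            if cohort is None:
                raise ConfigurationError(
                    "informative_panel dataset requires a synthetic cohort")
            matrix, _ = preprocessing.subset_panel(
                expr, informative_panel(cohort, self.panel_size))
            return matrix
        raise ConfigurationError(f"invalid DatasetDef.kind: {self.kind!r}")


@dataclass(frozen=True)
class CurveConfig:
    """Design of the learning-curve experiment."""

    training_sizes: tuple = tuple(range(100, 751, 50))
    test_fraction: float = 0.10
    n_rounds: int = 100
    classifier_specs: tuple = (ClassifierSpec("nsc"),)
    datasets: tuple = (("Top25", DatasetDef("top_variance", fraction=0.25)),)
    read_depth_grid: tuple | None = None
    inner_folds: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.training_sizes)
        if any(s <= 0 for s in sizes):
            raise ConfigurationError("invalid training_sizes: must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ConfigurationError("invalid training_sizes: must be strictly increasing")
        if not (0.0 <= self.test_fraction < 1.0):
            raise ConfigurationError("invalid test_fraction: must lie in [0, 1)")
        if self.n_rounds < 1:
            raise ConfigurationError("invalid n_rounds: must be >= 1")
        object.__setattr__(self, "training_sizes", sizes)
        object.__setattr__(self, "classifier_specs", tuple(self.classifier_specs))
        object.__setattr__(self, "datasets", tuple(self.datasets))
        if self.read_depth_grid is not None:
            object.__setattr__(self, "read_depth_grid",
                               tuple(int(d) for d in self.read_depth_grid))


@dataclass
class LearningCurveResult:
    """Per-round records, per-condition summary, pooled confusion matrices."""

    records: pd.DataFrame
    summary: pd.DataFrame
    confusions: dict[tuple, pd.DataFrame]

    def confusion_rates(self, key: tuple) -> pd.DataFrame:
        counts = self.confusions[key]
        totals = counts.sum(axis=1)
        return counts.div(totals.where(totals > 0, 1), axis=0)


_CONDITION_COLS = ["dataset", "depth", "classifier", "size"]


def summarize_records(records: pd.DataFrame,
                      value_cols: Sequence[str] = ("accuracy", "balanced_accuracy"),
                      by: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean, SD and SEM per experimental condition.

    SEM = SD / sqrt(n_rounds); with a single round both SD and SEM are
    reported as 0 by convention.
    """
    if len(records) == 0:
        raise StructuralError("no result rows to summarize")
    by = [c for c in (_CONDITION_COLS if by is None else by) if c in records.columns]
    grouped = records.groupby(by, sort=True)
    rows = []
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n_rounds"] = len(grp)
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{col}_sd"] = sd
            row[f"{col}_sem"] = sd / np.sqrt(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def evaluate_round(expr: pd.DataFrame, labels: pd.Series, size: int,
                   spec: ClassifierSpec, round_seed: int,
                   test_fraction: float = 0.10, inner_folds: int = 5,
                   split: tuple[list, list] | None = None) -> tuple[dict, ConfusionMatrix]:
    """One nested-CV round for one (size, classifier) condition.

    The outer test set is never seen by tuning or fitting; the returned
    record carries accuracies, per-class recall and the chosen
    hyperparameters.  ``split`` lets a caller share one outer split across
    conditions within a round.
    """
    seeds = np.random.SeedSequence(round_seed).generate_state(3) & 0x7FFFFFFF
    if split is None:
        split = stratified_split(labels, test_fraction, int(seeds[0]))
    pool, test_ids = split
    if size > len(pool):
        raise ConfigurationError(
            f"training size {size} exceeds available pool of {len(pool)}")
    train_ids = stratified_subsample(pool, labels, size, _seed(int(seeds[1]), size))
    assert not set(train_ids) & set(test_ids), "outer-test leakage"

    X_train = expr[train_ids].T
    X_test = expr[test_ids].T
    y_train = labels.loc[train_ids].to_numpy()
    y_test = labels.loc[test_ids].to_numpy()

    spec_seeded = ClassifierSpec(spec.family, spec.grid,
                                 seed=_seed(int(seeds[2]), size))
    params = tune(spec_seeded, X_train.to_numpy(), y_train,
                  inner_folds=inner_folds, seed=spec_seeded.seed)
    model = fit(spec_seeded, params, X_train.to_numpy(), y_train)
    y_pred = model.predict(X_test.to_numpy())

    m = metrics(y_test, y_pred)
    record = {
        "classifier": spec.family, "size": size,
        "accuracy": m.accuracy, "balanced_accuracy": m.balanced_accuracy,
        "hyperparameters": json.dumps(params, default=str, sort_keys=True),
    }
    for cls, val in m.per_class_accuracy.items():
        record[f"acc_{cls}"] = val
    return record, m.confusion


def run_learning_curve(cohort: Cohort, config: CurveConfig) -> LearningCurveResult:
    """The full factorial experiment: rounds x sizes x classifiers x
    datasets x read depths.

    Within a round, every condition shares the same outer test split, so
    comparisons across classifiers/datasets/depths are paired.  Read depths
    are applied by binomial thinning of the raw counts followed by fresh
    size-factor normalization.  Identical ``master_seed`` gives an identical
    result table.
    """
    labels = cohort.annotation["subtype"]
    depths = list(config.read_depth_grid) if config.read_depth_grid else [None]
    master = int(config.master_seed) & 0x7FFFFFFF

    # expression matrices per (depth, dataset), built once
    matrices: dict[tuple, pd.DataFrame] = {}
    for d_idx, depth in enumerate(depths):
        counts = cohort.counts if depth is None else preprocessing.thin_counts(
            cohort.counts, depth, seed=_seed(master, 4, d_idx))
        expr, _ = preprocessing.normalize_counts(counts)
        for name, dataset in config.datasets:
            matrices[(depth, name)] = dataset.resolve(expr, cohort)

    records: list[dict] = []
    confusions: dict[tuple, pd.DataFrame] = {}
    for r in range(config.n_rounds):
        split = stratified_split(labels, config.test_fraction, _seed(master, 1, r))
        pool = split[0]
        for size in config.training_sizes:
            if size > len(pool):
                warnings.warn(f"training size {size} infeasible for pool "
                              f"of {len(pool)}; skipped")
                continue
            for depth in depths:
                for name, _dataset in config.datasets:
                    expr = matrices[(depth, name)]
                    for s_idx, spec in enumerate(config.classifier_specs):
                        record, confusion = evaluate_round(
                            expr, labels, size, spec,
                            round_seed=_seed(master, 2, r, size, s_idx),
                            test_fraction=config.test_fraction,
                            inner_folds=config.inner_folds, split=split)
                        record.update(round=r, dataset=name,
                                      depth="full" if depth is None else depth)
                        records.append(record)
                        key = (name, record["depth"], spec.family, size)
                        if key in confusions:
                            confusions[key] = confusions[key].add(
                                confusion.counts, fill_value=0).astype(int)
                        else:
                            confusions[key] = confusion.counts

    records_df = pd.DataFrame(records)
    return LearningCurveResult(records=records_df,
                               summary=summarize_records(records_df),
                               confusions=confusions)
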