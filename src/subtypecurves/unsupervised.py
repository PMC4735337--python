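"""Unsupervised subtyping: clustering, significance pruning, label transfer.

The unsupervised arm discovers subtypes instead of learning them: samples
are clustered by average-linkage (UPGMA) hierarchical clustering on
1 - Pearson correlation between expression profiles; the tree is pruned
top-down, keeping only 2-way splits that a SigClust-style Monte-Carlo test
declares significant against a single-Gaussian null; cluster centroids are
matched to reference subtype centroids by Spearman rank correlation in a
fixed priority order (Basal, Normal, Her2, LumA, LumB); and held-out samples
are classified by the nearest-centroid rule against the labelled cluster
centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import median_abs_deviation, spearmanr

from .classifiers import NSCModel
from .errors import ConfigurationError, NumericalError, StructuralError
from .simulate import Cohort
from .supervised import (ConfusionMatrix, CurveConfig, LearningCurveResult,
                         _seed, metrics, stratified_split,
                         stratified_subsample, summarize_records)

#: Order in which subtype labels claim clusters during label transfer.
PRIORITY_ORDER = ("Basal", "Normal", "Her2", "LumA", "LumB")


@dataclass
class ClusterTree:
    """Average-linkage merge history over samples.

    ``linkage`` is a scipy linkage matrix; ``sample_ids`` maps leaf indices
    to sample identifiers.
    """

    linkage: np.ndarray
    sample_ids: list

    def to_newick(self) -> str:
        """Newick export (heights as branch lengths), for inspection."""
        root = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return str(self.sample_ids[node.id])
            left, right = node.get_left(), node.get_right()
            return (f"({walk(left)}:{node.dist - left.dist:.6g},"
                    f"{walk(right)}:{node.dist - right.dist:.6g})")

        return walk(root) + ";"


def hclust_corr_average(expr: pd.DataFrame) -> ClusterTree:
    """UPGMA clustering of samples on correlation distance.

    Dissimilarity between two samples is 1 - Pearson correlation of their
    expression profiles (gene vectors); merging uses average linkage.
    Constant profiles have undefined correlation and are rejected.
    """
    X = expr.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise StructuralError("need at least two samples to cluster")
    sds = X.std(axis=1)
    for i in np.flatnonzero(sds == 0):
        raise NumericalError(
            f"sample {expr.columns[i]!r} has a constant expression profile")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    return ClusterTree(linkage=Z, sample_ids=list(expr.columns))


# ---------------------------------------------------------------------------
# significance of a 2-way split
# ---------------------------------------------------------------------------

def _cluster_index(X: np.ndarray, split: np.ndarray) -> float:
    """Two-cluster index: within-split SS / total SS about the grand mean."""
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total == 0:
        raise NumericalError("degenerate data: zero total sum of squares")
    within = 0.0
    for side in (split, ~split):
        within += float(((X[side] - X[side].mean(axis=0)) ** 2).sum())
    return within / total


def _two_means_split(X: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=2, max_iter=100, random_state=seed)
    return km.fit_predict(X) == 0


def _null_spectrum(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of the diagonal Gaussian null, soft-thresholded.

    The empirical covariance spectrum is floored at the background noise
    variance sigma_N^2 (MAD of all matrix entries, normal-consistent); when
    flooring alone would inflate the total variance, eigenvalues are first
    soft-shifted down by a constant tau chosen (by bisection) to preserve
    the total.
    """
    n, d = X.shape
    centered = X - X.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    lam = np.zeros(d)
    lam[:len(sv)] = sv ** 2 / max(n - 1, 1)
    sigma2 = float(median_abs_deviation(X.ravel(), scale="normal") ** 2)
    if sigma2 == 0:
        raise NumericalError("degenerate data: zero background MAD")
    total = lam.sum()
    if np.maximum(lam, sigma2).sum() <= total:
        return np.maximum(lam, sigma2)
    lo, hi = 0.0, float(lam.max())
    for _ in range(200):
        tau = (lo + hi) / 2.0
        if np.maximum(lam - tau, sigma2).sum() > total:
            lo = tau
        else:
            hi = tau
    return np.maximum(lam - (lo + hi) / 2.0, sigma2)


def sigclust_pvalue(X, split: np.ndarray | None = None, n_sim: int = 100,
                    seed: int = 0) -> float:
    """Monte-Carlo p-value for a 2-way split against a Gaussian null.

    ``X`` is samples x features restricted to the candidate node; ``split``
    is a boolean side indicator (each side needs >= 2 samples).  When
    ``split`` is None the observed split is the best 2-means partition, the
    canonical choice and the one under which the test is calibrated.  The
    null is a diagonal Gaussian with the soft-thresholded empirical spectrum
    (:func:`_null_spectrum`); each simulated dataset is split by 2-means and
    p is the fraction of simulated cluster indices at or below the observed.
    """
    if n_sim < 1:
        raise ConfigurationError(f"invalid n_sim: {n_sim} < 1")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    if split is None:
        # internally derived best 2-means partition; a 1-sample side is a
        # legitimate outcome here (its within-SS is simply 0)
        split = _two_means_split(X, seed=int(rng.integers(2 ** 31)))
    else:
        split = np.asarray(split, dtype=bool)
        if split.sum() < 2 or (~split).sum() < 2:
            raise StructuralError("each side of the split needs at least 2 samples")
    split = np.asarray(split, dtype=bool)
    ci_obs = _cluster_index(X, split)
    lam = _null_spectrum(X)
    scale = np.sqrt(lam)
    hits = 0
    for _ in range(n_sim):
        Z = rng.standard_normal((n, d)) * scale[None, :]
        sim_split = _two_means_split(Z, seed=int(rng.integers(2 ** 31)))
        if _cluster_index(Z, sim_split) <= ci_obs:
            hits += 1
    return hits / n_sim


def prune_to_significant(tree: ClusterTree, expr: pd.DataFrame, alpha: float = 0.05,
                         n_sim: int = 100, seed: int = 0,
                         min_cluster_size: int = 5) -> pd.Series:
    """Cut the tree top-down at significance ``alpha``; return cluster labels.

    Starting from the root, each node is scored by the canonical SigClust
    statistic — the cluster index of its best 2-means partition, compared
    with the same statistic on draws from the fitted Gaussian null.  A node
    whose p-value is strictly below ``alpha`` is split along its two
    subtrees and descent recurses into both children; an insignificant node
    (or one with fewer than 4 samples) becomes a final cluster.  Scoring the
    2-means partition rather than the tree's own children keeps observed
    and simulated statistics comparable: average linkage routinely peels
    off single outliers near the root, and such lopsided splits would make
    the test blind to real structure.  Clusters smaller than
    ``min_cluster_size`` are not considered reproducible and are merged into
    the cluster whose centroid they correlate with best.  Cluster ids are
    integers in left-to-right leaf order (relabelled densely after merging).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError(f"invalid alpha: {alpha!r} not in [0, 1]")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    root = to_tree(tree.linkage)
    labels = np.empty(X.shape[0], dtype=int)
    next_id = 0
    stack = [root]  # depth-first, left-to-right
    while stack:
        node = stack.pop()
        leaves = node.pre_order(lambda leaf: leaf.id)
        accept = False
        if not node.is_leaf() and len(leaves) >= 4 and alpha > 0.0:
            p = sigclust_pvalue(X[leaves], None, n_sim=n_sim,
                                seed=_seed(seed, node.id))
            accept = p < alpha
        if accept:
            stack.append(node.get_right())
            stack.append(node.get_left())
        else:
            labels[leaves] = next_id
            next_id += 1

    labels = _merge_small_clusters(X, labels, min_cluster_size)
    return pd.Series(labels, index=tree.sample_ids, name="cluster")


def _merge_small_clusters(X: np.ndarray, labels: np.ndarray,
                          min_size: int) -> np.ndarray:
    """Absorb clusters below ``min_size`` into their best-correlated cluster."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) <= 1:
            break
        small = ids[counts < min_size]
        if len(small) == 0:
            break
        # absorb the smallest cluster first (deterministic order)
        victim = small[np.argmin(counts[np.isin(ids, small)])]
        centroids = {cid: X[labels == cid].mean(axis=0) for cid in ids}
        v = centroids[victim]
        best, best_corr = None, -np.inf
        for cid in ids:
            if cid == victim:
                continue
            c = centroids[cid]
            if np.std(v) == 0 or np.std(c) == 0:
                corr = -np.inf
            else:
                corr = float(np.corrcoef(v, c)[0, 1])
            if corr > best_corr:
                best, best_corr = cid, corr
        if best is None:
            best = [cid for cid in ids if cid != victim][0]
        labels[labels == victim] = best
    # dense relabelling in first-appearance (leaf) order
    out = np.empty_like(labels)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# label transfer and classification
# ---------------------------------------------------------------------------

def cluster_centroids(expr: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Mean expression profile per cluster (genes x clusters)."""
    return pd.DataFrame(
        {cid: expr[clusters.index[clusters == cid]].mean(axis=1)
         for cid in sorted(clusters.unique())},
        index=expr.index)


def assign_subtype_labels(centroids: pd.DataFrame, reference: pd.DataFrame,
                          priority: tuple = PRIORITY_ORDER) -> dict:
    """Map clusters to subtype labels by maximal Spearman correlation.

    Labels are handed out in ``priority`` order: each label claims the
    still-unassigned cluster whose centroid has the highest Spearman rank
    correlation with that label's reference centroid (ties: lowest cluster
    column index).  Each cluster receives at most one label; clusters left
    over once every label is placed take the label of their own best
    reference (duplicates allowed).
    """
    if centroids.shape[1] < 1:
        raise StructuralError("need at least one cluster centroid")
    genes = centroids.index
    if not genes.equals(reference.index):
        ref = reference.reindex(genes)
        if ref.isna().any().any():
            raise StructuralError("centroid gene sets are not aligned")
        reference = ref
    corr = pd.DataFrame(
        {label: [spearmanr(centroids[c], reference[label]).statistic
                 for c in centroids.columns]
         for label in reference.columns},
        index=centroids.columns)

    mapping: dict = {}
    unassigned = list(centroids.columns)
    for label in priority:
        if label not in reference.columns or not unassigned:
            continue
        scores = corr.loc[unassigned, label]
        best = scores.index[int(np.argmax(scores.to_numpy()))]
        mapping[best] = label
        unassigned.remove(best)
    for cid in unassigned:  # surplus clusters beyond the label set
        scores = corr.loc[cid]
        mapping[cid] = scores.index[int(np.argmax(scores.to_numpy()))]
    return mapping


def _nearest_centroid_model(expr_train: pd.DataFrame,
                            clusters: pd.Series) -> NSCModel:
    """Plain nearest-centroid rule (shrinkage 0) on standardized distance."""
    X = expr_train.to_numpy(dtype=float).T
    ids = sorted(clusters.unique())
    sample_order = list(expr_train.columns)
    y = clusters.loc[sample_order].to_numpy()
    n, K = len(y), len(ids)
    centroids = np.stack([X[y == cid].mean(axis=0) for cid in ids], axis=1)
    within = np.zeros(X.shape[1])
    for k, cid in enumerate(ids):
        members = X[y == cid]
        within += ((members - centroids[:, k]) ** 2).sum(axis=0)
    dof = max(n - K, 1)
    s = np.sqrt(within / dof)
    s0 = float(np.median(s))
    if s0 == 0 and s.max() == 0:
        s0 = 1.0  # all-degenerate clusters: fall back to Euclidean distance
    priors = np.array([(y == cid).sum() / n for cid in ids])
    return NSCModel(classes=np.asarray(ids), overall_centroid=X.mean(axis=0),
                    centroids=centroids, s=s, s0=s0, priors=priors,
                    threshold=0.0)


def run_unsupervised_curve(cohort: Cohort, config: CurveConfig,
                           alpha: float = 0.05, n_sim: int = 100,
                           reference: pd.DataFrame | None = None) -> LearningCurveResult:
    """Learning curve of the unsupervised subtyping procedure.

    Per round and training size: cluster the training subset, prune to
    significant clusters, build cluster centroids, transfer subtype labels
    from the reference centroid set (default: the synthetic cohort's true
    latent class centroids), classify the outer test set by the
    nearest-centroid rule, and score against the true subtype labels.
    """
    labels = cohort.annotation["subtype"]
    master = int(config.master_seed) & 0x7FFFFFFF
    from . import preprocessing
    expr_full, _ = preprocessing.normalize_counts(cohort.counts)

    records: list[dict] = []
    confusions: dict[tuple, pd.DataFrame] = {}
    for name, dataset in config.datasets:
        expr = dataset.resolve(expr_full, cohort)
        ref = (cohort.true_centroids if reference is None else reference)
        ref = ref.loc[expr.index]
        for r in range(config.n_rounds):
            pool, test_ids = stratified_split(labels, config.test_fraction,
                                              _seed(master, 21, r))
            for size in config.training_sizes:
                if size > len(pool):
                    warnings.warn(f"training size {size} infeasible; skipped")
                    continue
                train_ids = stratified_subsample(pool, labels, size,
                                                 _seed(master, 22, r, size))
                expr_train = expr[train_ids]
                tree = hclust_corr_average(expr_train)
                clusters = prune_to_significant(tree, expr_train, alpha=alpha,
                                                n_sim=n_sim,
                                                seed=_seed(master, 23, r, size))
                n_clusters = int(clusters.nunique())
                if n_clusters == 1:
                    warnings.warn(f"round {r}, size {size}: pruning left a "
                                  f"single cluster; test set gets one label")
                cents = cluster_centroids(expr_train, clusters)
                mapping = assign_subtype_labels(cents, ref)
                model = _nearest_centroid_model(expr_train, clusters)
                pred_cluster = model.predict(expr[test_ids].to_numpy().T)
                y_pred = np.array([mapping[c] for c in pred_cluster], dtype=object)
                m = metrics(labels.loc[test_ids].to_numpy(), y_pred)
                record = {
                    "dataset": name, "classifier": "unsupervised_ncc",
                    "size": size, "round": r, "n_clusters": n_clusters,
                    "accuracy": m.accuracy,
                    "balanced_accuracy": m.balanced_accuracy,
                }
                for cls, val in m.per_class_accuracy.items():
                    record[f"acc_{cls}"] = val
                records.append(record)
                key = (name, "full", "unsupervised_ncc", size)
                if key in confusions:
                    confusions[key] = confusions[key].add(
                        m.confusion.counts, fill_value=0).astype(int)
                else:
                    confusions[key] = m.confusion.counts

    records_df = pd.DataFrame(records)
    summary = summarize_records(records_df, by=("dataset", "classifier", "size"))
    return LearningCurveResult(records=records_df, summary=summary,
                               confusions=confusions)
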