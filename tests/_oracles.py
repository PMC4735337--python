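"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a pipeline quantity from first principles, by
direct enumeration or naive looping, without touching the package's own
implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Brute-force DESeq size factors: loops, statistics only."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for i in range(n_genes):
        row = counts[i]
        if all(v > 0 for v in row):
            geomeans.append((i, math.exp(sum(math.log(v) for v in row) / n_samples)))
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts[i, j] / g for i, g in geomeans)
        k = len(ratios)
        mid = ratios[k // 2] if k % 2 else (ratios[k // 2 - 1] + ratios[k // 2]) / 2
        factors.append(mid)
    return np.array(factors)


def nsc_predict(X_train, y_train, X_test, threshold: float) -> np.ndarray:
    """Hand-evaluated shrunken-centroid discriminant, all loops."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = list(y_train)
    classes = sorted(set(y_train))
    n, p = X_train.shape
    K = len(classes)
    overall = [sum(X_train[j, i] for j in range(n)) / n for i in range(p)]
    centroids, counts = {}, {}
    for c in classes:
        rows = [j for j in range(n) if y_train[j] == c]
        counts[c] = len(rows)
        centroids[c] = [sum(X_train[j, i] for j in rows) / len(rows) for i in range(p)]
    s = []
    for i in range(p):
        ss = sum((X_train[j, i] - centroids[y_train[j]][i]) ** 2 for j in range(n))
        s.append(math.sqrt(ss / (n - K)))
    s0 = sorted(s)[len(s) // 2] if p % 2 else \
        (sorted(s)[p // 2 - 1] + sorted(s)[p // 2]) / 2
    shrunken = {}
    for c in classes:
        m = math.sqrt(1.0 / counts[c] - 1.0 / n)
        shrunken[c] = []
        for i in range(p):
            d = (centroids[c][i] - overall[i]) / (m * (s[i] + s0))
            d_shr = math.copysign(max(abs(d) - threshold, 0.0), d)
            shrunken[c].append(overall[i] + m * (s[i] + s0) * d_shr)
    preds = []
    for x in X_test:
        best, best_delta = None, None
        for c in classes:
            delta = sum((x[i] - shrunken[c][i]) ** 2 / (s[i] + s0) ** 2
                        for i in range(p)) - 2.0 * math.log(counts[c] / n)
            if best_delta is None or delta < best_delta:
                best, best_delta = c, delta
        preds.append(best)
    return np.array(preds)


def youden_best_cutoff(scores, labels) -> tuple[float, float]:
    """Exhaustive search over all midpoint cutpoints; returns (cutoff, J).

    Ties resolved toward higher specificity, then the larger cutpoint —
    the same documented rule the implementation follows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    distinct = sorted(set(scores))
    cuts = [-math.inf] + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])] + [math.inf]
    best = None
    for c in cuts:
        pred = scores >= c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        key = (round(j, 12), round(spec, 12), c)
        if best is None or key > best[0]:
            best = (key, c, j)
    return best[1], best[2]


def upgma_cophenetic(dist: np.ndarray) -> np.ndarray:
    """Naive UPGMA agglomeration; returns the cophenetic distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        pair = min(d, key=lambda k: (d[k], sorted(k)))
        height = d[pair]
        a, b = sorted(pair)
        members = clusters[a] + clusters[b]
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = height
        sizes = {a: len(clusters[a]), b: len(clusters[b])}
        del clusters[a], clusters[b]
        for k in list(clusters):
            key_a, key_b = frozenset((a, k)), frozenset((b, k))
            merged = (d[key_a] * sizes[a] + d[key_b] * sizes[b]) / (sizes[a] + sizes[b])
            del d[key_a], d[key_b]
            d[frozenset((next_id, k))] = merged
        del d[pair]
        clusters[next_id] = members
        next_id += 1
    return coph


def largest_remainder(n: int, weights) -> list[int]:
    """Hand apportionment: floors, then +1 by descending fractional part."""
    weights = [float(w) for w in weights]
    total = sum(weights)
    quotas = [n * w / total for w in weights]
    base = [int(math.floor(q)) for q in quotas]
    order = sorted(range(len(weights)),
                   key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[: n - sum(base)]:
        base[i] += 1
    return base
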