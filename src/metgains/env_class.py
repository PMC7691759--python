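"""Yield-environment classification.

Retained trials are clustered on their mean yield with one-dimensional
k-means (k = 3 by default) and labeled LYE / MYE / HYE by ascending
cluster center.  The reference solver is an exact dynamic-programming
k-means (optimal partitions of sorted 1-D data are contiguous), which
makes the stage deterministic; a seeded Lloyd multi-start is provided as
a cross-check.  High-yielding trials are flagged for exclusion from the
downstream multi-environment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ClassificationError

CLASS_LABELS_3 = ("LYE", "MYE", "HYE")


@dataclass
class EnvAssignment:
    trial_id: str
    class_label: str
    cluster_center: float


def ckmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact 1-D k-means by dynamic programming.

    Returns (labels aligned with the input order, ascending cluster
    centers, within-cluster sum of squares).  O(k n^2) with prefix-sum
    segment costs — ample for trial counts in the hundreds.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k < 1 or k > n:
        raise ClassificationError(f"k={k} invalid for {n} points")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: int, j: int) -> float:
        # SSE of xs[i:j]
        s = csum[j] - csum[i]
        return max(csq[j] - csq[i] - s * s / (j - i), 0.0)

    INF = np.inf
    dp = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1, i] + seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            dp[m, j] = best
            cut[m, j] = arg
    # backtrack segment boundaries
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = cut[m, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for m in range(k):
        i, j = bounds[m], bounds[m + 1]
        labels_sorted[i:j] = m
        centers[m] = xs[i:j].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers, float(dp[k, n])


def kmeans_lloyd_1d(
    values: np.ndarray, k: int, seed: int = 0, n_init: int = 20
) -> tuple[np.ndarray, np.ndarray, float]:
    """Seeded Lloyd multi-start (scikit-learn); cross-check of the DP solver."""
    from sklearn.cluster import KMeans

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[km.labels_], km.cluster_centers_.ravel()[order], float(km.inertia_)


def classify_environments(summaries, seed: int = 0, k: int = 3) -> list[EnvAssignment]:
    """Assign each retained trial a yield-environment class.

    ``summaries`` is a list of TrialSummary (or anything with trial_id
    and mean_yield).  Labels are assigned by ascending cluster center;
    with k = 3 they are LYE < MYE < HYE.  The exact DP solver is used, so
    the result does not depend on ``seed`` (kept for interface parity
    with the Lloyd cross-check).
    """
    trial_ids = [s.trial_id for s in summaries]
    means = np.array([s.mean_yield for s in summaries], dtype=float)
    if len(np.unique(means)) < k:
        raise ClassificationError(
            f"need >= {k} distinct trial mean yields, found {len(np.unique(means))}"
        )
    labels, centers, _ = ckmeans_1d(means, k)
    if k == 3:
        names = CLASS_LABELS_3
    else:
        names = tuple(f"C{i + 1}" for i in range(k))
    return [
        EnvAssignment(tid, names[lab], float(centers[lab]))
        for tid, lab in zip(trial_ids, labels)
    ]


def assignments_frame(assignments: list[EnvAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"trial_id": a.trial_id, "class_label": a.class_label, "cluster_center": a.cluster_center}
            for a in assignments
        ],
        columns=["trial_id", "class_label", "cluster_center"],
    )
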