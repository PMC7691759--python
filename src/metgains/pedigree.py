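"""Coefficient of parentage (coancestry) and pedigree-based grouping.

The coancestry f(i, j) is the probability that alleles drawn at random
from individuals i and j are identical by descent.  It follows the
classic tabular recursion on a pedigree sorted so parents precede
offspring:

``f(i, i) = (1 + f(p1(i), p2(i))) / 2``
``f(i, j) = (f(p1(i), j) + f(p2(i), j)) / 2``   (expanding the younger)

with unknown parents treated as unique, unrelated, non-inbred founders
(a missing parent contributes coancestry 0).  Twice the coancestry
matrix is the numerator relationship matrix, so every COP matrix is
positive semidefinite.

Top lines are grouped by principal components of the COP matrix: the
matrix rows are (column-)centered, the leading two components are
extracted, and seeded multi-start k-means on the scores assigns groups
— an automated, reproducible stand-in for grouping by visual
inspection of pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PedigreeError


class Pedigree:
    """A parent table: id -> (parent1, parent2), empty/None = unknown."""

    def __init__(self, table: pd.DataFrame):
        cols = {"id", "parent1", "parent2"}
        if not cols.issubset(table.columns):
            raise PedigreeError(f"pedigree table needs columns {sorted(cols)}")
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for row in table.itertuples(index=False):
            iid = str(row.id)
            if iid in self.parents:
                raise PedigreeError(f"duplicate pedigree id {iid!r}")
            p1 = None if pd.isna(row.parent1) or row.parent1 == "" else str(row.parent1)
            p2 = None if pd.isna(row.parent2) or row.parent2 == "" else str(row.parent2)
            self.parents[iid] = (p1, p2)
        for iid, (p1, p2) in self.parents.items():
            for p in (p1, p2):
                if p is not None and p not in self.parents:
                    raise PedigreeError(f"parent {p!r} of {iid!r} not in pedigree")
        self._depth = self._toposort()

    def _toposort(self) -> dict[str, int]:
        """Generation depth per individual; raises on cycles."""
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.parents)
        for iid, (p1, p2) in self.parents.items():
            for p in (p1, p2):
                if p is not None:
                    G.add_edge(p, iid)
        if not nx.is_directed_acyclic_graph(G):
            raise PedigreeError("pedigree contains a cycle")
        depth = {}
        for iid in nx.topological_sort(G):
            ps = [p for p in self.parents[iid] if p is not None]
            depth[iid] = 1 + max((depth[p] for p in ps), default=-1)
        return depth

    def ids(self) -> list[str]:
        return list(self.parents)

    def __contains__(self, iid: str) -> bool:
        return iid in self.parents

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))


@dataclass
class COPMatrix:
    ids: list[str]
    f: np.ndarray  # symmetric coancestry matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f, index=self.ids, columns=self.ids)


def cop(pedigree: Pedigree, i: str, j: str, _memo: dict | None = None) -> float:
    """Coancestry of individuals i and j (memoized recursion)."""
    for x in (i, j):
        if x not in pedigree:
            raise PedigreeError(f"unknown id {x!r}")
    memo = _memo if _memo is not None else {}

    def rec(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            p1, p2 = pedigree.parents[a]
            val = 0.5 * (1.0 + (rec(p1, p2) if p1 is not None and p2 is not None else 0.0))
        else:
            # expand the younger individual (larger generation depth);
            # ties broken arbitrarily — the recursion is symmetric
            if pedigree._depth[a] < pedigree._depth[b]:
                a, b = b, a
            p1, p2 = pedigree.parents[a]
            if p1 is None and p2 is None:
                val = 0.0  # founder unrelated to everything older
            else:
                val = 0.5 * (
                    (rec(p1, b) if p1 is not None else 0.0)
                    + (rec(p2, b) if p2 is not None else 0.0)
                )
        memo[key] = val
        return val

    return rec(i, j)


def cop_matrix(pedigree: Pedigree, ids: list[str] | None = None) -> COPMatrix:
    """Full symmetric coancestry matrix over ``ids``.

    Computed by the tabular method over all ancestors in topological
    order (each pair visited once), then restricted to the requested
    ids.
    """
    if ids is None:
        ids = pedigree.ids()
    for x in ids:
        if x not in pedigree:
            raise PedigreeError(f"unknown id {x!r}")
    order = sorted(pedigree.ids(), key=lambda x: (pedigree._depth[x], x))
    pos = {iid: t for t, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))  # numerator relationship matrix, A = 2f
    for t, iid in enumerate(order):
        p1, p2 = pedigree.parents[iid]
        i1 = pos[p1] if p1 is not None else None
        i2 = pos[p2] if p2 is not None else None
        for u in range(t):
            a = 0.0
            if i1 is not None:
                a += 0.5 * A[i1, u]
            if i2 is not None:
                a += 0.5 * A[i2, u]
            A[t, u] = A[u, t] = a
        A[t, t] = 1.0 + (0.5 * A[i1, i2] if i1 is not None and i2 is not None else 0.0)
    sel = [pos[x] for x in ids]
    return COPMatrix(ids=list(ids), f=0.5 * A[np.ix_(sel, sel)])


@dataclass
class GroupAssignment:
    id: str
    pc1: float
    pc2: float
    group: int


def pca_scores(matrix: COPMatrix, n_components: int = 2, centering: str = "centered") -> np.ndarray:
    """Principal-component scores of the COP matrix rows.

    ``centering``: "centered" removes column means (default), "raw"
    decomposes the matrix as-is.
    """
    M = matrix.f.astype(float)
    if centering == "centered":
        M = M - M.mean(axis=0, keepdims=True)
    elif centering != "raw":
        raise ValueError(f"unknown centering {centering!r}")
    U, sv, _ = np.linalg.svd(M, full_matrices=False)
    if np.sum(sv > 1e-12) < n_components:
        raise PedigreeError(
            f"COP matrix rank < {n_components}: PCA scores are degenerate"
        )
    scores = U[:, :n_components] * sv[:n_components]
    # deterministic sign: largest-magnitude coordinate of each axis positive
    for c in range(n_components):
        j = int(np.argmax(np.abs(scores[:, c])))
        if scores[j, c] < 0:
            scores[:, c] = -scores[:, c]
    return scores


def group_lines(
    matrix: COPMatrix,
    n_groups: int = 4,
    seed: int = 0,
    centering: str = "centered",
    n_components: int | None = None,
) -> list[GroupAssignment]:
    """k-means grouping of lines on their leading COP PC scores.

    The reported coordinates are always PC1/PC2 (the usual scatter),
    but clustering uses ``n_components`` leading components — default
    ``max(2, n_groups - 1)``, since G well-separated ancestor groups
    span G-1 dimensions of the centered COP matrix and a strict 2-D
    projection can superimpose two of them.  Groups are numbered
    1..n_groups by decreasing size (ties broken by the smallest member
    id) so output labels are reproducible.
    """
    n = len(matrix.ids)
    if not (2 <= n_groups <= n):
        raise PedigreeError(f"n_groups={n_groups} invalid for {n} lines")
    from sklearn.cluster import KMeans

    if n_components is None:
        n_components = max(2, n_groups - 1)
    n_components = min(n_components, n)
    scores = pca_scores(matrix, n_components=n_components, centering=centering)
    km = KMeans(n_clusters=n_groups, n_init=20, random_state=seed).fit(scores)
    labels = km.labels_
    order = sorted(
        range(n_groups),
        key=lambda c: (
            -int(np.sum(labels == c)),
            min(matrix.ids[i] for i in range(n) if labels[i] == c),
        ),
    )
    relabel = {c: rank + 1 for rank, c in enumerate(order)}
    return [
        GroupAssignment(matrix.ids[i], float(scores[i, 0]), float(scores[i, 1]), relabel[labels[i]])
        for i in range(n)
    ]


def groups_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": a.id, "pc1": a.pc1, "pc2": a.pc2, "group": a.group} for a in assignments],
        columns=["id", "pc1", "pc2", "group"],
    )


def plot_groups(assignments: list[GroupAssignment], ax=None):
    """PCA scatter of the grouped lines (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = groups_frame(assignments)
    for grp, sub in df.groupby("group"):
        ax.scatter(sub["pc1"], sub["pc2"], label=f"group {grp}", s=18)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    return ax
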