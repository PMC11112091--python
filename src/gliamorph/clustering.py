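"""Hierarchical clustering of morphometric profiles.

Cells are clustered on the standardized 15-parameter panel with Euclidean
distance and Ward's minimum-variance criterion; the number of clusters is
chosen by majority vote over four internal validity indices (silhouette,
Calinski–Harabasz, Davies–Bouldin, Dunn), and the result is summarized as
a per-group cluster composition table.

The module exposes a small model/results pair::

    model = MorphologyClustering(features, groups)
    res = model.fit()           # Ward tree, k selection, composition
    print(res.summary())

alongside the individual building blocks (``standardize``,
``ward_linkage``, ``select_k``, ``compose``) for use à la carte.

``ward_linkage`` is implemented here (greedy Lance–Williams on squared
Euclidean distances with a documented lowest-index tie-break) so the merge
order is fully specified; heights follow the SciPy convention
(``sqrt(2·ΔESS)``, so two singletons merge at their Euclidean distance)
and the returned matrix is SciPy-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "standardize",
    "ward_linkage",
    "dunn_index",
    "select_k",
    "KSelection",
    "compose",
    "MorphologyClustering",
    "ClusteringResults",
    "linkage_to_newick",
]


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column zero mean, unit variance (sample sd, ddof=1).

    Raises ``ValueError`` naming the first constant column; features with
    no variance carry no distance information and would divide by zero.
    """
    df = pd.DataFrame(matrix).astype(float)
    sd = df.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant column: {constant.index[0]!r}")
    return (df - df.mean()) / sd


def ward_linkage(matrix) -> np.ndarray:
    """Agglomerative Ward linkage, SciPy-format output.

    Greedy Lance–Williams recurrence on squared Euclidean distances:
    at every step the pair with the smallest merge cost is joined, ties
    broken by the lowest (i, j) cluster-id pair.  Row ``k`` of the result
    is ``[id_a, id_b, height, size]`` with new clusters numbered ``n+k``
    and ``height = sqrt(2·ΔESS)``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    n = X.shape[0]
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    np.fill_diagonal(d2, np.inf)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    # map cluster id -> row index in the distance matrix
    ids = list(range(n))
    Z = np.zeros((n - 1, 4))
    D = d2.copy()

    for step in range(n - 1):
        # lowest-cost pair; ties -> lexicographically smallest (id_i, id_j)
        best = None
        for a_pos in range(len(ids)):
            for b_pos in range(a_pos + 1, len(ids)):
                cost = D[a_pos, b_pos]
                key = (cost, ids[a_pos], ids[b_pos])
                if best is None or key < best[0]:
                    best = (key, a_pos, b_pos)
        (_, id_a, id_b), a_pos, b_pos = best
        na, nb = active[id_a], active[id_b]
        new_id = n + step
        Z[step] = [id_a, id_b, np.sqrt(D[a_pos, b_pos]), na + nb]

        # Lance-Williams update of squared distances to the merged cluster
        new_row = np.empty(len(ids))
        for c_pos, id_c in enumerate(ids):
            if c_pos in (a_pos, b_pos):
                new_row[c_pos] = np.inf
                continue
            nc = active[id_c]
            t = na + nb + nc
            new_row[c_pos] = ((na + nc) * D[a_pos, c_pos]
                              + (nb + nc) * D[b_pos, c_pos]
                              - nc * D[a_pos, b_pos]) / t

        keep = [p for p in range(len(ids)) if p not in (a_pos, b_pos)]
        D = D[np.ix_(keep, keep)]
        merged_d = new_row[keep]
        D = np.pad(D, ((0, 1), (0, 1)), constant_values=np.inf)
        D[-1, :-1] = merged_d
        D[:-1, -1] = merged_d
        ids = [ids[p] for p in keep] + [new_id]
        del active[id_a], active[id_b]
        active[new_id] = na + nb
    return Z


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min inter-cluster distance / max intra-cluster diameter."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    D = squareform(pdist(X))
    max_diam = 0.0
    for u in uniq:
        idx = np.nonzero(labels == u)[0]
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_sep = np.inf
    for i, u in enumerate(uniq):
        for v in uniq[i + 1:]:
            iu, iv = np.nonzero(labels == u)[0], np.nonzero(labels == v)[0]
            min_sep = min(min_sep, float(D[np.ix_(iu, iv)].min()))
    if max_diam == 0.0:
        return np.inf
    return min_sep / max_diam


#: the reduced validity-index battery and each index's optimisation sense
_INDICES = {
    "silhouette": (silhouette_score, max),
    "calinski_harabasz": (calinski_harabasz_score, max),
    "davies_bouldin": (davies_bouldin_score, min),
    "dunn": (dunn_index, max),
}


@dataclass
class KSelection:
    """Chosen cluster count with the full per-index vote table."""

    k: int
    votes: dict[str, int]                  # index name -> voted k
    scores: pd.DataFrame                   # index x k score table

    def __repr__(self):
        return f"KSelection(k={self.k}, votes={self.votes})"


def select_k(linkage: np.ndarray, matrix, k_range=range(2, 11)) -> KSelection:
    """Data-driven cluster count: majority vote over four validity indices.

    For every ``k`` in ``k_range`` the tree is cut into ``k`` flat
    clusters and each index scores the partition; each index votes for
    its best ``k`` and the majority wins, ties resolved toward smaller
    ``k``.  ``k_range`` must lie within ``[2, n-1]``.
    """
    X = np.asarray(matrix, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = X.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must be within [2, {n - 1}]")

    scores = pd.DataFrame(index=list(_INDICES), columns=ks, dtype=float)
    for k in ks:
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        for name, (fn, _) in _INDICES.items():
            scores.loc[name, k] = float(fn(X, labels))

    votes: dict[str, int] = {}
    for name, (_, sense) in _INDICES.items():
        row = scores.loc[name].dropna()
        if row.empty:
            continue
        best = row.idxmax() if sense is max else row.idxmin()
        votes[name] = int(best)
    if not votes:
        raise ValueError("no index could score any partition")
    tally = pd.Series(list(votes.values())).value_counts()
    top = tally[tally == tally.max()].index
    return KSelection(k=int(min(top)), votes=votes, scores=scores)


def compose(assignment: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Cluster × group counts and within-cluster percentages.

    ``assignment`` and ``groups`` must be indexed by the same cells.
    Percentages sum to 100 within each cluster row.
    """
    assignment = pd.Series(assignment)
    groups = pd.Series(groups)
    if not assignment.index.sort_values().equals(groups.index.sort_values()):
        raise ValueError("assignment and group labels cover different cells")
    groups = groups.reindex(assignment.index)
    counts = pd.crosstab(assignment, groups)
    counts.index.name = "cluster"
    counts.columns.name = "group"
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"{c}_pct" for c in pct.columns]
    return pd.concat([counts, pct], axis=1)


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage tree as Newick with heights as branch lengths."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: leaf_names[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        new = n + step
        nodes[new] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[new] = h
    return nodes[n + len(linkage) - 1] + ";"


@dataclass
class ClusteringResults:
    """Fitted clustering: tree, flat assignment, composition, diagnostics."""

    linkage: np.ndarray
    k: int
    selection: KSelection | None
    assignment: pd.Series
    composition: pd.DataFrame | None
    feature_names: list[str]
    standardized: bool

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, [str(c) for c in self.assignment.index])

    def plot_dendrogram(self, ax=None, **kwargs):
        """Draw the dendrogram (matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        hierarchy.dendrogram(self.linkage, ax=ax,
                             labels=list(self.assignment.index),
                             color_threshold=None, **kwargs)
        ax.set_ylabel("Ward linkage distance (Euclidean)")
        return ax

    def summary(self) -> str:
        lines = [
            "Morphology hierarchical clustering (Euclidean + Ward)",
            f"  cells: {len(self.assignment)}   features: {len(self.feature_names)}"
            f"   standardized: {self.standardized}",
            f"  clusters: k = {self.k}"
            + (f"   votes: {self.selection.votes}" if self.selection else ""),
            f"  cluster sizes: {self.assignment.value_counts().sort_index().to_dict()}",
        ]
        if self.composition is not None:
            lines += ["", "Composition (counts and within-cluster %):",
                      self.composition.round(1).to_string()]
        return "\n".join(lines)


class MorphologyClustering:
    """Hierarchical clustering model over a cell × parameter feature matrix.

    Parameters
    ----------
    features
        DataFrame of finite morphometric parameters, one row per cell.
    groups
        Optional per-cell experimental group labels (same index) for the
        composition table.
    standardize_features
        Standardize columns before computing Euclidean distances
        (default on: the panel mixes px² areas with dimensionless ratios,
        and raw Euclidean distance would be dominated by the area terms).
    """

    def __init__(self, features: pd.DataFrame, groups: pd.Series | None = None,
                 standardize_features: bool = True):
        features = pd.DataFrame(features).astype(float)
        if features.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.features = features
        self.groups = None if groups is None else pd.Series(groups)
        self.standardize_features = standardize_features

    @classmethod
    def from_profiles(cls, profiles: pd.DataFrame, groups=None, **kwargs):
        """Build from a ``profile_cells`` output frame (drops QC columns)."""
        from .morphometry import MorphometricProfile
        cols = [c for c in MorphometricProfile.PARAMETERS if c in profiles.columns]
        return cls(profiles[cols], groups=groups, **kwargs)

    def fit(self, k: int | None = None, k_range=range(2, 11)) -> ClusteringResults:
        """Run Ward linkage; pick ``k`` by the index vote unless given."""
        X = standardize(self.features) if self.standardize_features else self.features
        Z = ward_linkage(X.to_numpy())
        selection = None
        if k is None:
            n = len(X)
            ks = [kk for kk in k_range if 2 <= kk <= n - 1]
            selection = select_k(Z, X.to_numpy(), ks)
            k = selection.k
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        assignment = pd.Series(labels, index=self.features.index, name="cluster")
        composition = (compose(assignment, self.groups)
                       if self.groups is not None else None)
        return ClusteringResults(
            linkage=Z, k=int(k), selection=selection, assignment=assignment,
            composition=composition, feature_names=list(self.features.columns),
            standardized=self.standardize_features,
        )
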