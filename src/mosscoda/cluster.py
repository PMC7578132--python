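"""Structure discovery on Aitchison dissimilarities.

Two complementary views of group structure in the sample set:

* a divisive (top-down) hierarchy — start with all samples in one cluster
  and repeatedly split the cluster of largest diameter by seeding a splinter
  group with the most estranged observation and letting similar points
  defect to it;
* fuzzy clustering of the dissimilarity matrix — each sample receives a
  membership grade in every cluster, obtained by minimising the
  dissimilarity-based fuzzy objective

  ``sum_v [ sum_{i,j} u_iv^m u_jv^m d_ij / (2 sum_j u_jv^m) ]``

  with membership exponent m, so overlapping or weak structure shows up as
  grades near 1/K rather than being forced into crisp clusters.

The FC contribution matrix scores each element's weight in each fuzzy
cluster as the membership-weighted sum of its concentrations; near-equal FC
components across clusters (component ratio near 1) indicate weak grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "DivisiveClustering",
    "FuzzyClustering",
    "fc_matrix",
    "divisive_cluster",
    "fuzzy_cluster",
    "Dendrogram",
    "FCMatrix",
]


def _check_distance(dist) -> tuple[np.ndarray, list]:
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=1e-8, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = list(range(d.shape[0]))
    return d, labels


@dataclass
class _Node:
    members: tuple[int, ...]
    height: float
    children: tuple["_Node", "_Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    """Divisive hierarchy over n samples.

    ``heights`` are the diameters of the clusters at each split, so they are
    monotone non-increasing from root to leaf.  ``merge_table`` lists the
    splits in execution order; ``to_newick`` exports the tree with branch
    lengths equal to parent-height minus child-height.
    """

    root: _Node
    labels: list
    heights: list[float] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Crisp partition obtained by undoing the last splits.

        Splits are applied in execution order (largest-diameter first) until
        ``n_clusters`` clusters exist; returns integer labels per sample.
        """
        if not 1 <= n_clusters <= self.n_leaves:
            raise ValueError("n_clusters out of range")
        clusters = [self.root]
        while len(clusters) < n_clusters:
            splittable = [c for c in clusters if not c.is_leaf]
            if not splittable:
                break
            nxt = max(
                splittable, key=lambda c: (c.height, -min(c.members))
            )
            clusters.remove(nxt)
            clusters.extend(nxt.children)
        out = np.empty(self.n_leaves, dtype=int)
        # stable numbering: cluster id by smallest member index
        clusters.sort(key=lambda c: min(c.members))
        for cid, c in enumerate(clusters):
            out[list(c.members)] = cid
        return out

    def merge_table(self) -> pd.DataFrame:
        rows = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            left, right = node.children
            rows.append(
                {
                    "height": node.height,
                    "size": len(node.members),
                    "left": ";".join(str(self.labels[i]) for i in sorted(left.members)),
                    "right": ";".join(str(self.labels[i]) for i in sorted(right.members)),
                }
            )
            stack.extend(node.children)
        rows.sort(key=lambda r: (-r["height"], r["left"]))
        return pd.DataFrame(rows, columns=["height", "size", "left", "right"])

    def to_newick(self) -> str:
        def render(node: _Node, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{self.labels[node.members[0]]}:{length:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.6g}"

        if self.root.is_leaf:
            return f"{self.labels[self.root.members[0]]}:0;"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def _diameter(d: np.ndarray, members: tuple[int, ...]) -> float:
    idx = np.asarray(members)
    return float(d[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0


def _split(d: np.ndarray, members: tuple[int, ...]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """One divisive split: splinter seeding followed by defections.

    The splinter is seeded with the member of maximal average dissimilarity
    to the rest; members then defect while their average dissimilarity to
    the remaining "old party" exceeds that to the splinter.  Ties break on
    the lowest sample index, making the algorithm deterministic.
    """
    rest = list(members)
    sub = d[np.ix_(rest, rest)]
    avg = sub.sum(axis=1) / (len(rest) - 1)
    seed_pos = int(np.lexsort((rest, -avg))[0])  # max avg, lowest index on ties
    splinter = [rest.pop(seed_pos)]
    while len(rest) > 1:
        rest_arr = np.asarray(rest)
        d_old = d[np.ix_(rest_arr, rest_arr)].sum(axis=1) / (len(rest) - 1)
        d_new = d[np.ix_(rest_arr, np.asarray(splinter))].mean(axis=1)
        gain = d_old - d_new
        best = int(np.lexsort((rest_arr, -gain))[0])
        if gain[best] <= 0:
            break
        splinter.append(rest.pop(best))
    return tuple(sorted(splinter)), tuple(sorted(rest))


def _build_diana(d: np.ndarray) -> _Node:
    def make(members: tuple[int, ...]) -> _Node:
        if len(members) == 1:
            return _Node(members, 0.0)
        diam = _diameter(d, members)
        if diam == 0.0:
            # all points identical: split off the lowest index repeatedly
            left = _Node((members[0],), 0.0)
            right = make(tuple(members[1:]))
            return _Node(members, 0.0, (left, right))
        a, b = _split(d, members)
        return _Node(members, diam, (make(a), make(b)))

    return make(tuple(range(d.shape[0])))


class DivisiveClustering(ClusterMixin, BaseEstimator):
    """Divisive (DIANA-type) hierarchical clustering of a dissimilarity matrix.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of clusters for the crisp ``labels_`` cut.

    Attributes
    ----------
    dendrogram_ : Dendrogram
    labels_ : ndarray of shape (n_samples,)
        Crisp partition at ``n_clusters``.
    heights_ : ndarray
        Split heights (cluster diameters) in execution order.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        d, labels = _check_distance(X)
        root = _build_diana(d)
        dend = Dendrogram(root, labels)
        heights = []
        stack = [root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                heights.append(node.height)
                stack.extend(node.children)
        dend.heights = sorted(heights, reverse=True)
        self.dendrogram_ = dend
        self.heights_ = np.asarray(dend.heights)
        self.labels_ = dend.cut(min(self.n_clusters, len(labels)))
        self.n_features_in_ = d.shape[1]
        return self


def divisive_cluster(dist) -> Dendrogram:
    """Fit a divisive hierarchy and return the dendrogram (thin wrapper)."""
    return DivisiveClustering().fit(dist).dendrogram_


class FuzzyClustering(ClusterMixin, BaseEstimator):
    """Fuzzy clustering of a dissimilarity matrix (FANNY-type).

    Minimises ``sum_v sum_{i,j} u_iv^m u_jv^m d_ij / (2 sum_j u_jv^m)`` over
    membership matrices u with unit row sums, by the classical alternating
    update: per-point per-cluster "costs" are computed from the current
    memberships and new grades are proportional to ``cost^(-1/(m-1))``.
    Iteration stops when the objective improves by less than ``tol``; if an
    update would increase the objective the previous memberships are kept
    and the run is reported converged.

    Parameters
    ----------
    n_clusters : int, default 2
    membership_exponent : float, default 2.0
        The fuzzifier m > 1; larger values give fuzzier solutions.
    max_iter : int, default 500
    tol : float, default 1e-8
    random_state : int, default 0
        Seeds the Dirichlet initialisation of the membership matrix.

    Attributes
    ----------
    membership_ : ndarray (n_samples, n_clusters), rows sum to 1
    labels_ : ndarray, argmax memberships
    objective_ : float
    objective_path_ : ndarray, objective after each accepted iteration
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        n_clusters: int = 2,
        membership_exponent: float = 2.0,
        max_iter: int = 500,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.membership_exponent = membership_exponent
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _objective(u_m: np.ndarray, d: np.ndarray) -> float:
        denom = u_m.sum(axis=0)
        num = np.einsum("iv,jv,ij->v", u_m, u_m, d)
        return float(np.sum(num / (2.0 * denom)))

    def fit(self, X, y=None):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.membership_exponent <= 1.0:
            raise ValueError("membership_exponent must exceed 1")
        d, labels = _check_distance(X)
        n, K, m = d.shape[0], self.n_clusters, self.membership_exponent
        rng = np.random.default_rng(self.random_state)
        u = rng.dirichlet(np.ones(K), size=n)
        u_m = u**m
        obj = self._objective(u_m, d)
        path = [obj]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            denom = u_m.sum(axis=0)  # (K,)
            du = d @ u_m  # (n, K): sum_j u_jv^m d_ij
            within = np.einsum("iv,iv->v", u_m, du)  # sum_ij u^m u^m d
            # marginal cost of assigning point i to cluster v
            a = du / denom - within / (2.0 * denom**2)
            a = np.maximum(a, 1e-12)
            new_u = a ** (-1.0 / (m - 1.0))
            new_u /= new_u.sum(axis=1, keepdims=True)
            new_u_m = new_u**m
            new_obj = self._objective(new_u_m, d)
            if new_obj > obj + 1e-15:
                converged = True  # fixed point reached within update precision
                break
            if obj - new_obj < self.tol:
                u, u_m, obj = new_u, new_u_m, new_obj
                path.append(obj)
                converged = True
                break
            u, u_m, obj = new_u, new_u_m, new_obj
            path.append(obj)
        if not converged:
            warnings.warn(
                f"fuzzy clustering did not converge in {self.max_iter} iterations",
                stacklevel=2,
            )
        self.membership_ = u
        self.labels_ = np.argmax(u, axis=1)
        self.objective_ = obj
        self.objective_path_ = np.asarray(path)
        self.converged_ = converged
        self.n_iter_ = it
        self.sample_labels_ = labels
        self.n_features_in_ = n
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fuzzy_cluster(
    dist,
    n_clusters: int = 2,
    membership_exponent: float = 2.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> FuzzyClustering:
    """Fit fuzzy clustering on a dissimilarity matrix (thin wrapper)."""
    return FuzzyClustering(
        n_clusters=n_clusters,
        membership_exponent=membership_exponent,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(dist)


@dataclass
class FCMatrix:
    """Membership-weighted element contributions per fuzzy cluster.

    ``fc[v, k] = sum_i u_iv * C_ik`` — large components mean element k
    carries weight in cluster v.  ``component_ratio`` is min/max of FC
    across clusters per element (1 means the element does not distinguish
    the clusters); ``cluster_ratio`` is the raw first/second-cluster ratio
    when K = 2, with ``dominant_cluster`` naming the larger side.
    """

    fc: pd.DataFrame
    component_ratio: pd.Series
    cluster_ratio: Optional[pd.Series]
    dominant_cluster: pd.Series


def fc_matrix(membership, C) -> FCMatrix:
    """Compute the FC contribution matrix from memberships and concentrations."""
    u = membership.membership_ if hasattr(membership, "membership_") else np.asarray(membership, float)
    cols = C.columns if isinstance(C, pd.DataFrame) else [f"x{i}" for i in range(np.shape(C)[1])]
    vals = C.to_numpy(dtype=float) if isinstance(C, pd.DataFrame) else np.asarray(C, float)
    if u.ndim != 2 or vals.ndim != 2 or u.shape[0] != vals.shape[0]:
        raise ValueError("membership rows must align with concentration rows")
    fc_vals = u.T @ vals  # (K, D)
    fc = pd.DataFrame(
        fc_vals,
        index=[f"cluster_{v + 1}" for v in range(u.shape[1])],
        columns=cols,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = fc_vals.min(axis=0) / fc_vals.max(axis=0)
    component_ratio = pd.Series(ratio, index=cols, name="component_ratio")
    dominant = pd.Series(
        [f"cluster_{v + 1}" for v in fc_vals.argmax(axis=0)],
        index=cols,
        name="dominant_cluster",
    )
    cluster_ratio = None
    if u.shape[1] == 2:
        cluster_ratio = pd.Series(
            fc_vals[0] / fc_vals[1], index=cols, name="cluster_ratio"
        )
    return FCMatrix(fc, component_ratio, cluster_ratio, dominant)
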