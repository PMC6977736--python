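"""Agglomerative linkage hierarchies over point sets.

A linkage hierarchy is the ordered sequence of pairwise merges produced by
agglomerative clustering of ``M`` points: starting from singleton sets, the
two active sets with the smallest set-to-set distance are merged, ``M - 1``
times, until one set remains.  Leaves are numbered ``1..M`` in row order and
the node created by the i-th merge is numbered ``M + i``, so every merge is
described by a coordinate pair ``(a, b)`` with ``1 <= a < b < 2M - 1`` plus
the merge height.  Those integer coordinates — not the heights — are the raw
material for the linkage-coordinate histogram features in
:mod:`hlr.features`.

Three set-to-set distances (linkages) are supported:

``single``
    minimum pairwise point distance between the two sets,
``complete``
    maximum pairwise point distance,
``ward``
    ``sqrt(2 * |A| * |B| / (|A| + |B|)) * ||centroid(A) - centroid(B)||_2``,
    the (square-rooted) increase in within-set variance caused by the merge.

Point distances use the L1 (Manhattan) or L2 (Euclidean) norm; Ward linkage
is defined with the Euclidean norm only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import cdist

LINKAGES = ("single", "complete", "ward")
METRICS = ("l1", "l2")

_SCIPY_METRIC = {"l1": "cityblock", "l2": "euclidean"}


def validate_points(X, min_rows: int = 1) -> np.ndarray:
    """Coerce ``X`` to a finite 2-D float array with at least ``min_rows`` rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D point matrix, got ndim={X.ndim}")
    if X.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {X.shape[0]}")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    if not np.all(np.isfinite(X)):
        raise ValueError("point matrix contains non-finite values")
    return X


def check_linkage_params(linkage: str, metric: str) -> None:
    """Validate a (linkage, metric) pair.

    Ward linkage is defined with the Euclidean norm; requesting it with the
    L1 metric is an error rather than a silent override.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if linkage == "ward" and metric != "l2":
        raise ValueError("Ward linkage is defined with the Euclidean (l2) norm; "
                         "metric='l1' is not valid")


def pairwise_set_distance(A, B, linkage: str = "complete", metric: str = "l1",
                          ward_sqrt: bool = True) -> float:
    """Set-to-set distance between two disjoint point sets.

    Parameters
    ----------
    A, B : array-like, shape (n_a, d) and (n_b, d)
        Non-empty point sets of equal dimensionality.
    linkage : {'single', 'complete', 'ward'}
    metric : {'l1', 'l2'}
        Point metric for single/complete linkage.  Ward requires 'l2'.
    ward_sqrt : bool
        If False, use the variance-increase form without the square root
        over ``2 n_a n_b / (n_a + n_b)``.  Both forms coincide for
        singleton sets.
    """
    A = validate_points(A, min_rows=1)
    B = validate_points(B, min_rows=1)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    check_linkage_params(linkage, metric)
    if linkage == "ward":
        na, nb = A.shape[0], B.shape[0]
        factor = 2.0 * na * nb / (na + nb)
        if ward_sqrt:
            factor = math.sqrt(factor)
        return float(factor * np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    D = cdist(A, B, _SCIPY_METRIC[metric])
    return float(D.min() if linkage == "single" else D.max())


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: children ``a < b`` form ``node`` at ``height``."""

    a: int
    b: int
    node: int
    height: float


@dataclass
class LinkageHierarchy:
    """Ordered merge sequence of an agglomerative clustering of ``M`` points.

    Attributes
    ----------
    M : int
        Leaf count.
    coordinates : ndarray of int, shape (M - 1, 2)
        Child node pairs ``(a_i, b_i)`` in merge order, 1-based: leaves are
        ``1..M``, the i-th merge creates node ``M + i`` (i from 1), and
        ``1 <= a_i < b_i < 2M - 1`` for every merge but the last, whose new
        node is the root ``2M - 1``.
    heights : ndarray of float, shape (M - 1,)
        Merge distances, non-decreasing for the monotone linkages used here.
    """

    M: int
    coordinates: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64).reshape(-1, 2)
        self.heights = np.asarray(self.heights, dtype=float).reshape(-1)
        if self.M < 2:
            raise ValueError("a hierarchy needs at least M=2 leaves")
        if len(self.coordinates) != self.M - 1 or len(self.heights) != self.M - 1:
            raise ValueError("a hierarchy of M leaves has exactly M-1 merges")
        self.validate()

    @property
    def nodes(self) -> np.ndarray:
        """Node index created by each merge: ``M + 1 .. 2M - 1``."""
        return np.arange(self.M + 1, 2 * self.M, dtype=np.int64)

    @property
    def merges(self) -> list[Merge]:
        return [Merge(int(a), int(b), int(n), float(h))
                for (a, b), n, h in zip(self.coordinates, self.nodes, self.heights)]

    def validate(self) -> None:
        """Check the structural invariants of a well-formed hierarchy."""
        a, b = self.coordinates[:, 0], self.coordinates[:, 1]
        nodes = self.nodes
        if not np.all((1 <= a) & (a < b) & (b < nodes)):
            raise ValueError("child indices must satisfy 1 <= a < b < node")
        children = np.concatenate([a, b])
        uniq = np.unique(children)
        if len(uniq) != len(children):
            raise ValueError("a node may appear as a child of at most one merge")
        expected = np.arange(1, 2 * self.M - 1)
        if not np.array_equal(np.sort(children), expected):
            raise ValueError("every node except the root must appear exactly once "
                             "as a child")

    @classmethod
    def from_linkage_matrix(cls, Z: np.ndarray, M: int | None = None) -> "LinkageHierarchy":
        """Build from a scipy linkage matrix (0-based observation labels)."""
        Z = np.asarray(Z, dtype=float)
        if M is None:
            M = Z.shape[0] + 1
        children = Z[:, :2].astype(np.int64) + 1
        coords = np.sort(children, axis=1)
        return cls(M=M, coordinates=coords, heights=Z[:, 2].copy())

    def to_linkage_matrix(self) -> np.ndarray:
        """Inverse of :meth:`from_linkage_matrix` (counts set to subtree sizes)."""
        Z = np.zeros((self.M - 1, 4))
        sizes = {i: 1 for i in range(1, self.M + 1)}
        for i, m in enumerate(self.merges):
            Z[i, 0], Z[i, 1] = m.a - 1, m.b - 1
            Z[i, 2] = m.height
            sizes[m.node] = sizes[m.a] + sizes[m.b]
            Z[i, 3] = sizes[m.node]
        return Z

    def to_table(self) -> pd.DataFrame:
        """Serialize to a 4-column table: a, b, node, height (one row per merge)."""
        return pd.DataFrame({
            "a": self.coordinates[:, 0],
            "b": self.coordinates[:, 1],
            "node": self.nodes,
            "height": self.heights,
        })

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LinkageHierarchy":
        table = table.sort_values("node")
        M = len(table) + 1
        return cls(M=M,
                   coordinates=table[["a", "b"]].to_numpy(dtype=np.int64),
                   heights=table["height"].to_numpy(dtype=float))

    def to_newick(self, leaf_names: Sequence[str] | None = None) -> str:
        """Newick string with branch lengths derived from merge heights.

        A node sits at its merge height (leaves at 0); the branch length to a
        child is the height difference, which is non-negative for monotone
        linkages.
        """
        if leaf_names is None:
            leaf_names = [str(i) for i in range(1, self.M + 1)]
        if len(leaf_names) != self.M:
            raise ValueError("need one name per leaf")
        children = {n: (int(a), int(b)) for (a, b), n
                    in zip(self.coordinates, self.nodes)}
        height = {n: h for n, h in zip(self.nodes, self.heights)}

        def render(node: int, parent_h: float) -> str:
            if node <= self.M:
                return f"{leaf_names[node - 1]}:{parent_h - 0.0:g}"
            a, b = children[node]
            h = height[node]
            return f"({render(a, h)},{render(b, h)}):{parent_h - h:g}"

        root = 2 * self.M - 1
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"


def build_hierarchy(X, linkage: str = "complete", metric: str = "l1",
                    engine: str = "auto", ward_sqrt: bool = True) -> LinkageHierarchy:
    """Agglomerate a point matrix into its linkage hierarchy.

    Parameters
    ----------
    X : array-like, shape (M, n), M >= 2
    linkage : {'single', 'complete', 'ward'}
    metric : {'l1', 'l2'}
    engine : {'auto', 'scipy', 'greedy'}
        'scipy' delegates to :func:`scipy.cluster.hierarchy.linkage`
        (fast, the default).  'greedy' is an explicit O(M^3) greedy
        agglomeration that recomputes set distances from raw memberships and
        breaks distance ties by the lexicographically smallest ``(a, b)``
        pair; use it for small inputs when exact tie behaviour or the
        non-sqrt Ward form matters.  'auto' picks scipy unless
        ``ward_sqrt=False`` forces the greedy engine.
    ward_sqrt : bool
        See :func:`pairwise_set_distance`.  Only the greedy engine supports
        ``ward_sqrt=False``.

    Returns
    -------
    LinkageHierarchy
    """
    X = validate_points(X, min_rows=2)
    check_linkage_params(linkage, metric)
    if engine == "auto":
        engine = "greedy" if (linkage == "ward" and not ward_sqrt) else "scipy"
    if engine == "scipy":
        if linkage == "ward" and not ward_sqrt:
            raise ValueError("ward_sqrt=False requires engine='greedy'")
        Z = _scipy_linkage(X, method=linkage, metric=_SCIPY_METRIC[metric])
        return LinkageHierarchy.from_linkage_matrix(Z, M=X.shape[0])
    if engine == "greedy":
        return _build_greedy(X, linkage, metric, ward_sqrt)
    raise ValueError(f"unknown engine {engine!r}")


def _build_greedy(X: np.ndarray, linkage: str, metric: str,
                  ward_sqrt: bool) -> LinkageHierarchy:
    # Plain greedy agglomeration from raw set memberships; ties resolved by
    # the smallest (a, b) node pair.  Quadratic scan per step: small M only.
    M = X.shape[0]
    active: dict[int, np.ndarray] = {i + 1: np.array([i]) for i in range(M)}
    coords = np.empty((M - 1, 2), dtype=np.int64)
    heights = np.empty(M - 1)
    for step in range(M - 1):
        ids = sorted(active)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = pairwise_set_distance(X[active[a]], X[active[b]],
                                          linkage, metric, ward_sqrt)
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        node = M + step + 1
        active[node] = np.concatenate([active.pop(a), active.pop(b)])
        coords[step] = (a, b)
        heights[step] = d
    return LinkageHierarchy(M=M, coordinates=coords, heights=heights)
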