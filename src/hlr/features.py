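"""Linkage-coordinate histogram features.

The i-th merge of an M-leaf hierarchy is an integer coordinate pair
``(a_i, b_i)`` with ``1 <= a_i < b_i <= 2M - 2``.  Binning the M - 1 pairs
on an R x R grid over the half-open index range ``(0, 2M - 1]`` and dividing
by M - 1 gives a 2-D histogram ``h`` whose entries sum to one and whose
strictly-lower triangle is identically zero (because ``b > a``).  Unrolling
the upper triangle row-major yields the feature vector of length
``R * (R + 1) / 2`` used for regression — e.g. 820 features for R = 40, 210
for R = 20.

Because the histogram depends only on the integer merge coordinates, the
feature vector is exactly invariant under translation and positive scaling
of the input points (those transforms preserve the distance ranking and
therefore the merge sequence).

A 1-D histogram of the merge *heights* (:func:`distance_histogram`,
:class:`DistanceHistogramFeaturizer`) is provided as an ablation baseline:
it carries only distance-magnitude information and, with a fixed bin range,
is *not* scale-invariant.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .hierarchy import (LinkageHierarchy, build_hierarchy, check_linkage_params,
                        validate_points)

__all__ = [
    "n_features",
    "linkage_histogram",
    "unroll",
    "roll",
    "featurize",
    "distance_histogram",
    "LinkageFeaturizer",
    "DistanceHistogramFeaturizer",
]


def n_features(R: int) -> int:
    """Length of the unrolled upper-triangle feature vector: R(R+1)/2."""
    if R < 1:
        raise ValueError("R must be a positive integer")
    return R * (R + 1) // 2


def linkage_histogram(hier: LinkageHierarchy, R: int) -> np.ndarray:
    """R x R histogram of the linkage coordinates, normalized by M - 1.

    Coordinate ``a`` falls in bin ``j`` when ``j * eps < a <= (j + 1) * eps``
    with bin width ``eps = (2M - 1) / R`` (left-open, right-closed), and
    likewise ``b`` in bin ``k``.  Since ``1 <= a < b <= 2M - 2``, every
    coordinate falls in exactly one bin and only the upper triangle
    (``k >= j``) can be populated.
    """
    if R < 1:
        raise ValueError("R must be a positive integer")
    M = hier.M
    a = hier.coordinates[:, 0]
    b = hier.coordinates[:, 1]
    denom = 2 * M - 1
    # bin index j = ceil(a * R / (2M - 1)) - 1, in exact integer arithmetic
    j = (a * R + denom - 1) // denom - 1
    k = (b * R + denom - 1) // denom - 1
    h = np.zeros((R, R))
    np.add.at(h, (j, k), 1.0 / (M - 1))
    return h


def unroll(h: np.ndarray) -> np.ndarray:
    """Unroll the diagonal-and-above entries of a square histogram, row-major.

    The entry at ``(j, k)`` with ``k >= j`` maps to position
    ``j * R - j * (j - 1) / 2 + (k - j)``; :func:`roll` is the exact inverse.
    """
    h = np.asarray(h)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("expected a square 2-D histogram")
    return h[np.triu_indices(h.shape[0])].copy()


def roll(f: np.ndarray, R: int) -> np.ndarray:
    """Rebuild the R x R upper-triangular histogram from its unrolled vector."""
    f = np.asarray(f).reshape(-1)
    if f.shape[0] != n_features(R):
        raise ValueError(f"expected length {n_features(R)} for R={R}, got {f.shape[0]}")
    h = np.zeros((R, R))
    h[np.triu_indices(R)] = f
    return h


def featurize(X, R: int = 40, linkage: str = "complete", metric: str = "l1") -> np.ndarray:
    """Point matrix -> unrolled linkage-coordinate feature vector."""
    hier = build_hierarchy(X, linkage=linkage, metric=metric)
    return unroll(linkage_histogram(hier, R))


def distance_histogram(X, n_bins: int = 200, metric: str = "l1",
                       linkage: str = "complete", hi: float | None = None) -> np.ndarray:
    """Normalized 1-D histogram of the M - 1 merge heights (ablation feature).

    Heights are binned uniformly on ``[0, hi]``; by default ``hi`` is the
    maximum height of the instance's own hierarchy.  Passing a fixed ``hi``
    (as :class:`DistanceHistogramFeaturizer` does after fitting) clips larger
    heights into the top bin, so the feature is then sensitive to the overall
    scale of the data — the property the ablation probes.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be a positive integer")
    hier = build_hierarchy(X, linkage=linkage, metric=metric)
    heights = hier.heights
    if hi is None:
        hi = float(heights.max())
    if hi <= 0:
        # degenerate: all merges at height zero
        h = np.zeros(n_bins)
        h[0] = 1.0
        return h
    counts, _ = np.histogram(np.clip(heights, 0.0, hi), bins=n_bins, range=(0.0, hi))
    return counts / heights.shape[0]


class LinkageFeaturizer(TransformerMixin, BaseEstimator):
    """Transform point sets into linkage-coordinate histogram features.

    A stateless sklearn transformer: ``transform`` maps a sequence of K
    point matrices (each of shape ``(M_i, n)``, ``M_i >= 2``) to a
    ``(K, R(R+1)/2)`` feature matrix whose rows each sum to one.

    Parameters
    ----------
    R : int, default 40
        Bins per histogram axis; feature length is R(R+1)/2.
    linkage : {'complete', 'single', 'ward'}, default 'complete'
    metric : {'l1', 'l2'}, default 'l1'
    """

    def __init__(self, R: int = 40, linkage: str = "complete", metric: str = "l1"):
        self.R = R
        self.linkage = linkage
        self.metric = metric

    def _validate(self):
        if self.R < 1:
            raise ValueError("R must be a positive integer")
        check_linkage_params(self.linkage, self.metric)

    def fit(self, X, y=None):
        self._validate()
        return self

    def transform(self, X) -> np.ndarray:
        self._validate()
        mats = _as_point_sets(X)
        return np.vstack([featurize(m, self.R, self.linkage, self.metric)
                          for m in mats])

    @property
    def n_features_out_(self) -> int:
        return n_features(self.R)


class DistanceHistogramFeaturizer(TransformerMixin, BaseEstimator):
    """Merge-height histogram features with a bin range fixed at fit time.

    ``fit`` records the largest merge height seen in the training instances;
    ``transform`` bins every instance's heights on ``[0, hi_]``, clipping
    overflow into the top bin.  With ``fixed_range=False`` each instance is
    binned on its own ``[0, max height]`` instead (which makes the feature
    scale-invariant and is mainly useful for diagnostics).
    """

    def __init__(self, n_bins: int = 200, linkage: str = "complete",
                 metric: str = "l1", fixed_range: bool = True):
        self.n_bins = n_bins
        self.linkage = linkage
        self.metric = metric
        self.fixed_range = fixed_range

    def fit(self, X, y=None):
        if self.n_bins < 1:
            raise ValueError("n_bins must be a positive integer")
        check_linkage_params(self.linkage, self.metric)
        hi = 0.0
        for m in _as_point_sets(X):
            hier = build_hierarchy(m, linkage=self.linkage, metric=self.metric)
            hi = max(hi, float(hier.heights.max()))
        self.hi_ = hi
        return self

    def transform(self, X) -> np.ndarray:
        hi = None
        if self.fixed_range:
            if not hasattr(self, "hi_"):
                raise ValueError("DistanceHistogramFeaturizer with fixed_range=True "
                                 "must be fitted before transform")
            hi = self.hi_
        return np.vstack([
            distance_histogram(m, self.n_bins, metric=self.metric,
                               linkage=self.linkage, hi=hi)
            for m in _as_point_sets(X)
        ])


def _as_point_sets(X) -> list[np.ndarray]:
    """Normalize input to a list of validated point matrices."""
    if isinstance(X, np.ndarray) and X.ndim == 2:
        X = [X]
    out = []
    for m in X:
        m = getattr(m, "points", m)  # accept ClusterInstance
        out.append(validate_points(m, min_rows=2))
    if not out:
        raise ValueError("empty input: need at least one point set")
    return out
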