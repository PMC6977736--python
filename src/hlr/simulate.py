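"""Synthetic clustered data with known ground-truth cluster counts.

Training data for hierarchical linkage regression is generated, never
collected: an instance with k clusters draws, for each cluster, a centroid
uniform on ``[w1, w2]`` per dimension, a per-dimension standard deviation
uniform on ``sigma_range``, and a size uniform on ``size_range``, then
samples points as ``centroid + Gaussian noise``.  Rows are shuffled so that
input order carries no cluster information (leaf indices enter the linkage
features, and real data arrive in arbitrary row order).

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so a training set is bit-reproducible
from its configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SyntheticConfig",
    "ClusterInstance",
    "TrainingSet",
    "generate_instance",
    "generate_training_set",
    "generate_fixed_total",
    "perturb_instance",
    "draw_cluster_counts",
]


@dataclass
class SyntheticConfig:
    """Generator settings for synthetic cluster instances.

    Parameters
    ----------
    dim : int
        Embedding dimension ``d_E`` of the generated points.  Should be at
        least the dimensionality of any real dataset the trained model will
        score.
    k_range : (int, int)
        Inclusive range of cluster counts per instance.
    size_range : (int, int)
        Inclusive range of per-cluster point counts.
    centroid_interval : (float, float)
        Per-dimension uniform interval for cluster centroids.
    sigma_range : (float, float)
        Per-cluster, per-dimension uniform interval for the Gaussian noise
        standard deviation.
    seed : int
        Master seed; every instance derives its own child seed from it.
    """

    dim: int = 50
    k_range: tuple[int, int] = (1, 30)
    size_range: tuple[int, int] = (50, 1000)
    centroid_interval: tuple[float, float] = (0.0, 10.0)
    sigma_range: tuple[float, float] = (0.25, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        k1, k2 = self.k_range
        if not (1 <= k1 <= k2):
            raise ValueError("k_range must satisfy 1 <= k_min <= k_max")
        s1, s2 = self.size_range
        if not (2 <= s1 <= s2):
            raise ValueError("size_range must satisfy 2 <= s_min <= s_max")
        w1, w2 = self.centroid_interval
        if not w1 < w2:
            raise ValueError("centroid_interval must satisfy w1 < w2")
        g1, g2 = self.sigma_range
        if not (0 < g1 <= g2):
            raise ValueError("sigma_range must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClusterInstance:
    """One clustered point set with its ground truth.

    ``sizes`` are the drawn per-cluster sizes (in draw order, before row
    shuffling); ``sum(sizes) == points.shape[0]`` and
    ``len(sizes) == n_clusters``.
    """

    points: np.ndarray
    n_clusters: int
    sizes: tuple[int, ...]
    seed: int | None = None
    labels: np.ndarray | None = None  # per-row cluster id, for diagnostics
    centroids: np.ndarray | None = None  # (k, dim) drawn centroids
    sigmas: np.ndarray | None = None  # (k, dim) drawn noise standard deviations

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.sizes = tuple(int(s) for s in self.sizes)
        if len(self.sizes) != self.n_clusters:
            raise ValueError("len(sizes) must equal n_clusters")
        if sum(self.sizes) != self.points.shape[0]:
            raise ValueError("sizes must sum to the number of rows")

    @property
    def M(self) -> int:
        return self.points.shape[0]


@dataclass
class TrainingSet:
    """K labelled cluster instances."""

    instances: list[ClusterInstance]
    labels: np.ndarray
    config: SyntheticConfig | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.instances) != len(self.labels):
            raise ValueError("one label per instance required")

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[ClusterInstance]:
        return iter(self.instances)

    def point_sets(self) -> list[np.ndarray]:
        return [inst.points for inst in self.instances]


def _materialize(sizes: Sequence[int], config: SyntheticConfig,
                 rng: np.random.Generator, seed: int | None) -> ClusterInstance:
    """Draw centroids/sigmas, sample points for the given sizes, shuffle rows."""
    w1, w2 = config.centroid_interval
    g1, g2 = config.sigma_range
    blocks, labels, centroids, sigmas = [], [], [], []
    for ci, size in enumerate(sizes):
        centroid = rng.uniform(w1, w2, size=config.dim)
        sigma = rng.uniform(g1, g2, size=config.dim)
        blocks.append(centroid + rng.normal(0.0, 1.0, size=(size, config.dim)) * sigma)
        labels.append(np.full(size, ci))
        centroids.append(centroid)
        sigmas.append(sigma)
    points = np.concatenate(blocks, axis=0)
    labels = np.concatenate(labels)
    perm = rng.permutation(points.shape[0])
    return ClusterInstance(points=points[perm], n_clusters=len(sizes),
                           sizes=tuple(sizes), seed=seed, labels=labels[perm],
                           centroids=np.vstack(centroids), sigmas=np.vstack(sigmas))


def generate_instance(k: int, config: SyntheticConfig,
                      seed: int | None = None) -> ClusterInstance:
    """Generate one instance with ``k`` Gaussian clusters of random sizes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    s1, s2 = config.size_range
    sizes = rng.integers(s1, s2 + 1, size=k)
    return _materialize(sizes, config, rng, seed)


def draw_cluster_counts(K: int, config: SyntheticConfig) -> np.ndarray:
    """The vector of K ground-truth cluster counts a training set will use.

    Counts are uniform on ``k_range`` and depend only on ``config.seed``,
    so label-level properties (coverage, balance) can be checked without
    materializing any points.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    k1, k2 = config.k_range
    return rng.integers(k1, k2 + 1, size=K)


def generate_training_set(K: int, config: SyntheticConfig) -> TrainingSet:
    """Generate K instances with cluster counts uniform on ``k_range``.

    Fully reproducible from ``config.seed``: instance i is generated from
    the i-th spawned child of the master seed sequence.
    """
    ks = draw_cluster_counts(K, config)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(K + 1)[1:]  # child 0 is the label stream
    instances = []
    for i, k in enumerate(ks):
        rng = np.random.default_rng(children[i])
        s1, s2 = config.size_range
        sizes = rng.integers(s1, s2 + 1, size=int(k))
        instances.append(_materialize(sizes, config, rng, seed=None))
    return TrainingSet(instances=instances, labels=ks, config=config)


def generate_fixed_total(M_total: int, k: int, config: SyntheticConfig,
                         seed: int | None = None) -> ClusterInstance:
    """Instance with exactly ``M_total`` points split into ``k`` clusters.

    Sizes are an unequal random composition with every cluster >= 2 points
    (two guaranteed points plus a uniform multinomial split of the rest).
    Used for the fixed-point-count control: the model must infer k while M
    stays constant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > M_total:
        raise ValueError(f"cannot split {M_total} points into {k} clusters of >= 2")
    rng = np.random.default_rng(seed)
    sizes = 2 + rng.multinomial(M_total - 2 * k, np.full(k, 1.0 / k))
    return _materialize(sizes, config, rng, seed)


def perturb_instance(inst: ClusterInstance, scale: float = 1.0,
                     jitter_frac: float = 0.0,
                     seed: int | None = None) -> ClusterInstance:
    """Rescale and jitter an instance without changing its ground truth.

    Returns ``scale * X`` plus Gaussian noise with per-feature standard
    deviation ``jitter_frac`` times the (scaled) per-feature std.  With
    ``scale=1, jitter_frac=0`` the points are returned unchanged.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if jitter_frac < 0:
        raise ValueError("jitter_frac must be >= 0")
    X = inst.points if scale == 1.0 else scale * inst.points
    if jitter_frac > 0:
        rng = np.random.default_rng(seed)
        std = X.std(axis=0)
        X = X + rng.normal(0.0, 1.0, size=X.shape) * (jitter_frac * std)
    return ClusterInstance(points=X, n_clusters=inst.n_clusters,
                           sizes=inst.sizes, seed=seed, labels=inst.labels)
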