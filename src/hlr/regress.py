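"""Neural-network regression on linkage-coordinate features.

:class:`HierarchicalLinkageRegressor` is the end-to-end estimator: ``fit``
takes a list of point matrices with their true cluster counts (normally a
synthetic :class:`~hlr.simulate.TrainingSet`), featurizes each through the
linkage-coordinate histogram, and trains a two-hidden-layer feedforward
network with a single linear output unit on the regularized MSE cost

    E = (1/K) * sum (y - y_hat)^2 + (beta/K) * sum phi^2

``predict`` featurizes new point sets internally with the stored feature
settings and returns the continuous (raw) inference; ``predict_count``
rounds half-away-from-zero and clamps to >= 1; :func:`ensemble_median`
implements the median-of-rounded-inferences protocol for ensembles of
independently initialized models.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from . import __version__ as _pkg_version
from .features import LinkageFeaturizer, n_features
from .simulate import ClusterInstance, TrainingSet

__all__ = [
    "HierarchicalLinkageRegressor",
    "cost",
    "build_feature_matrix",
    "round_half_away",
    "ensemble_median",
    "FeatureSpecMismatch",
]

_ACTIVATIONS = {"relu": "relu", "sigmoid": "logistic"}
_SOLVERS = {"adam": "adam", "lbfgs": "lbfgs"}


class FeatureSpecMismatch(ValueError):
    """Features were produced under a different (R, linkage, metric) than the model's."""


def cost(y, y_hat, weights=(), beta: float = 0.0) -> float:
    """Regularized mean-squared-error cost.

    ``(1/K) * sum (y - y_hat)^2 + (beta/K) * sum_i,j phi_ij^2`` where the
    second sum runs over all entries of the weight arrays in ``weights``.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    y_hat = np.asarray(y_hat, dtype=float).reshape(-1)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {y_hat.shape[0]}")
    K = y.shape[0]
    if K == 0:
        raise ValueError("empty input")
    if isinstance(weights, np.ndarray):
        weights = [weights]
    penalty = sum(float(np.sum(np.square(w))) for w in weights)
    return float(np.mean((y - y_hat) ** 2) + beta * penalty / K)


def round_half_away(x):
    """Round to nearest integer with halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(int) if out.ndim else int(out)


def _net_seeds(random_state, n: int) -> list:
    """Deterministic per-net seeds derived from the estimator seed."""
    if n == 1:
        return [random_state]
    ss = np.random.SeedSequence(random_state)
    return [int(x % (2 ** 31)) for x in ss.generate_state(n)]


def _unpack(X, y=None):
    """Accept a TrainingSet, a list of ClusterInstance, or a list of arrays."""
    if isinstance(X, TrainingSet):
        if y is None:
            y = X.labels
        X = X.point_sets()
    else:
        X = list(X)
        if y is None and X and isinstance(X[0], ClusterInstance):
            y = np.array([inst.n_clusters for inst in X])
        X = [getattr(m, "points", m) for m in X]
    return X, y


def build_feature_matrix(instances, R: int = 40, linkage: str = "complete",
                         metric: str = "l1"):
    """Featurize a collection of instances into a (K, R(R+1)/2) matrix.

    Rows are instances (sklearn orientation) and each row sums to one.
    Returns ``(F, labels)`` where ``labels`` is None unless the instances
    carry ground-truth cluster counts.
    """
    X, y = _unpack(instances)
    if not X:
        raise ValueError("empty input: need at least one instance")
    F = LinkageFeaturizer(R=R, linkage=linkage, metric=metric).fit_transform(X)
    return F, (None if y is None else np.asarray(y, dtype=int))


class HierarchicalLinkageRegressor(RegressorMixin, BaseEstimator):
    """Blind cluster-count estimator trained on synthetic linkage features.

    Parameters
    ----------
    R : int, default 40
        Histogram bins per axis; the network input has R(R+1)/2 features.
    linkage : {'complete', 'single', 'ward'}, default 'complete'
    metric : {'l1', 'l2'}, default 'l1'
        Linkage type and point metric used to build hierarchies, at fit and
        predict time alike.
    hidden_layer_sizes : (int, int), default (64, 32)
        Exactly two hidden layers.
    activation : {'relu', 'sigmoid'}, default 'relu'
        Hidden-layer activation; the output unit is always linear.
    beta : float, default 0.2
        L2 regularization weight of the cost function.
    solver : {'adam', 'lbfgs'}, default 'adam'
        'adam' is the adaptive stochastic solver; 'lbfgs' is a full-batch
        quasi-Newton alternative (deterministic given the seed, no early
        stopping).
    input_transform : {'sqrt', 'identity'}, default 'sqrt'
        Fixed elementwise map applied to the feature vector at the network
        input.  The square root stabilizes the variance of the normalized
        histogram counts (whose entries span several orders of magnitude at
        large M) and markedly improves network convergence and
        generalization; it is data-independent, so it preserves the
        translation and scale invariance of the features.  'identity' feeds
        the raw histogram.
    n_nets : int, default 1
        Number of independently initialized networks trained on the same
        features; the raw inference is their mean.  A small committee
        reduces initialization variance (the reference inference protocol
        for benchmark tables instead trains separate models and takes the
        median of rounded outputs; see :func:`ensemble_median`).
    max_iter : int, default 2000
    early_stopping : bool, default True
        Stop adam when the score on a held-out validation split stops
        improving.  The split is only ever used to stop training, never to
        tune per-dataset.
    validation_fraction : float, default 0.1
    tol : float, default 1e-5
    random_state : int or None
        Seeds weight initialization (and adam's shuffling/validation split).

    Attributes
    ----------
    mlps_ : list of fitted :class:`sklearn.neural_network.MLPRegressor`
        The internal committee (``mlp_`` is shorthand for the first).
    feature_spec_ : dict
        ``{'R', 'linkage', 'metric', 'd_E'}`` fingerprint of the features
        the model was trained on.  ``d_E`` is the training embedding
        dimension; scoring wider data triggers a warning.
    loss_curve_ : list of float or None
        Per-iteration training loss (adam only).

    Examples
    --------
    >>> from hlr.simulate import SyntheticConfig, generate_training_set
    >>> cfg = SyntheticConfig(dim=5, k_range=(1, 5), size_range=(20, 60), seed=0)
    >>> ts = generate_training_set(120, cfg)
    >>> model = HierarchicalLinkageRegressor(R=10, random_state=0).fit(ts)
    >>> model.predict_count(ts.instances[0].points)  # doctest: +SKIP
    3
    """

    def __init__(self, R: int = 40, linkage: str = "complete", metric: str = "l1",
                 hidden_layer_sizes: tuple[int, int] = (64, 32),
                 activation: str = "relu", beta: float = 0.2,
                 solver: str = "adam", input_transform: str = "sqrt",
                 n_nets: int = 1, max_iter: int = 2000,
                 early_stopping: bool = True, validation_fraction: float = 0.1,
                 tol: float = 1e-5, random_state: int | None = None):
        self.R = R
        self.linkage = linkage
        self.metric = metric
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.beta = beta
        self.solver = solver
        self.input_transform = input_transform
        self.n_nets = n_nets
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _check_params(self):
        if len(tuple(self.hidden_layer_sizes)) != 2:
            raise ValueError("the network has exactly two hidden layers; "
                             f"got hidden_layer_sizes={self.hidden_layer_sizes!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {tuple(_ACTIVATIONS)}")
        if self.solver not in _SOLVERS:
            raise ValueError(f"solver must be one of {tuple(_SOLVERS)}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.input_transform not in ("sqrt", "identity"):
            raise ValueError("input_transform must be 'sqrt' or 'identity'")
        if int(self.n_nets) < 1:
            raise ValueError("n_nets must be >= 1")

    def _transform_input(self, F: np.ndarray) -> np.ndarray:
        if self.input_transform == "sqrt":
            return np.sqrt(np.maximum(F, 0.0))
        return F

    def _make_mlp(self) -> MLPRegressor:
        kwargs = dict(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation=_ACTIVATIONS[self.activation],
            solver=_SOLVERS[self.solver],
            alpha=float(self.beta),  # sklearn's L2 term matches beta exactly
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        if self.solver == "adam":
            # generous patience: the validation score is noisy on small
            # corpora and the best epoch's weights are restored on stop
            kwargs.update(early_stopping=self.early_stopping,
                          validation_fraction=self.validation_fraction,
                          n_iter_no_change=max(100, self.max_iter // 10))
        return MLPRegressor(**kwargs)

    def fit(self, X, y=None):
        """Fit on point sets (TrainingSet, ClusterInstances, or arrays) + counts."""
        self._check_params()
        X, y = _unpack(X, y)
        if y is None:
            raise ValueError("ground-truth cluster counts are required to fit")
        F = LinkageFeaturizer(R=self.R, linkage=self.linkage,
                              metric=self.metric).fit_transform(X)
        dims = {m.shape[1] for m in (np.asarray(m) for m in X)}
        d_E = max(dims)
        return self.fit_features(F, y, d_E=d_E)

    def fit_features(self, F, y, d_E: int | None = None):
        """Fit directly on a precomputed (K, R(R+1)/2) feature matrix."""
        self._check_params()
        F = np.asarray(F, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if F.ndim != 2 or F.shape[0] != y.shape[0]:
            raise ValueError("feature matrix and labels are inconsistent")
        if F.shape[0] < 2:
            raise ValueError("need at least K=2 training instances")
        expected = n_features(self.R)
        if F.shape[1] != expected:
            raise FeatureSpecMismatch(
                f"feature length {F.shape[1]} does not match R={self.R} "
                f"(expected {expected})")
        if not np.all(np.isfinite(F)):
            raise ValueError("non-finite feature values")
        if np.all(y == y[0]):
            warnings.warn("all training labels are equal; the regression is "
                          "degenerate", UserWarning)
        Ft = self._transform_input(F)
        seeds = _net_seeds(self.random_state, int(self.n_nets))
        self.mlps_ = []
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
            warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")
            for seed in seeds:
                mlp = self._make_mlp()
                mlp.random_state = seed
                self.mlps_.append(mlp.fit(Ft, y))
        self.feature_spec_ = {"R": int(self.R), "linkage": self.linkage,
                              "metric": self.metric,
                              "d_E": None if d_E is None else int(d_E)}
        self.loss_curve_ = list(getattr(self.mlp_, "loss_curve_", []) or []) or None
        self.n_features_in_ = expected
        return self

    @property
    def mlp_(self) -> MLPRegressor:
        """The first (or only) fitted network of the internal committee."""
        check_is_fitted(self, "mlps_")
        return self.mlps_[0]

    # -------------------------------------------------------------- predict

    def _featurize(self, X) -> np.ndarray:
        X, _ = _unpack(X)
        d_E = self.feature_spec_.get("d_E")
        if d_E is not None:
            widest = max(np.asarray(m).shape[1] for m in X)
            if widest > d_E:
                warnings.warn(
                    f"scoring {widest}-dimensional data with a model trained at "
                    f"embedding dimension d_E={d_E}; the training embedding "
                    "dimension should be at least the data dimensionality",
                    UserWarning)
        return LinkageFeaturizer(R=self.R, linkage=self.linkage,
                                 metric=self.metric).transform(X)

    def predict(self, X):
        """Raw (continuous) cluster-count inference.

        ``X`` may be a single point matrix (returns a float) or a sequence
        of point matrices (returns an array, one raw inference per
        instance).  Featurization happens internally with the model's
        stored settings, so predictions inherit the exact translation and
        positive-scale invariance of the features.
        """
        check_is_fitted(self, "mlps_")
        single = isinstance(X, np.ndarray) and X.ndim == 2
        raw = self.predict_features(self._featurize([X] if single else X))
        return float(raw[0]) if single else raw

    def predict_features(self, F) -> np.ndarray:
        """Raw inference on a precomputed feature matrix (spec-checked)."""
        check_is_fitted(self, "mlps_")
        F = np.asarray(F, dtype=float)
        if F.ndim != 2 or F.shape[1] != n_features(self.R):
            raise FeatureSpecMismatch(
                f"expected {n_features(self.R)} features (R={self.R}), "
                f"got shape {F.shape}")
        Ft = self._transform_input(F)
        return np.mean([mlp.predict(Ft) for mlp in self.mlps_], axis=0)

    def predict_per_net(self, X) -> np.ndarray:
        """Raw inference of each committee member, shape (n_nets, n_instances).

        Lets a committee double as an ensemble for the
        median-of-rounded-inferences protocol without retraining.
        """
        check_is_fitted(self, "mlps_")
        X, _ = _unpack([X] if isinstance(X, np.ndarray) and X.ndim == 2 else X)
        Ft = self._transform_input(self._featurize(X))
        return np.vstack([mlp.predict(Ft) for mlp in self.mlps_])

    def predict_count(self, X):
        """Rounded (half-away-from-zero) inference, clamped to >= 1."""
        raw = self.predict(X)
        return int(max(1, round_half_away(raw))) if np.isscalar(raw) \
            else np.maximum(1, round_half_away(raw))

    def check_feature_spec(self, spec: dict) -> None:
        """Raise :class:`FeatureSpecMismatch` unless ``spec`` matches the model's."""
        check_is_fitted(self, "feature_spec_")
        for key in ("R", "linkage", "metric"):
            if key in spec and spec[key] != self.feature_spec_[key]:
                raise FeatureSpecMismatch(
                    f"model was trained with {key}={self.feature_spec_[key]!r} "
                    f"but the features were produced with {key}={spec[key]!r}")

    # -------------------------------------------------------- serialization

    def save(self, path) -> None:
        """Serialize to a portable JSON archive (bit-exact on reload)."""
        check_is_fitted(self, "mlps_")
        doc = {
            "format": "hlr-model",
            "version": _pkg_version,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "feature_spec": self.feature_spec_,
            "loss_curve": self.loss_curve_,
            "networks": [{
                "coefs": [w.tolist() for w in mlp.coefs_],
                "intercepts": [b.tolist() for b in mlp.intercepts_],
                "n_features_in": int(mlp.n_features_in_),
                "out_activation": mlp.out_activation_,
            } for mlp in self.mlps_],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "HierarchicalLinkageRegressor":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "hlr-model":
            raise ValueError(f"{path} is not a model archive")
        params = dict(doc["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        model.mlps_ = []
        for net in doc["networks"]:
            mlp = model._make_mlp()
            mlp.coefs_ = [np.asarray(w, dtype=float) for w in net["coefs"]]
            mlp.intercepts_ = [np.asarray(b, dtype=float) for b in net["intercepts"]]
            mlp.n_features_in_ = net["n_features_in"]
            mlp.n_layers_ = len(mlp.coefs_) + 1
            mlp.n_outputs_ = 1
            mlp.out_activation_ = net["out_activation"]
            model.mlps_.append(mlp)
        model.feature_spec_ = doc["feature_spec"]
        model.loss_curve_ = doc.get("loss_curve")
        model.n_features_in_ = doc["networks"][0]["n_features_in"]
        return model


def ensemble_median(models, X) -> int | np.ndarray:
    """Median of the rounded inferences of an ensemble of models.

    Each model's raw output is rounded half-away-from-zero; the median of
    the rounded values is taken across models (and rounded again, for
    even-sized ensembles whose median lands on a half-integer) and clamped
    to >= 1.  All models must share a feature spec.
    """
    models = list(models)
    if not models:
        raise ValueError("empty ensemble")
    ref = models[0].feature_spec_
    for m in models[1:]:
        m.check_feature_spec(ref)
    single = isinstance(X, np.ndarray) and X.ndim == 2
    rounded = np.array([round_half_away(np.atleast_1d(m.predict(X)))
                        for m in models])  # (n_models, n_instances)
    med = np.median(rounded, axis=0)
    out = np.maximum(1, round_half_away(med))
    return int(out[0]) if single else out
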