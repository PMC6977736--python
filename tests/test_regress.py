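"""Regressor mechanics: cost, training, prediction, ensembles, persistence."""

import numpy as np
import pytest

from hlr.features import n_features
from hlr.regress import (FeatureSpecMismatch, HierarchicalLinkageRegressor,
                         build_feature_matrix, cost, ensemble_median,
                         round_half_away)
from hlr.simulate import SyntheticConfig, generate_training_set

TINY = SyntheticConfig(dim=3, k_range=(1, 4), size_range=(10, 30),
                       sigma_range=(0.05, 0.2), seed=77)


@pytest.fixture(scope="module")
def tiny_set():
    return generate_training_set(24, TINY)


@pytest.fixture(scope="module")
def tiny_model(tiny_set):
    return HierarchicalLinkageRegressor(
        R=8, hidden_layer_sizes=(16, 8), solver="lbfgs", max_iter=2000,
        random_state=0).fit(tiny_set)


# --------------------------------------------------------------------- cost

def test_cost_vanishes_at_perfect_fit():
    assert cost([1, 2, 3], [1, 2, 3], [np.ones((2, 2))], beta=0.0) == 0.0


def test_cost_direct_substitution():
    # K=1, squared error 1, penalty 0.5 * 4 / 1 = 2
    phi = [np.array([[2.0]]), np.array([0.0])]  # sum of squares = 4
    assert cost([3.0], [2.0], phi, beta=0.5) == pytest.approx(3.0)


def test_cost_penalty_monotone_in_beta(rng):
    y, yh = rng.normal(size=10), rng.normal(size=10)
    w = [rng.normal(size=(4, 3))]
    assert cost(y, yh, w, beta=0.8) >= cost(y, yh, w, beta=0.2)
    with pytest.raises(ValueError):
        cost([1, 2], [1], beta=0.1)


def test_round_half_away_from_zero():
    assert round_half_away(2.5) == 3
    assert round_half_away(-2.5) == -3
    assert round_half_away(0.3) == 0
    assert round_half_away(np.array([2.4, 2.6, 3.4])).tolist() == [2, 3, 3]


# ----------------------------------------------------------- feature matrix

def test_feature_matrix_shape_and_column_sums(tiny_set):
    F, y = build_feature_matrix(tiny_set, R=8)
    assert F.shape == (24, n_features(8))
    assert F.sum(axis=1) == pytest.approx(np.ones(24))
    assert np.array_equal(y, tiny_set.labels)
    F1, y1 = build_feature_matrix([tiny_set.instances[0]], R=8)
    assert F1.shape == (1, n_features(8))
    with pytest.raises(ValueError):
        build_feature_matrix([], R=8)


# ----------------------------------------------------------------- training

def test_memorization_of_separated_instances(tiny_set):
    # beta=0 and a full-batch solver: the net should fit 20 easy instances
    model = HierarchicalLinkageRegressor(
        R=8, hidden_layer_sizes=(32, 16), beta=0.0, solver="lbfgs",
        max_iter=4000, random_state=0).fit(tiny_set.instances[:20])
    pred = model.predict([i.points for i in tiny_set.instances[:20]])
    mse = float(np.mean((pred - tiny_set.labels[:20]) ** 2))
    assert mse < 0.1


def test_two_hidden_layers_required():
    with pytest.raises(ValueError, match="two hidden"):
        HierarchicalLinkageRegressor(hidden_layer_sizes=(64,)).fit_features(
            np.ones((3, 820)) / 820, [1, 2, 3])


def test_full_batch_training_is_deterministic(tiny_set):
    F, y = build_feature_matrix(tiny_set, R=8)
    kw = dict(R=8, hidden_layer_sizes=(16, 8), solver="lbfgs", max_iter=500,
              random_state=3)
    a = HierarchicalLinkageRegressor(**kw).fit_features(F, y)
    b = HierarchicalLinkageRegressor(**kw).fit_features(F, y)
    for wa, wb in zip(a.mlp_.coefs_, b.mlp_.coefs_):
        assert np.array_equal(wa, wb)


def test_degenerate_labels_warn(tiny_set):
    F, _ = build_feature_matrix(tiny_set.instances[:4], R=8)
    with pytest.warns(UserWarning, match="degenerate"):
        HierarchicalLinkageRegressor(R=8, solver="lbfgs", max_iter=10,
                                     random_state=0).fit_features(F, [2, 2, 2, 2])


# --------------------------------------------------------------- prediction

def test_prediction_invariant_to_translation_and_scale(tiny_model, tiny_set):
    X = tiny_set.instances[0].points
    raw = tiny_model.predict(X)
    assert isinstance(raw, float)
    assert tiny_model.predict(X + 42.0) == raw
    assert tiny_model.predict(3.0 * X) == raw


def test_predict_count_clamps_to_one(tiny_model, tiny_set):
    assert tiny_model.predict_count(tiny_set.instances[0].points) >= 1


def test_feature_spec_is_enforced(tiny_model):
    with pytest.raises(FeatureSpecMismatch):
        tiny_model.predict_features(np.ones((2, 210)) / 210)  # R=20 features
    with pytest.raises(FeatureSpecMismatch):
        tiny_model.check_feature_spec({"R": 40})
    tiny_model.check_feature_spec(tiny_model.feature_spec_)  # no raise


def test_embedding_dimension_warning(tiny_model, rng):
    # model trained at d_E=3; scoring 6-dimensional data warns
    with pytest.warns(UserWarning, match="embedding dimension"):
        tiny_model.predict(rng.normal(size=(12, 6)))


# ---------------------------------------------------------------- ensembles

class _Stub:
    """Minimal model double with a fixed raw output."""

    def __init__(self, raw):
        self.raw = raw
        self.feature_spec_ = {"R": 8, "linkage": "complete", "metric": "l1",
                              "d_E": 3}

    def predict(self, X):
        return self.raw

    def check_feature_spec(self, spec):
        pass


def test_ensemble_median_of_rounded_inferences():
    X = np.zeros((3, 2))
    models = [_Stub(2.4), _Stub(2.6), _Stub(3.4)]  # rounded: 2, 3, 3
    assert ensemble_median(models, X) == 3
    assert ensemble_median([_Stub(0.3)], X) == 1  # clamped
    with pytest.raises(ValueError):
        ensemble_median([], X)


def test_ensemble_agrees_with_single_model(tiny_model, tiny_set):
    X = tiny_set.instances[1].points
    assert ensemble_median([tiny_model], X) == tiny_model.predict_count(X)


# -------------------------------------------------------------- persistence

def test_save_load_round_trip_is_bit_exact(tiny_model, tiny_set, tmp_path):
    path = tmp_path / "model.json"
    tiny_model.save(path)
    loaded = HierarchicalLinkageRegressor.load(path)
    assert loaded.feature_spec_ == tiny_model.feature_spec_
    for inst in tiny_set.instances[:5]:
        assert loaded.predict(inst.points) == tiny_model.predict(inst.points)
    for wa, wb in zip(loaded.mlp_.coefs_, tiny_model.mlp_.coefs_):
        assert np.array_equal(wa, wb)
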