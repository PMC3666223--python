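import numpy as np
import pytest

from bispecg import (
    ACTIVATIONS,
    DataError,
    LabeledFeatures,
    grid_search_hidden,
    hidden_output_matrix,
    one_hot,
    predict,
    pseudoinverse,
    train_elm,
)
from bispecg.elm import ELMModel, load_model, save_model
from oracles import naive_hidden_matrix


def blobs(n_per_class=100, n_features=5, separation=6.0, seed=0):
    """Two linearly separable Gaussian blobs (unit sigma, stated separation)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, n_features))
    b = rng.standard_normal((n_per_class, n_features)) + separation / np.sqrt(n_features)
    X = np.vstack([a, b])
    Y, names = one_hot(["a"] * n_per_class + ["b"] * n_per_class)
    return LabeledFeatures(X, Y, names)


class TestHiddenMatrix:
    def test_sigmoid_at_zero_is_half(self):
        H = hidden_output_matrix(np.zeros((4, 3)), np.zeros(4), "sigmoid", np.zeros((5, 3)))
        assert np.array_equal(H, np.full((5, 4), 0.5))

    def test_hardlim_is_binary(self, rng):
        H = hidden_output_matrix(rng.standard_normal((6, 3)), rng.standard_normal(6),
                                 "hardlim", rng.standard_normal((10, 3)))
        assert set(np.unique(H)) <= {0.0, 1.0}

    def test_sine_matches_scalar_loop_oracle(self, rng):
        W, b = rng.standard_normal((4, 3)), rng.standard_normal(4)
        X = rng.standard_normal((5, 3))
        H = hidden_output_matrix(W, b, "sine", X)
        assert np.abs(H - naive_hidden_matrix(W, b, ACTIVATIONS["sine"], X)).max() < 1e-12

    def test_saturation_never_nonfinite(self):
        X = np.array([[1e300, -1e300]])
        for act in ACTIVATIONS:
            H = hidden_output_matrix(np.ones((2, 2)), np.zeros(2), act, X)
            assert np.all(np.isfinite(H))


class TestPseudoinverse:
    def test_identity(self):
        assert np.allclose(pseudoinverse(np.eye(4)), np.eye(4), atol=1e-12)

    def test_singular_diagonal(self):
        P = pseudoinverse(np.diag([2.0, 0.0]))
        assert np.allclose(P, np.diag([0.5, 0.0]), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_four_penrose_conditions_rank_deficient(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((6, 3)) @ rng.standard_normal((3, 4))  # rank 3, 6x4
        P = pseudoinverse(H)
        s = np.abs(H).max()
        assert np.abs(H @ P @ H - H).max() < 1e-8 * s
        assert np.abs(P @ H @ P - P).max() < 1e-8
        assert np.abs((H @ P) - (H @ P).T).max() < 1e-8
        assert np.abs((P @ H) - (P @ H).T).max() < 1e-8


class TestTraining:
    def test_exact_interpolation_when_square_full_rank(self):
        data = blobs(n_per_class=10, seed=1)  # N = 20
        model = train_elm(data, hidden=20, seed=1)
        X = (data.features - model.feature_mean) / model.feature_scale
        H = hidden_output_matrix(model.input_weights, model.biases, model.activation, X)
        assert np.linalg.norm(H @ model.output_weights - data.targets) <= 1e-8
        pred, _ = predict(model, data.features)
        assert np.array_equal(pred, data.labels)  # 100% training accuracy

    def test_single_neuron_closed_form(self):
        data = blobs(n_per_class=20, seed=2)
        model = train_elm(data, hidden=1, seed=2, standardize=False)
        h = hidden_output_matrix(model.input_weights, model.biases,
                                 model.activation, data.features)[:, 0]
        beta_ls = (h @ data.targets) / (h @ h)  # scalar least squares per output
        assert np.allclose(model.output_weights[0], beta_ls, rtol=1e-10)

    def test_seeded_determinism_bitwise(self):
        data = blobs(seed=3)
        m1 = train_elm(data, hidden=8, seed=42)
        m2 = train_elm(data, hidden=8, seed=42)
        assert np.array_equal(m1.input_weights, m2.input_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)
        m3 = train_elm(data, hidden=8, seed=43)
        assert not np.array_equal(m1.input_weights, m3.input_weights)

    def test_least_squares_optimality(self, rng):
        data = blobs(n_per_class=30, seed=4)
        model = train_elm(data, hidden=10, seed=4, standardize=False)
        H = hidden_output_matrix(model.input_weights, model.biases,
                                 model.activation, data.features)
        Y = data.targets
        res = np.linalg.norm(H @ model.output_weights - Y)
        # normal-equations oracle (full column rank here)
        beta_ne = np.linalg.solve(H.T @ H, H.T @ Y)
        assert res <= np.linalg.norm(H @ beta_ne - Y) + 1e-8
        for _ in range(100):
            alt = model.output_weights + rng.standard_normal(model.output_weights.shape)
            assert res <= np.linalg.norm(H @ alt - Y) + 1e-8

    def test_training_error_monotone_in_nested_hidden_size(self):
        data = blobs(n_per_class=32, seed=5)  # N = 64
        errors = []
        for M in (1, 2, 4, 8, 16, 32, 64):
            model = train_elm(data, hidden=M, seed=7)
            _, raw = predict(model, data.features)
            errors.append(np.linalg.norm(raw - data.targets))
        # same seed draws per-neuron blocks: smaller nets are prefixes, so
        # the residual can only shrink as columns are added
        assert all(b <= a + 1e-8 for a, b in zip(errors, errors[1:]))
        m_small = train_elm(data, hidden=4, seed=7)
        m_big = train_elm(data, hidden=16, seed=7)
        assert np.array_equal(m_big.input_weights[:4], m_small.input_weights)

    def test_separable_blobs_high_test_accuracy(self):
        train = blobs(n_per_class=100, separation=6.0, seed=6)
        test = blobs(n_per_class=100, separation=6.0, seed=60)
        model = train_elm(train, hidden=20, activation="sigmoid", seed=6)
        pred, _ = predict(model, test.features)
        assert (pred == test.labels).mean() >= 0.99


class TestPrediction:
    def _trivial_model(self, beta):
        return ELMModel(
            input_weights=np.zeros((2, 3)), biases=np.zeros(2),
            output_weights=beta, activation="sigmoid",
            n_features=3, n_classes=3, seed=0, class_names=["a", "b", "c"],
        )

    def test_tie_breaks_to_lowest_class_index(self):
        # H is all 0.5; craft beta so raw outputs are [0.2, 0.2, 0.1]
        beta = np.array([[0.2, 0.2, 0.1], [0.2, 0.2, 0.1]])
        pred, raw = predict(self._trivial_model(beta), np.zeros((1, 3)))
        assert np.allclose(raw, [[0.2, 0.2, 0.1]])
        assert pred[0] == 0

    def test_zero_weights_all_class_zero(self):
        pred, raw = predict(self._trivial_model(np.zeros((2, 3))), np.ones((4, 3)))
        assert np.all(raw == 0) and np.all(pred == 0)

    def test_width_mismatch(self):
        with pytest.raises(DataError):
            predict(self._trivial_model(np.zeros((2, 3))), np.zeros((2, 5)))


class TestHelpers:
    def test_one_hot_rejects_unknown_and_validates(self):
        Y, names = one_hot(["N", "S", "N"])
        assert names == ["N", "S"] and Y.tolist() == [[1, 0], [0, 1], [1, 0]]
        with pytest.raises(DataError):
            one_hot(["N", "X"], class_names=["N", "S"])
        with pytest.raises(DataError):
            LabeledFeatures(np.zeros((2, 2)), np.array([[0.5, 0.5], [1, 0]]), ["a", "b"])

    def test_grid_search_returns_candidate(self):
        data = blobs(n_per_class=40, seed=8)
        best, scores = grid_search_hidden(data, candidates=(2, 5, 10), seed=8)
        assert best in (2, 5, 10) and set(scores) == {2, 5, 10}
        assert scores[best] == max(scores.values())

    def test_model_archive_round_trip(self, tmp_path):
        model = train_elm(blobs(seed=9), hidden=6, seed=9)
        save_model(tmp_path / "m.npz", model)
        back = load_model(tmp_path / "m.npz")
        assert np.array_equal(back.output_weights, model.output_weights)
        assert back.class_names == model.class_names
        assert np.array_equal(back.feature_mean, model.feature_mean)
        X = np.random.default_rng(0).standard_normal((7, 5))
        assert np.array_equal(predict(back, X)[1], predict(model, X)[1])
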