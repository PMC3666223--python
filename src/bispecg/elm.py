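"""Extreme learning machine: single-hidden-layer network, analytic training.

Hidden weights w_i and biases b_i are drawn once from a seeded uniform
distribution and never updated; the hidden layer output matrix is

    H[k, i] = g(w_i . x_k + b_i),

and the linear output weights are solved in one shot as beta = pinv(H) Y,
with pinv the Moore-Penrose generalized inverse (SVD with a relative
singular-value cutoff, so rank-deficient H yields the minimum-norm
least-squares solution rather than unstable weights). Targets are one-hot
rows; prediction takes the argmax of the linear outputs, ties toward the
lowest class index.

Hidden parameters are drawn neuron by neuron (each neuron's weights and
bias as one contiguous block of the seeded stream), so for a fixed seed the
first M neurons of a larger network coincide with the M-neuron network —
training error is then non-increasing in M by the nesting of column spaces.

Features are standardized (z-score with training-set statistics) before
training by default: bispectral energies scale with the sixth power of
signal amplitude and would otherwise saturate the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError, DataError, ParameterError

__all__ = [
    "ACTIVATIONS",
    "ELMModel",
    "LabeledFeatures",
    "one_hot",
    "hidden_output_matrix",
    "pseudoinverse",
    "train_elm",
    "predict",
    "grid_search_hidden",
    "save_model",
    "load_model",
]


def _gaussian(z: np.ndarray) -> np.ndarray:
    return np.exp(-np.square(z))


def _hardlim(z: np.ndarray) -> np.ndarray:
    return (z >= 0).astype(np.float64)


#: Hidden-layer activations. All are bounded, so H is finite for any input.
ACTIVATIONS = {
    "sigmoid": expit,
    "sine": np.sin,
    "gaussian": _gaussian,
    "hardlim": _hardlim,
}


@dataclass(frozen=True)
class LabeledFeatures:
    """Feature matrix (N x n) with one-hot targets (N x m) and class names."""

    features: np.ndarray
    targets: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        X = np.asarray(self.features, dtype=np.float64)
        Y = np.asarray(self.targets, dtype=np.float64)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise DataError(f"inconsistent shapes: features {X.shape}, targets {Y.shape}")
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite feature values")
        if Y.shape[1] != len(self.class_names):
            raise DataError("targets width does not match class_names")
        onehot = (np.abs(Y.sum(axis=1) - 1.0) < 1e-12) & ((Y != 0).sum(axis=1) == 1)
        if not onehot.all():
            raise DataError("each target row must be one-hot")
        if X.shape[0] < Y.shape[1]:
            raise DataError(f"need at least {Y.shape[1]} rows (one per class), got {X.shape[0]}")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "targets", Y)

    @property
    def labels(self) -> np.ndarray:
        """Integer class index per row."""
        return self.targets.argmax(axis=1)


def one_hot(labels, class_names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Encode string labels as a one-hot matrix; returns (targets, class_names)."""
    labels = list(labels)
    if class_names is None:
        class_names = sorted(set(labels))
    index = {c: i for i, c in enumerate(class_names)}
    Y = np.zeros((len(labels), len(class_names)))
    for r, lab in enumerate(labels):
        try:
            Y[r, index[lab]] = 1.0
        except KeyError:
            raise DataError(f"label {lab!r} not in class_names {class_names}")
    return Y, class_names


@dataclass(frozen=True)
class ELMModel:
    """Trained ELM: fixed random hidden layer plus solved linear output layer."""

    input_weights: np.ndarray  # (M, n)
    biases: np.ndarray  # (M,)
    output_weights: np.ndarray  # (M, m)
    activation: str
    n_features: int
    n_classes: int
    seed: int
    class_names: list[str]
    feature_mean: np.ndarray | None = None  # z-score constants (None = raw)
    feature_scale: np.ndarray | None = None

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(
                f"unknown activation {self.activation!r}; expected one of {sorted(ACTIVATIONS)}"
            )
        M, n = self.input_weights.shape
        if self.biases.shape != (M,) or self.output_weights.shape != (M, self.n_classes):
            raise DataError("inconsistent model matrix shapes")
        if n != self.n_features:
            raise DataError("input_weights width does not match n_features")
        for a in (self.input_weights, self.biases, self.output_weights):
            if not np.all(np.isfinite(a)):
                raise DataError("non-finite model parameters")


def hidden_output_matrix(
    input_weights: np.ndarray,
    biases: np.ndarray,
    activation: str,
    features: np.ndarray,
) -> np.ndarray:
    """H[k, i] = g(w_i . x_k + b_i) for every sample k and hidden neuron i."""
    try:
        g = ACTIVATIONS[activation]
    except KeyError:
        raise ConfigurationError(f"unknown activation {activation!r}")
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != input_weights.shape[1]:
        raise DataError(
            f"feature width {X.shape} does not match weights {input_weights.shape}"
        )
    H = g(X @ input_weights.T + biases[None, :])
    if not np.all(np.isfinite(H)):  # bounded activations should never trip this
        raise DataError("hidden layer produced non-finite values")
    return H


def pseudoinverse(H: np.ndarray) -> np.ndarray:
    """Moore-Penrose generalized inverse via SVD.

    Singular values below ``max(N, M) * eps * sigma_max`` are treated as
    zero, so rank-deficient matrices get the exact minimum-norm inverse
    instead of exploding weights.
    """
    H = np.asarray(H, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise DataError("non-finite entries in matrix")
    rcond = max(H.shape) * np.finfo(np.float64).eps
    return np.linalg.pinv(H, rcond=rcond)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature -> leave centered only
    return mu, sd


def train_elm(
    data: LabeledFeatures,
    hidden: int = 20,
    activation: str = "sigmoid",
    seed: int = 0,
    weight_scale: float = 1.0,
    standardize: bool = True,
) -> ELMModel:
    """Train an ELM in one shot (no iteration).

    Hidden weights and biases are i.i.d. uniform on
    [-weight_scale, +weight_scale], drawn per neuron from
    ``numpy.random.default_rng(seed)``; output weights are
    ``pinv(H) @ targets``.
    """
    if hidden < 1:
        raise ParameterError(f"hidden must be >= 1, got {hidden}")
    if weight_scale <= 0:
        raise ParameterError(f"weight_scale must be > 0, got {weight_scale}")
    X, Y = data.features, data.targets
    n = X.shape[1]
    if standardize:
        mu, sd = _standardize_fit(X)
        Xs = (X - mu) / sd
    else:
        mu = sd = None
        Xs = X
    rng = np.random.default_rng(seed)
    wb = rng.uniform(-weight_scale, weight_scale, size=(hidden, n + 1))
    W, b = wb[:, :n], wb[:, n]
    H = hidden_output_matrix(W, b, activation, Xs)
    beta = pseudoinverse(H) @ Y
    return ELMModel(
        input_weights=W,
        biases=b,
        output_weights=beta,
        activation=activation,
        n_features=n,
        n_classes=Y.shape[1],
        seed=seed,
        class_names=list(data.class_names),
        feature_mean=mu,
        feature_scale=sd,
    )


def predict(model: ELMModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and raw linear outputs for a feature matrix.

    Raw outputs are rows of H @ beta; the class is the argmax over outputs
    (numpy argmax returns the first, i.e. lowest, index on ties).
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise DataError(f"feature width {X.shape[1]} != model n_features {model.n_features}")
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_scale
    H = hidden_output_matrix(model.input_weights, model.biases, model.activation, X)
    raw = H @ model.output_weights
    return raw.argmax(axis=1), raw


def grid_search_hidden(
    data: LabeledFeatures,
    candidates=(5, 10, 20, 40, 80),
    val_fraction: float = 0.25,
    activation: str = "sigmoid",
    seed: int = 0,
    weight_scale: float = 1.0,
    standardize: bool = True,
) -> tuple[int, dict[int, float]]:
    """Pick the hidden-layer size by validation accuracy on a held-out
    stratified fraction. Returns (best_M, {M: accuracy}); ties go to the
    smaller network."""
    rng = np.random.default_rng(seed)
    y = data.labels
    val_idx: list[int] = []
    for c in range(data.targets.shape[1]):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        k = max(1, int(round(val_fraction * members.size)))
        if k >= members.size:
            raise DataError(f"class {data.class_names[c]!r} too small for validation split")
        val_idx.extend(perm[:k])
    val = np.zeros(y.size, dtype=bool)
    val[val_idx] = True
    sub = LabeledFeatures(data.features[~val], data.targets[~val], data.class_names)
    scores: dict[int, float] = {}
    for M in candidates:
        model = train_elm(sub, hidden=M, activation=activation, seed=seed,
                          weight_scale=weight_scale, standardize=standardize)
        pred, _ = predict(model, data.features[val])
        scores[M] = float((pred == y[val]).mean())
    best = max(sorted(scores), key=lambda M: scores[M])
    return best, scores


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(path, model: ELMModel) -> None:
    """Persist a model as a self-describing .npz archive."""
    np.savez(
        path,
        input_weights=model.input_weights,
        biases=model.biases,
        output_weights=model.output_weights,
        activation=np.array(model.activation),
        n_features=model.n_features,
        n_classes=model.n_classes,
        seed=model.seed,
        class_names=np.array(model.class_names),
        standardized=model.feature_mean is not None,
        feature_mean=model.feature_mean if model.feature_mean is not None else np.zeros(0),
        feature_scale=model.feature_scale if model.feature_scale is not None else np.zeros(0),
    )


def load_model(path) -> ELMModel:
    with np.load(path, allow_pickle=False) as z:
        standardized = bool(z["standardized"])
        return ELMModel(
            input_weights=z["input_weights"],
            biases=z["biases"],
            output_weights=z["output_weights"],
            activation=str(z["activation"]),
            n_features=int(z["n_features"]),
            n_classes=int(z["n_classes"]),
            seed=int(z["seed"]),
            class_names=[str(c) for c in z["class_names"]],
            feature_mean=z["feature_mean"] if standardized else None,
            feature_scale=z["feature_scale"] if standardized else None,
        )
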