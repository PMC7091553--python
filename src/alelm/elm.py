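"""Regularized extreme learning machine (ELM) classifier.

An ELM is a single-hidden-layer feedforward network whose hidden-layer
parameters (input weights ``a_i`` and biases ``b_i``) are drawn at random
and never trained.  Only the linear output weights ``beta`` are fit, in
closed form, by ridge-regularized least squares

    min_beta  0.5 * ||beta||^2  +  (c / 2) * ||H beta - Y||^2,

where ``H`` is the hidden-layer output matrix ``H[j, i] = g(a_i . x_j + b_i)``
and ``Y`` holds one-vs-rest encoded class targets.  The solution is

    beta = (I / c + H' H)^{-1} H' Y          (N > M, primal form)
    beta = H' (I / c + H H')^{-1} Y          (N <= M, dual form),

both computed with a symmetric linear solve, never an explicit inverse.

Multiclass posterior probabilities come from mapping each output node
through a logistic sigmoid ``p_i = 1 / (1 + exp(-f_i))`` and normalizing
each row to sum to one; the best-versus-second-best uncertainty score and
all query strategies in :mod:`alelm.strategies` consume these posteriors.
"""

from __future__ import annotations

import dataclasses
import numbers

import h5py
import numpy as np
from scipy.linalg import solve
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "HiddenLayer",
    "ELMClassifier",
    "init_hidden",
    "hidden_matrix",
    "fit_output_weights",
    "posteriors",
    "encode_targets",
    "train",
    "accuracy",
    "save_model",
    "load_model",
]


ACTIVATIONS = {
    "sigmoid": expit,
    "gaussian": lambda z: np.exp(-np.square(z)),
}


@dataclasses.dataclass(frozen=True)
class HiddenLayer:
    """Random, untrained hidden layer of an ELM.

    Attributes
    ----------
    input_weights : ndarray of shape (M, p)
        Row ``i`` is the input weight vector ``a_i``, drawn uniform on [-1, 1].
    biases : ndarray of shape (M,)
        Hidden biases ``b_i``, drawn uniform on [0, 1].
    activation : str
        Name of the elementwise nonlinearity ``g`` ("sigmoid" or "gaussian").
    seed : int
        Seed that generated the layer; regenerating with the same seed
        reproduces identical weights.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    activation: str = "sigmoid"
    seed: int = 0

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def init_hidden(p: int, M: int, seed: int, activation: str = "sigmoid") -> HiddenLayer:
    """Draw a random hidden layer for ``p`` input features and ``M`` neurons.

    Weights are i.i.d. uniform on [-1, 1] and biases uniform on [0, 1] (the
    common ELM convention); the draw is a pure function of ``seed``.
    """
    if not isinstance(p, numbers.Integral) or p < 1:
        raise ValueError(f"input dimension p must be a positive integer, got {p!r}")
    if not isinstance(M, numbers.Integral) or M < 1:
        raise ValueError(f"hidden count M must be a positive integer, got {M!r}")
    if activation not in ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-1.0, 1.0, size=(int(M), int(p)))
    biases = rng.uniform(0.0, 1.0, size=int(M))
    return HiddenLayer(weights, biases, activation, int(seed))


def hidden_matrix(layer: HiddenLayer, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix ``H[j, i] = g(a_i . x_j + b_i)``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != layer.n_features:
        raise ValueError(
            f"X must be 2-D with {layer.n_features} columns, got shape {X.shape}"
        )
    g = ACTIVATIONS[layer.activation]
    return g(X @ layer.input_weights.T + layer.biases)


def fit_output_weights(H: np.ndarray, Y: np.ndarray, c: float) -> np.ndarray:
    """Closed-form ridge solution for the output weights ``beta``.

    Uses the primal form when N > M and the dual form when N <= M; both are
    symmetric positive-definite solves for any finite c > 0.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if H.ndim != 2 or H.shape[0] != Y.shape[0]:
        raise ValueError(f"incompatible shapes H {H.shape} vs Y {Y.shape}")
    if not np.isfinite(c) or c <= 0:
        raise ValueError(f"regularizer c must be positive and finite, got {c!r}")
    n, m = H.shape
    if n > m:
        A = H.T @ H + np.eye(m) / c
        return solve(A, H.T @ Y, assume_a="pos")
    A = H @ H.T + np.eye(n) / c
    return H.T @ solve(A, Y, assume_a="pos")


def posteriors(F: np.ndarray) -> np.ndarray:
    """Map decision values to normalized per-class posterior probabilities.

    Each entry passes through the logistic sigmoid ``1 / (1 + exp(-f))`` and
    each row is divided by its sum so rows sum to one.  Rows whose sigmoid sum
    underflows to zero fall back to the uniform distribution ``1/q``.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    q = F.shape[1]
    if q < 2:
        raise ValueError(f"need at least 2 output nodes, got {q}")
    P = expit(F)
    s = P.sum(axis=1, keepdims=True)
    safe = s > 0
    out = np.where(safe, P / np.where(safe, s, 1.0), 1.0 / q)
    return out


def encode_targets(y_indices: np.ndarray, n_classes: int, scheme: str = "plus-minus-one") -> np.ndarray:
    """One-vs-rest target matrix: +1/-1 (default) or 1/0 per ``scheme``."""
    y_indices = np.asarray(y_indices)
    n = y_indices.shape[0]
    if scheme == "plus-minus-one":
        T = -np.ones((n, n_classes))
        T[np.arange(n), y_indices] = 1.0
    elif scheme == "zero-one":
        T = np.zeros((n, n_classes))
        T[np.arange(n), y_indices] = 1.0
    else:
        raise ValueError(f"unknown target encoding {scheme!r}")
    return T


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Ridge-regularized extreme learning machine classifier.

    Parameters
    ----------
    n_hidden : int, default=50
        Number of hidden neurons M.
    c : float, default=1.0
        Ridge regularizer; larger c weighs the data-fit term more heavily.
    activation : {"sigmoid", "gaussian"}, default="sigmoid"
        Hidden-layer nonlinearity.
    target_encoding : {"plus-minus-one", "zero-one"}, default="plus-minus-one"
        One-vs-rest target coding.  With +1/-1 targets the decision value 0
        maps to posterior 0.5, matching the sigmoid posterior mapping.
    standardize : bool, default=True
        Z-score features using the training-set mean and standard deviation
        before the random projection (improves conditioning; constant
        features get unit scale).
    random_state : int, default=0
        Seed for the random hidden layer; the whole train -> predict path is
        a pure function of (data, n_hidden, c, random_state).

    Attributes
    ----------
    classes_ : ndarray of shape (q,)
        Sorted distinct class labels.
    hidden_ : HiddenLayer
        The random hidden layer drawn at fit time.
    coef_ : ndarray of shape (n_hidden, q)
        Output weights beta.
    mean_, scale_ : ndarray of shape (p,)
        Standardization statistics (zeros/ones when ``standardize=False``).
    """

    def __init__(
        self,
        n_hidden: int = 50,
        c: float = 1.0,
        activation: str = "sigmoid",
        target_encoding: str = "plus-minus-one",
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.c = c
        self.activation = activation
        self.target_encoding = target_encoding
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        q = len(self.classes_)
        if q < 2:
            raise ValueError("training data must contain at least two classes")
        p = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(p)
            self.scale_ = np.ones(p)
        Xs = (X - self.mean_) / self.scale_
        self.hidden_ = init_hidden(p, self.n_hidden, self.random_state, self.activation)
        H = hidden_matrix(self.hidden_, Xs)
        T = encode_targets(y_idx, q, self.target_encoding)
        self.coef_ = fit_output_weights(H, T, self.c)
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw output-node values ``H beta``, shape (N, q)."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit with {self.n_features_in_}"
            )
        Xs = (X - self.mean_) / self.scale_
        return hidden_matrix(self.hidden_, Xs) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        """Normalized sigmoid posteriors; rows sum to one."""
        return posteriors(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        """Argmax of the posterior row; ties resolve to the lowest class index."""
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]


def train(X, y, M: int = 50, c: float = 1.0, seed: int = 0, **kwargs) -> ELMClassifier:
    """Fit an :class:`ELMClassifier` with M hidden neurons and regularizer c."""
    return ELMClassifier(n_hidden=M, c=c, random_state=seed, **kwargs).fit(X, y)


def accuracy(model: ELMClassifier, X_test, y_test) -> float:
    """Fraction of test samples whose predicted label matches the truth."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(model.predict(X_test) == y_test))


# -- serialization ------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def save_model(model: ELMClassifier, path) -> None:
    """Serialize a fitted model to a single HDF5 archive.

    Keys: input_weights, biases, output_weights, mean, scale, classes;
    attrs: regularizer, activation, target_encoding, seed, standardize.
    """
    check_is_fitted(model, "coef_")
    with h5py.File(path, "w") as f:
        f.create_dataset("input_weights", data=model.hidden_.input_weights)
        f.create_dataset("biases", data=model.hidden_.biases)
        f.create_dataset("output_weights", data=model.coef_)
        f.create_dataset("mean", data=model.mean_)
        f.create_dataset("scale", data=model.scale_)
        cls = np.asarray(model.classes_)
        if cls.dtype.kind in "US":
            f.create_dataset("classes", data=cls.astype(object), dtype=_STR)
        else:
            f.create_dataset("classes", data=cls)
        f.attrs["regularizer"] = float(model.c)
        f.attrs["activation"] = model.hidden_.activation
        f.attrs["target_encoding"] = model.target_encoding
        f.attrs["seed"] = int(model.random_state)
        f.attrs["standardize"] = bool(model.standardize)


def load_model(path) -> ELMClassifier:
    """Inverse of :func:`save_model`; returns a ready-to-predict classifier."""
    with h5py.File(path, "r") as f:
        W = f["input_weights"][()]
        model = ELMClassifier(
            n_hidden=W.shape[0],
            c=float(f.attrs["regularizer"]),
            activation=str(f.attrs["activation"]),
            target_encoding=str(f.attrs["target_encoding"]),
            standardize=bool(f.attrs["standardize"]),
            random_state=int(f.attrs["seed"]),
        )
        model.hidden_ = HiddenLayer(W, f["biases"][()], str(f.attrs["activation"]),
                                    int(f.attrs["seed"]))
        model.coef_ = f["output_weights"][()]
        model.mean_ = f["mean"][()]
        model.scale_ = f["scale"][()]
        cls = f["classes"][()]
        if cls.dtype.kind == "O":
            cls = np.array([x.decode() if isinstance(x, bytes) else str(x) for x in cls])
        model.classes_ = cls
        model.n_features_in_ = W.shape[1]
    return model
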