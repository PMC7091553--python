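"""Hyperparameter selection for the active ELM.

Three searches, mirroring common practice for regularized ELMs:

* **M (hidden neurons)** — grid search scored by stratified ten-fold
  cross-validated accuracy, with the regularizer c re-selected per fold so
  M's score never depends on a globally fixed c.
* **c (ridge regularizer)** — exact leave-one-out error via the PRESS
  (predicted residual sum of squares) hat-matrix shortcut: for ridge, the
  held-out residual of sample j is r_j / (1 - hat_jj) where hat_jj is the
  j-th diagonal of H (H'H + I/c)^{-1} H', so LOO costs one fit per c
  instead of N.
* **lambda (uncertainty/diversity tradeoff)** — grid search scored by the
  ALC of a short, seeded active-learning simulation on a held-out
  validation split (the labeled data is split into a small initial L and an
  internal pool).

All selectors return grid members; ties resolve to the smallest value.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np
from scipy.linalg import solve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .elm import encode_targets, fit_output_weights, hidden_matrix, init_hidden

__all__ = [
    "SearchSpace",
    "press_mse",
    "select_c_press",
    "select_M",
    "select_lambda",
    "MSearchResult",
    "LambdaSearchResult",
]

_LEVERAGE_CLAMP = 1e-12


def default_M_grid():
    return list(range(10, 201, 10))


def default_c_grid():
    return list(np.exp(np.arange(-5.0, 5.0 + 1e-9, 0.1)))


def default_lambda_grid():
    return [round(0.1 * k, 1) for k in range(1, 10)]


@dataclasses.dataclass
class SearchSpace:
    M_grid: list = dataclasses.field(default_factory=default_M_grid)
    c_grid: list = dataclasses.field(default_factory=default_c_grid)
    lambda_grid: list = dataclasses.field(default_factory=default_lambda_grid)
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.M_grid or not self.c_grid or not self.lambda_grid:
            raise ValueError("search grids must be nonempty")
        self.M_grid = sorted(int(m) for m in self.M_grid)
        self.c_grid = sorted(float(c) for c in self.c_grid)
        self.lambda_grid = sorted(float(l) for l in self.lambda_grid)
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("c grid must be positive")
        if any(not 0 <= l <= 1 for l in self.lambda_grid):
            raise ValueError("lambda grid must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class MSearchResult(NamedTuple):
    best: int
    scores: dict  # M -> mean CV accuracy


class LambdaSearchResult(NamedTuple):
    best: float
    scores: dict  # lambda -> validation ALC


def press_mse(H: np.ndarray, Y: np.ndarray, c: float) -> float:
    """Exact leave-one-out mean squared error of the ridge fit (PRESS).

    Works in the primal (N > M) or dual (N <= M) hat-matrix form; by the
    push-through identity both give the same hat matrix
    H (H'H + I/c)^{-1} H' = H H' (H H' + I/c)^{-1}.  Leverages within
    1e-12 of 1 are clamped with a warning.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = H.shape
    if n < 2:
        raise ValueError("PRESS needs at least two samples")
    if c <= 0:
        raise ValueError("c must be positive")
    if n > m:
        A = H.T @ H + np.eye(m) / c
        B = solve(A, H.T, assume_a="pos")  # (m, n)
        leverage = np.einsum("jm,mj->j", H, B)
        residual = Y - H @ (B @ Y)
    else:
        K = H @ H.T
        A = K + np.eye(n) / c
        S = solve(A, np.hstack([K, Y]), assume_a="pos")
        leverage = np.diag(S[:, :n])  # diag(K A^{-1}) = diag(A^{-1} K), A, K symmetric
        residual = Y - K @ S[:, n:]
    denom = 1.0 - leverage
    bad = denom < _LEVERAGE_CLAMP
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} leverage value(s) within 1e-12 of 1; clamping", stacklevel=2
        )
        denom = np.where(bad, _LEVERAGE_CLAMP, denom)
    loo = residual / denom[:, None]
    return float(np.mean(loo**2))


def select_c_press(H: np.ndarray, Y: np.ndarray, c_grid) -> float:
    """Grid value of c minimizing PRESS; ties resolve to the smallest c."""
    c_grid = sorted(float(c) for c in c_grid)
    if not c_grid:
        raise ValueError("c grid must be nonempty")
    best_c, best_press = None, np.inf
    for c in c_grid:
        p = press_mse(H, Y, c)
        if p < best_press:
            best_c, best_press = c, p
    return best_c


def _fold_accuracy(X_tr, y_tr, X_te, y_te, M, c_grid, seed):
    """Fit one fold (standardize, random layer, PRESS-selected c) and score it."""
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    layer = init_hidden(X_tr.shape[1], M, seed)
    H_tr = hidden_matrix(layer, (X_tr - mu) / sd)
    classes, y_idx = np.unique(y_tr, return_inverse=True)
    T = encode_targets(y_idx, len(classes))
    c = select_c_press(H_tr, T, c_grid)
    beta = fit_output_weights(H_tr, T, c)
    F = hidden_matrix(layer, (X_te - mu) / sd) @ beta
    pred = classes[np.argmax(F, axis=1)]
    return float(np.mean(pred == y_te))


def select_M(X, y, space: SearchSpace) -> MSearchResult:
    """Hidden-neuron count maximizing mean stratified k-fold CV accuracy.

    The regularizer is re-selected per fold by minimum PRESS.  If some class
    has fewer members than ``space.folds`` the fold count is reduced with a
    warning.  Ties resolve to the smallest M.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    folds = space.folds
    if counts.min() < folds:
        folds = max(int(counts.min()), 2)
        warnings.warn(
            f"smallest class has {counts.min()} members; reducing folds to {folds}",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=space.seed)
    fold_index = list(skf.split(X, y))
    scores = {}
    for M in space.M_grid:
        accs = [
            _fold_accuracy(X[tr], y[tr], X[te], y[te], M, space.c_grid, space.seed)
            for tr, te in fold_index
        ]
        scores[M] = float(np.mean(accs))
    best = max(space.M_grid, key=lambda M: (scores[M], -M))
    return MSearchResult(best=best, scores=scores)


def select_lambda(
    X, y, X_val, y_val, space: SearchSpace, M: int, c: float,
    init_frac: float = 0.2, m_frac: float = 0.1,
) -> LambdaSearchResult:
    """Tradeoff lambda maximizing validation ALC of a short AL simulation.

    The labeled data is split (stratified, seeded) into an initial labeled
    part (``init_frac``) and an internal pool; for each lambda a
    double-criteria run queries ``m_frac`` of the pool per round and its
    learning curve on the validation split is scored by ALC.  Ties resolve
    to the smallest lambda.
    """
    from .data import Split
    from .runner import ALConfig, run_active_learning

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_val = np.asarray(X_val, dtype=float)
    if len(X_val) == 0:
        raise ValueError("validation split must be nonempty")
    try:
        X_init, X_pool, y_init, y_pool = train_test_split(
            X, y, train_size=init_frac, stratify=y, random_state=space.seed
        )
    except ValueError as err:
        raise ValueError(f"insufficient labeled data to split for lambda search: {err}")
    if len(np.unique(y_init)) < 2 or len(y_pool) < 2:
        raise ValueError("insufficient labeled data to split for lambda search")
    split = Split(X_init, y_init, X_pool, y_pool, X_val, np.asarray(y_val))
    scores = {}
    for lam in space.lambda_grid:
        cfg = ALConfig(
            strategy="d-al-elm", m=m_frac, h="5m", lam=lam, n_hidden=M, c=c,
            n_runs=1, seed=space.seed,
        )
        scores[lam] = run_active_learning(split, cfg).curve.alc
    best = max(space.lambda_grid, key=lambda l: (scores[l], -l))
    return LambdaSearchResult(best=best, scores=scores)
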