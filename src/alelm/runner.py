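"""Pool-based batch-mode active-learning loop and evaluation.

Each round the learner (1) trains an ELM on the current labeled set L,
(2) records test accuracy, (3) asks the query strategy for a batch of m
pool samples, (4) has the oracle reveal their labels and (5) moves them
into L.  The loop stops when more than ``max_fraction`` of the original
pool has been queried or when the recorded accuracy has stabilized
(``stabilize_window`` consecutive values within ``stabilize_tol``).

The learning curve starts at y_0, the accuracy of the model trained on the
initial labeled set before any query, so a curve with N_iter query rounds
has N_iter + 1 points and the area under the learning curve (ALC) is the
trapezoidal mean

    ALC = sum_{i=0}^{N_iter - 1} (y_i + y_{i+1}) / 2  /  N_iter.
"""

from __future__ import annotations

import dataclasses
import logging
import numbers
import time

import numpy as np
import pandas as pd

from .data import Split
from .elm import ELMClassifier, encode_targets, hidden_matrix, init_hidden
from .strategies import STRATEGY_REGISTRY, build_strategy

__all__ = [
    "ALConfig",
    "LearningCurve",
    "ALResult",
    "ExperimentResult",
    "resolve_batch_size",
    "stop_check",
    "alc",
    "run_active_learning",
    "run_experiment",
]

logger = logging.getLogger(__name__)

# PRESS grid used when config.c == "auto": c in {e^-5, e^-4.5, ..., e^5}
AUTO_C_GRID = np.exp(np.arange(-5.0, 5.0 + 1e-9, 0.5))


@dataclasses.dataclass
class ALConfig:
    """Configuration of one active-learning experiment.

    ``m`` may be an integer batch size or a fraction of the original pool
    (resolved once, rounded to nearest, at least 1).  ``h`` is an integer or
    a rule such as "5m".  ``c`` is a positive float, or "auto" to re-select
    the regularizer every round by minimum-PRESS leave-one-out error.
    """

    strategy: str = "d-al-elm"
    m: float | int = 0.05
    h: int | str = "5m"
    lam: float = 0.5
    n_hidden: int = 50
    c: float | str = 1.0
    activation: str = "sigmoid"
    max_fraction: float = 0.8
    stabilize_window: int = 3
    stabilize_tol: float = 1e-3
    n_runs: int = 10
    seed: int = 0
    margin_on_posteriors: bool = False

    def __post_init__(self):
        if self.strategy not in STRATEGY_REGISTRY:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; registered: "
                f"{sorted(STRATEGY_REGISTRY)}"
            )
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if not 0.0 < self.max_fraction <= 1.0:
            raise ValueError("max_fraction must lie in (0, 1]")
        if isinstance(self.c, str):
            if self.c != "auto":
                raise ValueError("c must be a positive number or 'auto'")
        elif self.c <= 0:
            raise ValueError("c must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclasses.dataclass
class LearningCurve:
    """Test accuracies y_0..y_Niter plus the queried batch size."""

    accuracies: np.ndarray
    queried_per_round: int

    @property
    def alc(self) -> float:
        return alc(self.accuracies)


@dataclasses.dataclass
class ALResult:
    curve: LearningCurve
    model: ELMClassifier
    queried: list  # original pool indices queried each round
    n_labeled: np.ndarray  # |L| when each accuracy was recorded
    c_used: list  # regularizer used each round
    runtime_s: float


def resolve_batch_size(m, pool_size: int) -> int:
    """Fractional m resolves against the ORIGINAL pool size, >= 1."""
    if isinstance(m, numbers.Integral):
        out = int(m)
    elif 0 < m < 1:
        out = int(round(m * pool_size))
    else:
        out = int(round(m))
    if out < 1:
        out = 1
    if out > pool_size:
        raise ValueError(f"batch size {out} exceeds pool size {pool_size}")
    return out


def stop_check(accuracies, n_selected: int, pool_size: int, config: ALConfig) -> bool:
    """True when the query budget is spent or the curve has stabilized.

    Budget: strictly more than ``max_fraction`` of the original pool
    queried.  Stability: the last ``stabilize_window`` recorded accuracies
    all differ pairwise by less than ``stabilize_tol``.
    """
    if n_selected > config.max_fraction * pool_size:
        return True
    w = config.stabilize_window
    accuracies = np.asarray(accuracies, dtype=float)
    if w >= 2 and len(accuracies) >= w:
        tail = accuracies[-w:]
        if tail.max() - tail.min() < config.stabilize_tol:
            return True
    return False


def alc(accuracies) -> float:
    """Trapezoidal mean of the learning curve, in [0, 1] for accuracies in [0, 1]."""
    y = np.asarray(accuracies, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need at least two accuracy points")
    n_iter = len(y) - 1
    return float(np.sum((y[:-1] + y[1:]) / 2.0) / n_iter)


def _auto_c(X_labeled, y_labeled, config: ALConfig) -> float:
    """Minimum-PRESS regularizer for the current labeled set."""
    from .model_selection import select_c_press

    X = np.asarray(X_labeled, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    layer = init_hidden(X.shape[1], config.n_hidden, config.seed, config.activation)
    H = hidden_matrix(layer, (X - mu) / sd)
    classes, y_idx = np.unique(y_labeled, return_inverse=True)
    T = encode_targets(y_idx, len(classes))
    return select_c_press(H, T, AUTO_C_GRID)


def run_active_learning(split: Split, config: ALConfig) -> ALResult:
    """Run one seeded active-learning experiment on a fixed split.

    Deterministic given ``config.seed``: the ELM hidden layer, the random
    baseline's draws, and all tie-breaks are seed- or index-determined.
    If the pool is exhausted mid-round the remainder is queried and the
    loop stops.
    """
    t0 = time.perf_counter()
    X_L = np.array(split.X_labeled, dtype=float)
    y_L = np.array(split.y_labeled)
    X_U = np.array(split.X_pool, dtype=float)
    y_U = np.array(split.y_pool)  # held-back labels; the oracle
    X_test, y_test = split.X_test, split.y_test
    if len(np.unique(y_L)) < 2:
        raise ValueError("initial labeled set must contain at least two classes")
    if len(X_U) == 0 or len(X_test) == 0:
        raise ValueError("pool and test set must be nonempty")

    pool_size0 = len(X_U)
    remaining = np.arange(pool_size0)  # original pool indices still unlabeled
    m = resolve_batch_size(config.m, pool_size0)
    strategy = build_strategy(
        config.strategy, lam=config.lam, h=config.h,
        on_posteriors=config.margin_on_posteriors,
    )
    rng = np.random.default_rng(config.seed)

    accs, n_labeled, queried, c_used = [], [], [], []
    model = None
    while True:
        c = _auto_c(X_L, y_L, config) if config.c == "auto" else float(config.c)
        c_used.append(c)
        model = ELMClassifier(
            n_hidden=config.n_hidden, c=c, activation=config.activation,
            random_state=config.seed,
        ).fit(X_L, y_L)
        accs.append(float(np.mean(model.predict(X_test) == y_test)))
        n_labeled.append(len(y_L))
        n_selected = pool_size0 - len(remaining)
        if len(remaining) == 0 or stop_check(accs, n_selected, pool_size0, config):
            break
        k = min(m, len(remaining))
        local = np.asarray(
            strategy.select(model, X_U[remaining], X_L, k, rng), dtype=int
        )
        chosen = remaining[local]
        queried.append(chosen)
        X_L = np.vstack([X_L, X_U[chosen]])
        y_L = np.concatenate([y_L, y_U[chosen]])  # oracle reveals labels
        remaining = np.delete(remaining, local)

    curve = LearningCurve(np.asarray(accs), queried_per_round=m)
    return ALResult(
        curve=curve, model=model, queried=queried,
        n_labeled=np.asarray(n_labeled), c_used=c_used,
        runtime_s=time.perf_counter() - t0,
    )


@dataclasses.dataclass
class ExperimentResult:
    summary: pd.DataFrame  # strategy, mean_accuracy, mean_final_accuracy, alc, runtime_s
    curves: dict  # strategy -> list of LearningCurve (one per run)
    results: dict  # strategy -> list of ALResult

    def mean_curve(self, strategy: str) -> np.ndarray:
        """Run-averaged curve; shorter runs are padded with their final value."""
        cs = [c.accuracies for c in self.curves[strategy]]
        n = max(len(c) for c in cs)
        padded = [np.concatenate([c, np.full(n - len(c), c[-1])]) for c in cs]
        return np.mean(padded, axis=0)


def run_experiment(split: Split, strategies, config: ALConfig) -> ExperimentResult:
    """Repeat each strategy ``config.n_runs`` times with seeds seed+0..seed+n-1.

    The summary reports, per strategy, the mean accuracy over the whole
    learning process (curve mean, averaged over runs), the mean final
    accuracy, the mean ALC, and the mean wall time per run.
    """
    rows, curves, results = [], {}, {}
    for name in strategies:
        runs = []
        for r in range(config.n_runs):
            cfg = dataclasses.replace(config, strategy=name, seed=config.seed + r)
            runs.append(run_active_learning(split, cfg))
        curves[name] = [res.curve for res in runs]
        results[name] = runs
        rows.append({
            "strategy": name,
            "mean_accuracy": float(np.mean([res.curve.accuracies.mean() for res in runs])),
            "mean_final_accuracy": float(np.mean([res.curve.accuracies[-1] for res in runs])),
            "alc": float(np.mean([res.curve.alc for res in runs])),
            "runtime_s": float(np.mean([res.runtime_s for res in runs])),
        })
    return ExperimentResult(summary=pd.DataFrame(rows), curves=curves, results=results)
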