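"""Query strategies for pool-based batch-mode active learning.

Implements the double-criteria selector and its baselines:

* **BvSB uncertainty** — per sample, the difference between the largest and
  second-largest posterior probabilities; smaller means more uncertain.
* **Cosine diversity** — similarity of a candidate to a reference set is the
  maximum cosine of the angle to any member; the combined criterion sums the
  similarity to the already-selected batch and to the labeled set, so
  redundant candidates are penalized.
* **Greedy batch selection** — from the h most uncertain candidates W, pick
  m samples one at a time, each minimizing

      lambda * bvsb(s) + (1 - lambda) * [div(s, picked) + div(s, L)],

  with lambda in [0, 1] trading off informativeness against diversity.
* Baselines: raw-margin sampling, maximum-entropy sampling, and uniform
  random selection (passive learning).

All tie-breaks resolve to the lowest index, making every selection a pure
function of its inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

__all__ = [
    "CandidateBatch",
    "SelectedBatch",
    "bvsb_scores",
    "entropy_scores",
    "margin_scores",
    "random_select",
    "cosine_similarity",
    "diversity_to_set",
    "combined_diversity",
    "select_candidates",
    "select_batch",
    "QueryStrategy",
    "DALELMStrategy",
    "MarginStrategy",
    "EntropyStrategy",
    "RandomStrategy",
    "STRATEGY_REGISTRY",
    "register_strategy",
    "build_strategy",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CandidateBatch:
    """The h most uncertain pool samples W = {w_1, ..., w_h}."""

    indices: np.ndarray  # pool indices, ascending BvSB order
    features: np.ndarray  # (h, p)
    bvsb: np.ndarray  # (h,), each in [0, 1]


@dataclasses.dataclass
class SelectedBatch:
    """The m samples S_m chosen greedily from a candidate batch."""

    indices: np.ndarray  # pool indices in pick order
    scores: np.ndarray  # combined criterion value at each greedy pick


def bvsb_scores(P: np.ndarray) -> np.ndarray:
    """Best-versus-second-best margin of each posterior row.

    Returns ``p(y_best | x) - p(y_second_best | x)`` in [0, 1]; smaller
    values indicate greater uncertainty.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] < 2:
        raise ValueError("BvSB requires at least two classes")
    q = P.shape[1]
    top2 = np.partition(P, (q - 2, q - 1), axis=1)[:, -2:]
    return top2[:, 1] - top2[:, 0]


def entropy_scores(P: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of each posterior row; larger = more uncertain."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1)


def margin_scores(F: np.ndarray) -> np.ndarray:
    """Margin between the two largest raw decision values per row.

    The margin-sampling baseline operates on raw ELM outputs rather than
    mapped posteriors; the smallest margins are queried first.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[1] < 2:
        raise ValueError("margin requires at least two output nodes")
    q = F.shape[1]
    top2 = np.partition(F, (q - 2, q - 1), axis=1)[:, -2:]
    return top2[:, 1] - top2[:, 0]


def random_select(pool_size: int, m: int, rng) -> np.ndarray:
    """m distinct uniform indices from ``range(pool_size)`` (passive learning)."""
    if m > pool_size:
        raise ValueError(f"cannot select {m} from a pool of {pool_size}")
    rng = np.random.default_rng(rng)
    return rng.choice(pool_size, size=m, replace=False)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities; rows with zero norm yield 0 similarity."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        logger.warning("zero-norm sample in cosine computation; similarity set to 0")
    denom = np.outer(np.where(na == 0, 1.0, na), np.where(nb == 0, 1.0, nb))
    sim = (A @ B.T) / denom
    sim[na == 0, :] = 0.0
    sim[:, nb == 0] = 0.0
    return sim


def cosine_similarity(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Cosine of the angle between two samples, in [-1, 1]; 0 if either is zero."""
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise ValueError(f"length mismatch: {x_i.shape} vs {x_j.shape}")
    return float(_cosine_matrix(x_i[None, :], x_j[None, :])[0, 0])


def diversity_to_set(x: np.ndarray, W) -> float:
    """Similarity of a sample to a set: max cosine to any member; empty set -> 0.

    Smaller values mean the sample is more diverse from the set.  The
    empty-set convention 0 is constant across candidates, hence
    ranking-neutral.
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        return 0.0
    W = np.atleast_2d(W)
    return float(_cosine_matrix(np.asarray(x, float)[None, :], W).max())


def combined_diversity(w_i: np.ndarray, S_m, L) -> float:
    """Combined redundancy score: div(w_i, S_m) + div(w_i, L), in [-2, 2].

    ``S_m`` is the already-selected batch (the caller excludes ``w_i``
    itself); ``L`` is the labeled set and must be nonempty.
    """
    L = np.asarray(L, dtype=float)
    if L.size == 0:
        raise ValueError("labeled set L must be nonempty")
    return diversity_to_set(w_i, S_m) + diversity_to_set(w_i, L)


def select_candidates(model, U: np.ndarray, h: int) -> CandidateBatch:
    """The h pool samples with the smallest BvSB scores (most uncertain).

    Ties resolve to the lowest pool index; h larger than the pool is clamped
    with a warning.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if h > len(U):
        warnings.warn(
            f"candidate size h={h} exceeds pool size {len(U)}; clamping", stacklevel=2
        )
        h = len(U)
    if h < 1:
        raise ValueError("h must be at least 1")
    scores = bvsb_scores(model.predict_proba(U))
    order = np.argsort(scores, kind="stable")[:h]
    return CandidateBatch(indices=order, features=U[order], bvsb=scores[order])


def select_batch(W: CandidateBatch, L: np.ndarray, lam: float, m: int) -> SelectedBatch:
    """Greedy double-criteria batch selection from candidates W.

    Repeats m times: for every not-yet-picked candidate s, score

        lambda * bvsb(s) + (1 - lambda) * [div(s, picked) + div(s, L)]

    and pick the argmin (ties -> lowest candidate position).  The first
    pick's batch-diversity term is 0 (empty picked set).  With lambda = 1
    this degenerates to the m smallest-BvSB candidates.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    h = len(W.indices)
    if m > h:
        raise ValueError(f"batch size m={m} exceeds candidate count h={h}")
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.size == 0:
        raise ValueError("labeled set L must be nonempty")
    feats = np.atleast_2d(np.asarray(W.features, dtype=float))
    C = _cosine_matrix(feats, feats)
    div_L = _cosine_matrix(feats, L).max(axis=1)
    div_picked = np.zeros(h)  # empty-set convention; real max cosine once picked
    available = np.ones(h, dtype=bool)
    picks: list[int] = []
    pick_scores: list[float] = []
    for step in range(m):
        score = lam * W.bvsb + (1.0 - lam) * (div_picked + div_L)
        score = np.where(available, score, np.inf)
        j = int(np.argmin(score))
        picks.append(j)
        pick_scores.append(float(score[j]))
        available[j] = False
        div_picked = C[:, j] if step == 0 else np.maximum(div_picked, C[:, j])
    return SelectedBatch(
        indices=np.asarray(W.indices)[picks], scores=np.asarray(pick_scores)
    )


# -- strategy plug-ins --------------------------------------------------------


class QueryStrategy:
    """Interface: ``select(model, pool, labeled, m, rng) -> pool indices``.

    ``pool`` and ``labeled`` are raw (unstandardized) feature matrices; the
    fitted model handles its own standardization, and strategies that need
    geometry (cosine) z-score with labeled-set statistics themselves.
    """

    name = "base"

    def select(self, model, pool, labeled, m, rng):  # pragma: no cover - interface
        raise NotImplementedError


STRATEGY_REGISTRY: dict[str, type] = {}


def register_strategy(name: str):
    """Class decorator adding a user strategy to the plug-in registry."""

    def deco(cls):
        cls.name = name
        STRATEGY_REGISTRY[name] = cls
        return cls

    return deco


def _labeled_standardizer(labeled: np.ndarray):
    mu = labeled.mean(axis=0)
    sd = labeled.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda X: (X - mu) / sd


@register_strategy("d-al-elm")
class DALELMStrategy(QueryStrategy):
    """Double-criteria selector: BvSB candidate screen + greedy diversity batch.

    Parameters
    ----------
    lam : float
        Tradeoff between uncertainty (lam = 1) and diversity (lam = 0).
    h : int or str
        Candidate pool size, either an integer or a rule like "5m"/"2m"
        (a multiple of the batch size m).
    """

    def __init__(self, lam: float = 0.5, h="5m"):
        self.lam = lam
        self.h = h

    def _resolve_h(self, m: int) -> int:
        if isinstance(self.h, str):
            rule = self.h.strip().lower()
            if not rule.endswith("m"):
                raise ValueError(f"h rule must look like '5m', got {self.h!r}")
            factor = float(rule[:-1]) if rule[:-1] else 1.0
            return max(int(round(factor * m)), m)
        return int(self.h)

    def select(self, model, pool, labeled, m, rng):
        h = min(self._resolve_h(m), len(pool))  # routine near pool exhaustion
        cand = select_candidates(model, pool, h)
        z = _labeled_standardizer(np.asarray(labeled, dtype=float))
        cand_std = dataclasses.replace(cand, features=z(cand.features))
        batch = select_batch(cand_std, z(labeled), self.lam, min(m, len(cand.indices)))
        return batch.indices


@register_strategy("al-elm")
class MarginStrategy(QueryStrategy):
    """Margin sampling on raw decision values (smallest margins first).

    ``on_posteriors=True`` switches the margin to mapped posterior rows.
    """

    def __init__(self, on_posteriors: bool = False):
        self.on_posteriors = on_posteriors

    def select(self, model, pool, labeled, m, rng):
        F = model.predict_proba(pool) if self.on_posteriors else model.decision_function(pool)
        return np.argsort(margin_scores(F), kind="stable")[:m]


@register_strategy("elm-entropy")
class EntropyStrategy(QueryStrategy):
    """Maximum-entropy sampling on mapped posteriors (largest entropy first)."""

    def select(self, model, pool, labeled, m, rng):
        ent = entropy_scores(model.predict_proba(pool))
        return np.argsort(-ent, kind="stable")[:m]


@register_strategy("random")
class RandomStrategy(QueryStrategy):
    """Uniform random selection — the passive-learning baseline."""

    def select(self, model, pool, labeled, m, rng):
        return random_select(len(pool), m, rng)


def build_strategy(name: str, **kwargs) -> QueryStrategy:
    """Instantiate a registered strategy, passing only the kwargs it accepts."""
    if name not in STRATEGY_REGISTRY:
        raise ValueError(
            f"unknown strategy {name!r}; registered: {sorted(STRATEGY_REGISTRY)}"
        )
    cls = STRATEGY_REGISTRY[name]
    import inspect

    params = inspect.signature(cls.__init__).parameters
    accepted = {k: v for k, v in kwargs.items() if k in params}
    return cls(**accepted)
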