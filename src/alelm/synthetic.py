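"""Seeded synthetic-data generators.

Two families of fixtures exercise every stage of the package without any
download:

* **Gaussian-mixture pools** (:func:`make_pool`) — multiclass points split
  into labeled / unlabeled-pool / test parts the way active-learning
  benchmarks are set up (defaults: 10 % labeled, 40 % pool, 50 % test,
  stratified by class).  :func:`make_redundant_pool` additionally replicates
  pool points with tiny jitter so near-duplicate clusters (cosine > 0.999)
  probe the diversity criterion.
* **Oscillatory EEG epochs** (:func:`make_eeg`) — white-noise channels plus a
  class-specific band-limited oscillation on a class-specific channel group,
  emulating the band-power structure of motor-imagery EEG that CSP exploits.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import butter, sosfilt

from .data import Split

__all__ = [
    "MixtureSpec",
    "EEGSpec",
    "default_mixture_spec",
    "default_eeg_spec",
    "make_pool",
    "make_redundant_pool",
    "make_eeg",
]


@dataclasses.dataclass
class MixtureSpec:
    """Multiclass Gaussian mixture with benchmark-style split fractions."""

    means: np.ndarray  # (q, p)
    covs: np.ndarray  # (q, p, p)
    proportions: np.ndarray  # (q,), sums to 1
    n_total: int = 600
    frac_labeled: float = 0.10
    frac_pool: float = 0.40
    redundancy: int | None = None  # replicate factor for make_redundant_pool
    jitter: float = 1e-3  # replicate jitter, units of per-feature std
    seed: int = 0

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        q, p = self.means.shape
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.shape != (q, p, p):
            raise ValueError(f"covs must have shape {(q, p, p)}, got {self.covs.shape}")
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        for C in self.covs:
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("covariances must be positive-definite")


def default_mixture_spec(n_total: int = 600, seed: int = 0) -> MixtureSpec:
    """Three equiprobable unit-covariance classes in six dimensions.

    Class means sit at 2 * e_k (pairwise distance 2*sqrt(2) standard
    deviations), giving moderate class overlap: a classifier trained on a
    small labeled set has visible room to improve as queries arrive.
    """
    q, p = 3, 6
    means = np.zeros((q, p))
    means[np.arange(q), np.arange(q)] = 2.0
    covs = np.stack([np.eye(p)] * q)
    return MixtureSpec(
        means=means, covs=covs, proportions=np.full(q, 1.0 / q),
        n_total=n_total, seed=seed,
    )


def _stratified_three_way(y, frac_labeled, frac_pool, rng):
    """Per-class index partition into labeled / pool / test."""
    lab, pool, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n = len(idx)
        n_lab = max(int(round(frac_labeled * n)), 1)
        n_pool = max(int(round(frac_pool * n)), 1)
        n_lab = min(n_lab, n - 2) if n > 2 else n_lab
        lab.append(idx[:n_lab])
        pool.append(idx[n_lab:n_lab + n_pool])
        test.append(idx[n_lab + n_pool:])
    return (np.concatenate(lab), np.concatenate(pool), np.concatenate(test))


def make_pool(spec: MixtureSpec) -> Split:
    """Draw the mixture and split it into labeled / pool / test parts.

    Counts per class follow the spec proportions (largest-remainder
    rounding); the three-way split is stratified so the labeled part always
    contains every class.
    """
    rng = np.random.default_rng(spec.seed)
    q = len(spec.proportions)
    raw = spec.proportions * spec.n_total
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: spec.n_total - counts.sum()]:
        counts[i] += 1
    X_parts, y_parts = [], []
    for k in range(q):
        X_parts.append(rng.multivariate_normal(spec.means[k], spec.covs[k], size=counts[k]))
        y_parts.append(np.full(counts[k], k, dtype=int))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    lab, pool, test = _stratified_three_way(y, spec.frac_labeled, spec.frac_pool, rng)
    lab, pool, test = rng.permutation(lab), rng.permutation(pool), rng.permutation(test)
    return Split(X[lab], y[lab], X[pool], y[pool], X[test], y[test])


def make_redundant_pool(spec: MixtureSpec) -> Split:
    """A split whose pool contains near-duplicate replicate clusters.

    Every surviving pool point is replicated ``spec.redundancy`` times with
    isotropic Gaussian jitter of ``spec.jitter`` times the per-feature std,
    keeping within-replicate cosine similarity above 0.999.  The returned
    split's ``pool_groups`` gives the replicate-cluster id of each pool row.
    """
    if spec.redundancy is None or spec.redundancy < 2:
        raise ValueError("spec.redundancy must be an integer >= 2")
    base = make_pool(spec)
    rng = np.random.default_rng(spec.seed + 1)
    r = int(spec.redundancy)
    n_pool = len(base.y_pool)
    n_base = max(n_pool // r, 1)
    scale = base.X_pool.std(axis=0)
    scale[scale == 0] = 1.0
    X_rep, y_rep, groups = [], [], []
    for g in range(n_base):
        x = base.X_pool[g]
        for _ in range(r):
            X_rep.append(x + rng.normal(0.0, spec.jitter * scale))
            y_rep.append(base.y_pool[g])
            groups.append(g)
    return Split(
        base.X_labeled, base.y_labeled,
        np.vstack(X_rep), np.asarray(y_rep), base.X_test, base.y_test,
        pool_groups=np.asarray(groups),
    )


@dataclasses.dataclass
class EEGSpec:
    """Oscillatory multichannel epochs with class-dependent band power.

    ``class_bands`` maps each class to a (channel-group, (low, high) Hz,
    power) triple: those channels receive a band-limited oscillation with
    variance ``power`` on top of white noise of std ``noise_sigma``
    everywhere.  Defaults put each of four classes on its own channel pair
    with a distinct sub-band of the 8-30 Hz sensorimotor range.
    """

    n_trials_per_class: int = 80
    n_channels: int = 8
    fs: float = 250.0
    epoch_sec: float = 3.0
    class_bands: tuple = (
        ((0, 1), (8.0, 12.0), 6.0),
        ((2, 3), (13.0, 17.0), 6.0),
        ((4, 5), (18.0, 22.0), 6.0),
        ((6, 7), (23.0, 27.0), 6.0),
    )
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        nyq = self.fs / 2.0
        for _, (lo, hi), power in self.class_bands:
            if not 0 < lo < hi < nyq:
                raise ValueError(f"band ({lo}, {hi}) must lie within (0, {nyq})")
            if power < 0:
                raise ValueError("band power must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def default_eeg_spec(seed: int = 0) -> EEGSpec:
    return EEGSpec(seed=seed)


def make_eeg(spec: EEGSpec):
    """Generate a balanced, seeded :class:`~alelm.eeg.EpochSet`.

    Each trial of class k is white noise on all channels plus band-limited
    Gaussian noise (4th-order Butterworth-filtered, rescaled to the stated
    power) on class k's channel group.  Trials are shuffled so classes are
    interleaved.
    """
    from .eeg import EpochSet

    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.class_bands)
    n_samples = int(round(spec.epoch_sec * spec.fs))
    n_trials = spec.n_trials_per_class * n_classes
    data = rng.normal(0.0, spec.noise_sigma, size=(n_trials, spec.n_channels, n_samples))
    labels = np.repeat(np.arange(n_classes), spec.n_trials_per_class)
    for t in range(n_trials):
        group, (lo, hi), power = spec.class_bands[labels[t]]
        if power == 0:
            continue
        sos = butter(4, [lo, hi], btype="bandpass", fs=spec.fs, output="sos")
        for ch in group:
            osc = sosfilt(sos, rng.normal(0.0, 1.0, size=n_samples))
            sd = osc.std()
            if sd > 0:
                data[t, ch] += osc * (np.sqrt(power) / sd)
    order = rng.permutation(n_trials)
    return EpochSet(
        data=data[order], fs=spec.fs, labels=labels[order],
        window=(0.0, spec.epoch_sec),
    )
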