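"""Motor-imagery EEG preprocessing and one-versus-rest CSP features.

The standard pipeline for multiclass motor-imagery BCI data:

1. crop each epoch to the reactive window after the cue (default 0.5-2.5 s),
2. band-pass 8-30 Hz with a fifth-order Butterworth filter (zero-phase
   forward-backward application by default, avoiding phase distortion of
   the short window),
3. one-versus-rest common spatial patterns (OVR-CSP): for each class k,
   spatial filters W solving the generalized eigenproblem of (C_k,
   C_k + C_rest) of trial-averaged, trace-normalized spatial covariances;
   the eigenvectors at both ends of the spectrum maximize the band-power
   variance ratio of class k against the rest,
4. log-variance features of the filtered signals, normalized within each
   class's filter block — 4 classes x 6 filters = 24 features.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.linalg import eigh
from scipy.signal import butter, sosfilt, sosfiltfilt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "EpochSet",
    "OVRCSP",
    "extract_window",
    "bandpass",
    "fit_ovr_csp",
    "csp_features",
    "read_gdf_epochs",
]

_VAR_FLOOR = 1e-12
_COV_RIDGE = 1e-8


@dataclasses.dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x samples.

    ``window`` is the (start, end) time of the stored samples in seconds
    relative to the cue (cue at t = 0; sample indices 0-based, windows
    half-open).
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    window: tuple = (0.0, None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be trials x channels x samples, got {self.data.shape}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.window[1] is None:
            self.window = (self.window[0], self.window[0] + self.data.shape[2] / self.fs)
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed window start")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def extract_window(epochs: EpochSet, t_start: float = 0.5, t_end: float = 2.5) -> EpochSet:
    """Crop to cue-relative seconds [t_start, t_end) — half-open, 0-based.

    Sample indices are ``round((t - window_start) * fs)``; the requested
    window must lie within the recorded extent.
    """
    w0, w1 = epochs.window
    tol = 0.5 / epochs.fs
    if t_start < w0 - tol or t_end > w1 + tol or t_end <= t_start:
        raise ValueError(
            f"window ({t_start}, {t_end}) outside recorded extent ({w0}, {w1})"
        )
    i0 = int(round((t_start - w0) * epochs.fs))
    i1 = int(round((t_end - w0) * epochs.fs))
    i0 = max(i0, 0)
    i1 = min(i1, epochs.n_samples)
    # record the window actually achieved on the sample grid, so repeated
    # crops compose exactly
    return EpochSet(
        data=epochs.data[:, :, i0:i1], fs=epochs.fs, labels=epochs.labels,
        window=(w0 + i0 / epochs.fs, w0 + i1 / epochs.fs),
    )


def bandpass(
    epochs: EpochSet, low: float = 8.0, high: float = 30.0, order: int = 5,
    zero_phase: bool = True,
) -> EpochSet:
    """Butterworth band-pass each channel of each trial.

    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``), doubling the effective order but leaving phase
    untouched; ``zero_phase=False`` gives a single causal pass.
    """
    if high >= epochs.fs / 2.0:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {epochs.fs / 2} Hz")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = butter(order, [low, high], btype="bandpass", fs=epochs.fs, output="sos")
    apply = sosfiltfilt if zero_phase else sosfilt
    data = apply(sos, epochs.data, axis=-1)
    return EpochSet(data=np.ascontiguousarray(data), fs=epochs.fs,
                    labels=epochs.labels, window=epochs.window)


def _trial_covariances(X: np.ndarray) -> np.ndarray:
    """Per-trial spatial covariance, normalized by its trace."""
    covs = np.einsum("tcs,tds->tcd", X, X)
    traces = np.trace(covs, axis1=1, axis2=2)
    traces = np.where(traces <= 0, 1.0, traces)
    return covs / traces[:, None, None]


class OVRCSP(TransformerMixin, BaseEstimator):
    """One-versus-rest common spatial patterns on epoch tensors.

    Parameters
    ----------
    n_filters : int, default=6
        Spatial filters per class, split evenly between the two ends of the
        generalized eigen-spectrum (3 + 3 by default).  Feature dimension is
        ``n_classes * n_filters`` (24 for four classes).

    Attributes
    ----------
    classes_ : ndarray
        Class labels in block order.
    filters_ : ndarray of shape (n_classes, n_channels, n_filters)
        Per-class spatial filter banks; kept columns satisfy
        ``W' (C_k + C_rest) W = I``.
    eigenvalues_ : ndarray of shape (n_classes, n_filters)
        Generalized eigenvalues of the kept filters, each in (0, 1).
    """

    def __init__(self, n_filters: int = 6):
        self.n_filters = n_filters

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be trials x channels x samples")
        y = np.asarray(y)
        if self.n_filters < 2 or self.n_filters % 2:
            raise ValueError("n_filters must be an even integer >= 2")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        n_channels = X.shape[1]
        if self.n_filters > n_channels:
            raise ValueError(
                f"n_filters={self.n_filters} exceeds channel count {n_channels}"
            )
        covs = _trial_covariances(X)
        half = self.n_filters // 2
        filters, eigvals = [], []
        for cls in self.classes_:
            mask = y == cls
            if mask.sum() < 2 or (~mask).sum() < 2:
                raise ValueError(f"need at least two trials per class (class {cls!r})")
            C_k = covs[mask].mean(axis=0)
            C_rest = covs[~mask].mean(axis=0)
            composite = C_k + C_rest
            lo = np.linalg.eigvalsh(composite).min()
            if lo <= _COV_RIDGE * np.trace(composite) / n_channels:
                warnings.warn(
                    f"rank-deficient composite covariance for class {cls!r}; "
                    "applying ridge regularization", stacklevel=2,
                )
                composite = composite + (
                    _COV_RIDGE * np.trace(composite) / n_channels
                ) * np.eye(n_channels)
            w, V = eigh(C_k, composite)  # ascending; V' composite V = I
            keep = np.concatenate([np.arange(half), np.arange(n_channels - half, n_channels)])
            filters.append(V[:, keep])
            eigvals.append(w[keep])
        self.filters_ = np.stack(filters)
        self.eigenvalues_ = np.stack(eigvals)
        self.n_channels_ = n_channels
        return self

    def transform(self, X) -> np.ndarray:
        """Block-normalized log-variance features, trials x (classes * n_filters)."""
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.n_channels_:
            raise ValueError(
                f"X must be trials x {self.n_channels_} channels x samples, got {X.shape}"
            )
        blocks = []
        for k in range(len(self.classes_)):
            W = self.filters_[k]  # (channels, n_filters)
            Z = np.einsum("cf,tcs->tfs", W, X)
            v = Z.var(axis=2)
            v = np.maximum(v, _VAR_FLOOR)
            blocks.append(np.log(v / v.sum(axis=1, keepdims=True)))
        return np.hstack(blocks)


def fit_ovr_csp(epochs: EpochSet, filters_per_class: int = 6) -> OVRCSP:
    """Fit an :class:`OVRCSP` spatial filter bank on labeled epochs."""
    return OVRCSP(n_filters=filters_per_class).fit(epochs.data, epochs.labels)


def csp_features(model: OVRCSP, epochs: EpochSet) -> np.ndarray:
    """Project epochs through a fitted filter bank; returns trials x features."""
    return model.transform(epochs.data)


def read_gdf_epochs(path, t_start: float = 0.0, t_end: float = 4.0,
                    event_ids=None) -> EpochSet:
    """Optional adapter: epoch a GDF recording via MNE into an EpochSet.

    Requires ``mne``; the core pipeline never parses GDF itself.  Events are
    mapped to 0-based labels in ``event_ids`` order.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF files requires the optional 'mne' package") from err
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    events, mapping = mne.events_from_annotations(raw, event_id=event_ids, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True)
    ep = mne.Epochs(
        raw, events, tmin=t_start, tmax=t_end, picks=picks,
        baseline=None, preload=True, verbose="error",
    )
    codes = sorted(mapping.values())
    labels = np.array([codes.index(e) for e in ep.events[:, 2]])
    return EpochSet(
        data=ep.get_data(), fs=float(ep.info["sfreq"]), labels=labels,
        window=(t_start, t_end),
    )
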