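"""Data containers and plain-text / HDF5 I/O.

A :class:`Split` holds the three parts of a pool-based active-learning
problem: a small initial labeled set L, a large unlabeled pool U (whose
labels exist but are only revealed when queried), and a held-out test set.

On disk a split is a single CSV with a ``split`` column taking values
``labeled`` / ``pool`` / ``test``, a ``label`` column, and numeric feature
columns ``f0..f{p-1}``.  Epoched EEG travels in an HDF5 container with
datasets ``/data`` (trials x channels x samples) and ``/labels`` and root
attributes ``fs`` and ``window``.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd

__all__ = ["Split", "read_split_csv", "write_split_csv", "save_epochs", "load_epochs"]


@dataclasses.dataclass
class Split:
    X_labeled: np.ndarray
    y_labeled: np.ndarray
    X_pool: np.ndarray
    y_pool: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    pool_groups: np.ndarray | None = None  # replicate-cluster ids, if constructed

    def __post_init__(self):
        p = self.X_labeled.shape[1]
        if self.X_pool.shape[1] != p or self.X_test.shape[1] != p:
            raise ValueError("feature dimension differs between split parts")

    @property
    def n_features(self) -> int:
        return self.X_labeled.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{i}" for i in range(self.n_features)]
        parts = []
        for name, X, y in [
            ("labeled", self.X_labeled, self.y_labeled),
            ("pool", self.X_pool, self.y_pool),
            ("test", self.X_test, self.y_test),
        ]:
            df = pd.DataFrame(X, columns=cols)
            df.insert(0, "label", y)
            df.insert(0, "split", name)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Split":
        feat_cols = [c for c in df.columns if c not in ("split", "label")]
        out = {}
        for name in ("labeled", "pool", "test"):
            part = df[df["split"] == name]
            out[f"X_{name}"] = part[feat_cols].to_numpy(dtype=float)
            out[f"y_{name}"] = part["label"].to_numpy()
        return cls(
            out["X_labeled"], out["y_labeled"],
            out["X_pool"], out["y_pool"],
            out["X_test"], out["y_test"],
        )


def write_split_csv(split: Split, path) -> None:
    split.to_frame().to_csv(path, index=False)


def read_split_csv(path) -> Split:
    return Split.from_frame(pd.read_csv(path))


def save_epochs(path, data, fs, labels, window=(0.0, None)) -> None:
    """Write an epoch tensor to the documented HDF5 container."""
    data = np.asarray(data, dtype=float)
    if window[1] is None:
        window = (window[0], window[0] + data.shape[2] / fs)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("labels", data=np.asarray(labels))
        f.attrs["fs"] = float(fs)
        f.attrs["window"] = np.asarray(window, dtype=float)


def load_epochs(path):
    """Read the HDF5 epoch container; returns an :class:`alelm.eeg.EpochSet`."""
    from .eeg import EpochSet

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = f["labels"][()]
        fs = float(f.attrs["fs"])
        window = tuple(np.asarray(f.attrs["window"], dtype=float))
    return EpochSet(data=data, fs=fs, labels=labels, window=window)
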