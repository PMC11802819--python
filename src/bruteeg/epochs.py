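"""Canonical in-memory model for epoched multichannel EEG and its HDF5 container.

An :class:`EpochDataset` holds a trials x channels x samples tensor together
with per-trial class labels, per-trial subject ids and the sampling rate.  The
four classes are the Spanish direction words of the inner-speech paradigm,
with a fixed integer mapping (0 "arriba", 1 "abajo", 2 "derecha",
3 "izquierda"); the Spanish words are authoritative, no English gloss is
stored.

The on-disk container is a single HDF5 file with datasets ``/data``,
``/labels``, ``/subjects`` and root attributes ``sfreq`` and
``channel_names``.  Round trips are lossless at stored precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Fixed label mapping for the 4-class inner-speech paradigm.
CLASS_NAMES: tuple[str, ...] = ("arriba", "abajo", "derecha", "izquierda")
N_CLASSES = len(CLASS_NAMES)


@dataclass
class EpochDataset:
    """Epoched EEG trials with labels, subject ids and sampling rate.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``, arbitrary
        amplitude units.  Trials dimension first, 0-based indexing.
    labels
        Integer class per trial, each in ``{0, 1, 2, 3}``.
    subjects
        Integer subject id per trial, each >= 1.
    sfreq
        Sampling rate in Hz, > 0.
    channel_names
        Unique channel names, one per channel.
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    sfreq: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        self.validate()

    # -- shape helpers -----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first offending field."""
        if self.data.ndim != 3:
            raise ValidationError("data: expected 3-D (trials x channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data: non-finite values")
        n = self.data.shape[0]
        if self.labels.shape != (n,):
            raise ValidationError("labels: length must equal n_trials")
        if self.subjects.shape != (n,):
            raise ValidationError("subjects: length must equal n_trials")
        if n and not np.isin(self.labels, np.arange(N_CLASSES)).all():
            raise ValidationError("labels: values outside {0,1,2,3}")
        if n and (self.subjects < 1).any():
            raise ValidationError("subjects: ids must be >= 1")
        if not (np.isfinite(self.sfreq) and self.sfreq > 0):
            raise ValidationError("sfreq: must be a positive finite number")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError("channel_names: length must equal n_channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel_names: names must be unique")

    def select(self, idx: np.ndarray) -> "EpochDataset":
        """Return a new dataset restricted to trial indices ``idx`` (copy)."""
        idx = np.asarray(idx, dtype=np.int64)
        return EpochDataset(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            subjects=self.subjects[idx].copy(),
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochDataset):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subjects, other.subjects)
            and self.sfreq == other.sfreq
            and self.channel_names == other.channel_names
        )


@dataclass
class FeatureMatrix:
    """A trials x features table with provenance of the producing pipeline."""

    values: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    provenance: str
    feature_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    PROVENANCES = ("raw", "ica", "pca", "csp_pair", "csp_ova", "car_dwt", "all")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        self.validate()

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values: expected 2-D (trials x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values: non-finite values")
        n = self.values.shape[0]
        if self.labels.shape != (n,) or self.subjects.shape != (n,):
            raise ValidationError("labels/subjects: length must equal row count")
        if self.provenance not in self.PROVENANCES:
            raise ValidationError(f"provenance: unknown value {self.provenance!r}")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValidationError("feature_names: length must equal n_features")

    def select(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return FeatureMatrix(
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            subjects=self.subjects[idx].copy(),
            provenance=self.provenance,
            feature_names=list(self.feature_names),
            meta=dict(self.meta),
        )


# -- HDF5 container --------------------------------------------------------

def save_epochs(ds: EpochDataset, path) -> None:
    """Write ``ds`` to a single HDF5 container at ``path``.

    Layout: datasets ``/data``, ``/labels``, ``/subjects``; root attributes
    ``sfreq`` and ``channel_names``.
    """
    ds.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("subjects", data=ds.subjects)
        f.attrs["sfreq"] = float(ds.sfreq)
        f.attrs["channel_names"] = [str(c) for c in ds.channel_names]


def load_epochs(path) -> EpochDataset:
    """Load an epoch container written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "subjects"):
            if key not in f:
                raise FormatError(f"missing dataset '/{key}'")
        for attr in ("sfreq", "channel_names"):
            if attr not in f.attrs:
                raise FormatError(f"missing attribute '{attr}'")
        return EpochDataset(
            data=f["data"][()],
            labels=f["labels"][()],
            subjects=f["subjects"][()],
            sfreq=float(f.attrs["sfreq"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
        )


def save_features(fm: FeatureMatrix, path) -> None:
    """Write a feature matrix to an HDF5 container (CLI plumbing)."""
    fm.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fm.values)
        f.create_dataset("labels", data=fm.labels)
        f.create_dataset("subjects", data=fm.subjects)
        f.attrs["provenance"] = fm.provenance
        f.attrs["feature_names"] = [str(c) for c in fm.feature_names]


def load_features(path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        for key in ("values", "labels", "subjects"):
            if key not in f:
                raise FormatError(f"missing dataset '/{key}'")
        return FeatureMatrix(
            values=f["values"][()],
            labels=f["labels"][()],
            subjects=f["subjects"][()],
            provenance=str(f.attrs["provenance"]),
            feature_names=[str(c) for c in f.attrs["feature_names"]],
        )


def class_counts(ds: EpochDataset) -> pd.DataFrame:
    """Trial counts per (subject, label), zeros included for absent cells.

    Returns a DataFrame with columns ``subject``, ``label``, ``count`` whose
    counts sum to ``n_trials``.
    """
    subjects = np.unique(ds.subjects)
    rows = []
    for s in subjects:
        mask = ds.subjects == s
        counts = np.bincount(ds.labels[mask], minlength=N_CLASSES)
        for lab in range(N_CLASSES):
            rows.append((int(s), lab, int(counts[lab])))
    return pd.DataFrame(rows, columns=["subject", "label", "count"])
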