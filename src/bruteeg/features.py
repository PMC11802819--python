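"""Feature-extraction pipelines for epoched EEG.

Six pipelines produce a :class:`~bruteeg.epochs.FeatureMatrix` from an
:class:`~bruteeg.epochs.EpochDataset`:

``raw``
    trial tensor flattened to channels*samples columns;
``ica``
    channel-space FastICA unmixing fitted on the training trials, each
    component time series summarised per trial by (mean, sd, energy);
``pca``
    projection of the flattened trials onto all principal components of the
    training matrix (no dimensionality reduction);
``csp_pair`` / ``csp_ova``
    log-variance of common-spatial-pattern projections, one filter bank per
    class pair (6 contrasts) or per class-vs-rest contrast (4 contrasts);
``car_dwt``
    common average reference followed by a multilevel discrete wavelet
    transform, each band summarised per channel by (mean, sd, energy);
``all``
    column-wise concatenation of the six, in the fixed order
    (raw, ica, pca, csp_pair, csp_ova, car_dwt).

Everything that estimates parameters (ICA unmixing, PCA basis, CSP filters,
normalisation moments) is fitted on training trials only; transforming dev or
test rows never updates a fitted object.  Z-score normalisation (population
standard deviation; constant features map to zero) is a separate, fixed final
step applied after any pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import linalg

from .epochs import N_CLASSES, EpochDataset, FeatureMatrix
from .exceptions import StateError, ValidationError

ALL_ORDER = ("raw", "ica", "pca", "csp_pair", "csp_ova", "car_dwt")

#: Variance floor for log-variance CSP features.
VAR_FLOOR = 1e-12

# -- simple per-band / per-component summary ------------------------------

_STAT_NAMES = ("mean", "sd", "energy")


def _summary_stats(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """(mean, population sd, energy=sum of squares) along ``axis``, stacked last."""
    return np.stack(
        [x.mean(axis=axis), x.std(axis=axis), (x**2).sum(axis=axis)], axis=-1
    )


# -- common average reference ---------------------------------------------

def car(ds: EpochDataset) -> EpochDataset:
    """Common average reference: subtract the instantaneous channel mean.

    After CAR the mean across channels is zero at every trial and time
    sample; applying CAR twice is a no-op.
    """
    if ds.n_channels < 2:
        raise ValidationError("n_channels: CAR requires at least 2 channels")
    data = ds.data - ds.data.mean(axis=1, keepdims=True)
    return EpochDataset(
        data=data,
        labels=ds.labels.copy(),
        subjects=ds.subjects.copy(),
        sfreq=ds.sfreq,
        channel_names=list(ds.channel_names),
    )


# -- discrete wavelet features --------------------------------------------

def default_dwt_level(n_samples: int) -> int:
    return max(1, min(5, int(math.floor(math.log2(n_samples))) - 1))


def dwt_features(
    ds: EpochDataset,
    wavelet: str = "db4",
    level: int | None = None,
    summary: bool = True,
    provenance: str = "car_dwt",
) -> FeatureMatrix:
    """Multilevel DWT per trial and channel, summarised per band.

    Uses periodised signal extension so that, for an orthonormal wavelet, the
    band energies of each (trial, channel) signal sum exactly to its energy
    (Parseval).  Per band the summary statistics are (mean, sd, energy); with
    ``summary=False`` the raw coefficients are concatenated instead.

    Band order follows the decomposition: approximation at the deepest
    level, then detail bands from deepest to finest; channels vary slowest.
    """
    if level is None:
        level = default_dwt_level(ds.n_samples)
    if level < 1:
        raise ValidationError("level: must be >= 1")
    if ds.n_samples < 2**level:
        raise ValidationError(
            f"level: {level} too deep for {ds.n_samples} samples (need >= 2^level)"
        )
    wav = pywt.Wavelet(wavelet)
    band_names = [f"a{level}"] + [f"d{k}" for k in range(level, 0, -1)]
    rows = []
    with warnings.catch_warnings():
        # periodization is exact at any depth; silence pywt's boundary advice
        warnings.simplefilter("ignore", UserWarning)
        for t in range(ds.n_trials):
            feats = []
            for ch in range(ds.n_channels):
                coeffs = pywt.wavedec(ds.data[t, ch], wav, level=level, mode="periodization")
                for band in coeffs:
                    feats.append(_summary_stats(band) if summary else band)
            rows.append(np.concatenate(feats))
    names = []
    for ch in ds.channel_names:
        for band in band_names:
            if summary:
                names.extend(f"{ch}_{band}_{s}" for s in _STAT_NAMES)
            else:
                names.append(f"{ch}_{band}_coeffs")
    values = np.asarray(rows)
    if not summary:
        names = [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(
        values=values,
        labels=ds.labels,
        subjects=ds.subjects,
        provenance=provenance,
        feature_names=names,
    )


def dwt_band_energies(
    x: np.ndarray, wavelet: str = "haar", level: int = 1
) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose a 1-D signal; return (coefficient bands, per-band energies)."""
    coeffs = pywt.wavedec(np.asarray(x, float), wavelet, level=level, mode="periodization")
    return coeffs, np.array([(c**2).sum() for c in coeffs])


# -- raw ------------------------------------------------------------------

def raw_features(ds: EpochDataset) -> FeatureMatrix:
    """Flatten each trial to a channels*samples feature row."""
    values = ds.data.reshape(ds.n_trials, -1)
    names = [
        f"{ch}_t{t}" for ch in ds.channel_names for t in range(ds.n_samples)
    ]
    return FeatureMatrix(
        values=values,
        labels=ds.labels,
        subjects=ds.subjects,
        provenance="raw",
        feature_names=names,
    )


# -- PCA -------------------------------------------------------------------

class PCA:
    """Full-rank principal component analysis of a feature matrix.

    All components are retained (no dimensionality reduction); the transform
    is a rotation of the centred data, so total variance is preserved and
    transformed training columns are uncorrelated.  Component signs are fixed
    so each component's largest-magnitude loading is positive.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.components_: np.ndarray | None = None
        self.explained_variance_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "PCA":
        x = np.asarray(values, float)
        self.mean_ = x.mean(axis=0)
        xc = x - self.mean_
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        # deterministic sign: largest-|loading| entry of each component positive
        signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = vt * signs[:, None]
        n = max(x.shape[0] - 1, 1)
        self.explained_variance_ = s**2 / n
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise StateError("PCA.transform called before fit")
        x = np.asarray(values, float)
        if x.shape[1] != self.mean_.shape[0]:
            raise ValidationError("values: feature width differs from the fitted width")
        return (x - self.mean_) @ self.components_.T


def pca_fit_transform(train: FeatureMatrix, apply_to: FeatureMatrix) -> FeatureMatrix:
    """Fit PCA on the training rows only and project ``apply_to``."""
    pca = PCA().fit(train.values)
    values = pca.transform(apply_to.values)
    return FeatureMatrix(
        values=values,
        labels=apply_to.labels,
        subjects=apply_to.subjects,
        provenance="pca",
        feature_names=[f"pc{i}" for i in range(values.shape[1])],
    )


# -- ICA -------------------------------------------------------------------

class ICAExtractor:
    """Channel-space FastICA fitted on concatenated training trials.

    Symmetric FastICA with the logcosh contrast, initialised from a fixed
    internal seed so repeated fits on the same data are identical.  All
    components are retained.  If the iteration cap is reached before
    convergence the last iterate is used and ``converged_`` is False; the
    flag is copied into the ``meta`` of every transformed feature matrix.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-6, seed: int = 0) -> None:
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.mean_: np.ndarray | None = None
        self.unmixing_: np.ndarray | None = None
        self.converged_: bool | None = None

    def fit(self, train: EpochDataset) -> "ICAExtractor":
        # channels x (trials * samples)
        x = np.concatenate(list(train.data), axis=1)
        self.mean_ = x.mean(axis=1)
        xc = x - self.mean_[:, None]
        n = xc.shape[1]

        # whiten via eigendecomposition of the channel covariance
        cov = xc @ xc.T / n
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 1e-12, None)
        k = (evecs / np.sqrt(evals)).T  # whitening matrix
        z = k @ xc

        c = z.shape[0]
        rng = np.random.default_rng(self.seed)
        w = rng.standard_normal((c, c))
        w = self._sym_decorrelate(w)
        self.converged_ = False
        for _ in range(self.max_iter):
            wz = w @ z
            g = np.tanh(wz)
            g_prime = 1.0 - g**2
            w_new = (g @ z.T) / n - np.mean(g_prime, axis=1)[:, None] * w
            w_new = self._sym_decorrelate(w_new)
            delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
            w = w_new
            if delta < self.tol:
                self.converged_ = True
                break
        self.unmixing_ = w @ k
        return self

    @staticmethod
    def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
        s, u = np.linalg.eigh(w @ w.T)
        s = np.clip(s, 1e-12, None)
        return (u / np.sqrt(s)) @ u.T @ w

    def transform(self, ds: EpochDataset) -> FeatureMatrix:
        if self.unmixing_ is None:
            raise StateError("ICAExtractor.transform called before fit")
        if ds.n_channels != self.unmixing_.shape[1]:
            raise ValidationError("data: channel count differs from the fitted count")
        comps = np.einsum("kc,tcs->tks", self.unmixing_, ds.data - self.mean_[None, :, None])
        values = _summary_stats(comps).reshape(ds.n_trials, -1)
        names = [
            f"ic{i}_{s}" for i in range(self.unmixing_.shape[0]) for s in _STAT_NAMES
        ]
        return FeatureMatrix(
            values=values,
            labels=ds.labels,
            subjects=ds.subjects,
            provenance="ica",
            feature_names=names,
            meta={"ica_converged": bool(self.converged_)},
        )


def ica_fit_transform(train: EpochDataset, apply_to: EpochDataset) -> FeatureMatrix:
    """Fit FastICA on the training trials only and transform ``apply_to``."""
    return ICAExtractor().fit(train).transform(apply_to)


# -- CSP -------------------------------------------------------------------

@dataclass
class SpatialFilterBank:
    """CSP filters and eigenvalues for one two-way contrast.

    ``contrast`` is either a class pair ``(i, j)`` or ``("ova", i)`` for
    class ``i`` versus the pooled rest.  Eigenvalues are sorted descending
    and lie in [0, 1]; filter columns correspond index-wise to eigenvalues.
    ``n_keep`` filters are retained per contrast: the first and last
    ``n_keep // 2`` (the most discriminative ends of the spectrum).
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    contrast: tuple
    n_keep: int = 4

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValidationError("eigenvalues: must be sorted descending")
        if np.any(self.eigenvalues < -1e-9) or np.any(self.eigenvalues > 1 + 1e-9):
            raise ValidationError("eigenvalues: must lie in [0, 1]")
        if self.filters.shape[1] != self.eigenvalues.shape[0]:
            raise ValidationError("filters: one column per eigenvalue required")

    @property
    def selected(self) -> np.ndarray:
        """Retained filter columns: n_keep/2 from each end of the spectrum."""
        half = self.n_keep // 2
        n = self.filters.shape[1]
        idx = list(range(min(half, n))) + list(range(max(n - half, half), n))
        return self.filters[:, idx]

    @property
    def name(self) -> str:
        kind, a = self.contrast[0], self.contrast
        if kind == "ova":
            return f"ova{a[1]}"
        return f"{a[0]}v{a[1]}"


def _trial_covariances(ds: EpochDataset) -> np.ndarray:
    """Trace-normalised spatial covariance per trial."""
    xxt = np.einsum("tcs,tds->tcd", ds.data, ds.data)
    tr = np.trace(xxt, axis1=1, axis2=2)
    return xxt / tr[:, None, None]


def csp_solve(c1: np.ndarray, c2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``C1 w = lambda (C1 + C2) w``; eigenvalues sorted descending.

    Returns ``(eigenvalues, filters)`` with one filter per column.  The
    eigenvalues lie in [0, 1]; swapping ``c1`` and ``c2`` maps each
    eigenvalue to ``1 - lambda``.  A singular composite matrix is
    ridge-regularised (eps = 1e-9 * trace / n) before giving up.
    """
    composite = c1 + c2
    try:
        evals, evecs = linalg.eigh(c1, composite)
    except linalg.LinAlgError:
        n = composite.shape[0]
        ridge = 1e-9 * np.trace(composite) / n * np.eye(n)
        evals, evecs = linalg.eigh(c1, composite + ridge)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, 1.0)
    return evals, evecs[:, order]


def csp_fit(
    train: EpochDataset, scheme: str = "pairwise", n_keep: int = 4
) -> list[SpatialFilterBank]:
    """Fit CSP filter banks on training trials only.

    ``scheme='pairwise'`` yields one bank per class pair (6 for 4 classes);
    ``scheme='one_vs_all'`` one bank per class against the pooled rest (4).
    Class covariances are means of trace-normalised trial covariances.
    """
    if scheme not in ("pairwise", "one_vs_all"):
        raise ValidationError(f"scheme: unknown value {scheme!r}")
    present = np.unique(train.labels)
    covs = _trial_covariances(train)
    class_cov = {}
    for c in present:
        mask = train.labels == c
        if mask.sum() < 2:
            raise ValidationError(f"labels: class {c} has fewer than 2 trials")
        class_cov[int(c)] = covs[mask].mean(axis=0)
    banks = []
    if scheme == "pairwise":
        for i in range(N_CLASSES):
            for j in range(i + 1, N_CLASSES):
                if i not in class_cov or j not in class_cov:
                    continue
                evals, evecs = csp_solve(class_cov[i], class_cov[j])
                banks.append(SpatialFilterBank(evecs, evals, (i, j), n_keep))
    else:
        for i in range(N_CLASSES):
            if i not in class_cov:
                continue
            rest = covs[train.labels != i].mean(axis=0)
            evals, evecs = csp_solve(class_cov[i], rest)
            banks.append(SpatialFilterBank(evecs, evals, ("ova", i), n_keep))
    return banks


def csp_features(ds: EpochDataset, banks: list[SpatialFilterBank]) -> FeatureMatrix:
    """Log-variance of the retained CSP projections, concatenated per bank.

    Projections with variance below the floor (1e-12) yield the log of the
    floor instead of -inf.
    """
    if not banks:
        raise ValidationError("banks: at least one filter bank required")
    cols, names = [], []
    for bank in banks:
        w = bank.selected  # channels x kept
        proj = np.einsum("ck,tcs->tks", w, ds.data)
        var = proj.var(axis=-1)
        cols.append(np.log(np.maximum(var, VAR_FLOOR)))
        names.extend(f"csp_{bank.name}_f{i}" for i in range(w.shape[1]))
    provenance = "csp_ova" if banks[0].contrast[0] == "ova" else "csp_pair"
    return FeatureMatrix(
        values=np.concatenate(cols, axis=1),
        labels=ds.labels,
        subjects=ds.subjects,
        provenance=provenance,
        feature_names=names,
    )


# -- concatenation ---------------------------------------------------------

def concat_all(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate the six pipeline outputs column-wise, provenance 'all'.

    Parts must arrive in the fixed order (raw, ica, pca, csp_pair, csp_ova,
    car_dwt), share their row count and row order, and be non-empty.
    """
    provs = tuple(p.provenance for p in parts)
    if provs != ALL_ORDER:
        raise ValidationError(
            f"provenance: parts must arrive in order {ALL_ORDER}, got {provs}"
        )
    n = parts[0].n_trials
    if n == 0:
        raise ValidationError("values: parts must have at least one row")
    for p in parts:
        if p.n_trials != n:
            raise ValidationError("values: all parts must share the row count")
        if not np.array_equal(p.labels, parts[0].labels):
            raise ValidationError("labels: all parts must share row order")
    names = [f"{p.provenance}:{c}" for p in parts for c in p.feature_names]
    return FeatureMatrix(
        values=np.concatenate([p.values for p in parts], axis=1),
        labels=parts[0].labels,
        subjects=parts[0].subjects,
        provenance="all",
        feature_names=names,
    )


# -- normalisation ---------------------------------------------------------

class Normalizer:
    """Per-feature z-score with moments estimated on training rows only.

    Population standard deviation; features whose sd falls below ``tol`` are
    flagged constant and map to exactly zero.
    """

    def __init__(self, tol: float = 1e-12) -> None:
        self.tol = tol
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.constant_: np.ndarray | None = None

    def fit(self, train: FeatureMatrix) -> "Normalizer":
        x = train.values
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.constant_ = sd < self.tol
        self.scale_ = np.where(self.constant_, 1.0, sd)
        return self

    def apply(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self.mean_ is None:
            raise StateError("Normalizer.apply called before fit")
        if fm.n_features != self.mean_.shape[0]:
            raise ValidationError("values: feature width differs from the fitted width")
        values = (fm.values - self.mean_) / self.scale_
        values[:, self.constant_] = 0.0
        return FeatureMatrix(
            values=values,
            labels=fm.labels,
            subjects=fm.subjects,
            provenance=fm.provenance,
            feature_names=list(fm.feature_names),
            meta=dict(fm.meta),
        )


def normalize_fit(train: FeatureMatrix) -> Normalizer:
    return Normalizer().fit(train)


def normalize_apply(nz: Normalizer, fm: FeatureMatrix) -> FeatureMatrix:
    return nz.apply(fm)


# -- pipeline facade -------------------------------------------------------

class FeaturePipeline:
    """Fit-on-train / transform-anything facade over the six pipelines.

    ``method`` is one of raw, ica, pca, csp_pair, csp_ova, car_dwt, all.
    ``fit`` consumes training trials only; ``transform`` may then be applied
    to train, dev and test datasets alike.
    """

    METHODS = ("raw", "ica", "pca", "csp_pair", "csp_ova", "car_dwt", "all")

    def __init__(self, method: str, n_keep: int = 4, wavelet: str = "db4",
                 dwt_level: int | None = None) -> None:
        if method not in self.METHODS:
            raise ValidationError(f"method: unknown value {method!r}")
        self.method = method
        self.n_keep = n_keep
        self.wavelet = wavelet
        self.dwt_level = dwt_level
        self._state: dict = {}

    def fit(self, train: EpochDataset) -> "FeaturePipeline":
        m = self.method
        if m == "ica":
            self._state["ica"] = ICAExtractor().fit(train)
        elif m == "pca":
            self._state["pca"] = PCA().fit(raw_features(train).values)
        elif m == "csp_pair":
            self._state["banks"] = csp_fit(train, "pairwise", self.n_keep)
        elif m == "csp_ova":
            self._state["banks"] = csp_fit(train, "one_vs_all", self.n_keep)
        elif m == "all":
            self._state["ica"] = ICAExtractor().fit(train)
            self._state["pca"] = PCA().fit(raw_features(train).values)
            self._state["banks_pair"] = csp_fit(train, "pairwise", self.n_keep)
            self._state["banks_ova"] = csp_fit(train, "one_vs_all", self.n_keep)
        self._state["fitted"] = True
        return self

    def transform(self, ds: EpochDataset) -> FeatureMatrix:
        if not self._state.get("fitted"):
            raise StateError("FeaturePipeline.transform called before fit")
        m = self.method
        if m == "raw":
            return raw_features(ds)
        if m == "ica":
            return self._state["ica"].transform(ds)
        if m == "pca":
            fm = raw_features(ds)
            values = self._state["pca"].transform(fm.values)
            return FeatureMatrix(
                values=values, labels=ds.labels, subjects=ds.subjects,
                provenance="pca",
                feature_names=[f"pc{i}" for i in range(values.shape[1])],
            )
        if m in ("csp_pair", "csp_ova"):
            return csp_features(ds, self._state["banks"])
        if m == "car_dwt":
            return dwt_features(car(ds), wavelet=self.wavelet, level=self.dwt_level)
        # 'all'
        parts = [
            raw_features(ds),
            self._state["ica"].transform(ds),
        ]
        fm = raw_features(ds)
        values = self._state["pca"].transform(fm.values)
        parts.append(FeatureMatrix(
            values=values, labels=ds.labels, subjects=ds.subjects,
            provenance="pca",
            feature_names=[f"pc{i}" for i in range(values.shape[1])],
        ))
        parts.append(csp_features(ds, self._state["banks_pair"]))
        parts.append(csp_features(ds, self._state["banks_ova"]))
        parts.append(dwt_features(car(ds), wavelet=self.wavelet, level=self.dwt_level))
        return concat_all(parts)
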