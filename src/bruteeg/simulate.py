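"""Synthetic multi-subject, four-class EEG-like epoch generator.

The generator emulates the regime of a multi-subject inner-speech recording:
four classes, 45-60 trials per class per subject, class-dependent source
power (so spatial-filter and tree models have something to find), and
subject-specific sensor mixing (so cross-subject transfer is degraded).

Generative model, fixed and documented:

1. A base mixing matrix ``A0`` (channels x sources) with independent
   standard-normal entries is drawn from the master RNG.
2. Each subject ``j`` mixes through ``A_j = A0 + sigma_subj * E_j`` with
   ``E_j`` standard normal; ``sigma_subj = 0`` makes all subjects identical.
3. Each class ``c`` owns a distinct contiguous block of sources whose
   variance is ``class_power_contrast``; all other sources have variance 1.
4. Per trial, sources are white Gaussian noise band-limited to 1-40 Hz
   (4th-order Butterworth, forward-backward, gain-normalised to unit power)
   and scaled by the square root of the class variance vector; the sensor
   signal is ``A_j @ S`` plus white sensor noise scaled so the per-trial
   signal-to-noise power ratio equals ``snr`` exactly.

Trial counts per (subject, class) are drawn uniformly from
``trials_per_class_range``.  The master seed spawns four named substreams
(mixing, sources, noise, counts), so the same config always yields a
bit-identical dataset and changing, say, the noise draw does not shift the
mixing draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import N_CLASSES, EpochDataset
from .exceptions import ValidationError

# Substream order is part of the on-disk contract: mixing, sources, noise, counts.
_STREAMS = ("mixing", "sources", "noise", "counts")


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Defaults mirror the emulated recording regime: 10 subjects, four classes
    with 45-60 trials each, 1-s epochs, moderate class contrast and
    cross-subject variability.
    """

    n_subjects: int = 10
    n_channels: int = 16
    sfreq: float = 256.0
    epoch_seconds: float = 1.0
    trials_per_class_range: tuple[int, int] = (45, 60)
    n_sources: int | None = None  # default: n_channels
    class_power_contrast: float = 3.0
    subject_variability: float = 0.3
    snr: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources is None:
            self.n_sources = self.n_channels
        self.validate()

    def validate(self) -> None:
        lo, hi = self.trials_per_class_range
        if self.n_subjects < 1:
            raise ValidationError("n_subjects: must be >= 1")
        if self.n_channels < 2:
            raise ValidationError("n_channels: must be >= 2")
        if self.sfreq <= 0:
            raise ValidationError("sfreq: must be > 0")
        if self.epoch_seconds <= 0:
            raise ValidationError("epoch_seconds: must be > 0")
        if not (1 <= lo <= hi):
            raise ValidationError("trials_per_class_range: need 1 <= low <= high")
        if self.n_sources < N_CLASSES:
            raise ValidationError("n_sources: need at least one source per class")
        if self.class_power_contrast < 1:
            raise ValidationError("class_power_contrast: must be >= 1")
        if self.subject_variability < 0:
            raise ValidationError("subject_variability: must be >= 0")
        if self.snr <= 0:
            raise ValidationError("snr: must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.sfreq * self.epoch_seconds))


def _substreams(cfg: SynthConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _mixing_matrices(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Base + per-subject mixing; shape (n_subjects, n_channels, n_sources)."""
    a0 = rng.standard_normal((cfg.n_channels, cfg.n_sources))
    out = np.empty((cfg.n_subjects, cfg.n_channels, cfg.n_sources))
    for j in range(cfg.n_subjects):
        # E_j is drawn even when sigma is 0 to keep the stream position stable.
        e = rng.standard_normal((cfg.n_channels, cfg.n_sources))
        out[j] = a0 + cfg.subject_variability * e
    return out


def _class_variances(cfg: SynthConfig) -> np.ndarray:
    """Per-class source-variance vectors; shape (4, n_sources).

    Class ``c`` owns the contiguous source block ``[c*b, (c+1)*b)`` with
    ``b = n_sources // 4``; owned sources have variance
    ``class_power_contrast``, the rest variance 1.
    """
    block = cfg.n_sources // N_CLASSES
    v = np.ones((N_CLASSES, cfg.n_sources))
    for c in range(N_CLASSES):
        v[c, c * block : (c + 1) * block] = cfg.class_power_contrast
    return v


def _bandpass_sos(sfreq: float) -> np.ndarray:
    high = min(40.0, 0.45 * sfreq)  # keep the band valid at low sampling rates
    return signal.butter(4, [1.0, high], btype="bandpass", fs=sfreq, output="sos")


def _filter_gain(sos: np.ndarray) -> float:
    """Power gain of the forward-backward filter for white input."""
    _, h = signal.sosfreqz(sos, worN=4096)
    return float(np.mean(np.abs(h) ** 4))


def planted_truth(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground truth used by :func:`generate` with the same config.

    Returns
    -------
    class_variances
        Array ``(4, n_sources)`` of per-class source variances ``v_c``.
    mixing
        Array ``(n_subjects, n_channels, n_sources)`` of per-subject mixing
        matrices ``A_j``.
    """
    streams = _substreams(cfg)
    return _class_variances(cfg), _mixing_matrices(cfg, streams["mixing"])


def generate(cfg: SynthConfig) -> EpochDataset:
    """Generate a synthetic epoch dataset; pure function of ``cfg``.

    Trials are ordered by subject (1..n_subjects), then class (0..3), then
    trial index within the (subject, class) cell.
    """
    cfg.validate()
    streams = _substreams(cfg)
    n_samp = cfg.n_samples
    mixing = _mixing_matrices(cfg, streams["mixing"])
    variances = _class_variances(cfg)

    lo, hi = cfg.trials_per_class_range
    counts = streams["counts"].integers(lo, hi + 1, size=(cfg.n_subjects, N_CLASSES))
    n_trials = int(counts.sum())

    sos = _bandpass_sos(cfg.sfreq)
    gain = np.sqrt(_filter_gain(sos))

    data = np.empty((n_trials, cfg.n_channels, n_samp))
    labels = np.empty(n_trials, dtype=np.int64)
    subjects = np.empty(n_trials, dtype=np.int64)

    # Band-limited unit-power sources for all trials at once.
    raw = streams["sources"].standard_normal((n_trials, cfg.n_sources, n_samp))
    sources = signal.sosfiltfilt(sos, raw, axis=-1) / gain

    noise = streams["noise"].standard_normal((n_trials, cfg.n_channels, n_samp))

    t = 0
    for j in range(cfg.n_subjects):
        for c in range(N_CLASSES):
            for _ in range(int(counts[j, c])):
                s = sources[t] * np.sqrt(variances[c])[:, None]
                x = mixing[j] @ s
                sig_power = np.mean(x**2)
                e = noise[t]
                noise_power = np.mean(e**2)
                x = x + e * np.sqrt(sig_power / (cfg.snr * noise_power))
                data[t] = x
                labels[t] = c
                subjects[t] = j + 1
                t += 1
    return EpochDataset(
        data=data,
        labels=labels,
        subjects=subjects,
        sfreq=cfg.sfreq,
        channel_names=[f"ch{i:02d}" for i in range(cfg.n_channels)],
    )
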