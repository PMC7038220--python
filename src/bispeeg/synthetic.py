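"""Synthetic EEG cohorts with controllable quadratic phase coupling (QPC).

The generator emulates two groups of resting-state EEG recordings whose
*only* systematic difference is the probability that oscillatory triplets
(f1, f2, f1+f2) are quadratically phase coupled, i.e. phi3 = phi1 + phi2.
Phase coupling is invisible to the power spectrum (component amplitudes are
identical in both classes) but produces a peak in the bispectrum at the
bifrequency (f1, f2), so a pipeline built on bispectral statistics is
load-bearing for separating the classes.

Channels are assembled from independent fixed-length epochs with phases
re-drawn per epoch.  This matters: a single uncoupled realisation has a
*constant* non-zero triple product X(f1)X(f2)X*(f1+f2), and only phase
randomisation across epochs makes the block-averaged bispectrum of the
uncoupled class decay toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_io import EEGRecord

__all__ = [
    "SynthConfig",
    "generate_qpc_segment",
    "generate_cohort",
    "pink_noise",
]

#: default oscillatory triplets; every f1 + f2 <= 40 Hz so that the coupled
#: component survives a 0.3-40 Hz band-pass in downstream preprocessing
DEFAULT_TRIPLETS: tuple[tuple[float, float], ...] = ((8.0, 13.0), (6.0, 10.0), (11.0, 18.0))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a two-class synthetic EEG cohort.

    ``coupling_strength_normal`` / ``coupling_strength_asd`` are the
    per-epoch probabilities that a triplet is phase coupled in the
    respective class; the contrast between them is the (only) class signal.
    """

    n_normal: int = 37
    n_asd: int = 40
    n_channels: int = 64
    fs: float = 500.0
    duration_s: float = 60.0
    triplet_freqs: tuple[tuple[float, float], ...] = DEFAULT_TRIPLETS
    coupling_strength_normal: float = 0.1
    coupling_strength_asd: float = 0.9
    noise_exponent: float = 1.0
    snr_db: float = 10.0
    epoch_samples: int = 512
    freq_jitter_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in (("coupling_strength_normal", self.coupling_strength_normal),
                        ("coupling_strength_asd", self.coupling_strength_asd)):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {c}")
        if self.n_normal < 1 or self.n_asd < 1 or self.n_channels < 1:
            raise ValueError("subject and channel counts must be >= 1")
        _check_triplets(self.triplet_freqs, self.fs)
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.epoch_samples < 8:
            raise ValueError("epoch_samples must be >= 8")


def _check_triplets(triplets: Sequence[tuple[float, float]], fs: float) -> None:
    if len(triplets) == 0:
        raise ValueError("need at least one (f1, f2) triplet")
    for f1, f2 in triplets:
        if f1 <= 0 or f2 <= 0:
            raise ValueError(f"triplet frequencies must be positive, got ({f1}, {f2})")
        if f1 + f2 >= fs / 2:
            raise ValueError(
                f"aliasing: f1 + f2 = {f1 + f2} Hz must be below the Nyquist "
                f"frequency fs/2 = {fs / 2} Hz"
            )


def pink_noise(n_samples: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean 1/f**exponent Gaussian noise of unit variance, via spectral shaping."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _epoch(
    triplet_freqs: Sequence[tuple[float, float]],
    coupled: Sequence[bool],
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n) / fs
    x = np.zeros(n)
    for (f1, f2), c in zip(triplet_freqs, coupled):
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        p3 = (p1 + p2) if c else rng.uniform(0, 2 * np.pi)
        x += np.cos(2 * np.pi * f1 * t + p1)
        x += np.cos(2 * np.pi * f2 * t + p2)
        x += np.cos(2 * np.pi * (f1 + f2) * t + p3)
    return x


def generate_qpc_segment(
    triplet_freqs: Sequence[tuple[float, float]],
    coupled: bool | Sequence[bool],
    n_samples: int,
    fs: float = 500.0,
    snr_db: float = np.inf,
    seed: int | np.random.Generator = 0,
    noise_exponent: float = 1.0,
    epoch_samples: int = 512,
) -> np.ndarray:
    """Generate one zero-mean channel of QPC test signal.

    Each triplet (f1, f2) contributes unit cosines at f1, f2 and f1+f2.
    When ``coupled`` the third phase equals the sum of the first two; when
    not, it is an independent uniform draw.  Phases are re-randomised every
    ``epoch_samples`` samples.  1/f**noise_exponent noise is added at
    ``snr_db``; ``snr_db=inf`` means no noise.
    """
    triplet_freqs = [(float(f1), float(f2)) for f1, f2 in triplet_freqs]
    _check_triplets(triplet_freqs, fs)
    if np.isscalar(coupled):
        coupled_flags = [bool(coupled)] * len(triplet_freqs)
    else:
        coupled_flags = [bool(c) for c in coupled]
        if len(coupled_flags) != len(triplet_freqs):
            raise ValueError("coupled flags must match the number of triplets")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pieces = []
    produced = 0
    while produced < n_samples:
        n = min(epoch_samples, n_samples - produced)
        pieces.append(_epoch(triplet_freqs, coupled_flags, n, fs, rng))
        produced += n
    x = np.concatenate(pieces)

    if np.isfinite(snr_db):
        noise = pink_noise(n_samples, noise_exponent, rng)
        sig_power = np.mean(x**2)
        noise_power = sig_power / (10.0 ** (snr_db / 10.0))
        x = x + noise * np.sqrt(noise_power)
    return x - x.mean()


def _subject_record(
    cfg: SynthConfig,
    subject_id: str,
    class_label: str,
    coupling: float,
    rng: np.random.Generator,
) -> EEGRecord:
    n_samples = int(round(cfg.duration_s * cfg.fs))
    # per-subject frequency jitter (<= freq_jitter_hz) for inter-subject variability
    jitter = rng.uniform(-cfg.freq_jitter_hz, cfg.freq_jitter_hz, size=(len(cfg.triplet_freqs), 2))
    freqs = [
        (max(f1 + d1, 0.5), max(f2 + d2, 0.5))
        for (f1, f2), (d1, d2) in zip(cfg.triplet_freqs, jitter)
    ]
    data = np.empty((cfg.n_channels, n_samples))
    n_trip = len(freqs)
    for ch in range(cfg.n_channels):
        pieces = []
        produced = 0
        while produced < n_samples:
            n = min(cfg.epoch_samples, n_samples - produced)
            flags = rng.random(n_trip) < coupling
            pieces.append(_epoch(freqs, flags, n, cfg.fs, rng))
            produced += n
        x = np.concatenate(pieces)
        if np.isfinite(cfg.snr_db):
            noise = pink_noise(n_samples, cfg.noise_exponent, rng)
            noise_power = np.mean(x**2) / (10.0 ** (cfg.snr_db / 10.0))
            x = x + noise * np.sqrt(noise_power)
        data[ch] = x - x.mean()
    names = [f"EEG{ch + 1:03d}" for ch in range(cfg.n_channels)]
    return EEGRecord(
        data=data, fs=cfg.fs, channel_names=names,
        subject_id=subject_id, class_label=class_label,
    )


def generate_cohort(cfg: SynthConfig) -> list[EEGRecord]:
    """Generate the full labeled cohort: ``n_normal`` controls then ``n_asd`` cases.

    Deterministic: the same config (including seed) yields bit-identical records.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[EEGRecord] = []
    for i in range(cfg.n_normal):
        records.append(
            _subject_record(cfg, f"N{i + 1:03d}", "normal", cfg.coupling_strength_normal, rng)
        )
    for i in range(cfg.n_asd):
        records.append(
            _subject_record(cfg, f"A{i + 1:03d}", "asd", cfg.coupling_strength_asd, rng)
        )
    return records
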