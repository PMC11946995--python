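"""Log-mel spectrogram features and waveform augmentation.

Each sweep response is converted into a 256 x 218 log-mel spectrogram: the
waveform is resampled to the analysis rate, trimmed/zero-padded to a canonical
length, short-time Fourier transformed with a Hann window and hop 256, mapped
through 256 triangular filters evenly spaced on the mel scale
``f_mel = 2595 log10(1 + f/700)``, and converted to decibels
``X_dB = 10 log10(X^2)``.  Spectrograms are standardized by a global mean and
standard deviation; training data may additionally be augmented at the
waveform level by pitch shifting (+/- 3 semitones) and time stretching
(factors 0.9 / 1.1).

A note on the canonical length: a 2.5 s sweep at the 44.1 kHz capture rate
framed with hop 256 would give ~431 frames.  The pipeline therefore analyzes
at 22 050 Hz and fixes the canonical length at 55 552 samples so that centered
framing yields exactly 218 time frames, reproducing the published feature
shape with the published hop.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.signal import get_window, resample_poly

from .excitation import ConfigurationError, Recording

__all__ = [
    "FeatureConfig",
    "Spectrogram",
    "NormalizationStats",
    "stft",
    "istft",
    "power_to_db",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "logmel",
    "compute_norm_stats",
    "normalize",
    "denormalize",
    "augment",
    "time_stretch",
    "pitch_shift",
    "resample",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the log-mel front end (defaults give 256 x 218)."""

    n_fft: int = 2048
    hop: int = 256
    n_mels: int = 256
    analysis_rate: float = 22050.0
    canonical_length: int = 55552
    db_floor: float = 1e-10
    f_min: float = 0.0
    f_max: float | None = None  # defaults to analysis_rate / 2

    def __post_init__(self) -> None:
        if self.hop <= 0:
            raise ConfigurationError(f"hop must be positive, got {self.hop}")
        if self.n_fft <= 0 or self.n_fft % 2:
            raise ConfigurationError(f"n_fft must be a positive even int, got {self.n_fft}")
        if self.n_mels <= 0:
            raise ConfigurationError(f"n_mels must be positive, got {self.n_mels}")
        fmax = self.f_max if self.f_max is not None else self.analysis_rate / 2
        if not self.f_min < fmax <= self.analysis_rate / 2:
            raise ConfigurationError(
                f"need f_min < f_max <= analysis_rate/2, got "
                f"[{self.f_min}, {fmax}] at rate {self.analysis_rate}"
            )

    @property
    def effective_f_max(self) -> float:
        return self.f_max if self.f_max is not None else self.analysis_rate / 2

    @property
    def n_frames(self) -> int:
        """Frame count of a canonical-length input under centered framing."""
        return 1 + self.canonical_length // self.hop


@dataclass
class Spectrogram:
    """A (n_mels, n_frames) matrix of dB-scaled mel energies.

    Rows run low to high frequency, columns early to late time.  ``meta`` is
    copied from the source recording.
    """

    values: np.ndarray
    meta: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"spectrogram must be 2-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class NormalizationStats:
    """Global mean/std used to standardize spectrogram values.

    ``scope`` records whether the statistics were fitted on the training
    portion only (default, leakage-free) or on the entire dataset (the
    published protocol).
    """

    mu: float
    sigma: float
    scope: Literal["train_only", "entire_dataset"] = "train_only"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def stft(waveform: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Short-time Fourier transform with Hann window and centered framing.

    The waveform is reflect-padded by ``n_fft // 2`` on both ends, so frame
    ``m`` is centered on sample ``m * hop`` and the frame count is
    ``1 + len(waveform) // hop``.  Returns the complex one-sided transform
    with shape ``(n_fft // 2 + 1, n_frames)``.
    """
    config = config or FeatureConfig()
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("waveform must be a non-empty 1-D array")
    n_fft, hop = config.n_fft, config.hop
    pad = n_fft // 2
    if x.size > pad:
        xp = np.pad(x, pad, mode="reflect")
    else:  # too short for full reflection; fall back to zeros at the edges
        xp = np.pad(x, pad, mode="constant")
    n_frames = 1 + x.size // hop
    w = get_window("hann", n_fft, fftbins=True)
    idx = hop * np.arange(n_frames)[:, None] + np.arange(n_fft)[None, :]
    frames = xp[idx] * w
    return np.fft.rfft(frames, axis=1).T


def istft(X: np.ndarray, config: FeatureConfig | None = None, length: int | None = None) -> np.ndarray:
    """Inverse STFT by windowed overlap-add (used by the phase vocoder)."""
    config = config or FeatureConfig()
    n_fft, hop = config.n_fft, config.hop
    w = get_window("hann", n_fft, fftbins=True)
    frames = np.fft.irfft(X.T, n=n_fft, axis=1) * w
    n_frames = frames.shape[0]
    out_len = n_fft + hop * (n_frames - 1)
    y = np.zeros(out_len)
    norm = np.zeros(out_len)
    for m in range(n_frames):
        s = m * hop
        y[s : s + n_fft] += frames[m]
        norm[s : s + n_fft] += w**2
    y = y / np.maximum(norm, 1e-12)
    pad = n_fft // 2
    y = y[pad:-pad] if out_len > 2 * pad else y
    if length is not None:
        y = _fix_length(y, length)
    return y


def power_to_db(X: np.ndarray, db_floor: float = 1e-10) -> np.ndarray:
    """Map amplitudes to decibels: ``10 log10(max(|X|, floor)^2)``."""
    mag = np.abs(np.asarray(X, dtype=np.float64))
    return 20.0 * np.log10(np.maximum(mag, db_floor))


def hz_to_mel(f):
    """Mel scale: ``2595 log10(1 + f / 700)``."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return out if out.ndim else float(out)


def mel_to_hz(m):
    """Inverse mel scale: ``700 (10^(m / 2595) - 1)``."""
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("mel value must be non-negative")
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return out if out.ndim else float(out)


def mel_filterbank(config: FeatureConfig | None = None) -> np.ndarray:
    """Triangular filterbank evenly spaced on the mel scale.

    Returns a ``(n_mels, n_fft // 2 + 1)`` nonnegative matrix with unit-peak
    triangles whose centers are equally spaced in mel between ``f_min`` and
    ``f_max``.  Raises if the FFT resolution leaves any filter empty.
    """
    config = config or FeatureConfig()
    return _mel_filterbank_cached(config)


@lru_cache(maxsize=8)
def _mel_filterbank_cached(config: FeatureConfig) -> np.ndarray:
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.arange(n_bins) * config.analysis_rate / config.n_fft
    mel_pts = np.linspace(
        hz_to_mel(config.f_min), hz_to_mel(config.effective_f_max), config.n_mels + 2
    )
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((config.n_mels, n_bins))
    for i in range(config.n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    if np.any(fb.sum(axis=1) == 0):
        empty = int(np.sum(fb.sum(axis=1) == 0))
        raise ConfigurationError(
            f"{empty} mel filters have no FFT-bin support; increase n_fft or "
            f"decrease n_mels"
        )
    return fb


def _fix_length(x: np.ndarray, length: int) -> np.ndarray:
    if x.size >= length:
        return x[:length]
    return np.pad(x, (0, length - x.size))


def resample(x: np.ndarray, orig_rate: float, target_rate: float) -> np.ndarray:
    """Polyphase resampling between two (possibly non-integer-ratio) rates."""
    if orig_rate == target_rate:
        return np.asarray(x, dtype=np.float64)
    frac = Fraction(target_rate / orig_rate).limit_denominator(1000)
    return resample_poly(np.asarray(x, dtype=np.float64), frac.numerator, frac.denominator)


def logmel(rec: Recording, config: FeatureConfig | None = None) -> Spectrogram:
    """Full log-mel pipeline: resample, canonicalize, STFT, mel, dB.

    Output shape is ``(n_mels, 1 + canonical_length // hop)`` — (256, 218)
    with defaults — regardless of the recording's native rate or length.
    """
    config = config or FeatureConfig()
    if len(rec) == 0:
        raise ValueError("cannot featurize an empty recording")
    x = resample(rec.samples, rec.sample_rate, config.analysis_rate)
    x = _fix_length(x, config.canonical_length)
    X = np.abs(stft(x, config))
    mel = mel_filterbank(config) @ X
    return Spectrogram(values=power_to_db(mel, config.db_floor), meta=rec.meta)


def compute_norm_stats(
    spectrograms: Iterable[Spectrogram],
    scope: Literal["train_only", "entire_dataset"] = "train_only",
) -> NormalizationStats:
    """Global mean/std over the values of a spectrogram collection."""
    arrs = [s.values for s in spectrograms]
    if not arrs:
        raise ValueError("need at least one spectrogram")
    stacked = np.concatenate([a.ravel() for a in arrs])
    mu = float(stacked.mean())
    sigma = float(stacked.std())
    if sigma <= 0:
        raise ValueError("zero variance across spectrogram collection")
    return NormalizationStats(mu=mu, sigma=sigma, scope=scope)


def normalize(spec: Spectrogram, stats: NormalizationStats) -> Spectrogram:
    return Spectrogram(values=(spec.values - stats.mu) / stats.sigma, meta=spec.meta)


def denormalize(spec: Spectrogram, stats: NormalizationStats) -> Spectrogram:
    return Spectrogram(values=spec.values * stats.sigma + stats.mu, meta=spec.meta)


# --- Waveform augmentation (phase vocoder) ----------------------------------

_PV_CONFIG = FeatureConfig(n_fft=2048, hop=512, n_mels=8, analysis_rate=44100.0)


def _phase_vocoder(X: np.ndarray, rate: float, hop: int, n_fft: int) -> np.ndarray:
    """Stretch an STFT in time by ``1 / rate`` with phase accumulation."""
    n_bins, n_frames = X.shape
    steps = np.arange(0, n_frames, rate)
    omega = 2 * np.pi * np.arange(n_bins) * hop / n_fft  # expected phase advance
    out = np.empty((n_bins, len(steps)), dtype=complex)
    phase = np.angle(X[:, 0])
    Xpad = np.concatenate([X, np.zeros((n_bins, 2), dtype=complex)], axis=1)
    for j, step in enumerate(steps):
        k = int(step)
        frac = step - k
        mag = (1 - frac) * np.abs(Xpad[:, k]) + frac * np.abs(Xpad[:, k + 1])
        out[:, j] = mag * np.exp(1j * phase)
        dphi = np.angle(Xpad[:, k + 1]) - np.angle(Xpad[:, k]) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase += omega + dphi
    return out


def time_stretch(x: np.ndarray, factor: float) -> np.ndarray:
    """Stretch a waveform in time without changing pitch.

    ``factor > 1`` speeds the signal up; the output length is
    ``round(len(x) / factor)``.
    """
    if factor <= 0:
        raise ValueError(f"stretch factor must be positive, got {factor}")
    x = np.asarray(x, dtype=np.float64)
    target = int(round(x.size / factor))
    if factor == 1.0:
        return x.copy()
    cfg = _PV_CONFIG
    X = stft(x, cfg)
    Y = _phase_vocoder(X, factor, cfg.hop, cfg.n_fft)
    return _fix_length(istft(Y, cfg), target)


def pitch_shift(x: np.ndarray, sample_rate: float, semitones: float) -> np.ndarray:
    """Shift pitch by a (possibly fractional) number of semitones.

    Resampling scales all frequencies by ``2^(semitones / 12)``; a phase
    vocoder stretch then restores the original duration.
    """
    if semitones == 0:
        return np.asarray(x, dtype=np.float64).copy()
    alpha = 2.0 ** (semitones / 12.0)
    x = np.asarray(x, dtype=np.float64)
    sped = resample(x, sample_rate, sample_rate / alpha)  # freq x alpha
    return _fix_length(time_stretch(sped, 1.0 / alpha), x.size)


def augment(
    waveform: np.ndarray,
    rng: np.random.Generator,
    sample_rate: float = 44100.0,
    semitones: float | None = None,
    stretch: float | None = None,
    stretch_choices: Sequence[float] = (0.9, 1.1),
) -> np.ndarray:
    """Randomly pitch-shift and time-stretch a waveform.

    The semitone offset is drawn uniformly from [-3, 3] and the stretch factor
    from ``stretch_choices`` unless given explicitly.  The result is trimmed
    or zero-padded back to the input length, so augmented recordings stay
    compatible with the canonical feature pipeline.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot augment an empty waveform")
    if semitones is None:
        semitones = float(rng.uniform(-3.0, 3.0))
    if stretch is None:
        stretch = float(rng.choice(np.asarray(stretch_choices, dtype=np.float64)))
    y = pitch_shift(x, sample_rate, semitones)
    if stretch != 1.0:
        y = time_stretch(y, stretch)
    y = _fix_length(y, x.size)
    peak = np.max(np.abs(y))
    if peak > 1.0:  # keep within full scale after vocoder ringing
        y = y / peak
    return y
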