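"""Peripheral auditory model: waveform -> auditory spectrogram -> patches.

The front end emulates early cochlear processing: a bank of 128 asymmetric
constant-Q bandpass filters equally spaced on a log-frequency axis (24
filters/octave starting at 180 Hz, Q_ERB ~ 4), spectral sharpening by a first
difference across adjacent channels, half-wave rectification, and short-term
leaky integration with an exponential kernel (tau = 10 ms) sampled every
10 ms.  The result is a non-negative time x frequency energy matrix S(t, f).

Three consecutive 128-channel frames are concatenated into 384-dimensional
patches; these patches are the visible units of the simultaneous layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.io.wavfile
import scipy.signal

__all__ = [
    "AudioSignal",
    "AuditorySpectrogram",
    "PatchSet",
    "PeripheralConfig",
    "channel_center_freqs",
    "cochleagram",
    "extract_patches",
    "load_wav",
    "save_spectrogram",
    "load_spectrogram",
]

CANONICAL_RATE = 8000


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform with its sample rate (canonically 8 kHz)."""

    samples: np.ndarray
    sample_rate: int = CANONICAL_RATE

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if samples.ndim != 1:
            raise ValueError("AudioSignal expects a mono 1-D sample array")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def resampled(self, rate: int = CANONICAL_RATE) -> "AudioSignal":
        if self.sample_rate == rate:
            return self
        g = np.gcd(int(self.sample_rate), int(rate))
        out = scipy.signal.resample_poly(
            self.samples, rate // g, self.sample_rate // g
        )
        return AudioSignal(out, rate)


@dataclass(frozen=True)
class AuditorySpectrogram:
    """Frames x 128 non-negative energy matrix on a 10 ms frame clock."""

    values: np.ndarray
    frame_step: float
    channel_center_freqs: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        cf = np.asarray(self.channel_center_freqs, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != cf.size:
            raise ValueError("values must be frames x n_channels")
        if np.any(np.diff(cf) <= 0):
            raise ValueError("center frequencies must be strictly increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_center_freqs", cf)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PatchSet:
    """3-frame spectrogram patches flattened to 384-dim vectors."""

    patches: np.ndarray  # (n_patches, 3 * n_channels)
    frame_index: np.ndarray  # time index of each patch's *last* frame


@dataclass(frozen=True)
class PeripheralConfig:
    n_channels: int = 128
    filters_per_octave: int = 24
    f_min: float = 180.0
    q_erb: float = 4.0
    frame_step: float = 0.010
    tau_integrate: float = 0.010
    # high-side skirt is steeper than the low side (asymmetric filters)
    asymmetry: float = 0.6
    sample_rate: int = CANONICAL_RATE

    def center_freqs(self) -> np.ndarray:
        k = np.arange(self.n_channels)
        return self.f_min * 2.0 ** (k / self.filters_per_octave)


def channel_center_freqs(config: PeripheralConfig | None = None) -> np.ndarray:
    return (config or PeripheralConfig()).center_freqs()


@lru_cache(maxsize=8)
def _filterbank_response(n_fft: int, config: PeripheralConfig) -> np.ndarray:
    """Complex one-sided frequency responses, shape (n_channels, n_fft//2+1).

    Each channel is an asymmetric Gaussian magnitude around its center
    frequency (ERB = cf / Q_ERB, high-frequency skirt narrowed by the
    asymmetry factor) with a frequency-dependent group delay emulating the
    cochlear traveling wave (longer latency at low frequencies).  Channels
    whose center frequency exceeds Nyquist keep their (vanishing) in-band
    tail, so they are retained but carry near-zero energy.
    """
    f = np.fft.rfftfreq(n_fft, d=1.0 / config.sample_rate)
    cf = config.center_freqs()[:, None]
    erb = cf / config.q_erb
    sigma = erb / np.sqrt(2.0 * np.pi)  # Gaussian with matching ERB
    dev = f[None, :] - cf
    width = np.where(dev > 0, config.asymmetry * sigma, sigma)
    mag = np.exp(-0.5 * (dev / width) ** 2)
    group_delay = 3.0 / (2.0 * np.pi * erb)  # seconds, per channel
    phase = np.exp(-2j * np.pi * f[None, :] * group_delay)
    return (mag * phase).astype(np.complex128)


def cochleagram(
    signal: AudioSignal, config: PeripheralConfig | None = None
) -> AuditorySpectrogram:
    """Auditory spectrogram S(t, f): filterbank, cross-channel first
    difference, half-wave rectification, leaky integration, 10 ms frames."""
    config = config or PeripheralConfig()
    signal = signal.resampled(config.sample_rate)
    x = signal.samples
    if x.size == 0:
        raise ValueError("empty signal")
    step = int(round(config.frame_step * config.sample_rate))
    if x.size < step:
        raise ValueError("signal shorter than one frame")

    n_fft = int(scipy.fft.next_fast_len(x.size + config.sample_rate // 10))
    H = _filterbank_response(n_fft, config)
    X = np.fft.rfft(x, n_fft)
    y = np.fft.irfft(X[None, :] * H, n_fft, axis=1)[:, : x.size]

    # spectral sharpening: first difference along frequency (channel 0 kept)
    sharp = np.empty_like(y)
    sharp[0] = y[0]
    sharp[1:] = y[1:] - y[:-1]
    np.maximum(sharp, 0.0, out=sharp)  # half-wave rectification

    # leaky integration e^{-t/tau}, then sample every frame_step
    a = np.exp(-1.0 / (config.tau_integrate * config.sample_rate))
    integ = scipy.signal.lfilter([1.0 - a], [1.0, -a], sharp, axis=1)
    n_frames = x.size // step
    frames = integ[:, step - 1 : n_frames * step : step]
    return AuditorySpectrogram(
        frames.T.copy(), config.frame_step, config.center_freqs()
    )


def extract_patches(spec: AuditorySpectrogram) -> PatchSet:
    """Group 3 consecutive frames into flat 384-dim vectors x.

    Patch i concatenates frames (i, i+1, i+2), i.e. frames t-2..t for the
    patch indexed by its last frame t; count = n_frames - 2.
    """
    S = spec.values
    if S.shape[0] < 3:
        raise ValueError("need at least 3 frames to form a patch")
    win = np.lib.stride_tricks.sliding_window_view(S, 3, axis=0)
    # win: (n-2, channels, 3) -> (n-2, 3, channels) -> flat
    patches = win.transpose(0, 2, 1).reshape(S.shape[0] - 2, -1).copy()
    return PatchSet(patches, np.arange(2, S.shape[0]))


def load_wav(path) -> AudioSignal:
    """Read a PCM/float WAV, average channels to mono, resample to 8 kHz."""
    rate, data = scipy.io.wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(data, rate).resampled()


def save_spectrogram(path, spec: AuditorySpectrogram) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("spectrogram", data=spec.values, track_times=False)
        f.create_dataset("center_freqs", data=spec.channel_center_freqs, track_times=False)
        f.attrs["frame_step"] = spec.frame_step


def load_spectrogram(path) -> AuditorySpectrogram:
    import h5py

    with h5py.File(path, "r") as f:
        return AuditorySpectrogram(
            f["spectrogram"][...],
            float(f.attrs["frame_step"]),
            f["center_freqs"][...],
        )
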