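"""Bit-reproducible psychoacoustic stimulus generators.

Every classic streaming paradigm the model is probed with is synthesized
here from its printed parameters: two-tone alternating/synchronous
sequences, ABA triplet (buildup) sequences, amplitude-modulated noise
triplets, harmonic tone complexes (MBS/MBD with harmonic / shifted /
mistuned / async conditions), moving ripples, spectrally matched noise and
the synthetic natural-sound training ensemble.  All generators are pure
functions of their parameters and a seed, return audio bounded in [-1, 1],
and attach a machine-readable annotation (onsets, offsets, frequencies,
condition labels, and the final-target readout window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .peripheral import CANONICAL_RATE, AudioSignal

__all__ = [
    "ToneSpec",
    "RippleSpec",
    "ComplexBurstSpec",
    "semitone_to_hz",
    "tone",
    "two_tone_sequence",
    "aba_triplet_sequence",
    "am_noise_sequence",
    "complex_burst",
    "mbx_sequence",
    "ripple",
    "matched_noise",
    "training_ensemble",
]

FS = CANONICAL_RATE


@dataclass(frozen=True)
class ToneSpec:
    freq: float
    duration: float
    level: float = 0.5
    ramp: float = 0.010


@dataclass(frozen=True)
class RippleSpec:
    omega: float  # ripple velocity, Hz (negative = upward)
    Omega: float  # ripple density, cyc/oct
    dA: float = 1.0  # modulation depth in [0, 1]
    phi: float = 0.0
    L: float = 1.0
    n_tones: int = 280
    span_oct: float = 5.0
    f0: float = 180.0

    def __post_init__(self):
        if not (0.0 <= self.dA <= 1.0):
            raise ValueError("modulation depth dA must lie in [0, 1]")


@dataclass(frozen=True)
class ComplexBurstSpec:
    N: int  # harmonic index of the 1000 Hz target (3..6)
    condition: str = "harmonic"  # harmonic | shifted | mistuned
    sync: str = "sync"  # sync | async
    target_freq: float = 1000.0

    def __post_init__(self):
        if self.N not in (3, 4, 5, 6):
            raise ValueError("N must be one of 3, 4, 5, 6")
        if self.condition not in ("harmonic", "shifted", "mistuned"):
            raise ValueError("unknown condition")
        if self.sync not in ("sync", "async"):
            raise ValueError("sync must be 'sync' or 'async'")


def semitone_to_hz(base: float, semitones: float) -> float:
    """Frequency `semitones` above (or below, if negative) `base`."""
    if base <= 0:
        raise ValueError("base frequency must be positive")
    return base * 2.0 ** (semitones / 12.0)


def _n(dur: float) -> int:
    return int(round(dur * FS))


def tone(
    freq: float, duration: float, level: float = 0.5, ramp: float = 0.010,
    phase: float = 0.0,
) -> np.ndarray:
    """Pure tone with raised-cosine on/off ramps."""
    t = np.arange(_n(duration)) / FS
    y = level * np.sin(2 * np.pi * freq * t + phase)
    nr = min(_n(ramp), y.size // 2)
    if nr > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        y[:nr] *= win
        y[-nr:] *= win[::-1]
    return y


def _place(buf: np.ndarray, onset: float, y: np.ndarray) -> None:
    i = _n(onset)
    buf[i : i + y.size] += y[: buf.size - i]


def two_tone_sequence(
    dF_semitones: float,
    mode: str = "alternating",
    level: float = 0.45,
    final_shift_pct: float = 0.0,
):
    """Two-tone streaming sequence: 24 tones of 100 ms, A at 1000 Hz, B
    `dF` semitones below.

    Alternating: strict contiguous ABAB... (2.4 s total; 100 ms between
    same-frequency tone onsets and offsets).  Synchronous: 12 simultaneous
    A+B bursts separated by 100 ms of silence (2.3 s total).  The final A
    tone may be shifted by `final_shift_pct` percent (readout probe).
    """
    if mode not in ("alternating", "synchronous"):
        raise ValueError("mode must be 'alternating' or 'synchronous'")
    fA = 1000.0
    fB = semitone_to_hz(fA, -dF_semitones)
    dur = 0.100
    events = []
    if mode == "alternating":
        total = 2.4
        buf = np.zeros(_n(total))
        for i in range(24):
            f = fA if i % 2 == 0 else fB
            label = "A" if i % 2 == 0 else "B"
            if i == 22 and final_shift_pct:  # last A tone
                f *= 1.0 + final_shift_pct / 100.0
            _place(buf, i * dur, tone(f, dur, level))
            events.append(
                {"onset": i * dur, "offset": (i + 1) * dur, "freq": f, "label": label}
            )
        target_window = (22 * dur, 23 * dur)
    else:
        total = 2.3
        buf = np.zeros(_n(total))
        for i in range(12):
            onset = i * 0.200
            fa = fA
            if i == 11 and final_shift_pct:
                fa *= 1.0 + final_shift_pct / 100.0
            _place(buf, onset, tone(fa, dur, level))
            _place(buf, onset, tone(fB, dur, level))
            events.append({"onset": onset, "offset": onset + dur, "freq": fa, "label": "A"})
            events.append({"onset": onset, "offset": onset + dur, "freq": fB, "label": "B"})
        target_window = (11 * 0.200, 11 * 0.200 + dur)
    annot = {
        "paradigm": "two_tone",
        "mode": mode,
        "dF_semitones": dF_semitones,
        "events": events,
        "n_tones": 24,
        "target_window": target_window,
    }
    return AudioSignal(buf), annot


def aba_triplet_sequence(
    fA: float,
    d_semitones: float,
    total_s: float,
    level: float = 0.45,
    final_shift_pct: float = 0.0,
):
    """Repeating ABA_ triplets: three contiguous 125 ms tones then a 125 ms
    silent gap (500 ms period), B `d` semitones above A, truncated at
    total_s.  The final A tone may carry a frequency probe."""
    period, dur = 0.500, 0.125
    if total_s < period:
        raise ValueError("sequence must hold at least one triplet")
    fB = semitone_to_hz(fA, d_semitones)
    n_triplets = int(math.floor(total_s / period))
    buf = np.zeros(_n(total_s))
    events = []
    last_a = None
    for i in range(n_triplets):
        t0 = i * period
        for j, (f, lab) in enumerate(((fA, "A"), (fB, "B"), (fA, "A"))):
            onset = t0 + j * dur
            is_last_a = i == n_triplets - 1 and j == 2
            ff = f * (1.0 + final_shift_pct / 100.0) if (is_last_a and final_shift_pct) else f
            _place(buf, onset, tone(ff, dur, level))
            events.append({"onset": onset, "offset": onset + dur, "freq": ff, "label": lab})
            if is_last_a:
                last_a = (onset, onset + dur)
    annot = {
        "paradigm": "buildup",
        "fA": fA,
        "d_semitones": d_semitones,
        "n_triplets": n_triplets,
        "events": events,
        "target_window": last_a,
    }
    return AudioSignal(buf), annot


def _am_noise_burst(rate: float, duration: float, rng, level: float = 0.3) -> np.ndarray:
    """100%-depth sinusoidally AM broadband noise, band-limited 180-4000 Hz."""
    import scipy.signal

    n = _n(duration)
    noise = rng.standard_normal(n + 256)
    sos = scipy.signal.butter(4, [180, 3999], btype="bandpass", fs=FS, output="sos")
    noise = scipy.signal.sosfilt(sos, noise)[256:]
    noise /= max(np.max(np.abs(noise)), 1e-12)
    t = np.arange(n) / FS
    env = 0.5 * (1.0 + np.sin(2 * np.pi * rate * t - np.pi / 2))
    y = level * noise * env
    nr = _n(0.010)
    win = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    y[:nr] *= win
    y[-nr:] *= win[::-1]
    return y


def am_noise_sequence(
    d_octaves: float,
    seed: int = 0,
    final_rate_shift_pct: float = 0.0,
    total_s: float = 6.4,
):
    """ABA triplets of 100 ms AM noise bursts (contiguous within a triplet,
    20 ms silence after each triplet; 6.4 s total).  A is modulated at
    100 Hz, B at 100 * 2^d Hz; the final A burst's rate may be probed."""
    rng = np.random.default_rng(seed)
    rateA, dur, gap = 100.0, 0.100, 0.020
    rateB = rateA * 2.0 ** d_octaves
    period = 3 * dur + gap
    n_triplets = int(round(total_s / period))
    buf = np.zeros(_n(total_s))
    events = []
    last_a = None
    for i in range(n_triplets):
        t0 = i * period
        for j, (rate, lab) in enumerate(((rateA, "A"), (rateB, "B"), (rateA, "A"))):
            onset = t0 + j * dur
            is_last_a = i == n_triplets - 1 and j == 2
            r = rate * (1.0 + final_rate_shift_pct / 100.0) if (is_last_a and final_rate_shift_pct) else rate
            _place(buf, onset, _am_noise_burst(r, dur, rng))
            events.append({"onset": onset, "offset": onset + dur, "rate": r, "label": lab})
            if is_last_a:
                last_a = (onset, onset + dur)
    annot = {
        "paradigm": "am_noise",
        "d_octaves": d_octaves,
        "n_triplets": n_triplets,
        "events": events,
        "target_window": last_a,
    }
    return AudioSignal(buf), annot


def complex_burst(
    spec: ComplexBurstSpec,
    rng: np.random.Generator,
    target_shift_pct: float = 0.0,
):
    """One harmonic-complex burst around a 1000 Hz target.

    f0 = 1000 / N; all harmonics below 2000 Hz are present.  Conditions:
    'harmonic' leaves them in place; 'shifted' moves every background
    component by +-25% of f0 (one random direction per burst); 'mistuned'
    moves only the target by +-4%.  'async' starts the 100 ms background
    40 ms before the 60 ms target with synchronized offsets.  Returns
    (waveform, events, burst_duration)."""
    f0 = spec.target_freq / spec.N
    harmonics = [k * f0 for k in range(1, int(math.ceil(2000.0 / f0))) if k * f0 < 2000.0]
    direction = 1.0 if rng.random() < 0.5 else -1.0
    comps = []
    for k, f in enumerate(harmonics, start=1):
        is_target = k == spec.N
        ff = f
        if spec.condition == "shifted" and not is_target:
            ff = f + direction * 0.25 * f0
        if spec.condition == "mistuned" and is_target:
            ff = f * (1.0 + direction * 0.04)
        if is_target and target_shift_pct:
            ff *= 1.0 + target_shift_pct / 100.0
        comps.append((ff, is_target))
    level = 0.8 / max(len(comps), 1)
    if spec.sync == "sync":
        bg_onset = tgt_onset = 0.0
        bg_dur = tgt_dur = 0.100
    else:
        bg_onset, tgt_onset = 0.0, 0.040
        bg_dur, tgt_dur = 0.100, 0.060  # shared offset at 100 ms
    total = 0.100
    buf = np.zeros(_n(total))
    events = []
    for ff, is_target in comps:
        onset = tgt_onset if is_target else bg_onset
        dur = tgt_dur if is_target else bg_dur
        _place(buf, onset, tone(ff, dur, level))
        events.append(
            {"onset": onset, "offset": onset + dur, "freq": ff,
             "label": "A" if is_target else "bg"}
        )
    return buf, events, total


def mbx_sequence(
    mode: str = "MBS",
    condition: str = "harmonic",
    sync: str = "sync",
    seed: int = 0,
    final_target_shift_pct: float = 0.0,
    gap: float = 0.100,
):
    """MBS/MBD sequence of 8 complex bursts separated by `gap` silence.

    MBS ('multiple bursts same') draws a single harmonic index N for every
    burst; MBD redraws N per burst with no two consecutive N equal.  The
    target tone of the final burst may be shifted (readout probe)."""
    if mode not in ("MBS", "MBD"):
        raise ValueError("mode must be 'MBS' or 'MBD'")
    rng = np.random.default_rng(seed)
    choices = (3, 4, 5, 6)
    if mode == "MBS":
        Ns = [int(rng.choice(choices))] * 8
    else:
        Ns = [int(rng.choice(choices))]
        while len(Ns) < 8:
            nxt = int(rng.choice(choices))
            if nxt != Ns[-1]:
                Ns.append(nxt)
    burst_dur = 0.100
    total = 8 * burst_dur + 7 * gap
    buf = np.zeros(_n(total))
    events = []
    target_window = None
    for i, N in enumerate(Ns):
        t0 = i * (burst_dur + gap)
        shift = final_target_shift_pct if i == 7 else 0.0
        y, ev, _ = complex_burst(
            ComplexBurstSpec(N, condition, sync), rng, target_shift_pct=shift
        )
        _place(buf, t0, y)
        for e in ev:
            events.append({**e, "onset": e["onset"] + t0, "offset": e["offset"] + t0, "N": N})
            if i == 7 and e["label"] == "A":
                target_window = (e["onset"] + t0, e["offset"] + t0)
    annot = {
        "paradigm": "mbx",
        "mode": mode,
        "condition": condition,
        "sync": sync,
        "N_per_burst": Ns,
        "events": events,
        "target_window": target_window,
    }
    return AudioSignal(buf), annot


def ripple(spec: RippleSpec, duration: float, seed: int = 0) -> AudioSignal:
    """Moving ripple: 280 tones log-spaced over `span_oct` octaves whose
    per-tone envelope is L(1 + dA sin(2 pi (omega t + Omega x) + phi)),
    x = log2(f / f0); component phases randomized by seed."""
    rng = np.random.default_rng(seed)
    i = np.arange(spec.n_tones)
    freqs = spec.f0 * 2.0 ** (spec.span_oct * i / (spec.n_tones - 1))
    x = np.log2(freqs / spec.f0)
    t = np.arange(_n(duration)) / FS
    phases = rng.uniform(0, 2 * np.pi, spec.n_tones)
    env = spec.L * (
        1.0 + spec.dA * np.sin(2 * np.pi * (spec.omega * t[None, :] + spec.Omega * x[:, None]) + spec.phi)
    )
    env[freqs >= FS / 2] = 0.0  # anti-aliasing: mute super-Nyquist components
    carriers = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    y = (env * carriers).sum(axis=0)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.9 * y / peak
    return AudioSignal(y)


def matched_noise(
    references: list, duration: float = 3.0, seed: int = 0, n_taps: int = 512
) -> AudioSignal:
    """White noise spectrally shaped by a 512-tap linear-phase FIR fitted to
    the references' average Welch magnitude spectrum."""
    import scipy.signal

    if not references:
        raise ValueError("need at least one reference signal")
    spectra = []
    for ref in references:
        f, p = scipy.signal.welch(ref.samples, fs=FS, nperseg=1024)
        spectra.append(p)
    mean_mag = np.sqrt(np.mean(spectra, axis=0))
    mean_mag /= np.max(mean_mag)
    mean_mag[-1] = 0.0  # even-length linear-phase FIR needs a Nyquist null
    taps = scipy.signal.firwin2(n_taps, f, mean_mag, fs=FS)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(_n(duration) + n_taps)
    y = scipy.signal.lfilter(taps, [1.0], noise)[n_taps:]
    y = 0.5 * y / max(np.max(np.abs(y)), 1e-12)
    return AudioSignal(y)


def _segment_voiced(rng, n, t):
    """Harmonic stack with a slowly drifting f0 (80-300 Hz)."""
    f0 = rng.uniform(80, 300)
    drift = rng.uniform(-0.3, 0.3)  # octaves over the segment
    inst = f0 * 2.0 ** (drift * t / t[-1])
    phase0 = np.cumsum(inst) / FS
    y = np.zeros(n)
    for k in range(1, 9):
        if k * np.max(inst) >= FS / 2:
            break
        y += rng.uniform(0.3, 1.0) / k * np.sin(2 * np.pi * k * phase0 + rng.uniform(0, 2 * np.pi))
    # speech-like syllabic envelope
    y *= 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(2, 8) * t + rng.uniform(0, 2 * np.pi))
    return y


def _segment_am_noise(rng, n, t):
    import scipy.signal

    rate = rng.uniform(4, 300)
    sos = scipy.signal.butter(4, [180, 3999], btype="bandpass", fs=FS, output="sos")
    y = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    return y * (1.0 + rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * rate * t))


def _segment_chirp(rng, n, t):
    import scipy.signal

    f_lo, f_hi = sorted(rng.uniform(200, 3500, size=2))
    return scipy.signal.chirp(t, f_lo, t[-1], f_hi, method=rng.choice(["linear", "logarithmic"]))


def _segment_clicks(rng, n, t):
    y = np.zeros(n)
    rate = rng.uniform(5, 50)
    for onset in np.arange(0, t[-1], 1.0 / rate):
        i = int(onset * FS + rng.integers(0, 40))
        if i < n - 20:
            y[i : i + 16] += np.hanning(16) * rng.uniform(0.5, 1.0)
    return y


def training_ensemble(seed: int, total_seconds: float) -> list:
    """Synthetic natural-sound ensemble standing in for a speech + sound
    effects corpus: 3 s segments mixing voiced harmonic sounds with moving
    f0, AM/FM noises, chirps and click transients; raised-cosine windowed
    and standardized to zero mean, unit variance."""
    if total_seconds <= 0:
        raise ValueError("total_seconds must be positive")
    rng = np.random.default_rng(seed)
    seg_len = 3.0
    n = _n(seg_len)
    t = np.arange(n) / FS
    window = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))  # raised cosine
    makers = [_segment_voiced, _segment_am_noise, _segment_chirp, _segment_clicks]
    weights = np.array([0.4, 0.3, 0.15, 0.15])
    out = []
    for _ in range(int(math.ceil(total_seconds / seg_len))):
        maker = makers[rng.choice(len(makers), p=weights)]
        y = maker(rng, n, t)
        if rng.random() < 0.3:  # occasional low-level background noise bed
            y = y + 0.1 * rng.standard_normal(n)
        y = y * window
        y = y - np.mean(y)
        sd = np.std(y)
        y = y / sd if sd > 0 else y
        y = y - np.mean(y)
        out.append(AudioSignal(y))
    return out
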