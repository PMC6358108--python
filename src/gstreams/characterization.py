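"""Model characterization: ripple-derived modulation transfer functions,
rate-scale tuning of individual units, agglomerative clustering of tuning
profiles, semantic cluster tags, and lesioning for control experiments.

The MTF probes a stage (any callable mapping an `AudioSignal` to a
frames x units response matrix) with pairs of moving ripples at 100% and
0% modulation depth.  For each (rate omega0, density Omega0) the
modulation-synchronized activity M is the magnitude of the response DFT
coefficient at the bin nearest omega0, taken over the steady-state frames,
and the normalized tuning is 10 log10(||M_100||^2 / ||M_0||^2) with M
RMS-pooled across units (per-unit grids are kept for clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .peripheral import AudioSignal
from .stimuli import RippleSpec, ripple

__all__ = [
    "MTFGrid",
    "ClusterAssignment",
    "default_rates",
    "default_scales",
    "measure_mtf",
    "low_rate_energy_fraction",
    "cluster_units",
    "tag_clusters",
    "lesion",
]

INF_SENTINEL = np.inf


@dataclass
class MTFGrid:
    rates: np.ndarray  # Hz, signed (negative = upward ripples)
    scales: np.ndarray  # cyc/oct
    gain_dB: np.ndarray  # (n_rates, n_scales) pooled tuning
    per_unit: np.ndarray | None = None  # (units, n_rates, n_scales)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # unit -> cluster id
    centroids: np.ndarray  # (k, n_rates, n_scales)
    tags: dict = field(default_factory=dict)  # cluster id -> set of tags


def default_rates(n: int = 21) -> np.ndarray:
    """Signed rate axis covering [-50, 50] Hz (0 excluded)."""
    half = np.linspace(2.0, 50.0, n // 2)
    return np.concatenate([-half[::-1], half])


def default_scales(n: int = 13) -> np.ndarray:
    """Log-spaced density axis covering [0.25, 16] cyc/oct."""
    return np.geomspace(0.25, 16.0, n)


def _sync_magnitude(R: np.ndarray, rate_hz: float, frame_rate: float) -> np.ndarray:
    """|DFT coefficient| per unit at the bin nearest |rate_hz|."""
    n = R.shape[0]
    spec = np.fft.rfft(R - R.mean(axis=0, keepdims=True), axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    b = int(np.argmin(np.abs(freqs - abs(rate_hz))))
    return np.abs(spec[b]) / n


def measure_mtf(
    stage,
    rates: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    duration: float = 1.0,
    seed: int = 0,
    frame_rate: float = 100.0,
    settle: float = 0.2,
    ripple_f0: float = 180.0,
    level: float = 1.0,
    keep_per_unit: bool = True,
) -> MTFGrid:
    """Sweep ripple (rate, density) pairs through `stage` and return the
    normalized modulation transfer function."""
    rates = default_rates() if rates is None else np.asarray(rates, dtype=float)
    scales = default_scales() if scales is None else np.asarray(scales, dtype=float)
    n_settle = int(round(settle * frame_rate))
    gain = np.zeros((rates.size, scales.size))
    per_unit = None
    for i, w in enumerate(rates):
        for j, om in enumerate(scales):
            r100 = ripple(RippleSpec(w, om, dA=1.0, L=level, f0=ripple_f0), duration, seed)
            r0 = ripple(RippleSpec(w, om, dA=0.0, L=level, f0=ripple_f0), duration, seed)
            R100 = np.asarray(stage(r100))[n_settle:]
            R0 = np.asarray(stage(r0))[n_settle:]
            m100 = _sync_magnitude(R100, w, frame_rate)
            m0 = _sync_magnitude(R0, w, frame_rate)
            if per_unit is None and keep_per_unit:
                per_unit = np.zeros((m100.size, rates.size, scales.size))
            pooled100 = np.sqrt(np.mean(m100**2))
            pooled0 = np.sqrt(np.mean(m0**2))
            if pooled0 == 0.0:
                warnings.warn("zero noise-floor response; reporting +inf gain")
                gain[i, j] = INF_SENTINEL
            else:
                gain[i, j] = 10.0 * np.log10(pooled100**2 / pooled0**2)
            if keep_per_unit:
                with np.errstate(divide="ignore", invalid="ignore"):
                    pu = 10.0 * np.log10(m100**2 / m0**2)
                pu[~np.isfinite(pu)] = INF_SENTINEL if np.any(m0 == 0) else 0.0
                per_unit[:, i, j] = pu
    return MTFGrid(rates, scales, gain, per_unit)


def low_rate_energy_fraction(grid: MTFGrid, cutoff_hz: float = 30.0) -> float:
    """Fraction of total (positive, linear-power) MTF gain at |rate| < cutoff."""
    g = np.maximum(np.where(np.isfinite(grid.gain_dB), grid.gain_dB, 0.0), 0.0)
    power = 10.0 ** (g / 10.0) - 1.0
    mask = np.abs(grid.rates) < cutoff_hz
    total = power.sum()
    return float(power[mask].sum() / total) if total > 0 else 0.0


def cluster_units(per_unit_grids: np.ndarray, k: int) -> ClusterAssignment:
    """Agglomerative (average-linkage, Euclidean) clustering of flattened
    rate-scale tuning profiles; deterministic given inputs."""
    from sklearn.cluster import AgglomerativeClustering

    G = np.asarray(per_unit_grids, dtype=float)
    n_units = G.shape[0]
    if not (1 <= k <= n_units):
        raise ValueError("cluster count must lie in [1, n_units]")
    flat = G.reshape(n_units, -1)
    flat = np.where(np.isfinite(flat), flat, 0.0)
    if k == 1:
        labels = np.zeros(n_units, dtype=int)
    else:
        labels = AgglomerativeClustering(
            n_clusters=k, linkage="average", metric="euclidean"
        ).fit_predict(flat)
    centroids = np.stack([G[labels == c].mean(axis=0) for c in range(k)])
    return ClusterAssignment(labels=labels, centroids=centroids)


def tag_clusters(
    assignment: ClusterAssignment,
    rates: np.ndarray,
    scales: np.ndarray,
    filters=None,
    slow_fast_split_hz: float = 25.0,
    harmonic_band=(1.0, 2.0),
) -> ClusterAssignment:
    """Attach semantic tags to clusters from their centroid tuning.

    H: centroid scale-peak inside the harmonicity band [1, 2] cyc/oct.
    S / F: rate centroid below / above the 25 Hz split.
    O: fast cluster whose member filters have an onset-polarity time
       profile (late-frame weights exceed early-frame weights).
    """
    tags = {}
    rates = np.asarray(rates)
    scales = np.asarray(scales)
    for c, cent in enumerate(assignment.centroids):
        cent = np.where(np.isfinite(cent), cent, 0.0)
        pos = np.maximum(cent, 0.0)
        cluster_tags = set()
        scale_profile = pos.mean(axis=0)
        peak_scale = scales[int(np.argmax(scale_profile))]
        if harmonic_band[0] <= peak_scale <= harmonic_band[1]:
            cluster_tags.add("H")
        rate_profile = pos.mean(axis=1)
        wsum = rate_profile.sum()
        rate_centroid = (
            float(np.sum(np.abs(rates) * rate_profile) / wsum) if wsum > 0 else 0.0
        )
        cluster_tags.add("S" if rate_centroid < slow_fast_split_hz else "F")
        if "F" in cluster_tags and filters is not None:
            members = np.flatnonzero(assignment.labels == c)
            F = filters.filters[members]  # (m, 3, channels)
            onset_score = float(np.mean(F[:, 2, :].sum(axis=1) - F[:, 0, :].sum(axis=1)))
            if onset_score > 0:
                cluster_tags.add("O")
        tags[c] = cluster_tags
    assignment.tags = tags
    return assignment


def lesion(model, unit_ids, layer: str = "l1", retrain_l2: bool = False, config=None):
    """Remove units from the signal path; optionally retrain L2 on the
    reduced-dimension L1 output (same ensemble seed and hyperparameters).

    `config` is the ExperimentConfig the model was trained with; it is only
    needed when retrain_l2 is set.  Lesioning without retraining is
    idempotent and composable.
    """
    ids = np.atleast_1d(np.asarray(unit_ids, dtype=int))
    if layer == "l1":
        lesioned = model.with_l1_lesion(ids) if ids.size else model
        if retrain_l2:
            from .experiments import retrain_l2_for  # lazy: avoids cycle

            if config is None:
                raise ValueError("retraining L2 requires the experiment config")
            lesioned = retrain_l2_for(lesioned, config)
        return lesioned
    if layer == "l2":
        return model.with_l2_lesion(ids) if ids.size else model
    if layer == "coherence":
        return model.without_coherence()
    if layer == "adaptation":
        return model.without_adaptation()
    raise ValueError("layer must be one of l1, l2, coherence, adaptation")
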