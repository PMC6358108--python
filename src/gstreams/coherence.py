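"""Temporal coherence layer L3: Hebbian binding of coherent L2 channels.

A symmetric synaptic matrix V(t) accumulates the outer product of the
(centered) channel responses at every 10 ms step:

    V(t) = leak * V(t-1) + r(t) r(t)^T

Channels that are co-activated over time strengthen their mutual weights;
anti-correlated channels (negative products after centering by a moving
average over the channel's context window) weaken them.  The matrix is
applied multiplicatively to the model response, R^_t = R_t V_t, so
coherent groups reinforce each other while incoherent channels are
suppressed.  Coherence is computed separately within each L2 context
block; the final model response concatenates the per-context blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .l2 import L2Response

__all__ = [
    "CoherenceMatrix",
    "update_coherence",
    "center_responses",
    "apply_coherence",
    "coherence_output",
    "save_coherence_snapshots",
]


@dataclass
class CoherenceMatrix:
    V: np.ndarray  # (M, M) symmetric
    leak: float = 0.99  # per 10 ms step
    window: int = 30  # centering window, frames

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.V.ndim != 2 or self.V.shape[0] != self.V.shape[1]:
            raise ValueError("V must be square")
        if not (0.0 < self.leak <= 1.0):
            raise ValueError("leak must lie in (0, 1]")

    @classmethod
    def identity(cls, m: int, leak: float = 0.99, window: int = 30):
        return cls(np.eye(m), leak, window)


def update_coherence(state: CoherenceMatrix, r_t: np.ndarray) -> CoherenceMatrix:
    """One Hebbian step: V <- leak * V + r r^T (symmetry preserved)."""
    r = np.asarray(r_t, dtype=np.float64)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite response vector")
    if r.shape != (state.V.shape[0],):
        raise ValueError("dimension mismatch")
    state.V = state.leak * state.V + np.outer(r, r)
    return state


def center_responses(R: np.ndarray, window: int) -> np.ndarray:
    """Subtract a causal moving average over `window` frames per channel."""
    R = np.asarray(R, dtype=np.float64)
    n = R.shape[0]
    w = max(1, min(window, n))
    c = np.cumsum(np.vstack([np.zeros((1, R.shape[1])), R]), axis=0)
    lo = np.maximum(np.arange(n) - w + 1, 0)
    counts = (np.arange(n) - lo + 1).astype(np.float64)
    mean = (c[np.arange(n) + 1] - c[lo]) / counts[:, None]
    return R - mean


def apply_coherence(
    R: np.ndarray,
    leak: float = 0.99,
    window: int = 30,
    V0: np.ndarray | None = None,
    return_matrix: bool = False,
    normalize: bool = True,
):
    """Run the Hebbian matrix causally over R and return R^ with rows
    R^_t = R_t V_t.

    V is driven by the centered responses but applied to the raw rows.
    With leak < 1 and bounded input, the accumulated matrix stays bounded
    by max_t ||r_t||^2 / (1 - leak) plus the initial matrix.  With
    `normalize` (default) the matrix is rescaled to unit diagonal before
    application — a homeostatic synaptic scaling that leaves only the
    correlation structure of the binding weights, so overall response
    energy does not masquerade as coherence.
    """
    R = np.asarray(R, dtype=np.float64)
    n, m = R.shape
    state = CoherenceMatrix(np.eye(m) if V0 is None else V0, leak, window)
    centered = center_responses(R, window)
    out = np.empty_like(R)
    applied = state.V
    for t in range(n):
        update_coherence(state, centered[t])
        if normalize:
            d = np.sqrt(np.clip(np.diag(state.V), 1e-12, None))
            applied = state.V / np.outer(d, d)
        else:
            applied = state.V
        out[t] = R[t] @ applied
    if return_matrix:
        return out, applied
    return out


def snapshot_coherence(R: np.ndarray, every: int, leak: float = 0.99,
                       window: int = 30, normalize: bool = True) -> dict:
    """Binding-matrix snapshots {frame -> V} taken every `every` frames."""
    R = np.asarray(R, dtype=np.float64)
    n, m = R.shape
    state = CoherenceMatrix(np.eye(m), leak, window)
    centered = center_responses(R, window)
    snaps = {}
    for t in range(n):
        update_coherence(state, centered[t])
        if t % every == 0 or t == n - 1:
            V = state.V
            if normalize:
                d = np.sqrt(np.clip(np.diag(V), 1e-12, None))
                V = V / np.outer(d, d)
            snaps[t] = V.copy()
    return snaps


def save_coherence_snapshots(path, snaps: dict) -> None:
    """Dump {frame -> V} snapshots to HDF5 under /V/t_<frame>."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("V")
        for t, V in snaps.items():
            g.create_dataset(f"t_{t:06d}", data=V, track_times=False)


def coherence_output(
    l2: L2Response, leak: float = 0.99, enabled: bool = True
) -> np.ndarray:
    """Final model response: per-context Hebbian-weighted blocks,
    concatenated along channels.  Each block's centering window equals its
    own context tau.  With `enabled=False` (coherence lesion) the blocks
    are passed through unchanged (V = identity)."""
    blocks = []
    for tau in l2.context_tag:
        R = l2.values[tau]
        if enabled:
            blocks.append(apply_coherence(R, leak=leak, window=tau))
        else:
            blocks.append(np.asarray(R, dtype=np.float64))
    return np.hstack(blocks)
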