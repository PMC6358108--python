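"""Simultaneous layer L1: sparse Gaussian-Bernoulli RBM over 3-frame patches.

The RBM has real-valued (unit-variance Gaussian) visible units over the
384-dim spectrogram patches and K Bernoulli hidden units.  Energy:

    E(x, h) = 1/2 sum_k (x_k - A_k)^2 - sum_l B_l h_l - sum_kl x_k h_l w_kl

Training is contrastive divergence (CD-k) with a cross-entropy sparsity
penalty p log q + (1-p) log(1-q) that pulls each hidden unit's mean
activation q toward the sparsity target p.  After training, each weight
column is reshaped into a 2-D spectro-temporal filter F(t, f) (3 frames x
128 channels), applied convolutionally along time to the spectrogram, and
the responses are passed through Tsodyks-style closed-loop synaptic
adaptation:

    da/dt = (1 - a)/tau_a - alpha * a * r^      r(t) = a(t) * r^(t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .peripheral import AuditorySpectrogram, PatchSet

__all__ = [
    "RbmParams",
    "L1Config",
    "L1FilterBank",
    "AdaptationState",
    "L1Response",
    "rbm_energy",
    "hidden_prob",
    "sparsity_penalty",
    "cd_step",
    "train_l1",
    "weights_to_filters",
    "apply_l1",
    "adapt",
    "save_rbm",
    "load_rbm",
]

_EPS = 1e-7


@dataclass
class RbmParams:
    W: np.ndarray  # (n_visible, K)
    A: np.ndarray  # (n_visible,) visible biases
    B: np.ndarray  # (K,) hidden biases
    p: float = 0.05  # sparsity target
    sparsity_cost: float = 5.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        if self.W.shape != (self.A.size, self.B.size):
            raise ValueError("W must be (n_visible, K)")
        if not (0.0 < self.p < 1.0):
            raise ValueError("sparsity target p must lie in (0, 1)")
        if self.sparsity_cost < 0:
            raise ValueError("sparsity_cost must be non-negative")

    @property
    def n_visible(self) -> int:
        return self.A.size

    @property
    def n_hidden(self) -> int:
        return self.B.size


@dataclass(frozen=True)
class L1Config:
    n_hidden: int = 400
    sparsity_target: float = 0.05
    sparsity_cost: float = 5.0
    cd_steps: int = 1
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 128
    n_epochs: int = 50
    weight_init_scale: float = 0.01
    seed: int = 0


@dataclass(frozen=True)
class L1FilterBank:
    """K spectro-temporal filters of shape (3 time frames, 128 channels)."""

    filters: np.ndarray  # (K, 3, n_channels)


@dataclass
class AdaptationState:
    a: np.ndarray  # per-unit gains in (0, 1]
    tau_a: float = 0.300  # s
    alpha: float = 1e-5  # synaptic utilization
    dt: float = 0.010  # s, frame step


@dataclass(frozen=True)
class L1Response:
    values: np.ndarray  # (frames, K) adapted responses r_k(t)
    raw: np.ndarray  # (frames, K) pre-adaptation r^_k(t)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def rbm_energy(x: np.ndarray, h: np.ndarray, params: RbmParams) -> float:
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if x.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("dimension mismatch")
    return float(
        0.5 * np.sum((x - params.A) ** 2)
        - params.B @ h
        - x @ params.W @ h
    )


def hidden_prob(x: np.ndarray, params: RbmParams) -> np.ndarray:
    """P(h_l = 1 | x) = sigmoid(x . w_l + B_l), each in (0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != params.n_visible:
        raise ValueError("dimension mismatch")
    return _sigmoid(x @ params.W + params.B)


def sparsity_penalty(q: float | np.ndarray, p: float) -> float | np.ndarray:
    """Cross-entropy p log q + (1-p) log(1-q); maximal (least negative) at q=p."""
    q = np.clip(q, _EPS, 1.0 - _EPS)
    return p * np.log(q) + (1.0 - p) * np.log1p(-q)


def cd_step(
    batch: np.ndarray | PatchSet,
    params: RbmParams,
    k_steps: int = 1,
    lr: float = 1e-3,
    rng: np.random.Generator | None = None,
    momentum: float = 0.0,
    velocity: dict | None = None,
) -> tuple[RbmParams, float]:
    """One contrastive-divergence update on a minibatch.

    Positive phase uses the data; the negative phase runs k Gibbs
    half-steps with stochastic hidden samples and mean-field Gaussian
    visible reconstruction x^ = h W^T + A.  The sparsity gradient
    `cost * (p - q)` is added to the hidden biases (and weight columns,
    scaled by the mean visible vector).  Returns updated params and the
    mean squared reconstruction error.
    """
    if isinstance(batch, PatchSet):
        batch = batch.patches
    X = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    rng = rng or np.random.default_rng()
    n = X.shape[0]

    ph_data = hidden_prob(X, params)
    h = (rng.random(ph_data.shape) < ph_data).astype(np.float64)
    for _ in range(k_steps):
        Xneg = h @ params.W.T + params.A
        ph_neg = hidden_prob(Xneg, params)
        h = (rng.random(ph_neg.shape) < ph_neg).astype(np.float64)

    dW = (X.T @ ph_data - Xneg.T @ ph_neg) / n
    dA = (X - Xneg).mean(axis=0)
    dB = (ph_data - ph_neg).mean(axis=0)
    if not (np.all(np.isfinite(dW)) and np.all(np.isfinite(dA)) and np.all(np.isfinite(dB))):
        raise FloatingPointError("non-finite CD gradient; lower the learning rate")

    # sparsity: push mean activation q toward target p
    q = ph_data.mean(axis=0)
    spars = params.sparsity_cost * (params.p - q)
    dB = dB + spars
    dW = dW + np.outer(X.mean(axis=0), spars)

    if velocity is not None:
        velocity["W"] = momentum * velocity.get("W", 0.0) + lr * dW
        velocity["A"] = momentum * velocity.get("A", 0.0) + lr * dA
        velocity["B"] = momentum * velocity.get("B", 0.0) + lr * dB
        stepW, stepA, stepB = velocity["W"], velocity["A"], velocity["B"]
    else:
        stepW, stepA, stepB = lr * dW, lr * dA, lr * dB

    new = replace(
        params,
        W=params.W + stepW,
        A=params.A + stepA,
        B=params.B + stepB,
    )
    recon = ph_data @ params.W.T + params.A  # x^ = h W + A with mean-field h
    err = float(np.mean((X - recon) ** 2))
    return new, err


def train_l1(
    ensemble: PatchSet | np.ndarray,
    config: L1Config = L1Config(),
    log: list | None = None,
) -> RbmParams:
    """Train the sparse RBM by minibatch CD; deterministic given config.seed."""
    X = ensemble.patches if isinstance(ensemble, PatchSet) else np.asarray(ensemble)
    if X.size == 0:
        raise ValueError("empty training ensemble")
    rng = np.random.default_rng(config.seed)
    n, d = X.shape
    params = RbmParams(
        W=config.weight_init_scale * rng.standard_normal((d, config.n_hidden)),
        A=np.zeros(d),
        B=np.zeros(config.n_hidden),
        p=config.sparsity_target,
        sparsity_cost=config.sparsity_cost,
    )
    velocity: dict = {}
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        errs = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            params, err = cd_step(
                X[idx],
                params,
                k_steps=config.cd_steps,
                lr=config.learning_rate,
                rng=rng,
                momentum=config.momentum,
                velocity=velocity,
            )
            errs.append(err)
        if log is not None:
            q = hidden_prob(X[order[: min(n, 2048)]], params).mean()
            log.append(
                {"epoch": epoch, "recon_error": float(np.mean(errs)), "mean_q": float(q)}
            )
    return params


def weights_to_filters(params: RbmParams, n_channels: int = 128) -> L1FilterBank:
    """Reshape each weight column into a (3, n_channels) filter F(t, f);
    exact inverse of the patch flattening."""
    K = params.n_hidden
    filters = params.W.T.reshape(K, 3, n_channels)
    return L1FilterBank(filters.copy())


def apply_l1(spec: AuditorySpectrogram, filters: L1FilterBank) -> np.ndarray:
    """Causal convolution of the filters with S(t, f); raw responses r^.

    r^_k(t) = sum_f sum_{i=0..2} S(t-2+i, f) F_k(i, f), zero-padded at the
    start, so r^_k(t) equals the dot product of filter k with the patch
    ending at frame t.  Output shape (frames, K).
    """
    S = spec.values
    if S.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    F = filters.filters  # (K, 3, C)
    K = F.shape[0]
    Wmat = F.reshape(K, -1).T  # (3*C, K), same ordering as patches
    pad = np.vstack([np.zeros((2, S.shape[1])), S])
    win = np.lib.stride_tricks.sliding_window_view(pad, 3, axis=0)
    X = win.transpose(0, 2, 1).reshape(S.shape[0], -1)
    return X @ Wmat


def adapt(
    raw: np.ndarray,
    state: AdaptationState | None = None,
    rectify: bool = True,
) -> L1Response:
    """Tsodyks closed-loop adaptation applied per unit at 10 ms steps.

    Uses the exact per-step exponential solution with piecewise-constant
    input: with lam = 1/tau_a + alpha*r, the gain relaxes toward
    a_inf = (1/tau_a)/lam as a <- a_inf + (a - a_inf) e^{-lam dt}, which is
    unconditionally stable and keeps a in (0, 1].  Steady state for constant
    drive c is a* = 1 / (1 + tau_a * alpha * c).
    """
    raw = np.asarray(raw, dtype=np.float64)
    if rectify:
        raw = np.maximum(raw, 0.0)
    frames, K = raw.shape
    state = state or AdaptationState(a=np.ones(K))
    if state.a.shape != (K,):
        raise ValueError("adaptation state size mismatch")
    a = state.a.astype(np.float64).copy()
    out = np.empty_like(raw)
    inv_tau = 1.0 / state.tau_a
    for t in range(frames):
        lam = inv_tau + state.alpha * raw[t]
        a_inf = inv_tau / lam
        a = a_inf + (a - a_inf) * np.exp(-lam * state.dt)
        np.clip(a, _EPS, 1.0, out=a)
        out[t] = a * raw[t]
    state.a = a
    return L1Response(values=out, raw=raw)


def save_rbm(path, params: RbmParams, config: L1Config | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=params.W, track_times=False)
        f.create_dataset("A", data=params.A, track_times=False)
        f.create_dataset("B", data=params.B, track_times=False)
        f.attrs["p"] = params.p
        f.attrs["sparsity_cost"] = params.sparsity_cost
        if config is not None:
            f.attrs["config"] = json.dumps(config.__dict__)


def load_rbm(path) -> RbmParams:
    import h5py

    with h5py.File(path, "r") as f:
        return RbmParams(
            W=f["W"][...],
            A=f["A"][...],
            B=f["B"][...],
            p=float(f.attrs["p"]),
            sparsity_cost=float(f.attrs["sparsity_cost"]),
        )
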