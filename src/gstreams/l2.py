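"""Sequential layer L2: bank of conditional RBMs over temporal contexts.

Each cRBM models the current L1 response vector x(t) conditioned on a
history x_tau of the previous tau frames.  The conditioning enters through
dynamic biases that are linear in the history:

    a^_k(t) = A_k + sum_m C_mk * hist_m      (visible)
    b^_l(t) = B_l + sum_m D_ml * hist_m      (hidden)

with energy E = 1/2 sum_k (x_k - a^_k)^2 - sum_l h_l b^_l - sum_kl W_kl x_k h_l.

The bank spans contexts tau in 30-600 ms (default {30, 60, 120, 240, 480,
600} ms at the 10 ms frame clock).  Inference is linear: the per-frame
output of each cRBM is the pre-sigmoid hidden drive W^T x(t) + b^(t),
giving a multi-resolution sequential-cue representation.  Histories are
zero-padded at sequence start so onsets are not discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CrbmParams",
    "L2Config",
    "L2ContextBank",
    "L2Response",
    "dynamic_biases",
    "crbm_energy",
    "history_matrix",
    "train_l2",
    "train_bank",
    "apply_l2",
    "save_bank",
    "load_bank",
]

DEFAULT_TAUS_MS = (30, 60, 120, 240, 480, 600)


@dataclass
class CrbmParams:
    tau: int  # context length in frames
    W: np.ndarray  # (n_visible, n_hidden)
    A: np.ndarray  # (n_visible,) static visible bias
    B: np.ndarray  # (n_hidden,) static hidden bias
    C: np.ndarray  # (n_visible * tau, n_visible) history -> visible
    D: np.ndarray  # (n_visible * tau, n_hidden) history -> hidden

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError("tau must be >= 1 frame")
        nv, nh = self.A.size, self.B.size
        if self.W.shape != (nv, nh):
            raise ValueError("W must be (n_visible, n_hidden)")
        if self.C.shape != (nv * self.tau, nv) or self.D.shape != (nv * self.tau, nh):
            raise ValueError("autoregressive weight shape mismatch")

    @property
    def n_visible(self) -> int:
        return self.A.size

    @property
    def n_hidden(self) -> int:
        return self.B.size


@dataclass(frozen=True)
class L2Config:
    n_hidden: int = 300
    taus_ms: tuple = DEFAULT_TAUS_MS
    frame_step: float = 0.010
    cd_steps: int = 1
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 128
    n_epochs: int = 50
    weight_init_scale: float = 0.01
    seed: int = 0

    def taus_frames(self) -> tuple:
        return tuple(int(round(t / 1000.0 / self.frame_step)) for t in self.taus_ms)


@dataclass
class L2ContextBank:
    models: list  # CrbmParams, strictly increasing tau

    def __post_init__(self):
        taus = [m.tau for m in self.models]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("context lengths must be strictly increasing")


@dataclass(frozen=True)
class L2Response:
    """Per-context response matrices aligned to the L1 frame clock."""

    values: dict  # tau (frames) -> (frames, n_hidden) array
    context_tag: tuple  # ordered taus


def _sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dynamic_biases(history: np.ndarray, params: CrbmParams):
    """(a^, b^) from a flattened tau-frame history (oldest frame first)."""
    hist = np.asarray(history, dtype=np.float64).reshape(-1)
    if hist.size != params.n_visible * params.tau:
        raise ValueError("history length must equal tau frames")
    a_hat = params.A + hist @ params.C
    b_hat = params.B + hist @ params.D
    return a_hat, b_hat


def crbm_energy(
    x: np.ndarray, h: np.ndarray, history: np.ndarray, params: CrbmParams
) -> float:
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if x.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("dimension mismatch")
    a_hat, b_hat = dynamic_biases(history, params)
    return float(0.5 * np.sum((x - a_hat) ** 2) - h @ b_hat - x @ params.W @ h)


def history_matrix(X: np.ndarray, tau: int) -> np.ndarray:
    """Flattened tau-frame histories for every frame of one stream,
    zero-padded at the start; row t holds frames t-tau .. t-1 (oldest
    first)."""
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    pad = np.vstack([np.zeros((tau, d)), X])
    offsets = np.arange(-tau, 0)
    idx = np.arange(tau, tau + n)
    return pad[idx[:, None] + offsets].reshape(n, tau * d)


def _as_segments(l1_responses) -> list:
    if isinstance(l1_responses, np.ndarray):
        return [np.asarray(l1_responses, dtype=np.float64)]
    return [np.asarray(s, dtype=np.float64) for s in l1_responses]


def train_l2(
    l1_responses,
    tau: int,
    config: L2Config = L2Config(),
    log: list | None = None,
) -> CrbmParams:
    """Train one cRBM of context tau by CD on an L1 response stream.

    Accepts a single (frames, d) array or a list of per-segment arrays;
    histories never cross segment boundaries.  Minibatch histories are
    gathered lazily from the zero-padded streams to keep memory flat.
    """
    segments = _as_segments(l1_responses)
    d = segments[0].shape[1]
    if sum(s.shape[0] for s in segments) < tau + 1:
        raise ValueError("response stream shorter than tau + 1 frames")
    # concatenate with a tau-frame zero pad before each segment
    padded, valid = [], []
    pos = 0
    for s in segments:
        padded.append(np.zeros((tau, d)))
        padded.append(s)
        pos += tau
        valid.append(np.arange(pos, pos + s.shape[0]))
        pos += s.shape[0]
    Xcat = np.vstack(padded)
    valid_idx = np.concatenate(valid)
    offsets = np.arange(-tau, 0)

    rng = np.random.default_rng(config.seed + tau)
    params = CrbmParams(
        tau=tau,
        W=config.weight_init_scale * rng.standard_normal((d, config.n_hidden)),
        A=np.zeros(d),
        B=np.zeros(config.n_hidden),
        C=np.zeros((d * tau, d)),
        D=np.zeros((d * tau, config.n_hidden)),
    )
    vel = {k: 0.0 for k in ("W", "A", "B", "C", "D")}
    lr, mom = config.learning_rate, config.momentum
    n = valid_idx.size
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        errs = []
        for start in range(0, n, config.batch_size):
            idx = valid_idx[order[start : start + config.batch_size]]
            x = Xcat[idx]
            hist = Xcat[idx[:, None] + offsets].reshape(idx.size, tau * d)
            m = x.shape[0]
            a_hat = params.A + hist @ params.C
            b_hat = params.B + hist @ params.D
            ph = _sigmoid(x @ params.W + b_hat)
            h = (rng.random(ph.shape) < ph).astype(np.float64)
            for _ in range(config.cd_steps):
                xneg = h @ params.W.T + a_hat
                ph_neg = _sigmoid(xneg @ params.W + b_hat)
                h = (rng.random(ph_neg.shape) < ph_neg).astype(np.float64)
            dW = (x.T @ ph - xneg.T @ ph_neg) / m
            dA = (x - xneg).mean(axis=0)
            dB = (ph - ph_neg).mean(axis=0)
            dC = hist.T @ (x - xneg) / m
            dD = hist.T @ (ph - ph_neg) / m
            for name, g in (("W", dW), ("A", dA), ("B", dB), ("C", dC), ("D", dD)):
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError("non-finite cRBM gradient")
                vel[name] = mom * vel[name] + lr * g
            params = replace(
                params,
                W=params.W + vel["W"],
                A=params.A + vel["A"],
                B=params.B + vel["B"],
                C=params.C + vel["C"],
                D=params.D + vel["D"],
            )
            errs.append(float(np.mean((x - (ph @ params.W.T + a_hat)) ** 2)))
        if log is not None:
            log.append({"tau": tau, "epoch": epoch, "recon_error": float(np.mean(errs))})
    return params


def train_bank(
    l1_responses, config: L2Config = L2Config(), log: list | None = None
) -> L2ContextBank:
    models = [train_l2(l1_responses, tau, config, log) for tau in config.taus_frames()]
    return L2ContextBank(models)


def apply_l2(l1_responses: np.ndarray, bank: L2ContextBank) -> L2Response:
    """Linear multi-resolution output: per frame, W^T x(t) + b^(t)."""
    X = np.asarray(l1_responses, dtype=np.float64)
    out = {}
    for m in bank.models:
        H = history_matrix(X, m.tau)
        out[m.tau] = X @ m.W + m.B + H @ m.D
    return L2Response(values=out, context_tag=tuple(m.tau for m in bank.models))


def save_bank(path, bank: L2ContextBank, config: L2Config | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config"] = json.dumps(
                {**config.__dict__, "taus_ms": list(config.taus_ms)}
            )
        for m in bank.models:
            g = f.create_group(f"tau_{m.tau:03d}")
            for name in ("W", "A", "B", "C", "D"):
                g.create_dataset(name, data=getattr(m, name), track_times=False)


def load_bank(path) -> L2ContextBank:
    import h5py

    models = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            models.append(
                CrbmParams(
                    tau=int(key.split("_")[1]),
                    W=g["W"][...],
                    A=g["A"][...],
                    B=g["B"][...],
                    C=g["C"][...],
                    D=g["D"][...],
                )
            )
    return L2ContextBank(models)
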