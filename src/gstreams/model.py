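"""End-to-end streaming model: spectrogram -> L1 -> L2 -> coherence.

`StreamModel` bundles the trained layers with the normalization statistics
collected on the training ensemble and exposes `final_response`, the
concatenated Hebbian-weighted L2 output the readout stage consumes.
Lesion switches (removed L1/L2 units, disabled adaptation, disabled
coherence) live here so control experiments run through the same path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import coherence as l3
from .l1 import AdaptationState, L1FilterBank, RbmParams, adapt, apply_l1
from .l2 import L2ContextBank, L2Response, apply_l2
from .peripheral import AudioSignal, AuditorySpectrogram, PeripheralConfig, cochleagram

__all__ = ["StreamModel"]


@dataclass
class StreamModel:
    peripheral: PeripheralConfig
    rbm: RbmParams
    filters: L1FilterBank
    bank: L2ContextBank
    channel_mean: np.ndarray  # per-frequency-channel stats of the ensemble
    channel_std: np.ndarray
    l1_mean: np.ndarray  # per-L1-unit stats of adapted training responses
    l1_std: np.ndarray
    l1_raw_std: np.ndarray | None = None  # std of rectified raw responses
    leak: float = 0.99
    tau_a: float = 0.300
    alpha: float = 1e-5
    rate_scale: float = 1e5  # maps one raw-response std to rate-like units
    # lesion switches
    l1_keep: np.ndarray | None = None  # indices of surviving L1 units
    l2_keep: np.ndarray | None = None  # indices of surviving L2 hidden units
    adaptation_enabled: bool = True
    coherence_enabled: bool = True

    @property
    def n_l1(self) -> int:
        return self.filters.filters.shape[0] if self.l1_keep is None else self.l1_keep.size

    def _active_filters(self) -> L1FilterBank:
        if self.l1_keep is None:
            return self.filters
        return L1FilterBank(self.filters.filters[self.l1_keep])

    def spectrogram(self, signal: AudioSignal) -> AuditorySpectrogram:
        spec = cochleagram(signal, self.peripheral)
        std = np.where(self.channel_std > 0, self.channel_std, 1.0)
        values = (spec.values - self.channel_mean) / std
        return AuditorySpectrogram(values, spec.frame_step, spec.channel_center_freqs)

    def l1_response(self, signal: AudioSignal) -> np.ndarray:
        """Adapted, standardized L1 responses (frames x n_l1).

        The rectified convolution output is expressed in rate-like units
        (one training standard deviation -> `rate_scale`) so the printed
        adaptation constants produce meaningful depression.
        """
        spec = self.spectrogram(signal)
        raw = np.maximum(apply_l1(spec, self._active_filters()), 0.0)
        raw_std = self.l1_raw_std
        if raw_std is None:
            raw_std = np.ones(self.filters.filters.shape[0])
        if self.l1_keep is not None:
            raw_std = raw_std[self.l1_keep]
        rates = raw / np.where(raw_std > 0, raw_std, 1.0) * self.rate_scale
        if self.adaptation_enabled:
            state = AdaptationState(
                a=np.ones(rates.shape[1]), tau_a=self.tau_a, alpha=self.alpha
            )
            values = adapt(rates, state, rectify=False).values
        else:
            values = rates
        mean, std = self.l1_mean, np.where(self.l1_std > 0, self.l1_std, 1.0)
        if self.l1_keep is not None:
            mean, std = mean[self.l1_keep], std[self.l1_keep]
        return (values - mean) / std

    def l2_response(self, signal: AudioSignal) -> L2Response:
        resp = apply_l2(self.l1_response(signal), self.bank)
        if self.l2_keep is not None:
            resp = L2Response(
                values={t: resp.values[t][:, self.l2_keep] for t in resp.context_tag},
                context_tag=resp.context_tag,
            )
        return resp

    def final_response(self, signal: AudioSignal) -> np.ndarray:
        """Concatenated per-context Hebbian-weighted output R^ = R V."""
        return l3.coherence_output(
            self.l2_response(signal), leak=self.leak, enabled=self.coherence_enabled
        )

    # -- lesion helpers ----------------------------------------------------
    def with_l1_lesion(self, unit_ids) -> "StreamModel":
        ids = np.atleast_1d(np.asarray(unit_ids, dtype=int))
        current = (
            np.arange(self.filters.filters.shape[0])
            if self.l1_keep is None
            else self.l1_keep
        )
        keep = np.array([u for u in current if u not in set(ids.tolist())])
        if keep.size == 0:
            raise ValueError("cannot lesion every L1 unit")
        return replace(self, l1_keep=keep)

    def with_l2_lesion(self, unit_ids) -> "StreamModel":
        ids = set(np.atleast_1d(np.asarray(unit_ids, dtype=int)).tolist())
        nh = self.bank.models[0].n_hidden
        current = np.arange(nh) if self.l2_keep is None else self.l2_keep
        keep = np.array([u for u in current if u not in ids])
        if keep.size == 0:
            raise ValueError("cannot lesion every L2 unit")
        return replace(self, l2_keep=keep)

    def without_adaptation(self) -> "StreamModel":
        return replace(self, adaptation_enabled=False)

    def without_coherence(self) -> "StreamModel":
        return replace(self, coherence_enabled=False)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        import h5py


        with h5py.File(path, "w") as f:
            g = f.create_group("l1")
            g.create_dataset("W", data=self.rbm.W, track_times=False)
            g.create_dataset("A", data=self.rbm.A, track_times=False)
            g.create_dataset("B", data=self.rbm.B, track_times=False)
            g.attrs["p"] = self.rbm.p
            g.attrs["sparsity_cost"] = self.rbm.sparsity_cost
            g2 = f.create_group("l2")
            for m in self.bank.models:
                gg = g2.create_group(f"tau_{m.tau:03d}")
                for name in ("W", "A", "B", "C", "D"):
                    gg.create_dataset(name, data=getattr(m, name), track_times=False)
            f.create_dataset("channel_mean", data=self.channel_mean, track_times=False)
            f.create_dataset("channel_std", data=self.channel_std, track_times=False)
            f.create_dataset("l1_mean", data=self.l1_mean, track_times=False)
            f.create_dataset("l1_std", data=self.l1_std, track_times=False)
            if self.l1_raw_std is not None:
                f.create_dataset("l1_raw_std", data=self.l1_raw_std, track_times=False)
            f.attrs["leak"] = self.leak
            f.attrs["tau_a"] = self.tau_a
            f.attrs["alpha"] = self.alpha
            f.attrs["rate_scale"] = self.rate_scale
            for k in ("n_channels", "filters_per_octave", "f_min", "q_erb",
                      "frame_step", "tau_integrate", "asymmetry", "sample_rate"):
                f.attrs[f"peripheral_{k}"] = getattr(self.peripheral, k)

    @classmethod
    def load(cls, path) -> "StreamModel":
        import h5py

        from .l1 import weights_to_filters
        from .l2 import CrbmParams

        with h5py.File(path, "r") as f:
            rbm = RbmParams(
                W=f["l1/W"][...], A=f["l1/A"][...], B=f["l1/B"][...],
                p=float(f["l1"].attrs["p"]),
                sparsity_cost=float(f["l1"].attrs["sparsity_cost"]),
            )
            models = []
            for key in sorted(f["l2"].keys()):
                g = f["l2"][key]
                models.append(
                    CrbmParams(
                        tau=int(key.split("_")[1]), W=g["W"][...], A=g["A"][...],
                        B=g["B"][...], C=g["C"][...], D=g["D"][...],
                    )
                )
            peripheral = PeripheralConfig(
                n_channels=int(f.attrs["peripheral_n_channels"]),
                filters_per_octave=int(f.attrs["peripheral_filters_per_octave"]),
                f_min=float(f.attrs["peripheral_f_min"]),
                q_erb=float(f.attrs["peripheral_q_erb"]),
                frame_step=float(f.attrs["peripheral_frame_step"]),
                tau_integrate=float(f.attrs["peripheral_tau_integrate"]),
                asymmetry=float(f.attrs["peripheral_asymmetry"]),
                sample_rate=int(f.attrs["peripheral_sample_rate"]),
            )
            n_channels = peripheral.n_channels
            return cls(
                peripheral=peripheral,
                rbm=rbm,
                filters=weights_to_filters(rbm, n_channels),
                bank=L2ContextBank(models),
                channel_mean=f["channel_mean"][...],
                channel_std=f["channel_std"][...],
                l1_mean=f["l1_mean"][...],
                l1_std=f["l1_std"][...],
                l1_raw_std=f["l1_raw_std"][...] if "l1_raw_std" in f else None,
                leak=float(f.attrs["leak"]),
                tau_a=float(f.attrs["tau_a"]),
                alpha=float(f.attrs["alpha"]),
                rate_scale=float(f.attrs.get("rate_scale", 1e5)),
            )
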