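"""Config-driven training and experiment harness.

A run is a pure function of an `ExperimentConfig` plus its root seed: the
synthetic natural-sound ensemble (or a directory of WAV files) is pushed
through the peripheral model, L1 is trained by CD on the 3-frame patches,
the adapted L1 responses are standardized and used to train the cRBM bank,
and the resulting `StreamModel` carries all normalization statistics.
Paradigm runners emit tidy per-condition DataFrames; every output carries
the config hash in its manifest.  All randomness flows from the root seed
through named substreams (training / stimuli / decisions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterization, readout, stimuli
from .l1 import L1Config, adapt, AdaptationState, apply_l1, train_l1, weights_to_filters
from .l2 import L2Config, train_bank
from .model import StreamModel
from .peripheral import AuditorySpectrogram, PeripheralConfig, cochleagram, extract_patches, load_wav

__all__ = [
    "ExperimentConfig",
    "config_hash",
    "run_pipeline",
    "retrain_l2_for",
    "run_paradigm",
    "PARADIGMS",
]

_SUBSTREAMS = {"training": 1, "stimuli": 2, "decisions": 3, "ensemble": 4}


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named substream seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    ensemble_seconds: float = 600.0
    ensemble_wav_dir: str | None = None  # train on WAV files instead
    synthetic_ensemble: bool = True
    peripheral: PeripheralConfig = field(default_factory=PeripheralConfig)
    l1: L1Config = field(default_factory=L1Config)
    l2: L2Config = field(default_factory=L2Config)
    leak: float = 0.99
    n_trials: int = 50

    @classmethod
    def scaled_down(cls, seed: int = 0, ensemble_seconds: float = 600.0):
        """Desk-scale configuration: 64 L1 units, two L2 contexts
        (120 and 480 ms), 64 cRBM hidden units."""
        return cls(
            seed=seed,
            ensemble_seconds=ensemble_seconds,
            l1=L1Config(n_hidden=64, n_epochs=12, batch_size=256,
                        seed=substream_seed(seed, "training")),
            l2=L2Config(n_hidden=64, taus_ms=(120, 480), n_epochs=8,
                        batch_size=256, seed=substream_seed(seed, "training")),
        )

    def validate(self) -> None:
        if not self.synthetic_ensemble and not self.ensemble_wav_dir:
            raise ValueError(
                "config error: ensemble_wav_dir is required when "
                "synthetic_ensemble is disabled"
            )
        if self.ensemble_seconds <= 0:
            raise ValueError("config error: ensemble_seconds must be positive")

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        raw = json.loads(Path(path).read_text())
        per = PeripheralConfig(**raw.pop("peripheral", {}))
        l1 = L1Config(**raw.pop("l1", {}))
        l2raw = raw.pop("l2", {})
        if "taus_ms" in l2raw:
            l2raw["taus_ms"] = tuple(l2raw["taus_ms"])
        l2 = L2Config(**l2raw)
        return cls(peripheral=per, l1=l1, l2=l2, **raw)


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ensemble_signals(config: ExperimentConfig) -> list:
    if config.synthetic_ensemble:
        return stimuli.training_ensemble(
            substream_seed(config.seed, "ensemble"), config.ensemble_seconds
        )
    paths = sorted(Path(config.ensemble_wav_dir).glob("*.wav"))
    return [load_wav(p) for p in paths]


def _l1_stream(
    specs_std, filters, tau_a=0.300, alpha=1e-5, rate_scale=1e5
) -> tuple[list, np.ndarray]:
    """Adapted rate-scaled L1 responses per segment, plus the per-unit std
    of the rectified raw responses used as the rate-unit convention."""
    raws = [np.maximum(apply_l1(spec, filters), 0.0) for spec in specs_std]
    raw_std = np.vstack(raws).std(axis=0)
    safe = np.where(raw_std > 0, raw_std, 1.0)
    out = []
    for raw in raws:
        rates = raw / safe * rate_scale
        state = AdaptationState(a=np.ones(raw.shape[1]), tau_a=tau_a, alpha=alpha)
        out.append(adapt(rates, state, rectify=False).values)
    return out, raw_std


def run_pipeline(config: ExperimentConfig, out_dir=None, log: dict | None = None):
    """Train the full hierarchy; returns (StreamModel, manifest dict)."""
    config.validate()
    signals = _ensemble_signals(config)
    specs = [cochleagram(s, config.peripheral) for s in signals]
    frames = np.vstack([s.values for s in specs])
    ch_mean = frames.mean(axis=0)
    ch_std = frames.std(axis=0)
    ch_std_safe = np.where(ch_std > 0, ch_std, 1.0)
    specs_std = [
        AuditorySpectrogram(
            (s.values - ch_mean) / ch_std_safe, s.frame_step, s.channel_center_freqs
        )
        for s in specs
    ]
    patches = np.vstack([extract_patches(s).patches for s in specs_std])

    l1_log: list = []
    rbm = train_l1(patches, config.l1, log=l1_log)
    filters = weights_to_filters(rbm, config.peripheral.n_channels)

    streams, raw_std = _l1_stream(specs_std, filters)
    resp = np.vstack(streams)
    l1_mean, l1_std = resp.mean(axis=0), resp.std(axis=0)
    l1_std_safe = np.where(l1_std > 0, l1_std, 1.0)
    streams_std = [(s - l1_mean) / l1_std_safe for s in streams]

    l2_log: list = []
    bank = train_bank(streams_std, config.l2, log=l2_log)

    model = StreamModel(
        peripheral=config.peripheral,
        rbm=rbm,
        filters=filters,
        bank=bank,
        channel_mean=ch_mean,
        channel_std=ch_std,
        l1_mean=l1_mean,
        l1_std=l1_std,
        l1_raw_std=raw_std,
        leak=config.leak,
    )
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_segments": len(signals),
        "l1_final_recon": l1_log[-1]["recon_error"] if l1_log else None,
        "l1_final_mean_q": l1_log[-1]["mean_q"] if l1_log else None,
        "l2_final_recon": l2_log[-1]["recon_error"] if l2_log else None,
    }
    if log is not None:
        log["l1"] = l1_log
        log["l2"] = l2_log
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / "model.h5")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        pd.DataFrame(l1_log).to_csv(out_dir / "l1_training_log.csv", index=False)
        pd.DataFrame(l2_log).to_csv(out_dir / "l2_training_log.csv", index=False)
    return model, manifest


def retrain_l2_for(model: StreamModel, config: ExperimentConfig) -> StreamModel:
    """Retrain the cRBM bank on the (possibly lesioned) L1 output, using
    the same ensemble seed and L2 hyperparameters."""
    signals = _ensemble_signals(config)
    specs = [cochleagram(s, config.peripheral) for s in signals]
    ch_std_safe = np.where(model.channel_std > 0, model.channel_std, 1.0)
    specs_std = [
        AuditorySpectrogram(
            (s.values - model.channel_mean) / ch_std_safe,
            s.frame_step,
            s.channel_center_freqs,
        )
        for s in specs
    ]
    filters = (
        model.filters
        if model.l1_keep is None
        else type(model.filters)(model.filters.filters[model.l1_keep])
    )
    streams, raw_std = _l1_stream(
        specs_std, filters, model.tau_a, model.alpha, model.rate_scale
    )
    resp = np.vstack(streams)
    l1_mean, l1_std = resp.mean(axis=0), resp.std(axis=0)
    l1_std_safe = np.where(l1_std > 0, l1_std, 1.0)
    streams_std = [(s - l1_mean) / l1_std_safe for s in streams]
    bank = train_bank(streams_std, config.l2)
    full_mean = model.l1_mean.copy()
    full_std = model.l1_std.copy()
    full_raw = (
        model.l1_raw_std.copy()
        if model.l1_raw_std is not None
        else np.ones_like(full_std)
    )
    if model.l1_keep is not None:
        full_mean[model.l1_keep] = l1_mean
        full_std[model.l1_keep] = l1_std
        full_raw[model.l1_keep] = raw_std
    else:
        full_mean, full_std, full_raw = l1_mean, l1_std, raw_std
    return dataclasses.replace(
        model, bank=bank, l1_mean=full_mean, l1_std=full_std,
        l1_raw_std=full_raw, l2_keep=None,
    )


# ---------------------------------------------------------------------------
# paradigms
# ---------------------------------------------------------------------------

def _paradigm_two_tone(model, config):
    return readout.two_tone_experiment(
        model, n_trials=config.n_trials,
        seed=substream_seed(config.seed, "decisions"),
    )


def _paradigm_buildup(model, config):
    return readout.buildup_curve(
        model, n_trials=config.n_trials,
        seed=substream_seed(config.seed, "decisions"),
    )


def _paradigm_am_noise(model, config):
    return readout.am_noise_experiment(
        model, n_trials=config.n_trials,
        seed=substream_seed(config.seed, "decisions"),
    )


def _paradigm_mbx(model, config):
    return readout.mbx_experiment(
        model, n_trials=config.n_trials,
        seed=substream_seed(config.seed, "decisions"),
    )


def _paradigm_mtf(model, config):
    rates = characterization.default_rates(9)
    scales = characterization.default_scales(5)
    rows = []
    for name, stage in (
        ("L1", model.l1_response),
        ("L2", lambda s: np.hstack(list(model.l2_response(s).values.values()))),
    ):
        grid = characterization.measure_mtf(
            stage, rates, scales, duration=1.0,
            seed=substream_seed(config.seed, "stimuli"), keep_per_unit=False,
        )
        for i, w in enumerate(grid.rates):
            for j, om in enumerate(grid.scales):
                rows.append(
                    {"layer": name, "rate_hz": w, "scale_cyc_oct": om,
                     "gain_dB": grid.gain_dB[i, j]}
                )
    return pd.DataFrame(rows)


def _paradigm_speech_synthetic(model, config):
    from .speech import speech_synthetic_experiment

    return speech_synthetic_experiment(
        model, seed=substream_seed(config.seed, "stimuli")
    )


def _paradigm_lesion_suite(model, config):
    """Directional control experiments: harmonicity-cluster lesion and
    coherence lesion, compared against the intact model."""
    rates = characterization.default_rates(9)
    scales = characterization.default_scales(5)
    grid = characterization.measure_mtf(
        model.l1_response, rates, scales, duration=1.0,
        seed=substream_seed(config.seed, "stimuli"),
    )
    k = min(8, grid.per_unit.shape[0])
    assign = characterization.cluster_units(grid.per_unit, k)
    assign = characterization.tag_clusters(assign, rates, scales, model.filters)
    h_clusters = [c for c, tags in assign.tags.items() if "H" in tags]
    h_units = np.flatnonzero(np.isin(assign.labels, h_clusters))
    if h_units.size == 0 or h_units.size == assign.labels.size:
        # fall back: unit-level harmonic scoring
        scale_prof = np.maximum(grid.per_unit, 0.0).mean(axis=1)  # (units, scales)
        band = (scales >= 1.0) & (scales <= 2.0)
        with np.errstate(invalid="ignore"):
            score = scale_prof[:, band].sum(axis=1) / (scale_prof.sum(axis=1) + 1e-12)
        score[~np.isfinite(score)] = 0.0
        h_units = np.argsort(score)[-max(4, assign.labels.size // 8):]

    variants = {
        "intact": model,
        "h_lesion": characterization.lesion(
            model, h_units, "l1", retrain_l2=True, config=config
        ),
        "coherence_lesion": model.without_coherence(),
    }
    rows = []
    dec_seed = substream_seed(config.seed, "decisions")
    # calibrate once on the intact model so lesion effects stay visible
    tt_calib = mb_calib = None
    for name, m in variants.items():
        tt = readout.two_tone_experiment(
            m, n_trials=config.n_trials, seed=dec_seed, calib=tt_calib
        )
        mb = readout.mbx_experiment(
            m, conditions=(("harmonic", "sync"), ("mistuned", "sync")),
            n_trials=config.n_trials, seed=dec_seed, calib=mb_calib,
        )
        if name == "intact":
            d = tt.set_index(["mode", "dF_semitones"])["distance"]
            tt_calib = readout.calibrate(
                d[("synchronous", 15)], d[("alternating", 15)],
                d[("alternating", 6)],
            )
            dm = mb.set_index(["mode", "condition"])["distance"]
            mb_calib = readout.calibrate(
                dm[("MBS", "harmonic")], dm[("MBS", "mistuned")]
            )
        for _, r in tt.iterrows():
            rows.append({"variant": name, "paradigm": "two_tone", **r.to_dict()})
        for _, r in mb.iterrows():
            rows.append({"variant": name, "paradigm": "mbx", **r.to_dict()})
    return pd.DataFrame(rows)


PARADIGMS = {
    "two_tone": _paradigm_two_tone,
    "buildup": _paradigm_buildup,
    "am_noise": _paradigm_am_noise,
    "mbx": _paradigm_mbx,
    "mtf": _paradigm_mtf,
    "speech_synthetic": _paradigm_speech_synthetic,
    "lesion_suite": _paradigm_lesion_suite,
}


def run_paradigm(model, name: str, config: ExperimentConfig, out_dir=None):
    if name not in PARADIGMS:
        raise ValueError(
            f"unknown paradigm {name!r}; valid: {sorted(PARADIGMS)}"
        )
    df = PARADIGMS[name](model, config)
    df = df.assign(config_hash=config_hash(config))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / f"{name}_summary.csv", index=False)
        (out_dir / f"{name}_manifest.json").write_text(
            json.dumps({"config_hash": config_hash(config), "paradigm": name})
        )
    return df
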