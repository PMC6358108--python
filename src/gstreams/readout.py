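"""Readout: convert final model responses into streaming decisions.

For the non-speech paradigms the model is probed with a change-detection
task: a sequence whose final target element is altered (4% frequency for
tones and complexes, 10% of the modulation rate for AM noise) is compared
with the unchanged sequence, and the Euclidean distance between the final
responses inside the final-burst window (+- 50 ms) is thresholded.  A
trial adds zero-mean Gaussian decision noise; hits and false alarms yield

    d' = z(H) - z(F)

with rates clipped away from 0 and 1 before the z-transform.  Because the
network itself is deterministic, the decision-noise standard deviation and
the threshold are calibrated once per paradigm from anchor conditions
(threshold at the midpoint of the clearly-fused / clearly-segregated
anchor distances, noise scaled so the mid-difficulty condition lands near
70% correct) and then frozen for every condition of that paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import stimuli

__all__ = [
    "TrialResult",
    "DPrimeScore",
    "Calibration",
    "response_distance",
    "trial_decision",
    "dprime",
    "calibrate",
    "condition_dprime",
    "two_tone_experiment",
    "buildup_curve",
    "am_noise_experiment",
    "mbx_experiment",
    "gmm_token_readout",
]

WINDOW_PAD_S = 0.050
FRAME_RATE = 100.0


@dataclass(frozen=True)
class TrialResult:
    distance: float
    decision: str  # change | no-change
    truth: str  # changed | unchanged


@dataclass(frozen=True)
class DPrimeScore:
    hits: float
    false_alarms: float
    dprime: float


@dataclass(frozen=True)
class Calibration:
    threshold: float
    noise_sd: float


def _window_frames(window, n_frames: int) -> slice:
    t0, t1 = window
    lo = max(0, int(np.floor((t0 - WINDOW_PAD_S) * FRAME_RATE)))
    hi = min(n_frames, int(np.ceil((t1 + WINDOW_PAD_S) * FRAME_RATE)))
    return slice(lo, hi)


def response_distance(R1: np.ndarray, R2: np.ndarray, window=None) -> float:
    """Euclidean distance between responses, restricted to the final-burst
    window (seconds) when given."""
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.shape != R2.shape:
        raise ValueError("response shapes must match")
    if window is not None:
        sl = _window_frames(window, R1.shape[0])
        R1, R2 = R1[sl], R2[sl]
    return float(np.linalg.norm(R1 - R2))


def trial_decision(
    distance: float,
    threshold: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> str:
    """'change' iff distance + eps exceeds the threshold, eps ~ N(0, sd)."""
    if threshold < 0 or noise_sd < 0:
        raise ValueError("threshold and noise_sd must be non-negative")
    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return "change" if distance + eps > threshold else "no-change"


def dprime(hits: float, false_alarms: float, n_trials: int) -> DPrimeScore:
    """d' = z(H) - z(F) with rates clipped to [1/(2n), 1 - 1/(2n)]."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
    H = float(np.clip(hits, lo, hi))
    F = float(np.clip(false_alarms, lo, hi))
    z = scipy.stats.norm.ppf
    return DPrimeScore(H, F, float(z(H) - z(F)))


def calibrate(
    d_fused: float, d_segregated: float, d_mid: float | None = None,
    target_correct: float = 0.70,
) -> Calibration:
    """Threshold at the anchor midpoint; noise so the mid-difficulty
    distance yields ~`target_correct` hits."""
    theta = 0.5 * (d_fused + d_segregated)
    if d_mid is None:
        d_mid = 0.5 * (theta + d_segregated)
    spread = abs(d_mid - theta)
    if spread == 0.0:
        spread = 0.25 * max(abs(d_segregated - d_fused), 1e-12)
    sd = spread / float(scipy.stats.norm.ppf(target_correct))
    return Calibration(threshold=theta, noise_sd=max(sd, 1e-12))


def condition_dprime(
    change_distances,
    calib: Calibration,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[DPrimeScore, list]:
    """Run seeded change/no-change trials at given change distances.

    Half the trials present the changed sequence (distance drawn from
    `change_distances`, cycled), half the unchanged one (distance 0).
    """
    dists = np.atleast_1d(np.asarray(change_distances, dtype=float))
    trials = []
    hits = fas = 0
    for i in range(n_trials):
        d = float(dists[i % dists.size])
        dec = trial_decision(d, calib.threshold, calib.noise_sd, rng)
        trials.append(TrialResult(d, dec, "changed"))
        hits += dec == "change"
        dec0 = trial_decision(0.0, calib.threshold, calib.noise_sd, rng)
        trials.append(TrialResult(0.0, dec0, "unchanged"))
        fas += dec0 == "change"
    return dprime(hits / n_trials, fas / n_trials, n_trials), trials


# ---------------------------------------------------------------------------
# paradigm drivers
# ---------------------------------------------------------------------------

def streaming_distance(model, sig_changed, sig_nochange, window) -> float:
    """Change salience as reorganization of the binding structure.

    The probe alters the final target element; what distinguishes a
    segregated from a fused percept in the model is whether that probe
    *reorganizes* the Hebbian binding state, not merely whether the
    waveform changed.  The statistic is the Euclidean distance between the
    changed sequence's windowed response weighted by its own final binding
    matrix and the same response weighted by the no-change binding matrix,
    normalized by the direct response difference under fixed binding
    (which removes trivial probe salience, e.g. shorter target tones).
    With the coherence layer lesioned the binding matrices are identical
    and the distance is zero for every condition.
    """
    from .coherence import apply_coherence

    l2c = model.l2_response(sig_changed)
    l2n = model.l2_response(sig_nochange)
    num = den = 0.0
    for tau in l2c.context_tag:
        Rc, Rn = l2c.values[tau], l2n.values[tau]
        if model.coherence_enabled:
            _, Vc = apply_coherence(Rc, leak=model.leak, window=tau,
                                    return_matrix=True)
            _, Vn = apply_coherence(Rn, leak=model.leak, window=tau,
                                    return_matrix=True)
        else:
            Vc = Vn = np.eye(Rc.shape[1])
        sl = _window_frames(window, Rc.shape[0])
        num += np.linalg.norm(Rc[sl] @ (Vc - Vn)) ** 2
        den += np.linalg.norm((Rc[sl] - Rn[sl]) @ Vn) ** 2
    return float(np.sqrt(num) / max(np.sqrt(den), 1e-12))


def two_tone_distances(model, dF: float, mode: str, directions=(+4.0, -4.0)):
    out = []
    for s in directions:
        sig_c, ann = stimuli.two_tone_sequence(dF, mode, final_shift_pct=s)
        sig_n, _ = stimuli.two_tone_sequence(dF, mode)
        out.append(streaming_distance(model, sig_c, sig_n, ann["target_window"]))
    return out


def two_tone_experiment(
    model,
    dFs=(1, 3, 6, 9, 15),
    modes=("alternating", "synchronous"),
    n_trials: int = 50,
    seed: int = 0,
    calib: Calibration | None = None,
) -> pd.DataFrame:
    """d' vs frequency separation for alternating and synchronous two-tone
    sequences.  Calibration anchors: synchronous dF=15 (fused) vs
    alternating dF=15 (segregated); mid-difficulty alternating dF=6."""
    rng = np.random.default_rng(seed)
    dist = {
        (dF, mode): np.mean(two_tone_distances(model, dF, mode))
        for dF in dFs
        for mode in modes
    }
    if calib is None:
        calib = calibrate(
            d_fused=dist[(max(dFs), "synchronous")],
            d_segregated=dist[(max(dFs), "alternating")],
            d_mid=dist.get((6, "alternating")),
        )
    rows = []
    for (dF, mode), d in dist.items():
        score, _ = condition_dprime([d], calib, n_trials, rng)
        rows.append(
            {"dF_semitones": dF, "mode": mode, "distance": d,
             "hit_rate": score.hits, "fa_rate": score.false_alarms,
             "dprime": score.dprime}
        )
    return pd.DataFrame(rows)


def buildup_curve(
    model,
    durations=tuple(range(1, 11)),
    d_semitones=(1, 3, 6, 9),
    fAs=(500.0, 1000.0, 2000.0),
    n_trials: int = 50,
    seed: int = 0,
    calib: Calibration | None = None,
) -> pd.DataFrame:
    """Percent correct detection of the final-A probe vs sequence duration,
    averaged over base frequencies.  Calibration anchors: d=1 (fused) vs
    d=9 (segregated) at the longest duration."""
    rng = np.random.default_rng(seed)

    def dist(fA, d, T):
        sig_c, ann = stimuli.aba_triplet_sequence(fA, d, T, final_shift_pct=4.0)
        sig_n, _ = stimuli.aba_triplet_sequence(fA, d, T)
        return streaming_distance(model, sig_c, sig_n, ann["target_window"])

    Tmax = max(durations)
    if calib is None:
        lo = np.mean([dist(fA, min(d_semitones), Tmax) for fA in fAs])
        hi = np.mean([dist(fA, max(d_semitones), Tmax) for fA in fAs])
        calib = calibrate(lo, hi)
    rows = []
    for d in d_semitones:
        for T in durations:
            correct = 0
            per_fa = [dist(fA, d, T) for fA in fAs]
            for i in range(n_trials):
                dd = per_fa[i % len(per_fa)]
                if trial_decision(dd, calib.threshold, calib.noise_sd, rng) == "change":
                    correct += 1
                if trial_decision(0.0, calib.threshold, calib.noise_sd, rng) == "no-change":
                    correct += 1
            rows.append(
                {"d_semitones": d, "duration_s": T, "distance": float(np.mean(per_fa)),
                 "percent_correct": 100.0 * correct / (2 * n_trials)}
            )
    return pd.DataFrame(rows)


def am_noise_experiment(
    model,
    d_octaves=(0, 0.3, 0.5, 0.7, 0.8, 1, 1.2, 1.4, 1.6, 1.8, 2, 2.5, 3),
    n_trials: int = 50,
    seed: int = 0,
    calib: Calibration | None = None,
    n_stimulus_seeds: int = 2,
) -> pd.DataFrame:
    """Percent 2-streams (correct detection of the 10% AM-rate probe on the
    final A burst) vs AM-rate separation.  Anchors: dAM=0 vs max dAM."""
    rng = np.random.default_rng(seed)

    def dists(d):
        out = []
        for s in range(n_stimulus_seeds):
            sig_c, ann = stimuli.am_noise_sequence(
                d, seed=seed + 7919 * s, final_rate_shift_pct=10.0
            )
            sig_n, _ = stimuli.am_noise_sequence(d, seed=seed + 7919 * s)
            out.append(
                streaming_distance(model, sig_c, sig_n, ann["target_window"])
            )
        return out

    cond = {d: dists(d) for d in d_octaves}
    if calib is None:
        calib = calibrate(
            d_fused=float(np.mean(cond[min(d_octaves)])),
            d_segregated=float(np.mean(cond[max(d_octaves)])),
            d_mid=float(np.mean(cond.get(1, cond[max(d_octaves)]))),
        )
    rows = []
    for d, ds in cond.items():
        correct = 0
        for i in range(n_trials):
            dd = ds[i % len(ds)]
            if trial_decision(dd, calib.threshold, calib.noise_sd, rng) == "change":
                correct += 1
            if trial_decision(0.0, calib.threshold, calib.noise_sd, rng) == "no-change":
                correct += 1
        rows.append(
            {"d_octaves": d, "distance": float(np.mean(ds)),
             "percent_2_streams": 100.0 * correct / (2 * n_trials)}
        )
    return pd.DataFrame(rows)


def mbx_experiment(
    model,
    modes=("MBS", "MBD"),
    conditions=(("harmonic", "sync"), ("mistuned", "sync"), ("shifted", "sync"),
                ("harmonic", "async")),
    n_trials: int = 50,
    n_stimulus_seeds: int = 4,
    seed: int = 0,
    calib: Calibration | None = None,
) -> pd.DataFrame:
    """d' for MBS/MBD complexes across harmonicity / onset conditions.
    Anchors: MBS harmonic-sync (fused) vs MBS mistuned-sync (segregated)."""
    rng = np.random.default_rng(seed)

    def dists(mode, condition, sync):
        out = []
        for s in range(n_stimulus_seeds):
            st_seed = seed + 104729 * s
            sig_c, ann = stimuli.mbx_sequence(
                mode, condition, sync, seed=st_seed, final_target_shift_pct=4.0
            )
            sig_n, _ = stimuli.mbx_sequence(mode, condition, sync, seed=st_seed)
            out.append(
                streaming_distance(model, sig_c, sig_n, ann["target_window"])
            )
        return out

    cond = {
        (mode, c, s): dists(mode, c, s) for mode in modes for (c, s) in conditions
    }
    if calib is None:
        lo = float(np.mean(cond[("MBS", "harmonic", "sync")]))
        hi = float(np.mean(cond[("MBS", "mistuned", "sync")]))
        calib = calibrate(lo, hi)
    rows = []
    for (mode, c, s), ds in cond.items():
        score, _ = condition_dprime(ds, calib, n_trials, rng)
        rows.append(
            {"mode": mode, "condition": c, "sync": s,
             "distance": float(np.mean(ds)), "hit_rate": score.hits,
             "fa_rate": score.false_alarms, "dprime": score.dprime}
        )
    return pd.DataFrame(rows)


def gmm_token_readout(
    train_responses: dict,
    test_responses,
    n_components: int = 2,
    threshold: float | None = None,
    seed: int = 0,
) -> dict:
    """Gaussian-mixture token identification on per-utterance mean responses.

    `train_responses` maps class label -> list of mean response vectors;
    `test_responses` is a list of (true_label, vector).  One GMM is fitted
    per class (components reduced with a warning if a class has too few
    examples); test vectors are assigned to the class with maximum
    log-likelihood, subject to an optional acceptance threshold.
    """
    import warnings

    from sklearn.mixture import GaussianMixture

    if len(train_responses) < 2:
        raise ValueError("need at least 2 target classes")
    models = {}
    for label, vecs in train_responses.items():
        X = np.vstack(vecs)
        nc = min(n_components, X.shape[0])
        if nc < n_components:
            warnings.warn(f"class {label!r}: reducing GMM components to {nc}")
        if X.shape[0] < 2:  # degenerate class: duplicate with tiny jitter
            X = np.vstack([X, X + 1e-6])
        models[label] = GaussianMixture(
            n_components=nc, covariance_type="diag", random_state=seed,
            reg_covar=1e-4,
        ).fit(X)
    per_class = {label: [0, 0] for label in models}
    for true_label, vec in test_responses:
        vec = np.asarray(vec, dtype=float)[None, :]
        scores = {label: float(m.score(vec)) for label, m in models.items()}
        pred = max(scores, key=scores.get)
        if threshold is not None and scores[pred] < threshold:
            pred = None
        per_class[true_label][1] += 1
        if pred == true_label:
            per_class[true_label][0] += 1
    acc = {
        label: 100.0 * c / t if t else np.nan for label, (c, t) in per_class.items()
    }
    total_c = sum(c for c, _ in per_class.values())
    total_t = sum(t for _, t in per_class.values())
    return {
        "per_class": acc,
        "overall": 100.0 * total_c / total_t if total_t else np.nan,
    }
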