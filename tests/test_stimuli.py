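import numpy as np
import pytest

from gstreams import stimuli
from gstreams.stimuli import (
    ComplexBurstSpec,
    RippleSpec,
    aba_triplet_sequence,
    am_noise_sequence,
    complex_burst,
    matched_noise,
    mbx_sequence,
    ripple,
    semitone_to_hz,
    training_ensemble,
    two_tone_sequence,
)

FS = 8000


class TestSemitone:
    @pytest.mark.parametrize(
        "st,expected",
        [(-1, 943.9), (-3, 840.9), (-6, 707.1), (-9, 594.6), (-15, 420.4)],
    )
    def test_printed_b_tone_frequencies(self, st, expected):
        assert semitone_to_hz(1000.0, st) == pytest.approx(expected, abs=0.05)

    def test_identity_and_octave(self):
        assert semitone_to_hz(1000.0, 0) == 1000.0
        assert semitone_to_hz(1000.0, -12) == pytest.approx(500.0)


class TestTwoTone:
    def test_synchronous_duration(self):
        sig, annot = two_tone_sequence(6, "synchronous")
        assert sig.duration == pytest.approx(2.3)
        assert annot["n_tones"] == 24

    def test_alternating_duration_and_count(self):
        sig, annot = two_tone_sequence(6, "alternating")
        assert sig.duration == pytest.approx(2.4)
        assert len(annot["events"]) == 24

    def test_alternating_same_frequency_spacing(self):
        _, annot = two_tone_sequence(3, "alternating")
        a_onsets = [e["onset"] for e in annot["events"] if e["label"] == "A"]
        assert np.allclose(np.diff(a_onsets), 0.200)

    def test_final_probe_shifts_last_a_tone(self):
        _, annot = two_tone_sequence(3, "alternating", final_shift_pct=4.0)
        a_events = [e for e in annot["events"] if e["label"] == "A"]
        assert a_events[-1]["freq"] == pytest.approx(1040.0)
        assert a_events[-2]["freq"] == pytest.approx(1000.0)

    def test_annotation_matches_waveform_energy(self):
        sig, annot = two_tone_sequence(6, "alternating")
        for e in annot["events"][:4]:
            seg = sig.samples[int(e["onset"] * FS) : int(e["offset"] * FS)]
            assert np.max(np.abs(seg)) > 0.1
        assert np.max(np.abs(sig.samples)) <= 1.0


class TestBuildup:
    def test_triplet_period_and_count(self):
        sig, annot = aba_triplet_sequence(1000.0, 6, 1.0)
        assert annot["n_triplets"] == 2
        assert sig.duration == pytest.approx(1.0)

    def test_b_frequency_octave(self):
        _, annot = aba_triplet_sequence(1000.0, 12, 1.0)
        b = [e for e in annot["events"] if e["label"] == "B"][0]
        assert b["freq"] == pytest.approx(2000.0)

    def test_target_window_is_last_a(self):
        _, annot = aba_triplet_sequence(500.0, 3, 2.0)
        t0, t1 = annot["target_window"]
        assert t1 - t0 == pytest.approx(0.125)
        assert t1 == pytest.approx(1.875)  # last triplet's final A tone


class TestAmNoise:
    def test_total_duration(self):
        sig, _ = am_noise_sequence(1.0, seed=0)
        assert sig.duration == pytest.approx(6.4)

    def test_rate_mapping(self):
        _, annot = am_noise_sequence(3.0, seed=0)
        rates = {e["label"]: e["rate"] for e in annot["events"][:2]}
        assert rates["A"] == pytest.approx(100.0)
        assert rates["B"] == pytest.approx(800.0)

    def test_zero_separation_same_rate(self):
        _, annot = am_noise_sequence(0.0, seed=0)
        assert all(e["rate"] == pytest.approx(100.0) for e in annot["events"])


class TestComplexes:
    def test_harmonic_components_below_2khz(self):
        rng = np.random.default_rng(0)
        _, events, _ = complex_burst(ComplexBurstSpec(3), rng)
        freqs = sorted(e["freq"] for e in events)
        assert freqs == pytest.approx(
            [333.33, 666.67, 1000.0, 1333.33, 1666.67], abs=0.05
        )

    def test_mistuned_target_pm_4pct(self):
        seen = set()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, events, _ = complex_burst(ComplexBurstSpec(4, "mistuned"), rng)
            tgt = [e for e in events if e["label"] == "A"][0]
            assert tgt["freq"] in (pytest.approx(1040.0), pytest.approx(960.0))
            seen.add(round(tgt["freq"]))
        assert seen == {1040, 960}

    def test_async_onset_lead_and_shared_offset(self):
        rng = np.random.default_rng(1)
        _, events, _ = complex_burst(ComplexBurstSpec(5, "harmonic", "async"), rng)
        tgt = [e for e in events if e["label"] == "A"][0]
        bg = [e for e in events if e["label"] == "bg"][0]
        assert tgt["onset"] - bg["onset"] == pytest.approx(0.040)
        assert tgt["offset"] == pytest.approx(bg["offset"])

    def test_mbs_single_n_and_8_bursts(self):
        _, annot = mbx_sequence("MBS", seed=3)
        assert len(annot["N_per_burst"]) == 8
        assert len(set(annot["N_per_burst"])) == 1

    def test_mbd_no_consecutive_repeats(self):
        for seed in range(1000):
            _, annot = mbx_sequence("MBD", seed=seed)
            Ns = annot["N_per_burst"]
            assert all(a != b for a, b in zip(Ns, Ns[1:]))


class TestRipple:
    def test_component_count_and_flat_envelope_at_zero_depth(self):
        spec = RippleSpec(8.0, 1.0, dA=0.0)
        assert spec.n_tones == 280
        sig = ripple(spec, 0.5, seed=0)
        assert sig.duration == pytest.approx(0.5)

    def test_depth_out_of_range_raises(self):
        with pytest.raises(ValueError):
            RippleSpec(8.0, 1.0, dA=1.5)

    def test_envelope_value_at_origin(self):
        # at t=0, x=0, phi=0 the envelope is exactly L (sin(0)=0)
        spec = RippleSpec(4.0, 0.5, dA=1.0, L=2.0)
        i = np.arange(280)
        x = np.log2((spec.f0 * 2 ** (5 * i / 279)) / spec.f0)
        env0 = spec.L * (1 + spec.dA * np.sin(2 * np.pi * (spec.Omega * x)))
        assert env0[0] == pytest.approx(spec.L)

    def test_seeded_determinism(self):
        a = ripple(RippleSpec(8.0, 1.0), 0.3, seed=5)
        b = ripple(RippleSpec(8.0, 1.0), 0.3, seed=5)
        assert np.array_equal(a.samples, b.samples)


class TestMatchedNoise:
    def test_filter_matches_reference_spectrum(self):
        import scipy.signal

        rng = np.random.default_rng(0)
        # pink-ish reference: lowpassed noise
        refs = []
        for s in range(3):
            x = np.random.default_rng(s).standard_normal(24000)
            b, a = scipy.signal.butter(2, 1000, fs=FS)
            refs.append(stimuli.AudioSignal(scipy.signal.lfilter(b, a, x)))
        out = matched_noise(refs, duration=3.0, seed=1)
        f, p_out = scipy.signal.welch(out.samples, fs=FS, nperseg=1024)
        p_ref = np.mean(
            [scipy.signal.welch(r.samples, fs=FS, nperseg=1024)[1] for r in refs],
            axis=0,
        )
        band = (f > 200) & (f < 3000)
        ratio_db = 10 * np.log10(p_out[band] / p_ref[band])
        ratio_db -= ratio_db.mean()  # overall level is arbitrary
        assert np.percentile(np.abs(ratio_db), 90) < 3.0

    def test_white_reference_stays_flat(self):
        import scipy.signal

        refs = [
            stimuli.AudioSignal(np.random.default_rng(s).standard_normal(24000))
            for s in range(2)
        ]
        out = matched_noise(refs, duration=2.0, seed=0)
        f, p = scipy.signal.welch(out.samples, fs=FS, nperseg=1024)
        band = (f > 300) & (f < 3500)
        spread = 10 * np.log10(p[band].max() / p[band].min())
        assert spread < 6.0

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            matched_noise([])


class TestEnsemble:
    def test_segment_length_and_standardization(self):
        segs = training_ensemble(0, 9.0)
        assert len(segs) == 3
        for s in segs:
            assert s.samples.size == 24000
            assert abs(s.samples.mean()) < 1e-10
            assert abs(s.samples.var() - 1.0) < 1e-6

    def test_seeded_determinism(self):
        a = training_ensemble(4, 6.0)
        b = training_ensemble(4, 6.0)
        for x, y in zip(a, b):
            assert np.array_equal(x.samples, y.samples)

    def test_segments_differ(self):
        segs = training_ensemble(1, 12.0)
        assert not np.array_equal(segs[0].samples, segs[1].samples)
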