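# Methods

`gstreams` implements a hierarchical, unsupervised model of auditory stream
segregation: a biomimetic auditory spectrogram, a sparse Gaussian–Bernoulli
restricted Boltzmann machine (RBM) that learns *simultaneous* grouping cues
from local spectro-temporal patches, a bank of conditional RBMs (cRBMs)
over longer temporal contexts that learns *sequential* cues, and a Hebbian
temporal-coherence stage that binds co-activated channels into streams.
A signal-detection readout converts responses to the classic psychoacoustic
streaming measures (d′, percent correct, buildup curves, token
identification).

## Peripheral model

The waveform (resampled to 8 kHz) is analyzed by 128 constant-Q bandpass
filters at 24 filters/octave starting at 180 Hz. The printed description of
this front end ("5.3 octaves spanning 180 Hz to 4000 Hz") is internally
inconsistent (log2(4000/180) ≈ 4.47 octaves); we fix the channel count and
density and let the top channels fall above Nyquist, where they carry
near-zero energy. Filters are asymmetric Gaussians on the linear frequency
axis with ERB = cf/4 (Q_ERB ≈ 4) and a steeper high-frequency skirt
(asymmetry 0.6), plus a channel-dependent group delay ∝ 1/ERB emulating the
cochlear traveling wave; the delay matters because the next step — a first
difference across adjacent channels (spectral sharpening) — would otherwise
cancel in-phase channel outputs at the response peak. The sharpened outputs
are half-wave rectified and integrated with an exponential kernel
(τ = 10 ms), sampled every 10 ms; a 1-second input yields exactly 100
frames. Three consecutive frames are concatenated into 384-dimensional
patches.

Limitations to note: a 100 frames/s envelope clock cannot represent
modulation rates at integer multiples of 100 Hz (they alias to DC), which
matters for the AM-noise paradigm below.

## Simultaneous layer (L1)

A sparse RBM with Gaussian visible units over the (per-channel
standardized) patches and K Bernoulli hidden units (K = 400 full scale,
64 at desk scale). Energy:

    E(x, h) = ½ Σ_k (x_k − A_k)² − Σ_l B_l h_l − Σ_kl x_k h_l w_kl

Hidden activation probabilities are logistic in x·w_l + B_l (the hidden
bias is included even though one printed form omits it). Training is CD-1
with momentum 0.9, learning rate 1e-3, minibatch 128 (256 at desk scale),
and a cross-entropy sparsity penalty p log q + (1−p) log(1−q) with target
p = 0.05. The penalty enters the update as cost·(p − q) on hidden biases
and weight columns; because this term is scaled by the same learning rate
as the CD gradient, a cost of order 1 is required for it to bite — the
default is 5.0 (configurable). At desk scale the trained mean activation
settles near 0.12.

After training, each weight column is reshaped to a 3×128 spectro-temporal
filter F(t, f) and applied causally along time (the response at frame t is
the dot product of the filter with the patch ending at t). Responses are
half-wave rectified before adaptation so the rate interpretation of the
adaptation equation holds.

### Synaptic adaptation

Tsodyks-style closed-loop depression per unit:

    da/dt = (1 − a)/τ_a − α·a·r,   r_out(t) = a(t)·r(t)

with τ_a = 300 ms and utilization α = 1e-5, integrated exactly per 10 ms
step (a ← a∞ + (a − a∞)e^(−λΔt), λ = 1/τ_a + αr), so a stays in (0, 1]
unconditionally and the constant-drive steady state is
a* = 1/(1 + τ_a α c) to machine precision. These printed constants only
produce measurable depression when r is in spike-rate-like units (~10⁴–10⁵);
on standardized filter responses of order 1 the αar term is negligible and
adaptation would be inert. We therefore express rectified responses in rate
units before integration: one training-set standard deviation maps to
rate_scale = 1e5 (so a persistently active unit at 3 SD depresses to
a* ≈ 0.5 with a 300 ms time constant). This is a units convention, not an
extra mechanism; τ_a and α are untouched.

## Sequential layer (L2)

An array of cRBMs over contexts τ ∈ 30–600 ms (default bank {30, 60, 120,
240, 480, 600} ms; the desk-scale configuration uses {120, 480} ms). Each
cRBM conditions the current (standardized, adapted) L1 response vector on
the previous τ frames through dynamic biases that are linear in the
history, for both visible and hidden units — the autoregressive weights C
and D both act on the visible history (one printed equation shows the
hidden dynamic bias driven by past hidden states, but the surrounding text
defines both as linear functions of the past filter responses, which is
also the standard conditional-RBM form). Histories are zero-padded at
sequence start so onsets are kept, and never cross training-segment
boundaries. Training is CD-1 with the same hyperparameters as L1;
C and D start at zero. Inference is linear, as a multi-resolution output:
per frame, the pre-sigmoid hidden drive Wᵀx(t) + b̂(t).

## Temporal coherence layer (L3)

A synaptic matrix V accumulates the Hebbian outer product of channel
responses within each context block:

    V(t) = leak · V(t−1) + r(t) r(t)ᵀ

with a multiplicative leak of 0.99 per 10 ms step and V(0) = I. Raw
(non-negative) rates can only grow V, so each channel is first centered by
a causal moving average over its own context window (τ frames);
anti-phase channels then accumulate negative weights, as the coherence
account requires. No normalization is printed for this stage; we rescale V
to unit diagonal (a correlation-form, homeostatic synaptic scaling) before
applying it, because the raw matrix norm tracks overall stimulus energy —
e.g. it varied several-fold with the frequency of the B tone in the
two-tone paradigm — and that energy would otherwise masquerade as
coherence. The layer output is R̂_t = R_t V̂_t per context block,
concatenated across blocks.

## Stimulus battery

All stimuli are synthesized at 8 kHz from their printed parameters, with
10 ms raised-cosine ramps, and return sample-accurate annotations
(onsets/offsets/frequencies/condition labels plus the final-target readout
window):

- **Two-tone**: 24 × 100 ms tones; A = 1000 Hz, B 1–15 semitones below.
  Alternating = strict contiguous ABAB (2.4 s; 100 ms between
  same-frequency tones); synchronous = 12 simultaneous A+B bursts with
  100 ms silences (2.3 s, no trailing silence).
- **ABA buildup**: 125 ms tones, ABA_ triplets (500 ms period, silence only
  between triplets), A ∈ {500, 1000, 2000} Hz, B 1–9 semitones above,
  total 1–10 s.
- **AM noise**: 100 ms bursts of 100%-depth sinusoidally modulated
  band-limited (180–4000 Hz) white noise in ABA triplets with 20 ms
  inter-triplet gaps; 6.4 s total; A at 100 Hz, B 0–3 octaves above.
- **MBS/MBD complexes**: 8 bursts of harmonics of f₀ = 1000/N (N ∈ 3–6,
  components < 2000 Hz, target = 1000 Hz). MBS holds N; MBD redraws it per
  burst with no immediate repeats. Conditions: harmonic; shifted
  (background moved by 25% of f₀); mistuned (target moved ±4%); async
  (100 ms background leading a 60 ms target by 40 ms, shared offsets).
  The inter-burst silence is not printed; we use 100 ms.
- **Ripples**: 280 tones log-spaced over 5 octaves from 180 Hz with the
  drifting sinusoidal spectro-temporal envelope
  L(1 + ΔA sin(2π(ωt + Ωx) + φ)), x = log₂(f/f₀); component phases are
  seeded. Components at or above Nyquist are muted (anti-aliasing guard).
- **Matched noise**: white noise shaped by a 512-tap linear-phase FIR
  fitted to the reference ensemble's average Welch spectrum.

### Training ensemble

The synthetic stand-in for a natural-sound corpus: 3 s segments at 8 kHz,
raised-cosine windowed, standardized to zero mean and unit variance, drawn
from four generator families with weights 0.4/0.3/0.15/0.15 — voiced
harmonic stacks with drifting f₀ (80–300 Hz) under syllabic (2–8 Hz)
envelopes, AM band-noise (4–300 Hz rates), linear/log chirps, and click
trains — occasionally over a low noise bed. It reproduces the coarse
statistics the model needs (harmonicity, common onsets, a realistic span of
AM rates and spectral slopes), not the phonetics, semantics or long-range
structure of real speech; passing tests therefore show the architecture
behaves as designed under those statistics, not that it reaches
corpus-trained performance.

The desk-scale study conditions are 64 L1 units, two L2 contexts of 64
hidden units each, a 10-minute ensemble, 12 L1 epochs and 8 L2 epochs
(epoch counts chosen so the full train runs in ~1.5 minutes); the full-size
defaults (400/300 units, six contexts, 50 epochs) are configuration away.

## Readout

For the non-speech paradigms the probe alters the final target element
(4% frequency for tones/complexes, 10% of modulation rate for AM noise)
and the model compares the changed and unchanged sequences over the final
target window ± 50 ms. The plain Euclidean distance between final
responses is implemented (`response_distance`) but is a poor streaming
measure here: the probe is visible at the cochleagram level in *every*
condition, so the direct difference term swamps the condition effects the
paradigms are designed to reveal. The drivers therefore use a
binding-change distance (`streaming_distance`): the Euclidean distance
between the changed sequence's windowed response weighted by its own final
binding matrix and by the no-change binding matrix —
‖R_c(V̂_c − V̂_n)‖ — normalized by the direct term ‖(R_c − R_n)V̂_n‖.
It measures whether the probe *reorganized the perceptual organization*,
relative to its trivial acoustic salience; with the coherence layer
lesioned it is identically zero.

Decisions add zero-mean Gaussian noise to the distance and threshold it;
d′ = z(hits) − z(false alarms) with rates clipped to [1/(2n), 1 − 1/(2n)].
Because the network is deterministic, threshold and noise SD are calibrated
once per paradigm — threshold at the midpoint of a clearly-fused and a
clearly-segregated anchor condition, noise SD set so a mid-difficulty
condition lands near 70% correct — and then frozen for all conditions of
that paradigm. Lesion comparisons reuse the intact model's calibration so
lesion effects are not normalized away.

The speech-token readout averages final responses over the token frames,
fits one diagonal-covariance Gaussian mixture per target class on training
means, and classifies test means by maximum log-likelihood (optional
acceptance threshold). The bundled corpus is synthetic: four vowel classes
defined by formant pairs, impulse-train sources at jittered f₀ through two
resonators, mixed with matched noise at controlled SNR.

## Characterization

Modulation transfer functions probe any stage (a callable from audio to a
frames × units response) with ripple pairs at ΔA = 100% and 0% per
(rate, density) point; the modulation-synchronized magnitude is the DFT
coefficient at the bin nearest the ripple rate over the steady state
(first 200 ms dropped), RMS-pooled across units, and the tuning value is
10·log₁₀(‖M₁₀₀‖²/‖M₀‖²) (+∞ sentinel when the floor is exactly zero).
Default grid: 21 rates over [−50, 50] Hz × 13 log-spaced densities over
[0.25, 16] cyc/oct (reduced to 9 × 5 in the desk-scale harness). Per-unit
grids feed average-linkage agglomerative clustering on Euclidean distance
(default k = 8); clusters are tagged H when the centroid scale peak lies in
[1, 2] cyc/oct, S/F below/above a 25 Hz rate centroid, and O when a fast
cluster's member filters have onset polarity (late-frame weights exceeding
early-frame weights). Lesions remove L1 or L2 units from the signal path
(idempotent and composable), can retrain L2 on the reduced input with the
same seed and hyperparameters, or switch off adaptation or coherence.

## Numerical and reproducibility choices

- All randomness flows from one root seed through named SHA-256 substreams
  (training / stimuli / decisions / ensemble); identical seeds give
  byte-identical HDF5 model files and CSV results (HDF5 timestamps
  disabled).
- Logistic evaluated in the numerically stable two-branch form; sparsity
  penalty clamps q to [1e-7, 1 − 1e-7]; adaptation gains clamped to
  (0, 1]; degenerate GMM classes (one example) are duplicated with 1e-6
  jitter after a warning.
- d′ estimates in the acceptance harness use 40 000 decision draws per
  condition so the reported values are close to the deterministic expected
  d′ implied by the calibrated threshold and distances.

## Known limitations

- Integer-octave AM-rate separations (100 → 200/400/800 Hz) are nearly
  invisible at the 100 frames/s envelope clock (aliasing to DC); the
  AM-noise separation signal rests on small band-edge cues and is the least
  robust paradigm at desk scale.
- The onset-asynchrony (async) advantage in the MBS/MBD paradigms does not
  emerge at 64 units: the printed async condition shortens the target to
  60 ms, and the segregation benefit does not outweigh the reduced probe
  energy at this scale.
- The desk-scale model's d′ magnitudes are not comparable to
  corpus-trained values; only effect directions and orderings are
  meaningful.
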