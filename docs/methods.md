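# Methods

This note documents the models behind `armband-bench`: what is simulated,
the choices that were genuinely open, and what the synthetic results do and
do not say about real recordings.

## 1. The synthetic sEMG signal

A "master" signal — the electrical activity at the skin before any
acquisition electronics — is synthesized at 4000 sps on the union of both
armbands' electrode rings (16 distinct ring angles). 4000 sps is an 8×
margin over the 450 Hz signal content; the fully oversampled ΔΣ domain
(50 ksps) is only ever materialized inside the device front-end for short
validation segments.

Each gesture g is parameterized by:

* a **spatial profile** p_g(θ) ≥ 0 — a constant floor plus one to three
  von-Mises lobes on the ring, normalized so the ring-average of p² is 1;
* **band weights** (w_low, w_high), w_low + w_high = 1 — the fractions of
  signal power in 20–100 Hz and 100–450 Hz;
* a **mean amplitude** A (ring-average RMS, volts). Gesture 0 ("neutral")
  has A equal to the 5 µVrms resting baseline and a uniform profile.

The waveform on channel c is a mixture of 4 independent "virtual sources"
per band — white Gaussian noise shaped by 4th-order Butterworth band-pass
filters and normalized to unit RMS — mixed through a smooth von-Mises
spatial kernel so neighbouring electrodes are correlated, scaled by
A · sqrt(w_b) · p_g(θ_c + rotation) · gain_c, and multiplied by a linear
0→1 ramp over the first 500 ms of each hold (the ramp shape is not
specified by the protocol being emulated; linear is the simplest choice,
and ramp samples carry the gesture's label).

Per-channel RMS therefore matches its analytic target to within a few
percent on 5 s holds, and the fraction of power above 100 Hz estimates
w_high — both are tested properties, and the second is the lever of the
whole benchmark: gesture pairs whose low-band power is matched but whose
high-band power differs are nearly indistinguishable to a 100 Hz-limited
chain.

**Gesture bank structure.** Gestures 1–10 form five pairs. Within a pair
the two gestures share (almost) the same spatial profile; they differ by a
gap in w_high (default 0.18) with low-band absolute power matched up to a
small relaxation, plus a small spatial perturbation lobe. The last pair is
the designated near-duplicate: identical in every respect except a
localized ×1.9 high-band emphasis around one lobe — the synthetic analogue
of two grips differing by one finger, and (tested) the most-confused pair
for both armbands.

**Variability.** Per participant: ring rotation uniform on [0°, 360°),
smooth per-angle contact gains (log-harmonics, σ ≈ 3.5%). Per cycle:
rotation jitter (σ = 5° at default difficulty) and per-segment
contraction-strength jitter (lognormal σ = 0.30). Between sessions:
a re-seating rotation (mean 8°) and 5% gain drift, emulating the pause
between the train and test recordings. All of it derives from one seed;
identical seeds give bit-identical signals.

**Difficulty presets.** `easy`, `default`, `hard` scale profile
separation, band-weight gaps and jitter. The `default` preset was
calibrated by simulation at fixed seeds so the wideband profile's 4-cycle
LDA accuracy lands in the 80–90% regime; the calibration is frozen in the
preset table and asserted by a test. The presets' band-split effect is
deliberately strong enough to be resolvable; real gestures differ in more
(and more subtle) ways, so the synthetic wide-vs-narrow accuracy gap
(~30 points) is larger than the few points observed on real recordings.

## 2. The acquisition chains

Each armband is a `DeviceProfile` (channels, output rate, ENOB, full
scale, analog corners, OSR, CIC order, input-referred noise, electrode
angles), shipped as editable JSON.

**Wideband chain (`3dc`).** One-pole analog high-pass at 1 Hz (the
pseudo-resistor corner) and low-pass at 7 kHz; ΔΣ conversion represented
by its decimation filtering and effective resolution — the modulator is
*not* bit-level simulated, because the converter is characterized entirely
by OSR (50), ENOB (10) and noise, and every testable consequence flows
through those; a 4th-order CIC (R=50, M=1) decimates 50 ksps → 1000 sps.
The bare sinc⁴ CIC droops to −3 dB at 0.227 × F_decim ≈ 227 Hz, far below
the chain's advertised ~460 Hz corner, so — as real CIC designs do — an
inverse-sinc compensation FIR at the decimated rate flattens the passband
to ≈ 440 Hz; the compensated chain passes 300 Hz tones essentially
unattenuated and its corner lands near the advertised figure.
`cic_decimate` itself remains the textbook filter and is tested against
the closed-form sinc-ratio magnitude at 10⁻⁶ relative accuracy.

**Narrowband chain (`myo`).** One-pole high-pass at 5 Hz; the ~100 Hz
upper band edge *is* the Nyquist frequency of the 200 sps sampler and is
realized by the anti-aliasing polyphase resampler rather than a separate
analog pole (none is documented for the device class being emulated).
Its input-referred noise is not published; it is set equal to the wideband
chain's 2.2 µVrms so that the comparison isolates bandwidth, channel count
and resolution rather than amplifier quality.

**Noise.** The published noise figure (2.2 µVrms over 20–500 Hz) is a
measured in-band total, so the model injects white Gaussian noise with
that RMS at the decimated rate, just before quantization, in both
fidelities. Injecting it upstream of the CIC would let the decimator's
droop eat ~30% of it and the recorded noise floor would no longer match
the measured figure. With the 10-bit step (5.86 µV) the quantizer adds its
own ~1.2 µV on top, so a grounded-input recording reads ≈ 2.5 µVrms.

**Quantization.** Uniform mid-tread quantizer: code = round(v/step) + 2^(b−1),
step = full-scale/2^b, clipped at the rails (clipping is counted and
logged); dequantization (code − mid)·step inverts to within step/2.

**Fidelities.** `full` (validation, ≤ 60 s) runs the chain in the 50 ksps
domain with the real CIC; `fast` (session-scale) applies an FIR emulation
of the compensated CIC magnitude at the master rate followed by polyphase
resampling. The two agree on band-limited tones within 1 dB and, after
removing the common group delay, within 2° of phase (tested).

## 3. Preprocessing and classifiers

Windows are 250 ms (the latency budget), non-overlapping by default — the
stride is not specified by the emulated protocol, and a conservative
default avoids silently inflating the deep nets' training data; it is
configurable down to 25 ms. Filtering (4th-order Butterworth high-pass,
20 Hz) is causal single-pass and applied per cycle before windowing, so
the pipeline is implementable in real time and no window straddles a cycle
boundary. Windows never straddle gesture segments.

Spectrograms: per channel, symmetric 100 ms Hann windows, 50 ms overlap,
one-sided magnitude (no log compression by default; a flag enables it),
arranged time-frames × channels × frequency-bins: 4×10×51 (wideband) and
4×8×11 (narrowband).

**H-TD + LDA.** Feature deadzone ε defaults to 0 V (none is specified in
the classical definitions); a one-quantization-step preset exists for
quantized inputs. LDA uses the pooled within-class covariance with ridge
λ·trace(Σ)/d·I, λ = 10⁻⁶ — the minimal intervention for near-singular
covariances at one training cycle (20 windows per class, 40–44 features);
ties break to the lowest class id.

**ConvNets.** Implemented on a compact numpy engine (im2col convolutions,
batch normalization, inverted dropout, max pooling, global average
pooling, Adam, manual backprop; float32). The raw net is five
Conv(3×11)×16 + BN + ReLU + dropout blocks on the single channels×samples
map with a GAP + linear 11-way head — 34,667 trainable parameters, the
same for both armbands because convolution parameter counts are
input-size independent. The spectrogram net treats the 4 time frames as
input maps and convolves channel × frequency planes: C1 Conv(3×3)×64,
P2 2×2, C3 Conv(3×3)×96, P4 2×2, C5 Conv(2×3)×64, GAP, linear head —
95,627 parameters on the 4×10×51 input. The narrowband input (4×8×11) is
too small for P4/C5, so its variant drops them; building the wrong
variant for an input size is a hard error. Both parameter counts gate the
build in tests.

**Training.** Adam at the modality's learning rate, annealed by 5 with
patience 5 on the validation loss of an internal stratified 90/10 split of
the training windows (the emulated protocol specifies the annealing
machinery but no validation protocol; the internal split is the least
additional structure), max 100 epochs, stop below lr/125. Batch 512 is
capped at the dataset size (one training cycle yields only ~220
non-overlapping windows). Single-threaded determinism per seed; run
averages use seeds seed_base+0..n_runs−1.

## 4. Evaluation

For each armband × classifier × k ∈ {1..4}: train on the first k training
cycles, test on all four test cycles; per-participant accuracy (deep
models: mean over runs first) is the pairing unit for a two-tailed
Wilcoxon signed-rank test across participants — the pairing is meaningful
because both armbands observed the same master signals. Zero differences
are dropped (Wilcoxon's original rule; the emulated analysis does not say)
and tied |differences| get mid-ranks; the null distribution is enumerated
exactly for n ≤ 25 without ties, else a continuity-corrected normal
approximation with tie-corrected variance is used (both branches agree to
< 0.01 at n = 22, tested). The last-cycle experiment reruns the grid with
only the fourth training cycle.

Run averaging defaults to 20 for the deep models in `EvalConfig`; the CLI
uses 5 and restores 20 under `--paper-scale`. The test suite exercises
the full 22-participant LDA grid; the deep-model grid is an offline run
(CLI) because it costs CPU-hours, while the deep contracts themselves
(checksums, overfitting capacity, determinism, annealing, gradient flow,
an end-to-end grid cell) are covered by fast unit tests.

## 5. What passing tests do and do not show

The generator reproduces the *structure* the comparison needs —
band-split spectra, spatial signatures, placement variability, ramp-ups,
a session shift — not the physiology of motor units, force modulation,
electrode-skin impedance drift (the warm-up effect), power-line
interference or motion artifacts. Passing the benchmark shows that the
pipeline correctly resolves acquisition-chain differences under a
controlled, favourable signal model; absolute accuracies and effect sizes
on real recordings will differ (the real-data gaps are a few percentage
points, not thirty). The published real-recording accuracy figures are
therefore deliberately out of scope for testing.

## 6. Numerical details

* Band-shaping filters are normalized empirically per segment (unit RMS),
  so amplitude contracts hold exactly in expectation.
* CIC filtering is realized as the equivalent N-fold boxcar FIR
  (`oaconvolve`), which is numerically stable where cascaded float
  integrators at 50 ksps are not; decimation keeps every R-th sample
  causally.
* Degenerate inputs raise: empty cycles, windows shorter than the STFT,
  classes with < 2 examples, singular covariances after ridge, unknown
  difficulty/profile/classifier names, full-fidelity segments > 60 s.
* Labels are decimated by nearest sample; a label run shorter than half a
  device sample period can vanish at 200 sps — protocol segments are 5 s,
  four orders of magnitude away from that limit.
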