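# armband-bench

A synthetic, fully reproducible benchmark of two surface-electromyography
(sEMG) armband acquisition chains for hand/wrist gesture recognition:

* a **wideband** armband: 10 channels, 1000 sps, 10-bit ENOB, 6 mVpp full
  scale, 20–500 Hz bandwidth realized by an oversampled ΔΣ converter
  (OSR 50) with a 4th-order CIC decimation filter and 2.2 µVrms
  input-referred noise;
* a **narrowband** consumer-style armband: 8 channels, 200 sps, 8-bit,
  ±1 mV full scale, ~5–100 Hz band.

It is aimed at researchers who want to study *how much acquisition
bandwidth, spatial resolution and quantization actually matter* for
myoelectric gesture classification, without collecting human data: both
simulated armbands sample the *same* synthetic muscle signals (the
simultaneous-wear design), so every difference in downstream accuracy is
attributable to the acquisition chain.

## What it simulates

**Recording protocol.** 22 virtual participants, 11 gestures held 5 s each
(ramp-up included in the label), 4 training cycles + 4 test cycles
(55 s per cycle, 220 s per session), variable armband placement/rotation
between participants and a re-seating shift between sessions.

**Signal model.** Each gesture is a mixture of band-shaped Gaussian
processes with a gesture-specific spatial activation profile around the
electrode ring and a gesture-specific split of power between a low
(20–100 Hz) and a high (100–450 Hz) band, `(w_low, w_high)`,
`w_low + w_high = 1`. Several gesture pairs differ mainly in the high
band — content the narrowband chain physically cannot see — which is the
mechanism under study.

**Classifiers.** Three standard pipelines on 250 ms windows after a causal
4th-order 20 Hz Butterworth high-pass:

1. **H-TD + LDA** — Hudgins' time-domain set (MAV, ZC, SSC, WL per
   channel) with a pooled-covariance linear discriminant;
2. **raw ConvNet** — 34,667 parameters, on channels × samples windows
   (10×250 / 8×50);
3. **spectrogram ConvNet** — 95,627 parameters, on time × channel ×
   frequency tensors (4×10×51 / 4×8×11) from 100 ms Hann / 50 ms overlap
   STFTs.

Deep training: Adam (lr 0.0404709 raw, 0.00681292 spectrogram), plateau
annealing (factor 5, patience 5), batch 512, dropout 0.5, averaged over
seeded runs. The statistics are per-participant accuracies compared with a
two-tailed Wilcoxon signed-rank test (exact for n ≤ 25).

## Worked example

```python
from armband_bench import generate_study, run_comparison, compare_profiles, EvalConfig

study = generate_study(n_participants=22, seed=1)       # ~1.5 min on CPU
result = run_comparison(study, classifiers=("lda",), config=EvalConfig(seed=1))

for profile in ("3dc", "myo"):
    print(profile, [round(result.mean_accuracy(profile, "lda", k), 3)
                    for k in (1, 2, 3, 4)])
for k in (2, 3, 4):
    print("k =", k, "Wilcoxon p =", compare_profiles(result, "lda", k).pvalue)
```

prints (seed 1):

```
3dc [0.788, 0.852, 0.873, 0.888]
myo [0.516, 0.55, 0.563, 0.567]
k = 2 Wilcoxon p = 4.2912648760483464e-05
k = 3 Wilcoxon p = 4.2912648760483464e-05
k = 4 Wilcoxon p = 4.296256238030105e-05
```

Read: with one cycle (5 s) of training data per gesture the wideband LDA
reaches 78.8% over 11 gestures, climbing to 88.8% with four cycles; the
narrowband chain plateaus near 57% because several gesture pairs differ
only above its band; the advantage is significant across the 22
participants at every training-set size. The same grid runs with
`classifiers=("raw", "spectrogram")` (hours on one CPU at full run
averaging; see the CLI's `--paper-scale` flag).

The command-line interface mirrors this:

```bash
armband-bench generate --participants 22 --seed 1 --out study/
armband-bench run --classifier lda --seed 1 --out results.json
armband-bench compare --results results.json
armband-bench report --results results.json --out figures/
```

## Layout

| Module | Role |
| --- | --- |
| `synthetic_semg` | gesture bank, participant models, master-signal synthesis |
| `device_frontend` | CIC decimation, quantization, noise, both armband profiles |
| `dataset_io` | `.emg16` + JSON sidecar persistence, study manifest |
| `preprocessing` | Butterworth high-pass, windowing, spectrogram tensors |
| `baseline_htd_lda` | H-TD features and pooled-covariance LDA |
| `deep_models` | numpy ConvNet engine, the two architectures, training loop |
| `evaluation_stats` | experiment grid, Wilcoxon statistics, reports |

See `docs/methods.md` for the model, its assumptions and known limits.
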