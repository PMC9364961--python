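# somnostage

Automatic five-stage sleep scoring of 30-s EEG + EOG epochs with a
parallel CNN-LSTM fusion network — together with everything needed to
exercise it without a polysomnography archive: a synthetic generator whose
stages follow the standard AASM rhythm descriptions, an imbalance-aware
subject-level training regimen, the PRE/REC/F1/ACC/MF1 evaluation suite,
and Hilbert-Huang (EMD + instantaneous frequency) analysis of sleep EEG.

**Who it is for.** Researchers prototyping sleep-staging pipelines who need
a fully reproducible, self-contained test bed; students of biomedical
signal processing who want a transparent (pure numpy, exact
backpropagation) reference implementation of a CNN-LSTM stager and of
empirical mode decomposition.

## The model

One epoch is a 300 × 2 matrix (30 s at the 10 Hz model rate; EEG, EOG in
µV). Two branches process it in parallel:

* an **LSTM branch** — two stacked 64-unit LSTM layers
  (`c_t = f_t ⊙ c_{t-1} + i_t ⊙ tanh(W_c x_t + U_c h_{t-1} + b_c)`,
  `h_t = o_t ⊙ tanh(c_t)`), the first returning its full 300 × 64
  sequence, the second its final 64-vector;
* a **CNN branch** — conv(64 @ 5, valid) → batch norm → ReLU →
  dropout 0.2 → max-pool(3) → conv(32 @ 5) → batch norm → ReLU → dropout →
  max-pool(3) → flatten, i.e. temporal lengths 300 → 296 → 98 → 94 → 31
  and flatten width 992.

The concatenated feature (992 + 64 = 1056) passes through fully connected
layers of 64 and 32 units (ReLU, dropout 0.5) to a five-way softmax over
{W, N1, N2, N3, REM}; the stage is the arg-max. Training is plain SGD on
cross-entropy with the step-decayed rate `0.015 × 0.1^⌊epoch/20⌋`, after
per-night class rebalancing (cap per night and stage, minority stages
oversampled, N2 undersampled) and strict by-subject train/test splitting.

See `docs/methods.md` for the full account, including the synthetic
generator and the EMD/Hilbert analysis.

## Worked example

```python
import numpy as np
import somnostage as ss

# 4 subjects x 1 night x 150 epochs of synthetic EEG/EOG, stage-labelled
records = ss.generate_dataset(4, 1, 150, fs_hz=100.0, seed=11)

plan = ss.SplitPlan(train_subjects=("S01", "S02", "S03"),
                    test_subjects=("S04",))
train_recs, test_recs = ss.split_by_subject(records, plan)
balanced = ss.resample(train_recs,
                       ss.ResamplePolicy(cap_per_stage_per_night=100),
                       np.random.default_rng(0))

model = ss.build_model(ss.ModelConfig(), seed=0)
schedule = ss.TrainSchedule(epochs=30, batch_size=128, lr_init=0.192, seed=0)
result = ss.train(model, balanced, schedule)

labels, _ = ss.predict(model, test_recs)
cm = ss.confusion([r.stage for r in test_recs], labels)
print(f"accuracy {ss.accuracy(cm):.3f}  macro-F1 {ss.macro_f1(cm):.3f}")
```

On one CPU this trains in a few minutes and prints

```
accuracy 0.940  macro-F1 0.923
```

meaning 94.0 % of the held-out subject's 150 epochs were scored with the
correct stage, and the unweighted mean of the five per-stage F1 scores is
0.923 (the macro average treats rare stages such as N1 the same as the
dominant N2). Exact numbers depend on the platform's BLAS only through
float32 rounding; a fixed seed reproduces the run bit-for-bit on one
machine.

The same pipeline is available from the shell:

```bash
somnostage simulate --subjects 4 --nights 1 --epochs 150 --seed 11 --out data/
somnostage run --config run.yaml
somnostage hht --in data/ --n-imfs 4 --bins 50 --out hht_out/
```

`simulate` writes standard EDF nights with plain-text hypnogram sidecars;
`hht` decomposes each stage's EEG into intrinsic mode functions and writes
per-stage probability-density histograms of their Hilbert instantaneous
frequencies.

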