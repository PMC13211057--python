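# eegdecoder

Subject-independent EEG classification of Alzheimer's disease (AD),
Creutzfeldt–Jakob disease (CJD) and healthy controls (CNTRL) from
19-channel, 10–20-montage clinical EEG, with a compact CNN–Transformer
classifier, a leakage-safe nested leave-one-subject-out (LOSO) evaluation
protocol, and edge-deployment footprint tooling.

## Who this is for

Researchers in clinical neurophysiology and biomedical signal modelling who
need a complete, reproducible pipeline from annotated raw EEG to
subject-level diagnostic metrics — and who want to audit every stage:
artifact excision, filtering, ICA ocular removal, epoching, normalization,
model, cross-validation, metrics, and deployment export. Because clinical
EEG cannot be redistributed, the package ships a synthetic cohort generator
that emulates the statistical structure of such a study (three balanced
classes, class-dependent spectral signatures, strong inter-subject
variability, annotated artifact segments), so the entire chain is testable
without any data download.

## The model

`EEGDecoder` classifies one 5-s trial X ∈ ℝ^{19×1280} (256 Hz):

1. **1-D CNN front end** — two stages of conv → batch-norm → ELU →
   max-pool(4), kernels 25 and 15, 64 output channels, *valid* padding.
   The time axis contracts 1280 → 1256 → 314 → 300 → 75, giving a 64×75
   feature map, permuted to a sequence Z ∈ ℝ^{75×64}.
2. **Transformer encoder** — 2 post-norm layers, 2 heads
   (d_model = 64, d_k = 32, feed-forward width 2048, dropout 0.1), with
   scaled dot-product attention
   Attention(Q,K,V) = softmax(QKᵀ/√d_k)V
   and sublayers combined as y = LayerNorm(x + F(x)). No positional
   encoding is used.
3. **Head** — temporal mean pooling p = (1/T′)Σ_t z_t ∈ ℝ^{64} followed by
   a linear 64→3 map to raw class scores.

The default model has **exactly 654,723 trainable parameters (654.7 K)**
and needs **≈ 2.0×10⁸ FLOPs per inference** (one multiply–accumulate
counted as 2 FLOPs, elementwise work counted once). An EEGNet-8,2 baseline
(F1 = 8, D = 2, F2 = 16, temporal kernel 64, dropout 0.25, max-norm 1.0 on
the depthwise spatial filters) is included under the identical protocol.

Evaluation is nested LOSO: every subject is held out once; the remaining
subjects are split into 5 subject-level, class-stratified inner folds;
per-channel z-scoring is fitted on inner-training trials only; Adam
(lr 10⁻³, weight decay 10⁻⁴, batches of 64, ≤ 30 epochs, patience-10 early
stopping on validation accuracy) trains one model per inner fold; the best
validation model is applied to the held-out subject, whose label is the
majority vote over its trials. Metrics are reported one-vs-rest at both the
trial and the subject level (accuracy, weighted precision/recall/F1,
Cohen's κ, both confusion matrices).

The networks are implemented directly in NumPy — layers with explicit
forward/backward passes (convolutions run via FFT for long signals),
verified against finite differences — so the package has no deep-learning
framework dependency.

## Worked example

```python
from eegdecoder import LOSOExperiment, PipelineConfig, TrainConfig, preprocess_cohort
from eegdecoder.synth import iter_cohort, small_cohort_spec, strong_effect_class_effects

# reduced strong-effect cohort: 3 subjects/class, 60 s recordings, 8 trials each
spec = small_cohort_spec(n_subjects_per_class=3, duration_s=60, master_seed=2025,
                         class_effects=strong_effect_class_effects())
cfg = PipelineConfig(apply_ica=False, trials_per_subject_cap=8)
trials = preprocess_cohort(((rec, ann) for _, rec, ann in iter_cohort(spec)), cfg)

exp = LOSOExperiment(trials, architecture="eegdecoder",
                     train_config=TrainConfig(max_epochs=6, early_stop_patience=6,
                                              batch_size=8))
res = exp.fit(seed=42)
print(res.summary())
```

prints (a few minutes on one CPU)

```
Leave-one-subject-out evaluation
============================================
architecture:        eegdecoder
trainable params:    654,723
subjects (folds):    9
trials:              72
train seed:          42
wall time:           477.6 s

metric                   trial level   subject level
----------------------------------------------------
accuracy (%)                  100.00          100.00
precision, wtd (%)            100.00          100.00
recall, wtd (%)               100.00          100.00
F1, wtd (%)                   100.00          100.00
Cohen kappa                    1.000           1.000

subject-level confusion (rows=true, cols=pred): AD/CJD/CNTRL
     3    0    0
     0    3    0
     0    0    3
```

i.e. every held-out subject (and every individual 5-s trial) is recovered;
the trial-level column shows performance before majority voting. Deployment tooling:

```python
from eegdecoder import export_portable, check_equivalence, profile_latency
from eegdecoder.model import build_eegdecoder

net = build_eegdecoder(seed=0)
export_portable(net, "model.npz")
print(check_equivalence(net, "model.npz", n=100))   # max |Δscore| < 1e-4
print(profile_latency(net, n_trials=40).to_dict())  # params, FLOPs, ms/trial
```

A `eegdecoder` console script exposes the same chain
(`simulate`, `preprocess`, `train-loso`, `report`, `export`, `verify`,
`profile`); run `eegdecoder --help`.

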