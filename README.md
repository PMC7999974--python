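# plvsleep

Phase-locking-value (PLV) functional connectivity analysis of sleep EEG,
with frequency-band evaluation and band-fusion sleep staging.

Sleep stages (REM, N2, N3) differ not only in local spectral content but
in how brain regions synchronize with each other. `plvsleep` implements
a complete connectivity-based staging pipeline for multichannel
polysomnography EEG:

1. **Preprocessing** — hypnogram curation (dropping too-short stage runs,
   brief wake intrusions with their flanking epochs, and the first/last
   epoch of every run), common average reference, zero-phase 0.5–40 Hz
   band-pass, non-overlapping 30 s segmentation, and a six-band filter
   bank: delta (0.5–4 Hz), theta (4–8), alpha (8–13), beta1 (13–22),
   beta2 (22–30), gamma (30–40 Hz).
2. **Connectivity** — per epoch and band, the PLV between channels *a*
   and *b*:

   PLV = | (1/T) Σₜ exp( i(ϕₐ(t) − ϕᵦ(t)) ) |  ∈ [0, 1],

   with instantaneous phase ϕ(t) from the analytic (Hilbert) signal.
   For 12 channels this gives a symmetric 12×12 matrix per epoch (66
   distinct channel pairs). Stage-average matrices are thresholded into
   binary brain networks at the largest threshold leaving no isolated
   node (τ = minᵢ maxⱼ wᵢⱼ), compared between stages via signed
   difference matrices and one-way ANOVA.
3. **Band evaluation** — every (class pair, band, channel pair) feature
   is scored with the squared point-biserial correlation
   r² = [√(N⁺N⁻)/(N⁺+N⁻) · (mean X⁺ − mean X⁻)/std(X⁺∪X⁻)]²,
   equal to the squared Pearson correlation with the binary class label.
   The 3×6×66 scores are ranked globally; summaries include top-*k* band
   percentages and per-class-pair discriminative ratios (top-*t* r² mass
   per band, *t* = 36).
4. **Classification** — RBF-kernel SVM (one-against-one multiclass,
   stratified 75/25 split) on single-band features and three fusion
   strategies: feature-level concatenation (`C`), decision-level
   stacking with out-of-fold meta-features (`E`), and hybrid fusion of
   band pairs (`E(C)`).

Because real polysomnography is bulky, the package ships a first-class
**synthetic generator**: 12-channel, 30 s epochs in which each band's
channels share a narrowband carrier with per-channel wrapped-normal
phase jitter σ, giving an analytically known pairwise PLV target
exp(−σ²/2). Stage-dependent jitter plants the qualitative NREM pattern
(PLV rises from N2 to N3 in delta/alpha, falls in beta2/gamma), so every
stage of the pipeline is testable end to end against closed forms.

## Worked example

```python
from plvsleep.pipeline import PipelineConfig, run_pipeline
from plvsleep.synthetic import GeneratorConfig

summary = run_pipeline(
    PipelineConfig(
        synthetic_config=GeneratorConfig(
            epochs_per_stage=20, sampling_rate=128.0, seed=1),
        seed=1),
    "artifacts")

print({k: round(v, 2) for k, v in summary["top_k_band_percentage"]["95"].items()})
print([(r["strategy"], r["bands"], round(r["accuracy"], 2))
       for r in summary["classification"][:3]])
```

Output:

```
{'delta': 62.11, 'theta': 0.0, 'alpha': 37.89, 'beta1': 0.0, 'beta2': 0.0, 'gamma': 0.0}
[('single', 'delta', 100.0), ('single', 'theta', 86.67), ('single', 'alpha', 93.33)]
```

With the default planted contrasts, the largest stage differences sit in
delta and alpha, so those bands dominate the top-95 r² ranking (62% and
38%) and delta alone classifies the 60-epoch synthetic night perfectly;
bands with weak planted contrast (beta1) stay near chance. The artifact
directory holds the per-band feature tables, the full r² ranking,
stage-mean/difference matrices, no-isolate thresholds (e.g. τ = 0.63 for
the delta N3 network, matching its planted mean PLV), ANOVA table and the
classification report, all as delimited text plus a JSON summary carrying
the config hash and seed. The same pipeline runs on real EDF recordings
with plain-text stage annotations via `PipelineConfig(edf_paths=...,
annotation_paths=...)` or the `plvsleep` CLI (`synth`, `preprocess`,
`connectivity`, `evaluate-bands`, `classify`, `run`).

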