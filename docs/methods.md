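# Methods

## Phase-locking value

Connectivity is measured per 30 s epoch, per frequency band, as the
phase-locking value between channel pairs:

PLV = | (1/T) Σₜ exp(i Δϕ(t)) |,

where Δϕ(t) is the instantaneous phase difference over the T samples of
one epoch and phase is the angle of the analytic (Hilbert) signal of the
narrowband epoch. PLV is amplitude-invariant, equals 1 for any constant
phase lag, and for T iid uniform phase differences has the Rayleigh null
mean √(π/(4T)) (≈ 0.0071 at 512 Hz × 30 s = 15360 samples). Averaging
runs over time within an epoch, yielding one matrix per epoch — the
representation the per-epoch classification features require. The first
and last 0.5 s of each epoch (configurable) are excluded from the
average to suppress Hilbert edge artifacts.

## Preprocessing and hypnogram curation

Recordings are common-average referenced, band-passed 0.5–40 Hz, and
split into the six canonical bands with zero-phase forward–backward
Butterworth filters (order 4 per pass). Zero-phase filtering is a hard
requirement: any causal filter would add frequency-dependent phase and
bias PLV. CAR precedes filtering (the order is a package choice; both
operations are linear, so only edge effects differ).

Stage labels are curated with three deletion rules before segmentation:

1. stage runs shorter than `min_run_epochs` (default 6 epochs = 3 min)
   are dropped — transitions are gradual and short runs are unreliable;
2. wake runs of at most `intrusion_max_epochs` (default 2) flanked by
   non-wake sleep on both sides are dropped together with one epoch on
   each side;
3. the first and last epoch of every surviving run are trimmed.

Rules 1 and 2 are evaluated on the original run structure and their
deletions combined; fragments created by intrusion removal are
re-checked against the run-length minimum before trimming. This makes
the rule set well defined when a brief intrusion splits a run that rule
1 would otherwise have seen whole. Only REM, N2 and N3 epochs are
analyzed; N1 and wake are discarded (N1 is transitional and rare, wake
is not sleep). Independent-component artifact removal is out of scope; a
peak-amplitude epoch-rejection hook (disabled by default) stands in for
gross artifact rejection.

Both thresholds are configurable because the underlying notions ("too
short", "brief intrusion") are only exemplified, not fixed, in standard
practice.

## Synthetic generator

The generator produces stage-labeled epochs whose band-wise PLV is
analytically known, which is what makes the pipeline testable without a
polysomnography download.

* **Carrier**: per band, band-pass filtered Gaussian noise converted to
  its analytic signal and normalized to unit RMS. Filtered noise rather
  than a pure tone keeps the instantaneous phase non-trivial and the
  spectrum EEG-like. Carrier passband edges are inset by 10% of the
  bandwidth so carrier power does not sit on the analysis filter's
  half-power edge, where adjacent bands would cross-talk and bias the
  measured PLV below its target.
* **Coupling**: every channel receives the band carrier rotated by its
  own Gaussian phase jitter with per-sample wrapped-normal marginal
  σ_ch. The PLV of a wrapped-normal phase error is exp(−σ²/2) (the
  characteristic-function modulus), so a channel pair has target
  exp(−(σᵢ²+σⱼ²)/2). Pairwise targets are specified as a scalar or a
  full pair matrix; channel σ are recovered by non-negative least
  squares on σᵢ²+σⱼ² (exact for consistent matrices, e.g. uniform σ
  with σ_ch = σ/√2). σ = ∞ yields an independent carrier (uncoupled).
  The calibration convention checked throughout is **pairwise**: a
  uniform pair σ is compared against exp(−σ²/2).
* **Jitter smoothness**: the jitter is low-pass filtered noise (default
  cutoff 1 Hz) rescaled to marginal σ, not per-sample white noise. A
  white phase process would widen the signal spectrum, and the
  Hilbert-extracted phase would under-read the planted jitter (measured
  bias up to ≈ 0.03); with slowly varying jitter the signal stays
  narrowband and the measured PLV tracks exp(−σ²/2) to better than 0.01
  across σ ∈ [0, 1.5]. The marginal distribution, and hence the
  closed-form target, is unchanged.
* **Seeding**: a master seed spawns per-epoch child seeds through
  `numpy.random.SeedSequence`; identical configs give bit-identical
  datasets.

Default stage contrasts plant pairwise PLV targets of
(REM, N2, N3) = (0.45, 0.50, 0.65) in delta, (0.42, 0.45, 0.60) in
alpha, (0.25, 0.30, 0.22) in beta2 and (0.18, 0.25, 0.15) in gamma, with
theta (≈ 0.38) and beta1 (≈ 0.31) nearly flat — i.e. PLV rising from N2
to N3 in the low bands, falling in the high bands, decreasing overall
with frequency but with alpha above theta. The magnitudes are package
choices: the qualitative ordering is the modeled phenomenon; no
published effect sizes exist for these contrasts at the pairwise-PLV
level. Two further coupling designs support specific experiments:
`single_band_contrast_coupling` (contrast in one band only, for
planted-band recovery) and `complementary_coupling` (each of delta/
alpha/beta1 singles out a different stage, so no single band separates
all three classes but fused bands do).

What the generator does **not** emulate: realistic sleep microstructure
(spindles, K-complexes, slow-wave morphology), 1/f spectral slopes,
artifacts, volume conduction, or electrode geometry. Passing tests
therefore demonstrate correctness of the analysis chain and its
statistical behavior under known ground truth — not staging performance
on real polysomnography, whose headline accuracies depend on the actual
recordings and their manual curation.

## Band evaluation

The discriminability score is the squared point-biserial correlation,
computed with the **population** pooled standard deviation so perfect
separation scores exactly 1; it is algebraically identical to the
squared Pearson correlation between the feature and a 0/1 class
indicator, which the tests assert to 1e−12. (The printed form of this
coefficient in the source literature has a prefactor that would cancel
between numerator and denominator and unbound the score, contradicting
its own [0, 1] range; the standard point-biserial form is used.)
Rankings use deterministic tie-breaks: r² descending, then canonical
band order, then channel-pair index. Top-k percentages pool the three
class pairs; discriminative ratios are computed per class pair
(configurable).

## Classification

RBF-kernel SVM with C = 1 and scikit-learn's `gamma="scale"`
(1/(n_features · feature variance)); features are standardized with
train-split statistics only. The multiclass decomposition is libsvm's
one-against-one. The 75/25 split is stratified and seeded. Stacking
(`E`) trains one base SVM per band and an RBF-SVM meta classifier on
out-of-fold (5-fold) per-class decision scores of the training split —
scores rather than hard labels, as is standard for stacking — so the
test split is never touched before final evaluation. Hybrid fusion
(`E(C)`) concatenates features within fixed band pairs (default
delta+beta1, theta+gamma, alpha+beta2) and stacks across the pair
classifiers.

## Numerical choices and problem sizes

* Butterworth order 4 per pass everywhere; band edges validated against
  Nyquist.
* No-isolate threshold keeps edges with w ≥ τ, making τ itself
  attainable; τ = minᵢ maxⱼ≠ᵢ wᵢⱼ is proved equal to the brute-force
  scan in tests.
* ANOVA operates on per-epoch means over the 66 channel pairs; all-equal
  degenerate input returns (F, p) = (0, 1).
* Synthetic test runs use 12 channels at 128 Hz with 20–67 epochs per
  stage, chosen so statistical margins (binomial SE over 20 seeds,
  calibration tolerance 0.05) remain wide while the whole suite stays
  desk-scale; generator defaults keep 512 Hz.
* EDF export writes plain 16-bit EDF with 1 s records and per-channel
  physical scaling; round-trip error is bounded by the quantization
  step.

## Known limitations

* Eq.-level ambiguity in the literature about whether PLV averages over
  time within an epoch or across epochs at fixed time is resolved here
  as within-epoch (required for per-epoch features); the alternative
  reading is not implemented.
* The generator's pair-matrix coupling can only realize pairwise σ
  structures expressible as σᵢ²+σⱼ² (shared-carrier model); arbitrary
  pair matrices are approximated in least squares.
* Inter-subject variability is not modeled; "intra-" vs "inter-subject"
  evaluation differ only in which samples are pooled.
* Stacking accuracy on very small test splits is noisy; chance-level
  checks therefore average 20 seeds.
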