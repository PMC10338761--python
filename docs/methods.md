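# Methods

This note documents the models, numerical choices and design decisions
behind `fcreeg`, and what the synthetic experiments do and do not show.

## Phase lag index

For two signals with instantaneous phases φ₁(t), φ₂(t) (from the analytic
signal via the Hilbert transform), the phase lag index is

    PLI = | (1/T) Σ_t sgn( wrap(φ₁(t) − φ₂(t)) ) |,

with the difference wrapped into (−π, π] and sgn(0) = 0. It is the
absolute asymmetry of the phase-difference distribution around zero:
PLI = 0 when phase differences are symmetric about zero (no coupling, or
pure zero-lag mixtures as produced by volume conduction), PLI = 1 when
the sign of the lag is the same at every sample. The sgn(0) = 0
convention makes identical signals — and amplitude-scaled copies —
give exactly 0. This formulation is equivalent to |mean(sgn(sin Δφ))|
and is the only reading of the index consistent with its [0, 1] range;
an unwrapped raw difference would not be bounded.

Numerical choices:

- **Zero-lag tolerance.** Wrapped differences below 1e-9 rad count as
  sgn(0) ties. Amplitude-scaled copies of a signal acquire phase
  differences of order 1e-16 rad from floating-point rounding; without
  the tolerance those rounding signs average to ≈ 0.05 rather than 0.
  Genuine phase differences essentially never fall in this band, so the
  estimator is unchanged elsewhere.
- **Degenerate input.** A constant (zero-variance) channel has no defined
  phase; `instantaneous_phase` and `connectivity_matrix` raise, naming
  the offending channel.
- **No edge trimming.** Hilbert end effects are left in by default (they
  are small at T = 1280 and identical across pairs).
- The vectorized 16×16 matrix path computes only the upper triangle and
  mirrors it, and is tested against a literal loop implementation to
  1e-12.

## Segmentation and filtering

Recordings are cut into contiguous, non-overlapping windows of
`window_s` seconds (default 10 s; a 60 s recording at 128 Hz gives 6
multi-channel epochs = 96 single-channel segments; both counters are
exposed by `count_segments`). Trailing samples that do not fill a window
are discarded; recordings shorter than one window yield an empty list
with a warning so cohort loops continue.

Bands: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45,
broadband 0.5–45 Hz. The gamma band is conventionally open-ended
(">30 Hz"); it is implemented as 30–45 Hz to match the broadband ceiling
and stay clear of the 64 Hz Nyquist limit — configurable via `BandSpec`.

The filter is a 4th-order Butterworth band-pass applied
forward-backward (`sosfiltfilt`), i.e. zero-phase: PLI rests entirely on
phase relationships, and zero-phase filtering is the standard way to
band-limit EEG without shifting them. The zero-phase design response is
≥ 40 dB down one octave outside each band edge (measured ≥ 55 dB).
Filtering is applied per epoch after segmentation by default; note that
for bands with a very low edge (delta's 0.5 Hz) the filter's start-up
transient then occupies a visible fraction of a 10 s window, so the
*realized* attenuation of out-of-band tones inside one epoch is
transient-limited (~37 dB) rather than stopband-limited. The
`bandpass_recording` path (filter the continuous recording, then
segment) avoids this (~126 dB on a central epoch) and is the recommended
order for delta-band work.

## FCR rendering

A connectivity matrix becomes an image by upsampling the 16×16 values to
342×342 (bicubic by default), clipping to [0, 1], and mapping through a
fixed colormap (viridis) with a **fixed** [0, 1] value range — never
per-image normalization, which would erase exactly the between-class
intensity differences the classifier needs. The image is then resized
bilinearly to 224×224. Rendering is deterministic: identical matrices
produce byte-identical PNGs. Only the data area is rendered (no axes or
colorbar).

Bicubic interpolation is sharper but has negative lobes, so it is not
order-preserving; the `interpolation="bilinear"` option is, and is the
mode under which the monotonicity property (m₁ ≤ m₂ elementwise ⇒
upsampled field ≤ pointwise) is guaranteed and tested.

## Networks and training

`fcreeg.nn` is a compact NumPy CNN engine — im2col convolution, batch
normalization, max/global-average pooling, residual blocks with
projection shortcuts, Adam, explicit backprop (verified against central
differences). On top of it:

- **ResNet-18** (basic blocks ×[2,2,2,2]), **ResNet-50** (bottlenecks
  ×[3,4,6,3]) and **ResNet-101** (×[3,4,23,3]), each with the standard
  7×7/2 stem, 3×3/2 max pool, global average pooling and a 2-class
  softmax head. Trainable parameters: ≈ 11.2 M, 23.5 M and 42.5 M.
- **TinyCNN**, a two-stage conv-BN-ReLU network for CPU-scale
  experiments. Its head flattens the feature map instead of averaging
  it: the FCR class signal is positional (specific matrix cells), and
  global pooling in so shallow a network erases it.

Training protocol (defaults of `TrainConfig`): Adam, initial learning
rate 0.001 multiplied by 0.4 every 4 epochs ("decreased by 0.4" is read
as a multiplicative step — subtraction from 0.001 would go negative on
the first step), mini-batch 32, at most 15 epochs, early stopping on
validation loss with patience 3 and best-weights restore. Images are
scaled to [0, 1] and standardized per channel by the **training part's**
mean/SD only. Weight initialization is He-normal from a fixed seed; no
ImageNet pretraining (the architectures, not pretrained weights, are the
reference).

## Cross-validation

Subjects are dealt into five class-stratified parts (shuffled
deterministically per seed, round-robin within class); all epochs of a
subject stay in its part. Fold f uses part f as test, part f+1 (mod 5)
as validation and the remaining three as training — the 0.6/0.2/0.2
split with every part serving as test exactly once. Disjointness of the
three roles' subject sets is asserted on every fold.

With the reference cohort (45 SZ / 39 HC subjects, 6 images each) every
test fold holds exactly 54 SZ images; HC parts hold 42 or 48. A
subject-pure split of 39 subjects × 6 epochs can only produce multiples
of six — HC fold sizes such as 46/47 are possible only by splitting some
subject's epochs across parts, which this package never does (identity
leakage inflates EEG classification estimates).

Metrics treat SZ as the positive class: accuracy (TP+TN)/total,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
F1 the harmonic mean of precision and recall, all as percentages.
Undefined rates (zero denominators) become NaN with a warning, not an
exception. Accuracy is checked on every evaluation against its identity
as the prevalence-weighted mix of sensitivity and specificity.

## Group statistics

For each of the 120 unordered channel pairs, a classical one-way ANOVA
(df = 1, n_SZ + n_HC − 2; equivalent to the squared pooled-variance t)
compares the groups' PLI values. Two raw-p tiers are reported —
0.001 ≤ p < 0.05 ("tier1") and p < 0.001 ("tier2") — with no
multiple-testing correction by default (Bonferroni and Benjamini-
Hochberg are available but off, mirroring the two-tier raw-p reporting
convention). The default unit of analysis is the epoch; epoch-level
samples from one subject are correlated, which inflates effective
significance — the `per_subject=True` option averages within subject
first and is the conservative alternative. The connectogram draws
electrodes at schematic 10-20 positions with edges for pairs at the
requested tier, colored by pooled mean strength; it is a diagnostic
plot, not an anatomical rendering.

## Synthetic cohorts

Each channel is a sum of narrowband oscillators with band-limited
Gaussian phase noise: one private oscillator per channel and one shared
oscillator per coupled pair, each at a distinct carrier inside the
band (beta components sit on a grid spanning ≈14–28 Hz). The members of
a coupled pair carry the shared component with phase offsets +lag/2 and
−lag/2 (default lag π/4).

The central design constraint is **locality of the class effect**: the
patient-like class must differ from the control class only at the
designed pairs. Any class difference in a channel's marginal signal —
amplitudes, jitter magnitude — changes that channel's phase-velocity
statistics and thereby the finite-sample PLI of *every* pair it belongs
to (this was measured, not hypothesized: amplitude- and jitter-based
class effects flagged 15–30 undesigned pairs at p < 0.001).
The generator therefore keeps all component amplitudes and all jitter
*marginals* identical across classes and encodes coupling strength c
purely in the **correlation** ρ between the two copies' jitter
processes: the phase-difference SD is √(2(1−ρ))·σ, and ρ is chosen so
the shared components alone would have PLI = c
(PLI = 2Φ(lag/(√(2(1−ρ))σ)) − 1, with σ fixed per pair at the weaker
class's ρ = 0 point and capped at 2.5 rad). Each channel's marginal law
is then identical in distribution across classes and leakage is ruled
out by construction; measured undesigned tier2 counts are 0–1 per
cohort. Cross-talk from a channel's other components lowers the realized
pair PLI below c but keeps it monotone in c (tested over three effect
sizes).

Default study conditions (chosen once): 45 SZ / 39 HC subjects, 128 Hz,
60 s; designed deficit Δc = 0.3 from c = 0.7 on five
parietal↔central/occipital/temporal pairs (Pz–Cz, P3–O1, P4–O2, P3–T5,
P4–C4), with the control class higher — the direction reported for
schizophrenia; five neutral pairs at c = 0.5 in both classes give both
groups common structure; private-oscillator jitter SD 0.4 rad; additive
white noise at 0.3 of signal SD; optional zero-lag mixing (row-
normalized leakage matrix) emulating volume conduction, and an optional
1/f background. Subject s is generated from seed + s, so cohorts are
fully reproducible from (config, seed).

What the generator does *not* emulate: 1/f broadband spectra (unless the
pink background is enabled), non-stationarity, artifacts, inter-subject
anatomical variability, or realistic scalp mixing. Passing tests on
synthetic cohorts therefore validate the *pipeline* — phase extraction,
the PLI estimator, rendering, leakage-free cross-validation, the
statistics — not clinical classification performance on real EEG.

### Finite-sample PLI noise and the volume-conduction check

At T = 1280 the PLI of a genuinely uncoupled pair is a noisy magnitude
with expectation well above zero (it is the absolute value of a mean of
±1 signs with a long correlation time for narrowband signals). The
maximum over 120 pairs of single-epoch estimates reaches ≈ 0.1 with
*no* mixing at all, so a per-epoch max cannot detect leakage. The
volume-conduction honesty check therefore averages each pair's PLI over
the recording's six epochs (noise shrinks, genuine mixing-induced
coupling would persist); under strong zero-lag mixing the largest
pair average stays below 0.1 (measured 0.074).

## Desk-scale problem sizes

Tests and the acceptance script size their experiments for a laptop-class
CPU: parameter-recovery experiments use 12 + 12 subject cohorts (ANOVA
recovery and five-fold classification with TinyCNN on 32×32 inputs);
bookkeeping checks generate the full 84-subject reference geometry;
effect-size and null-rate simulations use 6 + 6 subjects and 200
replicate draws respectively. The full residual networks are exercised
for construction, forward pass, parameter counts and gradient
correctness; full ResNet training runs belong on accelerated hardware
and are out of the test suite's scope.

## Known limitations

- The NumPy engine is single-threaded matmul-bound; ResNet-50/101
  training at realistic dataset sizes is impractically slow on CPU.
- EDF support is read-only (no EDF writer).
- Epoch-level ANOVA ignores within-subject correlation (see
  `per_subject`).
- The connectogram is schematic; no source-space or anatomically
  accurate rendering.
- Coupling strengths below ≈ 0.18 are not reachable for *coupled* pairs
  at the default π/4 lag (the jitter ceiling); uncoupled pairs are
  simply omitted from the graph.
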