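# Methods

This note documents the models, conventions and numerical choices behind
`mcgkle`: what each stage computes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where genuinely open design
choices were settled.

## Averaged-map format and γ-normalization

All analysis operates on the common averaged-map format: `B` with 36
positions × 1,000 samples at 1,000 Hz, R peak at printed sample 333
(0-based index 332 internally). At every file boundary, segment cursors
are expressed in milliseconds relative to the R peak; sample indices are
an internal convention only. This avoids off-by-one ambiguity between the
two conventions.

Beat averaging aligns windows of 333 samples up to and including R plus
667 after it; beats whose window crosses a recording edge are dropped
with a logged count, never zero-padded. Input at other sampling rates
(e.g. 500 Hz) is linearly interpolated onto the 1,000 Hz grid first —
the simplest reproducible choice; band-limited resampling would be a
defensible alternative but is not implemented. Optional baseline
correction (on by default) subtracts the per-channel mean over the first
100 samples of the map, a pre-QRS quiet zone; the window length is a
package choice, as no canonical value exists.

The normalization factor γ is the mean absolute field over the **closed**
QRS interval `[onset, end]` across all 36 positions, with
`t_QRS = end − onset + 1` samples. The closed-interval convention (both
boundary samples included) is asserted by a worked toy example in the
tests so it is auditable. Normalization divides the entire map by γ; it
is idempotent and invariant to any positive rescaling of the input.
`t_QRS` is counted in samples; at 1,000 Hz samples and milliseconds
coincide, and segments are extracted before any further resampling, so
the distinction never leaks into results.

## Segment windows

Two variants, reflecting the two analysis configurations:

* **fixed** — 80 samples from QRS onset, 250 from STT onset, pure slices;
* **resampled** — the full cursor-to-cursor segment mapped by linear
  interpolation onto 20 (QRS) / 40 (STT) equispaced points including both
  endpoints. Cubic interpolation is available behind a flag but never the
  default.

Segment cursors are required inputs (ground truth for synthetic data,
sidecar metadata for imported data); no wave-boundary detection is
attempted. The inter-sample correlation of the KLE features across
subjects is reported as a diagnostic with a warning threshold of 0.2 —
the sample counts 20/40 are fixed constants of the published
configuration, not re-selected at run time. The correlation is evaluated
on the KLE features (the discriminant inputs, where the assumption
matters) rather than on raw field values; judging it on raw values would
be the other defensible reading of such a threshold.

## KLE features

At each time point within a segment, a map column (36 signed field
values) becomes a probability distribution by ε-smoothed absolute-value
normalization:

    pᵢ = (|bᵢ| + ε) / Σⱼ (|bⱼ| + ε),  ε = 10⁻⁶ · maxⱼ |bⱼ|.

Tying ε to the column maximum keeps the conversion invariant under global
rescaling; 10⁻⁶ is small enough not to disturb the topology and large
enough to keep the logarithms finite. Absolute values preserve the
two-pole structure of a dipolar map, which is the discriminative signal;
`square` and `minshift` conversions are provided as alternatives
(results should state the strategy used), since no canonical conversion
from signed fields to distributions exists. An all-zero column is a hard
error, not silently smoothed.

The divergence KL(P,Q) = Σ Pᵢ ln(Pᵢ/Qᵢ) uses the natural logarithm, so
features are in nats. One feature per time point is produced (20 QRS, 40
STT, 60 joint) rather than one pooled value per segment — this is what
makes the feature-count and decorrelation statements meaningful. KL is
asymmetric and not a metric; absolute values are only meaningful relative
to a fixed reference.

The reference map Q is the element-wise mean of the reference group's
segment maps, tagged with the subject ids it was built from so leakage is
checkable.

## Classification

Two-class Fisher LDA with equal priors: pooled within-class covariance
S (ridge-stabilized as S + λ·tr(S)/p·I, default λ = 10⁻³), weights
w ∝ S⁻¹(μ₁ − μ₀), threshold at the midpoint of the projected class
means. The ridge default guards folds with more features than training
subjects; priors, regularization and threshold conventions are package
choices, stated here because reported accuracies depend on them.

LOOCV is strict: for every fold the healthy reference map is recomputed
from the training-fold healthy subjects only, all training features are
recomputed against it, and the held-out subject's features are evaluated
against the same fold reference. A sentinel-perturbation test verifies
the held-out subject cannot influence the fold's trained model even at
the bit level. Whether a reference should exclude the held-out subject is
genuinely ambiguous in practice; the strict choice is the defensible one
and can only make reported accuracies conservative.

PCA (for cluster visualization) is the eigen-decomposition of the
mean-centred covariance; each component's largest-magnitude loading is
made positive so projections are reproducible.

Mann–Whitney U tests (heart rate, segment lengths) use the exact null
distribution when both groups have ≤ 20 observations and the combined
sample is tie-free, otherwise the normal approximation with continuity
and tie correction — a fixed rule, so p-values are bit-reproducible.

## Synthetic cohorts

The generator stands in for non-deposited patient data. It emulates the
statistical structure the analysis depends on, not cardiac biophysics:

* **Forward model.** A single equivalent point dipole; the field
  component perpendicular to a planar 6×6 grid (20 cm side, 10 cm above
  the source) via the free-space dipole equation. No volume conductor, no
  lead fields, no inverse problem. Field units are arbitrary
  (γ-normalization removes scale); the canonical beat peaks near 10
  units so the default noise has a meaningful scale.
* **Beat.** Distinct QRS (fast rotation of a large moment, sweep ≈ 2.5
  rad) and STT (slow drift of a smaller moment at a different angle)
  phases; the P wave is omitted as it is never analyzed. Wave envelopes
  are raised sines with a 2% plateau so cursor samples never carry an
  exactly-zero field, as in measured data.
* **Healthy group.** Per-subject i.i.d. jitter (scale `healthy_jitter`,
  default 0.05) on angles, amplitudes and dipole position, plus
  per-subject QRS/STT lengths (90 ± 8 ms, 300 ± 25 ms, identical between
  groups) and heart rate (70 ± 5 bpm) — so segment-length distributions
  overlap and heart rate is not a confound.
* **Pathology mechanism.** Within the STT interval only (configurable to
  QRS): one dipole rotation whose angle grows proportionally with
  `effect_size` (bounded away from zero, so every patient deviates) about
  an axis scattered around a disease-typical axis (so every patient
  deviates differently), plus a disease-directed dipole displacement and
  a subject-specific repolarization timing warp. `pathology_scatter`
  scales all subject-specific components: 0 collapses the group onto one
  coherent distorted topology (the separable limit used in tests), 1 is
  the default heterogeneity. With `effect_size = 0` the groups are
  exchangeable by construction — pathology subjects draw their extra
  random numbers but apply them scaled by zero, so the same per-subject
  seed yields the identical beat.
* **Noise and beats.** `n_beats` template repetitions at jittered R-R
  intervals plus i.i.d. Gaussian sensor noise (`beat_noise_sd`, default
  6.0 ≈ 60% of the QRS peak). The default is deliberately noisy: after
  averaging 30 beats the residual noise dominates healthy inter-subject
  feature variation, which reproduces two empirical properties of this
  kind of data at once — weakly correlated within-segment features, and
  near-chance classification when the reference map is built from the
  heterogeneous pathology group.
* **Determinism.** One master seed; per-subject seeds derive from a
  stable hash of (seed, subject id), so cohorts are extensible without
  reshuffling existing subjects.

Known limitations: a single dipole cannot produce multipolar map
topologies; rotations approaching π are partially invisible to the
absolute-value distribution (a flipped dipole has the same |B| map), so
effect sizes are meaningful roughly up to ~1.3 with the default angle
range; no hardware effects (filter ringing, gradiometer geometry) are
modelled beyond white sensor noise. Passing tests on these cohorts show
the pipeline's statistical machinery behaves correctly under the assumed
group structure — they cannot certify performance on real patients.

## Study-level analyses and problem sizes

The headline analysis mimics the larger cohort's group sizes (57 healthy,
40 pathology, 30 beats per subject). The working effect size is chosen by
a pilot grid (0.35, 0.70, 1.05): pilot cohorts at each grid value are
cross-validated and the best-performing value wins (ties to the smaller
effect); the pilot cohorts are then discarded and fresh evaluation
cohorts generated. The grid's top point sits below the rotation-wrap
regime noted above.

Null calibration uses 100 replicate cohorts of 30 + 30 subjects at
`effect_size = 0` with 8 beats per subject — a deliberately small
per-subject problem size, since the null behaviour under test (chance
LOOCV accuracy, nominal heart-rate test size) does not depend on the
averaging depth.

## Error handling conventions

Degenerate inputs fail loudly with the offending stage, subject or time
point named: fewer than two usable beats, zero γ, all-zero map columns,
single-class training folds, zero-denominator metrics (reported as NaN
with a warning, never silently 0). All file writes are atomic
(write-temp-then-rename), artefacts embed the configuration fingerprint,
and loading an artefact under a mismatched configuration is an error.
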