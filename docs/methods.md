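# Methods

## Overview

`gaitkit` implements a markerless gait-assessment pipeline for sagittal-plane
walking recorded with a monocular camera.  The input is what a 3D human pose
estimator emits: per-frame 3D positions for eight joints (shoulders, hips,
knees, ankles) with a per-joint visibility score in [0, 1].  The pipeline
converts keypoints into knee/hip angle signals, repairs and denoises them,
summarises them as discrete gait parameters, and scores a subject's gait
against a normal cohort with the Hotelling T² statistic.

## Joint-angle signals

The knee angle at frame *t* is the angle at the knee between the knee→hip
and knee→ankle vectors, via the cosine law with the argument clamped to
[−1, 1].  The hip angle is measured between the thigh (hip→knee) and a
*virtual forward vector*: the left→right shoulder line rotated 90° about the
configured vertical axis.  A trunk-referenced hip angle would saturate at
180° and reflect whenever shoulder, hip and knee align, corrupting later
filtering; the forward-vector construction avoids that fold.

Two conventions are left open by the geometry and fixed here:

* **Handedness.**  The 90° rotation follows the right-hand rule about the
  vertical axis; if the resulting direction opposes the subject's net hip
  displacement over the clip, it is flipped.  The walking direction itself
  disambiguates the convention, so no extra configuration is needed.
* **Signal visibility.**  An angle built from several joints inherits the
  *minimum* of their visibilities: the least reliable joint governs the
  angle's reliability.

Signals are labelled **near**/**far** (camera side) rather than left/right:
the far side suffers occlusion and is systematically noisier.  The side
whose lower-limb joints have the greater mean visibility over the clip is
"near"; exact ties fall back to mean position along an optional camera
depth axis, then to left.

## Kalman filtering with missing-measurement substitution

Each angle signal is filtered by a constant-acceleration Kalman filter with
state (θ, v, a) in degrees, °/s, °/s², transition

    A = [[1, Δt, Δt²/2], [0, 1, Δt], [0, 0, 1]],  Δt = 1/fps seconds,

process noise Q = α·I₃ and scalar measurement noise R = β (the observed
quantity is the single angle, H = [1 0 0], so the innovation is 1×1).
Frames whose visibility falls below the threshold VT are treated as missing
and a substitute measurement is fed to the update:

* **KF1** substitutes the prior estimate θ̂_{t|t−1}.  The innovation is then
  zero and the filter free-runs on the linear kinematic model; on curved
  stretches of the (quasi-sinusoidal) gait cycle it extrapolates away from
  the truth.
* **KF2** substitutes the previous posterior θ̂_{t−1|t−1}, tethering the
  filter to its last corrected value.  Across seeded dropout placements on
  two-harmonic signals its mean RMSE is consistently below KF1's; this
  ordering is asserted in the test suite (100 seeds).

Near- and far-side signals get separate noise pairs (defaults α_far = 10⁻²,
β_far = 10⁻³; α_near = 10, β_near = 1), reflecting the different noise
regimes of the two sides.  The filter initialises at the first frame whose
visibility reaches VT (θ seed, zero velocity/acceleration, P₀ = 100·I);
earlier frames are back-filled with the seed value.  The measurement
actually used at every frame is logged, so the substitution rule is
directly assertable rather than inferred.  A grid-search harness
(`noise_grid_search`) evaluates (α, β) combinations against gold-standard
signals by summed DTW and PE, for recalibrating the noise pairs on new
data.

## Frequency-domain filter (least-RMSE selection)

After the Kalman pass, the leading `cut` fraction of frames (default 10 %)
is discarded — the recursion needs time to converge — and the signal is
reduced to the N DFT components whose retention reconstructs it with least
RMS error.  By Parseval's theorem that equals keeping the N largest
combined-energy components, where DC counts alone and each conjugate pair
counts as one component (twice the one-sided energy; the Nyquist bin, when
present, counts singly).  Ties break toward the lower frequency index so
the selection is deterministic.  N = 5 (DC plus ~4 harmonics) captures
quasi-periodic gait while rejecting broadband noise.  No windowing or
zero-padding is applied; the DFT length is the post-cut signal length.
Optimality is verified against exhaustive subset search for lengths ≤ 32,
and band-limited signals that are periodic in the analysis window pass
through unchanged to 1e−8.

## Discrete gait parameters

* **Flexion** of a joint = range of motion (max − min) of its filtered
  signal, in degrees.  ROM is the standard discrete summary of a joint
  excursion and is translation-invariant by construction.
* **Striding speed** = the dominant (largest-energy non-DC) frequency of
  the near-side hip signal's spectral selection, in strides/s — one hip
  flexion-extension cycle per stride.  Resolution is one DFT bin,
  fps/m Hz for a post-cut length m (0.15 Hz at 30 fps, m = 200).

The feature vector is (age yr, mass kg, height m, far-knee, far-hip,
near-knee, near-hip flexion °, striding speed strides/s), in a fixed,
versioned order; gender is carried as a stratification key, not a feature.

## Feature models and Hotelling T²

Per gender stratum, cohort features are z-scored (the features mix years,
kilograms, metres, degrees and hertz; unstandardised PCA would be dominated
by the degree-valued flexions — the standardisation choice is ours, made
once) and decomposed by PCA (sample covariance, n−1).  Components are
retained in decreasing eigenvalue order until cumulative explained variance
reaches the threshold (default 90 %), at least one and never a numerically
null direction.  A subject x is scored

    T² = Σ_{i≤d₂} t_i²/λ_i,  t = loadings · z(x),

which under full retention equals the squared Mahalanobis distance (oracle-
checked against the direct inverse covariance).  A `t2_normalisation`
option (`none` | `per_pc`) is exposed because published T² magnitudes vary
by convention; the default applies no extra scaling.  Leave-one-out scoring
rebuilds the model per held-out subject.  PC similarity between two models
is |cos| of paired loading vectors, absorbing PC sign ambiguity.

## Agreement metrics

* **PE** (percentage error): per (sample, joint) RMSE divided by the gold
  signal's range, averaged over joints, then samples, ×100.  The nesting
  order matters and is fixed as stated.
* **DTW**: classic dynamic programme with |difference| point cost over
  monotone warping paths anchored at both ends, normalised by
  len(g) + len(p) (2m for equal lengths).  Unequal lengths warp across
  their full extents.
* **Missing data** are substituted before scoring: signal mean for PE,
  last-valid-carried-forward (leading gap back-filled) for DTW.
* **Bland–Altman**: differences pred − gold (or ×100/gold in relative
  mode); mean, SD, LoA = mean ± 1.96 SD, t-based 95 % CIs (SE of a limit
  taken as sd·√(3/n)), and a Kolmogorov–Smirnov normality p-value.
* **Correlation/regression**: Pearson r and OLS of y on x.

## Synthetic data: what it emulates, and what it does not

Gait angle signals are generated as a harmonic series (offset plus cosines
at multiples of a stride fundamental) with Gaussian measurement noise.
Dropout windows lower visibility *and corrupt the observed angle*
(default N(0, 15°)): low-confidence pose estimates are wrong, not merely
flagged, and without corruption the substitution strategies would be
indistinguishable from simply using the still-correct measurement.

The stick-walker places shoulders, hips, knees and ankles by forward
kinematics from known hip/knee profiles, so angle extraction inverts it
exactly at zero noise; one body side is displaced along the camera depth
axis and given lower baseline visibility to create a far side.  Default
profiles (hip ≈ 26° ROM about 160°, knee ≈ 50° ROM about 140°, 0.9
strides/s) are physiologically plausible fixture parameters.  The default
clip is 222 frames at 30 fps: after the 10 % cut, 200 frames remain and the
0.9 Hz fundamental sits exactly on a DFT bin, making the band-limited
closure and zero-noise recovery checks exact rather than
leakage-contaminated.

The acceptance study (scripts/acceptance.py) simulates 78 subjects
(50 female, 28 male, the cohort structure of a typical public walking
dataset) with per-subject randomised gait shape and fundamentals in
0.7–1.1 strides/s, near-side noise 5° and far-side noise 10° plus two
far-side dropout windows per signal.  The noise levels were fixed once so
that the *raw* signals carry range-normalised errors in the tens of
percent, matching the raw quality of consumer-camera markerless estimation;
with much cleaner inputs, filtering has nothing to repair and the
comparison between filter variants is uninformative.

What the generators do **not** emulate: pose-estimator error is neither
Gaussian nor stationary in reality (shape distortions, identity swaps,
depth errors correlated across joints), visibility is correlated with
error magnitude in a richer way than a binary window, and real gait
contains cycle-to-cycle variability beyond a fixed harmonic recipe.
Passing tests therefore demonstrate the correctness of the algorithms and
their claimed orderings under controlled conditions, not field accuracy on
video.

## Numerical choices and degenerate inputs

* Cosine arguments clamped to [−1, 1]; zero-length vectors raise a
  degenerate-geometry error, converted to missing samples (visibility 0)
  with a warning during batch extraction.
* Posterior covariance re-symmetrised each update; symmetry and
  positive-semidefiniteness are property-tested over 10⁴ steps.
* Spectral ties break toward lower frequency; a selection whose non-DC
  energy is numerically null reports "no periodicity" rather than a
  spurious bin.
* Constant signals: flexion 0 with a warning; flat gold signals make PE
  undefined and raise, naming the sample and joint.
* Zero-variance cohort features are detected with a relative tolerance
  (std ≤ 1e−10 · max(|mean|, 1)) and named in the error.
* Clips shorter than 40 frames — too little of a walking period — are
  refused outright.

## Known limitations

* Striding speed is quantised to one DFT bin; short clips at low frame
  rates limit its resolution.
* The far/near assignment assumes occlusion manifests as reduced
  visibility; estimators that report confident-but-wrong far-side joints
  would need the depth-axis tie-break.
* T² agreement between predicted and truth-derived features in the
  synthetic study (r ≈ 0.5 at the default conditions) is limited by the
  flexion error relative to cohort flexion spread; it is reported as
  computed, not calibrated.
* Irregular sampling is rejected, not resampled; the pipeline assumes a
  fixed frame rate.
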