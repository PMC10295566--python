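# gaitkit

Markerless gait assessment from monocular 3D pose keypoints.

Clinical gait analysis traditionally needs optical motion-capture labs or
wearable sensors.  A consumer camera plus a 3D human pose estimator offers
a cheap alternative, but the raw joint estimates are noisy and drop out
when limbs occlude each other — especially on the body side facing away
from the camera.  `gaitkit` is the post-processing and analysis layer of
such a system: it turns per-frame 3D keypoints (shoulders, hips, knees,
ankles) with visibility scores into clean sagittal-plane knee/hip angle
signals, discrete gait parameters, and a single atypicality score a
clinician can track, together with the evaluation machinery to validate
all of it against gold-standard signals.

## Method

1. **Angle signals.**  Knee angle θ = arccos(·) between the knee→hip and
   knee→ankle vectors; hip angle between the thigh and a *virtual forward
   vector* (the shoulder line rotated 90° about the vertical axis), which
   avoids the 180° fold of a trunk-referenced angle.  Signals are labelled
   near/far by camera side.
2. **Kalman filter.**  Constant-acceleration state (θ, v, a), Q = αI,
   scalar R = β, with separate (α, β) per side.  Frames whose visibility
   falls below VT = 40 % are missing; the substituted measurement is the
   previous *posterior* θ̂_{t−1|t−1} (strategy "KF2"), which tracks curved
   gait segments through dropouts better than prior substitution ("KF1").
3. **Frequency-domain filter.**  Drop the first 10 % of frames (filter
   burn-in), then keep the N = 5 DFT components (DC and conjugate pairs
   counting once) whose retention minimises reconstruction RMSE.
4. **Parameters.**  Joint flexion = range of motion of each filtered
   signal; striding speed = dominant frequency of the near-hip signal.
5. **Feature model.**  Per gender stratum, z-scored PCA of
   (age, mass, height, four flexions, striding speed) retaining ≥ 90 %
   variance; a subject is scored with Hotelling T² = Σ tᵢ²/λᵢ — larger
   means more atypical gait relative to the cohort.
6. **Evaluation.**  Percentage error (range-normalised RMSE), normalised
   dynamic-time-warping distance, Bland–Altman limits of agreement,
   Pearson/OLS, and PC cosine similarity.

## Worked example

Simulate a stick-walker (a forward-kinematic figure driven by known joint
profiles), run the pipeline, and score the subject against a synthetic
normal cohort:

```python
from gaitkit import PipelineConfig, run_pipeline, build_feature_model
from gaitkit.synthetic import WalkerSpec, generate_walker, generate_cohort

pose, truth = generate_walker(WalkerSpec(seed=1))
config = PipelineConfig(depth_axis="+z")
model = build_feature_model(generate_cohort(50, "female", seed=2))
report = run_pipeline(
    pose, {"age": 25, "mass": 70, "height": 1.75, "gender": "female"},
    config, model=model)
print(report.flexions)
print(report.striding_speed, report.t2)
```

prints

```
{'near_knee': 50.05, 'near_hip': 25.6, 'far_knee': 50.15, 'far_hip': 25.68}
0.9 5.222
```

The generating profiles have knee ROM 49.98° and hip ROM 25.55° at 0.9
strides/s, so at zero noise the pipeline recovers the flexions within
0.2° and the stride frequency exactly (it falls on a DFT bin).  The T²
of 5.2 sits near the typical in-cohort level for a 7-component model —
this synthetic subject's gait is unremarkable relative to the cohort.

The same flow is available from the shell:

```
gaitkit simulate --out-dir sim --seed 3
gaitkit run --pose sim/subject_000_keypoints.csv --subject subject.json --out report.json
gaitkit evaluate --pred pred.csv --gold gold.csv --out agreement.json
gaitkit fit-model --features cohort.csv --stratum female --out model.json
```

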