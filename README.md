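# saccadekit

Detection of **normal and pathologically slow saccades** in eye-tracking
time-series, built around sparse-derivative denoising.

Saccades are the rapid ballistic eye movements that redirect gaze between
fixations. Their kinematics follow the *main sequence*: peak velocity grows
with amplitude as **V**<sub>p</sub> = η(1 − e<sup>−A/c</sup>), where η is
the subject's velocity ceiling (deg/s) and c the small-amplitude scale
(deg). Abnormally slow saccades — a main sequence falling below the
normative band — are a key clinical sign of brainstem disease (PSP,
spinocerebellar ataxia, INO), but conventional detectors tuned to normal
saccade speeds routinely miss them or clip their endpoints. This package
is for eye-movement researchers and neuro-ophthalmology labs who need a
detector that works for both populations with no hand-tuned parameters.

## Method

Eye position during fixations-plus-saccades is modeled as an
*intermittent piecewise quadratic* signal: constant between movements
(sparse first derivative) and smoothly polynomial during them (sparse
third derivative). Given a noisy recording y, the denoised trace x̂
minimizes the convex objective

```
J(x) = ½‖y − x‖₂² + α‖D₁x‖₁ + β‖D₃x‖₁
```

with D₁, D₃ the first-/third-order difference operators. β = 0 reduces to
classical total-variation denoising (staircase artifacts on saccades);
the third-order term preserves the saccadic velocity profile while the
first-order term holds fixation velocity at zero. The minimizer is found
by majorization–minimization: each iteration solves the banded SPD system

```
x⁽ᵏ⁺¹⁾ = (I + α D₁ᵀΛ₁⁽ᵏ⁾D₁ + β D₃ᵀΛ₃⁽ᵏ⁾D₃)⁻¹ y,   Λ⁽ᵏ⁾ = diag(1/(|Dx⁽ᵏ⁾|+ε))
```

in O(n) time with guaranteed objective descent. Saccades are then read off
the central-difference velocity of x̂ with hysteresis thresholds (open at
30 deg/s, close at 10 deg/s) and standard plausibility rules (blink
proximity, 12 ms minimum duration, 40 ms minimum inter-saccadic interval,
800 deg/s cap). The weights α and β are set automatically from the
recording — estimated noise σ, mean candidate-saccade amplitude A and
duration D, and the sampling rate f:

- f ≤ 500 Hz: α = 0.016 f σ, β = 0.008 f √A e<sup>5D</sup> σ
- f > 500 Hz: α = (0.0032 f + 6.4) σ, β = (0.0016 f + 3.2) √A e<sup>5D</sup> σ

A parametric simulator (soft-ramp saccade waveforms consistent with the
main sequence, white Gaussian measurement noise) provides ground-truthed
benchmarks, and the package ships fixed-velocity-threshold (VT) and
dispersion (I-DT) baselines plus event-level precision/recall/F1 scoring
by temporal-overlap matching.

## Worked example

```sh
$ saccadekit simulate --rate 500 --n-saccades 8 --sigma 0.4 --seed 7 --out demo
wrote demo_gaze.csv (3008 samples) and demo_truth.csv (8 events)

$ saccadekit detect --in demo_gaze.csv --out demo_events.csv
INFO estimated sigma=0.4079 A=10.83 D=0.172 (n_candidates=9)
INFO denoiser alpha=3.26352 beta=12.7172 epsilon=1e-10 max_iter=100 tol=1e-08
wrote demo_events.csv (8 events)

$ saccadekit evaluate --truth demo_truth.csv --detected demo_events.csv
{
  "tp": 8, "fp": 0, "fn": 0,
  "precision": 1.0, "recall": 1.0, "f1": 1.0,
  "tpr": 1.0, "fnr": 0.0
}
```

The simulator injected 8 saccades under heavy noise (σ = 0.4 deg; the raw
central-difference velocity noise is ~280 deg/s RMS, far above the peak
velocity of a small saccade). The detector estimated the noise level
(σ̂ = 0.408 vs true 0.4), set α and β itself, and recovered every event
with no false positives. The events CSV reports onset/offset (seconds and
sample indices), amplitude (deg), peak velocity (deg/s), and duration per
saccade, e.g. a 12.95-deg saccade at 517 deg/s — on the normal main
sequence. The same can be done from Python:

```python
from saccadekit import (random_scanpath_spec, synthesize_scanpath,
                        add_noise, detect_saccades, evaluate_detection)

spec = random_scanpath_spec(50, sampling_rate=500, profile="slow", seed=0)
clean, truth = synthesize_scanpath(spec)
events = detect_saccades(add_noise(clean, 0.3, seed=1))
print(evaluate_detection(truth, events).f1)   # 1.0
```

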