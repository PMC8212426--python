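# Methods

## Signal model and objective

A monocular gaze-angle recording y (degrees, uniformly sampled at f Hz)
is modeled as y = x + w: an underlying fixation/saccade trajectory x plus
i.i.d. zero-mean Gaussian measurement noise w of standard deviation σ —
the standard noise model for video eye trackers. The trajectory itself is
taken to be *intermittent piecewise quadratic*: exactly constant during
fixations, approximately piecewise quadratic during saccades. Both
structural assumptions are sparsity statements — the first difference
D₁x is mostly zero (the eye is mostly still) and the third difference
D₃x is mostly zero (quadratic pieces are annihilated by the third
difference) — and are encoded as L1 penalties:

J(x) = ½‖y − x‖₂² + α‖D₁x‖₁ + β‖D₃x‖₁.

The objective is convex; β = 0 gives classical TV denoising (which
staircases the saccadic transient), α = 0 gives a smoothing spline-like
result that does not hold fixations flat. The combination is what yields
near-zero velocity between saccades *and* a preserved velocity profile
within them, so that a fixed velocity threshold suffices downstream.

## Majorization–minimization solver

Each L1 term is majorized at the current iterate by a quadratic with
diagonal weights Λ = diag(1/(|d| + ε)), d the current differences,
ε = 10⁻¹⁰ guarding division. The surrogate minimizer is the solution of

(I + α D₁ᵀΛ₁D₁ + β D₃ᵀΛ₃D₃) x⁽ᵏ⁺¹⁾ = y,

a symmetric positive-definite banded matrix of bandwidth 3, solved by
banded Cholesky (`scipy.linalg.solveh_banded`) in O(n) per iteration, so
hour-long recordings remain tractable. Properties and choices:

- **Initialization** x⁽⁰⁾ = y. Convexity makes the limit independent of
  the start; y is the natural choice.
- **Stopping.** Default cap of 100 iterations with early stop when the
  relative objective decrease falls below 10⁻⁸. The objective trace is
  returned for audit and is non-increasing by the MM guarantee.
- **Numerical floor.** On converged flat stretches |d| → 0 and the
  weights grow like 1/ε, so at extreme accuracy the banded solve loses
  descent to rounding. If a step would increase the objective the solver
  stops and returns the previous (best) iterate; the recorded trace
  therefore stays exactly monotone. A consequence worth knowing: with
  β = 0 the iteration matches an exact TV solver only to ≈10⁻⁶–10⁻⁴ RMSE
  (the ε-smoothing floor), while the *objective value* agrees with a
  convex-programming reference to better than 10⁻⁴ relative error —
  orders of magnitude below anything detection-relevant.
- **Blinks/NaNs.** The solver requires finite input; masked samples are
  linearly interpolated beforehand and the mask is honored again during
  post-processing. Each position channel is denoised independently.

## Automatic parameter setting

α and β are tied to three per-recording estimates. A 10 Hz zero-phase
low-pass differentiator (4th-order Butterworth, forward–backward, then
central differences) yields a smooth speed trace; *candidate saccades*
are excursions above 10 deg/s lasting ≥ 12 ms, after merging bursts
separated by < 20 samples. Then:

- σ̂ = standard deviation of the pooled fixation residuals (each
  inter-candidate segment individually de-meaned; segments shorter than
  50 ms excluded to avoid drift bias);
- Â = mean |displacement| of the low-pass trace across each candidate;
- D̂ = mean candidate duration, in seconds (so e^{5D} stays in ≈1.1–2.7
  for physiological saccades).

With sampling rate f: α = 0.016 f σ̂ and β = 0.008 f √Â e^{5D̂} σ̂ for
f ≤ 500, and α = (0.0032 f + 6.4) σ̂, β = (0.0016 f + 3.2) √Â e^{5D̂} σ̂
above; the branches coincide at f = 500 (α = 8σ̂, β = 4√Â e^{5D̂} σ̂).
These estimates need not be precise: on three simulated regimes (small
normal, large normal, large slow saccades) the automatic setting denoises
within 1.2× the RMSE of a grid-search optimum. Records with no candidate
saccades fall back to Â = 8 deg, D̂ = 50 ms (a typical normal saccade).
The candidate thresholds (10 deg/s, 12 ms, 20 samples) are applied
literally at the native sampling rate.

## Detection and post-processing

Velocity is the central difference [0.5, 0, −0.5] of the denoised trace
(one-sided at the ends); two channels combine as the Euclidean norm,
one channel as the absolute value. Hysteresis thresholding opens an event
above 30 deg/s and closes it below 10 deg/s — the lower closing threshold
respects the acceleration/deceleration asymmetry of saccades and is what
keeps the long tails of slow saccades inside the event. Events are
0-based, half-open [onset, offset) with times at sample centers; an event
still open at the record end is flagged truncated. Post-processing, in
order: discard events < 10 samples from a blink; merge events separated
by < 40 ms (post-saccadic oscillations are not separate saccades);
discard events < 12 ms (configurable — microsaccade studies may lower
it); discard events with peak velocity > 800 deg/s (implausible).
Merging precedes the duration filter so a split slow saccade is not
discarded piecewise. Amplitude (endpoint displacement of the denoised
trace) and peak velocity are re-measured on the final intervals.

## Simulator

Saccade waveforms follow the three-parameter soft-ramp model
s(t) = c f(ηt/c) − c f(ηt/c − A/c) with f(u) = u + 0.25e^{−2u} (u ≥ 0),
0.25e^{2u} (u ≤ 0), whose peak velocity is exactly η(1 − e^{−A/c}) — the
main sequence by construction. Default profiles: normal η = 550 deg/s,
slow η = 150 deg/s, both with c = 6 deg. A scanpath interleaves constant
fixations with saccades; the infinite-support waveform is truncated where
it is within 10⁻⁴ deg of its asymptotes (below any realistic noise floor)
and linearly renormalized so displacement is exactly ±A and fixation
velocity exactly zero. Defaults for randomized benchmarks: amplitudes
uniform on [2, 20] deg, fixation durations uniform on [0.3, 0.8] s,
directions random with a ±25 deg gaze-range bound. Fixations shorter than
40 ms are rejected, since adjacent saccades then become one movement by
any threshold convention. Ground-truth onsets/offsets apply the same
30/10 deg/s hysteresis rule to the noise-free velocity, so evaluation
never penalizes a convention mismatch. One seeded generator per synthesis
call makes output bit-reproducible; noise addition is seeded separately.

What the simulator does *not* emulate: post-saccadic oscillations,
smooth pursuit, nystagmus, drift or microtremor within fixations,
blink waveforms (masks can be injected but carry no physiological shape),
and colored or heteroscedastic tracker noise. Perfect benchmark scores
therefore demonstrate noise robustness and endpoint accuracy under the
stated model, not performance on recording artifacts absent from it.

## Evaluation

Scoring is event-by-event: a detection is a true positive when it
overlaps a ground-truth saccade in time, under one-to-one pairing (truth
visited in time order, each taking the unmatched overlapping detection
that ends earliest, ties broken by larger overlap — a rule that attains
maximum-cardinality matching on interval overlap graphs, verified against
exhaustive matching in tests). Precision, recall, F1, true-positive and
false-negative rates follow; empty-on-empty scores 1.0 and detections
without truth score precision 0 by convention. Main-sequence curves are
fit by bounded nonlinear least squares initialized at η₀ = max observed
peak velocity, c₀ = median amplitude.

The benchmark grids use 50-saccade recordings, σ ∈ {0.1, …, 0.9} deg,
ten independent noise realizations per level (a fresh random scanpath per
realization), at 250/500/1000 samples/s — sizes chosen so the full study
re-runs in about a minute while keeping the Monte-Carlo error of a grid
mean below 0.01.

## Known limitations

- Single-channel thresholds assume world-fixed (not wearable) trackers.
- Slow-saccade offsets are recovered to within one 20 ms post-filter
  sample span in simulation; sub-sample onset/offset refinement is not
  attempted.
- The ε-smoothing floor of the MM solver (above) bounds attainable
  agreement with exact-TV references; irrelevant at detection scales.
- The VT/DT baselines use classical textbook parameters (30 deg/s;
  1 deg over 100 ms) and are meant for ordering comparisons, not as
  tuned competitors.
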