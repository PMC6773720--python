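# Methods

This note documents the models implemented in `gravipursuit`, the
parameter choices that matter, the synthetic-data generator used to
validate the pipeline, and known limitations.

## Stimulus kinematics

Targets move on parabolas in the fronto-parallel plane at z = −6.15 m
(coordinates: observer at the origin, x rightward, y upward).  Air
resistance is linear in velocity with drag coefficient c = 0.005 kg/s
and target mass m = 0.057 kg; gravity is 9.81 m/s² times the magnitude
of the condition's gravity multiplier.  Writing k = c/m, the solution
is evaluated through φ₁(z) = (1−e^(−z))/z and φ₂(z) = (z−(1−e^(−z)))/z²:

    x(t) = x₀ + v_xi · t · φ₁(kt)
    Δy(t) = v_yi · t · φ₁(kt) − g · t² · φ₂(kt)
    y(t) = y₀ ± Δy(t)

For |z| < 10⁻⁴ the φ functions switch to fourth-order series, making
the ballistic limit (c → 0, including c = 0 exactly) free of the
g/k − g/k cancellation that destroys the naive exponential form in
double precision.  The closed form agrees with adaptive Runge–Kutta
integration of the drag ODE to < 10⁻¹⁰ m over the full design.

Upright conditions start at y₀ = 0.5 m moving upward; the −1 g
condition is the exact mirror image about the mid-height y = 2 m:
start at 3.5 m, initial velocity downward, "gravity" pulling upward.
The launch x is −(horizontal span)/2, so the vertical extremum lies at
x = 0 in the ballistic limit; with drag the extremum shifts by up to
0.079 m across the design (worst case 0.7 g, v_yi = 6 m/s).

*Flight time* is the smallest positive root of Δy(t) = 0, found by
Brent's method on [t_peak, 2·t_peak·1.5ⁿ] to 10⁻¹² s — deterministic
and bracket-safe because Δy is single-peaked.  *Occlusion onset* is
(1 − fraction) × flight time: the stimulus hides the **last** 20–25 %
(short) or 45–50 % (long) of the flight, the fraction drawn uniformly
per trial within its interval.  Occluded durations then average ≈ 0.3 s
across the design, matching the task's premise of extrapolating a
sub-second hidden interval.

## Earth-gravity extrapolation

At occlusion onset the remaining distance to the coincidence height is
d ≥ 0 and the last seen vertical velocity v (positive away from
coincidence; the inverted geometry is queried in its mirrored frame).
An observer assuming earth gravity and no drag predicts the remaining
time as the positive root of d = (g_e/2)t² − v·t:

    t̂ = (v + √(v² + 2 g_e d)) / g_e,   g_e = 9.81 m/s².

The predicted temporal error is t̂ minus the true remaining flight
time.  With drag, the 1 g prediction errs by only −1.3 to −5.3 ms for
1 g stimuli (justifying the drag-free prediction), but by −26 to
−134 ms for 0.7 g and +4 to +54 ms for 1.3 g — early for weak
gravities, late for strong ones, in every design cell, and twice to
four times larger for long occlusions.  By symmetry, the −1 g
prediction equals the 1 g one in the mirrored frame.

The alternative *central-tendency* observer times every occlusion by
the mean occluded duration of its block type; its predicted error is
that mean minus the trial's occluded duration.  The two predictors are
correlated (both depend on occluded duration) but not collinear, which
is what makes the generating strategy identifiable from data.

## Design

Per subject: a 48-trial training block (each combination once), three
main blocks of 320 trials (5 upright gravities × 2 vertical × 2
horizontal launch speeds × 2 occlusion categories × 8 repetitions,
freshly shuffled per block) and one inversion block of 384 trials
({1 g, −1 g} × 2 × 2 × 2 × 24), totalling 1344 experimental trials.
The inversion block is first for alternating subjects.  Balance holds
by construction (enumerate, then permute); occlusion fractions are
drawn per trial.

## Gaze pipeline

Input samples are (t, x_surf, y_surf, confidence) at 200 Hz, surface
coordinates normalized to a 1.84 m × 2.44 m display seen from 2 m.

1. **Filtering**, in order, each stage's percentage taken of the frames
   surviving the previous one: confidence < 0.9; gaze outside the
   display (x outside [0, 1] or y outside [−0.3, 1]); missing fields.
2. **Scene mapping**: surface → centred screen metres → ray-scaled by
   6.15/2 = 3.075 to the stimulus plane, where all velocities are
   expressed.
3. **Smoothing**: Gaussian, σ = 3 samples (15 ms), reflected
   boundaries.  The width is a package default (configurable); the
   analysis it reimplements specifies a Gaussian but not its width.
4. **Differentiation** with lagged differences over recorded
   timestamps — tangential speed with lag 9, its time-derivative with
   lag 5 — assigned to the window-centre sample (i − ⌊lag/2⌋).
   Windows spanning a timestamp gap longer than 3×lag×5 ms are masked,
   so dropouts never alias into velocities.
5. **Saccade classification**: a sample is saccadic if acceleration
   exceeds 300 m/s² or eye speed exceeds 1.5× the instantaneous target
   speed.  Runs merge across gaps of ≤ 2 samples; runs shorter than 2
   samples are discarded.  For isolated ~2° saccades this recovers
   onsets within ±2 samples; large (≥ 0.3 m) saccades can be flagged a
   few samples early because smoothing and the 45 ms velocity window
   spread the transient outward.
6. **Gain**: mean eye/target speed ratio over samples after the first
   catch-up saccade's offset and before occlusion onset, excluding
   saccades *widened by 8 samples per side* (velocity-lag half-window
   + smoothing support).  Without this margin, saccadic displacement
   leaking into neighbouring speed estimates biases gains upward by up
   to +0.09; with it, closed-loop recovery is accurate to < 0.005.
   Trials with no usable window are flagged invalid, never zero.

## Timing analysis

Raw temporal error is button time minus true coincidence time;
corrected error subtracts the display system delay (0.049259 s).
Trials with |raw error| ≥ 0.5 s are excluded — the absolute-value
reading, since both early and late outliers occur.  Observed errors are
compared with both predictors via Pearson correlations (overall and per
occlusion category) and per-cell medians; a data set's generating
strategy is identified by the larger overall correlation.

## Mixed models and power

All models are `response ~ fixed + (1 | subject)` fitted by **maximum
likelihood** (not REML) so that likelihood-ratio tests between nested
fixed-effect structures are valid; p-values use the χ² reference.
Gravity is an unordered categorical factor with 1 g as reference, so
coefficients are per-level contrasts against earth gravity.  Fitting
uses a deterministic optimizer cascade (BFGS, then Powell, then
Nelder–Mead) and rejects non-finite likelihoods; a random-intercept
variance estimated at zero is floored and flagged as singular rather
than failing.  The timing analysis fits the pre-planned
gravity × occlusion interaction model, drops the interaction if it does
not improve fit at α = 0.05, and compares the selected model against
the intercept-only null.

The power analysis simulates two-condition within-subject cohorts with
between-subject intercept SD 0.025 (gain units) and trial-to-trial SD
six times larger (0.15), runs the full fit-and-test pipeline, and
reports the rejection fraction.  The 6:1 ratio is the design
assumption; 0.025/0.15 gain units reproduce standard errors of ~0.005
on a gravity contrast at the inversion-block sample size, which is the
scale of interest.  Under a null effect the measured test size is
0.04–0.05, and an 0.1 gain difference at 10 subjects × 60
trials/condition is detected essentially always.

## Synthetic gaze generator

The generator produces traces with the statistical structure the
analysis assumes, so every stage can be validated closed-loop:

* Fixation at the launch point until the pursuit latency (150 ms),
  then a minimum-jerk catch-up saccade onto the target (50 ms), then
  pursuit with eye velocity = gain × target velocity.  Position error
  above 0.3 m triggers further catch-up saccades.  The latency and
  threshold defaults yield ~2 saccades per trial, the realistic range.
* After occlusion the pursuit gain decays exponentially (τ = 0.3 s) and
  one predictive saccade (latency 210 ms) jumps to the landing point
  implied by the earth-gravity extrapolation — under 0.7 g this lands
  left of the true coincidence point, giving the characteristic
  undershoot.
* Measurement: Gaussian position noise (default 0.005 m at the
  stimulus plane ≈ 0.05°), confidence dropouts at rate 0.064 drawn
  Uniform(0, 0.9) (kept samples Uniform(0.9, 1) — only the 0.9
  threshold matters), exact 200 Hz sampling, inverse scene mapping to
  surface coordinates.
* Cohorts: per-subject gain intercepts ~ Normal(0, 0.025), per-trial
  gain noise ~ Normal(0, 0.15), per-gravity true gains supplied as a
  mapping.  Responses mix the earth-gravity extrapolation with the
  central-tendency predictor via a weight λ ∈ [0, 1], plus motor noise
  (SD 0.05 s) and the system delay.

The pursuit model scales eye velocity by the gain at the *same* time
as the target velocity (the latency enters through the delayed pursuit
onset, not as a running velocity delay); a running delay would make the
measured speed ratio deviate from the generating gain by several
percent over a curved trajectory and break the closed-loop
identifiability that validation relies on.

**What validation on these data shows and does not show.**  Passing
closed-loop tests demonstrates that the pipeline's estimators recover
the quantities they are defined on, at realistic noise, dropout and
saccade rates — it does not certify performance on real recordings,
which contain drifts, blinks with recovery artifacts, anticipatory and
vergence components, head-slip decalibration, and oculomotor dynamics
(main-sequence velocity profiles, pursuit latency jitter) that the
generator deliberately omits.  Statistical results on synthetic cohorts
(effect recovery, test size, power, strategy identification) are exact
statements about the generating model only.

## Numerical and validation scale choices

Validation studies are sized to run on one core in a couple of minutes
while keeping Monte-Carlo error well inside the asserted margins: gain
recovery uses 4 trials per design cell; test-size calibration 500
simulated null cohorts at 10 subjects × 24 trials/condition; strategy
identification 200 cohorts of 4 subjects × 160 trials; power curves 100
simulations per point.  All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning.

## Known limitations

* The drag model is linear in velocity; quadratic drag is out of scope.
* The saccade generator uses minimum-jerk position steps, not
  main-sequence kinematics; classifier thresholds, not waveform shape,
  are what downstream stages depend on.
* The −1 g extrapolation query is defined in the mirrored frame; an
  observer applying earth gravity *unmirrored* to upward motion would
  predict no return at all, a qualitatively different strategy that the
  package does not model.
* Mixed models use random intercepts only (no random slopes), matching
  the analysis design.
* The OSF-deposit import shim maps column names via configuration; no
  byte-exact schema compatibility with any particular export version is
  promised.
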