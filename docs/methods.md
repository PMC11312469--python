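# Methods

This note documents the models implemented in `steerid`, the parameter
choices that matter, and the decisions taken where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The closed loop

All simulation and analysis live on the display frame grid, dt = 1/85 s.
The loop state advances as

    x[i] = T_disp[i] − (H[i] + h_off[i])          displayed error
    r[i] = dt · Σ_{j=1..L} k[j] (x[i−j] + n[i−j])  response
    H[i+1] = H[i] + g_joy · r[i] · dt              heading integration

where `h_off` is the block-held heading display noise, `n` is i.i.d.
Gaussian sensory noise on the error, and `g_joy` is the joystick gain
(deg/s of heading rate per unit response). The convolution uses the
rectangle rule with an explicit dt factor and excludes lag zero: the
response may not depend on the instantaneous error, so every constructible
kernel is causal by construction. The 1 kHz joystick sampling of the
physical apparatus is not modeled; the loop closes at display rate because
that is the rate at which the error the subject sees is refreshed.

**Joystick gain convention.** The unit of the response r is left
implicit by the task hardware (full stick deflection maps to 255 or
85 deg/s depending on the animal). We default to `joystick_gain = 1` with r
in deg/s, keeping the per-animal gains available in `PlantConfig` for
realism studies. Under this convention the outer loop is slow (DC crossover
≈ 0.026 rad/s for the reference drift-context controller), so steady-state
step errors decay over hundreds of seconds rather than seconds; tests that
check the integrator property therefore use long horizons. The within-loop
resonance (≈ ω_d of the controller) is unaffected by this convention up to
a mild closed-loop correction, which is why the remnant analyses are robust
to it.

**Steering onset.** The 500 ms pre-steer hold only delays the first target
event; the controller itself runs from frame 0. This keeps
r = k∗(x+n) exact at every recorded sample, which in turn makes noiseless
regression recovery exact. The identification stage simply drops the
hold-period rows.

## Task generators

Step context: inter-step intervals are shifted-exponential
(min + Exp(mean − min), 1000 + Exp(1000) ms by default) — the simplest
one-parameter family consistent with a stated minimum and mean. Step
magnitudes come from {5, 10, 15, 20, 25} deg with default weights
proportional to 1/amplitude (the task description says only that
probability decreased with amplitude and varied day to day); signs are
equiprobable. Steps displace the target relative to its **previous target
position**: the experimental intent — that the induced error equal the
step magnitude — presumes the subject had nulled the previous error, which
a standalone generator cannot know. Trial durations are uniform on
15–30 s.

Drift context: after the hold, the target jumps ±4 deg, then moves at a
piecewise-constant velocity ~ N(0, 0.1² deg²/s²) redrawn every 259–494 ms
(uniform, rounded to 22–42 frames), integrated on the frame grid. Display
noise offsets are zero-mean Gaussians held for 94 ms blocks (8 frames):
σ = 0.1 deg on the target, σ = 2.5 deg on the heading. Drift trials last
15 s.

What the generator does **not** emulate: VR scene rendering, eye movements
and fixation enforcement, reward delivery, inter-trial intervals, response
clipping at full stick deflection (available but off by default), and any
left/right asymmetry or amplitude-dependent nonlinearity of a real subject.
Tests passing on these synthetics therefore certify the estimators under
the model's own assumptions — linearity and injected sensory noise — not
the behavior of real animals.

## Nonparametric kernel

The basis is N = 56 raised half-cosine bumps, f = 2 Hz (support half-width
1/(4f) = 0.125 s), centers linearly spaced 0.125–4.708 s, sampled on the
lag grid dt…411·dt. Assembled kernels are zeroed beyond 4.835 s to avoid
edge artifacts from the final bumps' asymmetric overlap (on the default
85 Hz grid this truncation removes no in-support samples, so basis
re-projection is exact to machine precision). Center placement is exact;
only the lag grid snaps to frames.

Weights are ordinary least squares on the stacked design whose column j is
the causal convolution of bump j with each trial's displayed error. No
regularization is applied: the smooth, causal, finite-memory basis is the
only constraint. Early-trial samples keep a zero-padded lag history rather
than being dropped — this matches both the simulator (there is no
pre-trial error) and the free-running prediction convention; the
alternative drop policy is available via `drop_incomplete_history`.

Validation is free-running: the fitted kernel runs in closed loop given
only the initial heading and the target, and "variance explained" is the
squared Pearson correlation between predicted and observed responses pooled
over time and trials (1 − SSE/SStot is logged alongside). The prediction
replays the *stored displayed* target and the *recorded heading
display-noise offsets*: the display noise is part of the stimulus the
controller actually saw, and replaying both streams is the only convention
under which a noiseless plant's prediction reproduces its simulation sample
for sample.

## Second-order model

The parametric controller is the underdamped second-order system with
delay; its impulse response is

    k(τ) = G sin(ω_d (τ−τ′)) e^{−ζω_n(τ−τ′)},  τ ≥ τ′,   ω_d = ω_n√(1−ζ²).

The amplitude is G = g/ω_d, the standard inverse Laplace transform of
g e^{−τ′s}/(s² + 2ζω_n s + ω_n²). Only the underdamped branch (ζ < 1) is
implemented; ζ ≥ 1 is rejected rather than silently switching to the
overdamped form.

Fitting minimizes squared response residuals with the prediction formed
open-loop (convolution of the candidate kernel with each trial's *observed*
errors) — the same protocol that trains the nonparametric kernel, which
makes the two model classes directly comparable; free-running closed-loop
prediction is reserved for evaluation. The optimizer is bounded
trust-region least squares with 5 multi-starts jittered around a coarse
(τ′, ω_n) grid (τ′ ∈ {0.1, 0.2, 0.35} s, ω_n ∈ {6, 10, 16} rad/s); the
best final objective wins. Residuals are evaluated through one cached rFFT
of the error matrix per dataset, so each objective evaluation costs one
batched inverse FFT.

Bootstrap: `n_boot = 100` replicates of `n_per_boot = 200` trials drawn
uniformly with replacement; replicates with any parameter > 2.5 SD from the
across-replicate mean are discarded; CIs are 1.96 × SD of the retained
fits. Replicates after the first warm-start at the first full fit.
Context comparison reports 100·(test − ref)/ref and
t = Δmean/√(var_test + var_ref) with df = n_boot − 1, two-tailed. Note
this t-test treats bootstrap replicates as independent samples and is
therefore anti-conservative; it is provided as the published-table
convention, not as a calibrated inferential procedure.

## Remnant analysis

Residuals are q = r − r̂ with r̂ the free-running prediction. Spectra are
single whole-trial FFTs (no windowing, no detrending beyond per-trial mean
removal), squared magnitudes averaged across trials after truncation to the
common minimum length; normalization modes are raw, unit total power, and
division by the task's steering-error variance.

Because the loop is linear, the injected noise n and the exogenous input
pass through the *same* closed-loop transfer to the response. Hence
Φ_r̂r̂/Φ_TT = Φ_qq/Φ_nn bin-wise, giving the estimator

    Φ_nn = Φ_qq · Φ_TT / Φ_r̂r̂.

Two practical points:

* **Effective input.** In the drift context the heading display noise
  enters the summing junction exactly like target motion
  (x = T_disp − H − h_off), so Φ_TT must be the spectrum of the effective
  input u = T_displayed − (H_displayed − H_world). Using the raw target
  spectrum would bias the estimate by Φ_TT/(Φ_TT + Φ_hh), badly at
  frequencies where the σ = 2.5 deg heading noise dominates the
  σ = 0.1 deg/s drift. In the step context u reduces to the target.
* **Masking.** Bins where Φ_r̂r̂ < 10⁻⁶ × its maximum are masked (NaN with
  a `valid` flag) instead of producing unstable ratios.

The estimator is exact only up to per-trial DFT edge effects (linear vs
circular convolution over a 15 s trial with a ~1 s-memory kernel); with
500 trials the recovered spectrum of known white injected noise is flat to
well under 1 dB over 0.3–2 Hz (computed by the acceptance script and
asserted in the test suite at a ±3 dB criterion).

## Noise calibration

`tune_noise_sd` sets the sensory-noise SD to hit a requested validation r²:
a paired pilot simulation at unit noise splits each response into its
deterministic part s and noise-driven part q, and because the loop is
linear in n, r²(σ) = Var(s)/(Var(s) + σ²Var(q₁)) is solved in closed form
(variances pooled across trials, matching the pooled r² definition). This
defines the "moderate noise" regime used in recovery experiments before
any fit is run.

## Numerical choices and degenerate inputs

* Least squares via `numpy.linalg.lstsq`; a rank-deficient design returns
  the minimum-norm solution with a warning, an underdetermined one raises.
* `variance_explained` raises on zero-variance inputs rather than
  returning NaN.
* Conditional-response bins with a single observation report NaN SEM and
  are flagged; empty bins are flagged, never silently dropped.
* All dataset generation derives per-trial seeds from one `SeedSequence`,
  so datasets are bit-reproducible given (seed, configs).
* Problem sizes in tests and the acceptance script (e.g. 120–150 trials
  per dataset, 8–20 recovery seeds, 500 trials for spectrum estimates) were
  chosen as the smallest sizes at which the Monte-Carlo error of each
  statistic is comfortably below its acceptance margin.

## Known limitations

* Only the underdamped second-order branch is available; critically damped
  or overdamped controllers cannot be represented.
* Open-loop regression on closed-loop data is slightly biased when the
  feedback from past noise into the current error is strong (high loop
  gain); at the default gain convention the bias is far below the
  recovery tolerances, but users adopting the 255 deg/s hardware gain
  should expect it to grow.
* The t-test on bootstrap distributions is anti-conservative (above).
* The noise model is stationary, Gaussian, and white; signal-dependent
  motor noise and static output nonlinearities are out of scope.
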