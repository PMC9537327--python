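# Methods

This note documents the models implemented in `fatiguelag`, the choices
made where the design was genuinely open, and what the synthetic approach
can and cannot show.

## The paradigm being emulated

Participants flex and extend the index finger cyclically at a paced
2.14 Hz (cycle ≈ 467 ms) between target lines spanning 38°–55°, while an
avatar displays the movement at 60 Hz from 500 Hz motion capture.  On each
trial the test period contains two 4 s phases separated by a 1 s blank; in
one phase (the *comparison*) the avatar is shifted in time by a signed lag,
in the other (the *standard*) it is synchronous.  The participant reports,
two-alternative forced choice, which phase felt more fatiguing (fatigue
session) or more asynchronous (delay session).

Design 1: lags 0/+50/+83 ms, crossed with metronome sound on/off; blocks of
190 s = 10 trials × (8 s preparation + 9 s test + 2 s response); the target
span is reduced by 3.6% at +50 ms and 6% at +83 ms to cancel a known
amplitude confound.  Design 2: lags −50/−33/0/+33/+50 ms (span reduction
2.4%/1.6% at ±50/±33), blocks of 180 s (7 s preparation); its delay session
uses −50…+50 ms in 17 ms steps over 10 blocks of 14 trials.  Negative lags
require *predicting* the movement; trials where prediction quality ω_t
dropped below 0.05 are excluded.

## Synthetic data generation

**Choices.**  Fatigue choices are Bernoulli draws from one of three probit
models (Model 1 by default — the design the other stages must recover):
P_i(x) = Φ(α + α_i + (β + β_i)x), with participant effects
α_i ~ N(0, σ²_α), β_i ~ N(0, σ²_β).  Delay-session choices come from an
analogous probit in x.  Defaults: α = 0, β = 0.008/ms (fatigue),
β = 0.02/ms (detection), σ_α = 0.2, σ_β = 0.003 (fatigue) /
σ = 0.2, 0.006 (detection).  These place the fatigue choice rate near 0.66
at +50 ms and detection near 0.84 at +50 ms — the magnitudes the published
figures show — with realistic between-participant spread; no numeric
population values are published, so these scales are conventional.  The
slope deviations of the two tasks can be drawn with a configurable
correlation (`slope_corr`) for recovery studies, and an optional order bias
adds ±δ to the linear predictor by presentation phase to exercise the
phase-pooling correction.  Every dataset stores `p_true`, the exact
Bernoulli parameter per trial, so simulation is auditable against its
`GroundTruth`.

**Kinematics.**  Each cycle is a raised cosine θ(t) = A/2·(1 − cos 2πu),
u ∈ [0, 1): smooth, periodic, zero velocity at the turning points.  The
waveform shape is not specified by the study; a raised cosine is the
simplest C¹ profile with distinct flexion/extension half-cycles.  Cycle
periods are (1/2.14 s)·ε with lognormal ε (mean 1, CV 3% by default) —
multiplicative period jitter typical of paced movement, chosen to make
prediction nontrivial but realistic.  Amplitude is the participant's target
span, with the design's span reduction applied to cycles inside comparison
phases.  A 60 Hz display track is emitted alongside the 500 Hz capture
track.

**EMG.**  The study specifies only the analysis (band-pass, rectification,
median frequency), not a generative model.  Channels are Gaussian noise
shaped in the frequency domain by a lognormal magnitude profile (log-σ
0.35) whose location is solved by bisection so the *in-band* [20, 240] Hz
spectral median equals the target; the target declines linearly with block
index at the participant's drift rate (default 1 Hz/block from ≈110 Hz,
floored at 40 Hz), emulating the downward spectral compression of fatiguing
muscle.  Amplitude is gated by movement phase (flexor active during
flexion, extensor during extension, 0.3 tonic floor); the ±2.14 Hz sidebands
this modulation creates are symmetric and move the median by far less than
the ±3 Hz verification tolerance.  Within a block the median frequency is
constant; the fatigue drift operates across blocks, which is the scale the
analysis uses.

**Seeding.**  One master seed; every sub-stream derives from
`SeedSequence(master, spawn_key=(purpose, participant, block, session))`,
so cohorts, schedules, traces and choices are independently reproducible.

## The cyclic predictor

The original real-time prediction algorithm is described only in a
supplementary file that is not part of the available text, so this module
is a functional re-design that must meet the published validation figures
(peak cross-correlation, recovered lag, ω-gating), not a port.

State: phase φ, angular frequency ω, harmonic coefficients
{c₀, a_k, b_k} for K = 4 harmonics.  Per 500 Hz sample:

1. prediction ŷ = c₀ + Σ a_k cos kφ + b_k sin kφ, error e = y − ŷ;
2. NLMS coefficient update with step μ_c = 0.004, boosted ×10 during the
   2 s burn-in and afterwards scaled by the quality state (confidence
   gating) — an unpredictable input must not be slowly memorized;
3. phase correction along the model gradient,
   Δφ = μ_φ·e·(∂ŷ/∂φ)/((∂ŷ/∂φ)² + ¼·var), μ_φ = 0.3, clipped to
   ±0.01 rad per sample.  The clip is deliberately below ω·dt ≈ 0.027 rad,
   so the oscillator can never be "parked" by a frozen input — tracking a
   stopped movement must fail, visibly, in ω_t;
4. canonical-form anchoring: the NLMS update can slowly rotate the harmonic
   phasors, which would let phase and frequency drift while one-step
   predictions stay accurate (a joint degeneracy we observed directly).
   Each step the coefficients are rotated so the fundamental is a pure
   negative cosine (angle minimum at φ = 0) and the rotation is folded into
   the phase correction;
5. frequency integrates a fraction μ_f = 0.002 of the total phase
   correction (a second-order phase-locked loop), clamped to 0.8–4.5 Hz.
   During burn-in the phase advances feedforward at the paced 2.14 Hz —
   known to the renderer, since the metronome paces the task — because
   corrections driven by a half-learned model bias the loop.

**Quality ω_t** is 1 − (smoothed squared error of the *100 ms look-ahead*
prediction)/(0.9 × smoothed signal variance), clipped to [0, 1], with a 1 s
error time constant.  Scoring a horizon rather than one step is essential:
sample-to-sample chasing can make white noise look predictable.  The 0.9
slack maps "no better than predicting the mean" robustly to zero.  The
exclusion threshold ω_t < 0.05 is as published.  Corrections and learning
disengage below ω_t = 0.2, so a lost lock free-runs rather than corrupting
the model; within a trial this is conservative (the trial gets gated).
Typical exclusion rates at 3% jitter are 10–15% of negative-lag trials
(the published rate on human data was 7.0%; reported for context, not as a
target).

**Rendering.**  Positive lags replay the capture buffer delayed by the lag
(causal linear interpolation; at lag 0 this is passthrough resampling to
60 Hz, stale by at most one capture sample).  Negative lags evaluate the
harmonic model at φ + ω·(Δt + |lag|), where Δt bridges the last processed
capture instant to the display tick.  Rendering never reads future samples.

**Validation.**  Normalized cross-correlation between the actual trace and
the displayed track, both restricted to the analysis window, mean-removed,
on the 500 Hz grid, over ±250 ms of integer lags, with parabolic sub-sample
refinement at the peak.  Positive reported lag means the display trails the
movement.

## Probit mixed models, Laplace likelihood, AIC

Trials are aggregated to binomial counts per (participant, lag) — choices
pooled over the two presentation phases, cancelling order bias to first
order.  For Models 2/3 the predictor P^d_i(x) is the participant's
empirical delay-session proportion at that lag, with 0/1 proportions pulled
in by 0.5/n so linear predictors stay finite.

The marginal likelihood integrates the participant's random-effect vector
b_i ~ N(0, D), D diagonal, out of the Bernoulli-probit likelihood.  For
each participant the integrand is maximized by damped Newton steps (exact
gradient and Hessian of the probit log-likelihood, computed via `log_ndtr`
for stability), and the Laplace approximation is
ℓ_i = ℓ(b̂_i) − ½ b̂_iᵀD⁻¹b̂_i − ½ log det(I + D·ZᵀWZ).  The outer
optimization is L-BFGS-B over (fixed effects, log SDs), with predictor
columns scaled to unit SD for conditioning and starting values from a plain
probit fit; log SDs are bounded in [−8, 3], so a vanishing variance
component degenerates smoothly to ordinary probit regression.  Reported
log-likelihoods are per-trial Bernoulli (no binomial coefficient), so they
do not depend on the aggregation.  Standard errors come from the numerical
Hessian at the optimum; `fix_re_sd` profiles the variance components at a
fixed value (used to verify the zero-variance limit, where free ML on
finite data legitimately estimates small positive variances).

AIC = −2 logL + 2k with k counting fixed effects plus variance components:
4, 4 and 7 for Models 1–3.  Model 3's two intercept random effects are only
jointly identified; they are kept separate to mirror the published model
structure, and k counts both.  Participant-level sensitivities are the
posterior-mode slopes β + b̂_i; across-task correlation uses Pearson r.
Posterior-mode shrinkage attenuates such correlations when the slope spread
is small relative to per-participant estimation noise — recovery studies
should use slope SDs comfortably above that noise floor.

## Signal metrics

EMG preprocessing is a zero-phase (forward–backward) 4th-order Butterworth
band-pass, 20–240 Hz, then full-wave rectification.  Median frequency is
computed on the band-passed (not rectified) signal: Welch PSD with 2 s Hann
windows, 50% overlap, and the in-band equal-power split located by linear
interpolation of cumulative power *from both ends*, averaging the two
crossings (tolerance 1e-4) — on smooth spectra this equals the usual
interpolated median to ≪0.1 Hz, and it makes the two-equal-lines case
return the plateau midpoint instead of an arbitrary edge.  The estimator,
window length and phase handling are not specified by the study; these are
documented defaults.

Movement indices per window: amplitude = mean over cycles of (max peak −
preceding min peak); velocity = mean |dθ/dt|; cycle interval = mean spacing
of flexion-direction crossings of the target-line center, with crossing
instants linearly interpolated and exact hits resolved to the earlier
sample.  ΔI = (I_comparison − I_standard)/I_baseline, the baseline being
the participant's average over preparation periods without a leading delay
(comparison in phase 2, or zero-lag trials — when the comparison occupies
phase 1 the lag runs from the preparation onset in Design 1).

## Inferential statistics

One-sample t against chance 0.5 on raw per-participant proportions (the
d = 1.00 effect-size anchor is consistent with raw proportions), Cohen's
d = (mean − μ₀)/sd; Holm step-down adjustment by default (plain Bonferroni
available), matching the figure-level reporting.  The two-way
repeated-measures ANOVA uses the classical within-subject decomposition,
each effect tested against its subject×effect stratum, partial
η² = SS_eff/(SS_eff + SS_err); no sphericity correction by default
(uncorrected dfs are what the study reports).  The decomposition is
verified to close (residual < 1e-10 of total SS) on every call.  Power for
the one-sample t uses the noncentral t with noncentrality d√n; "power 0.8"
is the conventional reading of the design's β = 0.8 statement (β normally
denotes the type-II rate).  With d = 1.00, α = 0.05 two-sided, the minimal
n is 10.

## Problem sizes and numerical tolerances

Default verification sizes, chosen to make sampling noise small relative to
the tolerances: 120 simulated trials per lag for predictor validation
(9 s test windows after 7 s burn-in); 50 replicate datasets at the
14 × 150-trial scale for model recovery and 100 for parameter recovery;
2 s spectral windows (0.5 Hz bins); quadrature cross-checks with 31 (2-D)
or 11 (4-D) Hermite nodes per dimension.  Inner Newton tolerance 1e-9,
outer optimizer ftol 1e-12.

## Limitations

* The EMG generator reproduces the spectral statistics the analysis
  measures, not muscle physiology: no motor-unit structure, no
  force–EMG coupling, no conduction-velocity model.  Passing tests show the
  *analysis chain* is correct, not that real EMG would behave this way.
* Kinematic jitter is white per cycle; human paced movement also drifts
  slowly with the metronome.  Predictor performance on real data depends on
  that structure and on the ~57 ms hardware latency of the original
  apparatus, which is not simulated by default.
* The predictor is a re-design: it satisfies the published validation
  criteria but is not the original supplementary algorithm, and its ω_t is
  a re-definition with the published threshold.
* Random effects are independent Gaussians (diagonal covariance), as the
  published equations list them; correlated within-model random effects are
  not fitted.  The *generator* can induce cross-task slope correlation for
  recovery studies.
* The published human-data statistics (choice probabilities, AIC values,
  F/t statistics) are not reproducible without the human dataset; the
  pipeline reproduces the *procedures* and verifies them by recovery on
  synthetic ground truth.
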