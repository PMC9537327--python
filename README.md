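# fatiguelag

Does the *feeling* of muscle fatigue track the body, or the brain's model of
the body?  In a paced finger-flexion paradigm, delaying the visual feedback
of one's own cyclic movement by tens of milliseconds makes the movement feel
more fatiguing, and feedback that *precedes* the movement (rendered by
predicting the cyclic trajectory) makes it feel less so — even though the
muscles do the same work.  `fatiguelag` is a synthetic re-implementation of
that study's computational pipeline: because the human dataset is not
deposited, every analysis runs on simulated experiments with known ground
truth, so each stage of the chain is testable end to end.

The package covers:

* **Synthetic experiments** (`fatiguelag.synthetic`) — cohorts with Gaussian
  random effects, the full trial schedules of both experimental designs
  (lags 0/+50/+83 ms crossed with metronome sound; signed lags −50…+50 ms
  with a delay-detection session in 17 ms steps), 500 Hz raised-cosine
  flexion kinematics with lognormal cycle jitter, two-channel surface EMG
  whose spectral median frequency declines with accumulated fatigue, and
  2AFC choices drawn from probit psychometric models.
* **Online cyclic-motion prediction** (`fatiguelag.predictor`) — an adaptive
  frequency oscillator with NLMS-adapted harmonics that renders visual
  feedback at negative lags (extrapolating the phase ahead of the movement),
  a quality state ω_t ∈ [0, 1] that gates untrackable trials at ω_t < 0.05,
  and cross-correlation validation of the rendered feedback.
* **Signal metrics** (`fatiguelag.signal_metrics`) — EMG band-pass
  (20–240 Hz, 4th-order Butterworth, zero-phase) + rectification, Welch
  median frequency, movement amplitude/velocity/cycle-interval indices, and
  the baseline-normalized change ΔI = (I_comparison − I_standard)/I_baseline.
* **Psychometric mixed models** (`fatiguelag.glmm`) — three probit GLMMs for
  the fatigue choice probability, fitted by maximizing the
  Laplace-approximated marginal likelihood and compared by AIC:

  * Model 1: P_i(x) = Φ(α + α_i + (β + β_i)·x)
  * Model 2: P_i(x) = Φ(α + α^d_i + (β^d + β^d_i)·P^d_i(x))
  * Model 3: both predictors, with the union of the random effects,

  where x is the visual lag (ms) and P^d_i(x) the participant's own
  delay-detection probability; random effects are independent Gaussians per
  participant.
* **Inferential statistics** (`fatiguelag.stats`) — one-sample/paired
  t-tests with Cohen's d, Bonferroni–Holm adjustment, two-way
  repeated-measures ANOVA with partial η², and power analysis via the
  noncentral t distribution.
* **Orchestration** (`fatiguelag.pipeline`, `fatiguelag` CLI) — one JSON
  config drives simulate → render/validate → metrics → fits → stats, with
  SHA-256 manifests for reproducibility.

## Worked example

```python
from fatiguelag import synthetic as syn
from fatiguelag.pipeline import fit_psychometrics

cfg = syn.experiment1_config(n_participants=14, blocks=15, seed=23)
cohort, truth = syn.make_cohort(cfg, seed=23, model_id=1)
trials = syn.build_dataset(cfg, cohort, truth, seed=23)
psych = fit_psychometrics(trials)
print(psych["ranking"].to_string(index=False))
```

prints

```
 model_id  k       loglik         aic  converged  delta_aic  best
        1  4 -1289.646282 2587.292564       True   0.000000  True
        3  7 -1289.646253 2593.292506       True   5.999942 False
        2  4 -1300.013570 2608.027140       True  20.734576 False
```

The data were generated under Model 1 (fatigue probability driven directly
by the lag), and the AIC ranking recovers that: Model 3 nests Model 1 but
pays for its three extra parameters, and Model 2 (fatigue driven by the
perceived delay) fits worst.  The fitted slope β̂ = 0.0070/ms against a
generating β = 0.0080/ms; at +50 ms this puts the fatigue choice
probability near Φ(0.35) ≈ 0.64, matching the simulated cohort's observed
0.67.

The numbered drivers under `analysis/` run the full study sequence and
write tables to `results/`:

```bash
python analysis/01_simulate_experiments.py        # trial tables + choice rates
python analysis/02_validate_preceding_feedback.py # predictor fidelity
python analysis/03_movement_and_emg_metrics.py    # kinematic/EMG indices
python analysis/04_fit_psychometric_models.py     # GLMMs + AIC + slopes
python analysis/05_inferential_statistics.py      # t-tests, ANOVA, power
```

For example, `02_validate_preceding_feedback.py` reports

```
120 trials simulated; 10.0% excluded by the omega_t < 0.05 gate
lag -50 ms: peak r = 0.9939 (sem 0.0011), recovered lag = -50.6 ms (sem 0.29)
lag -33 ms: peak r = 0.9954 (sem 0.0013), recovered lag = -33.4 ms (sem 0.14)
```

i.e. the rendered feedback precedes the jittered movement by almost exactly
the nominal lead, with near-unity cross-correlation on retained trials.

## Documentation

`docs/methods.md` describes the generative models, the predictor design,
the Laplace approximation, every tunable parameter with its default and
rationale, and the known limitations of the synthetic approach.
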