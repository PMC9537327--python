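"""Online prediction of quasi-periodic movement for lagged visual feedback.

To display visual feedback that *precedes* the ongoing movement (a negative
lag), the renderer must extrapolate the trajectory into the near future.
Cyclic finger flexion is predictable over tens of milliseconds, so the
predictor maintains an adaptive oscillator locked to the movement:

* an instantaneous phase ``phi`` and angular frequency ``omega`` advanced
  every capture sample and pulled toward the observation by a normalized
  gradient (phase-locked-loop) correction,
* a harmonic model ``y(phi) = c0 + sum_k a_k cos(k phi) + b_k sin(k phi)``
  (K = 4 harmonics) whose coefficients adapt by normalized least mean
  squares,
* a quality state ``omega_t`` in [0, 1]: one minus the exponentially
  smoothed one-step squared prediction error normalized by the smoothed
  signal variance.  Trials whose minimum quality falls below 0.05 are
  excluded from analysis.

Positive lags are rendered from a delay buffer of past samples; negative
lags evaluate the harmonic model at ``phi + omega * |lag|``.  Rendering is
strictly causal: the displayed value at time t never uses samples after t.

Validation follows the study protocol: the normalized cross-correlation
between the actual trajectory and the displayed feedback is maximized over
a +/-250 ms lag window, with sub-sample refinement by parabolic
interpolation around the discrete peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Trace, CAPTURE_HZ, DISPLAY_HZ

__all__ = [
    "PredictorParams",
    "CyclicPredictor",
    "LagValidation",
    "render_lagged_feedback",
    "validate_lag",
    "gate_by_quality",
]

OMEGA_THRESHOLD = 0.05
MAX_POSITIVE_LAG_MS = 83.0
MAX_NEGATIVE_LAG_MS = 50.0


@dataclass
class PredictorParams:
    """Gains and limits of the adaptive oscillator.

    Time constants are in seconds; the per-sample NLMS/PLL step sizes are
    derived from them at the configured capture rate.
    """

    fs: float = CAPTURE_HZ
    n_harmonics: int = 4
    f0_hz: float = 2.14            # paced movement frequency (initialization)
    f_min_hz: float = 0.8
    f_max_hz: float = 4.5
    mu_coeff: float = 0.004        # NLMS step for harmonic coefficients
    mu_phase: float = 0.30         # normalized phase-correction gain
    mu_freq: float = 0.002         # fraction of phase correction fed to frequency
    burn_in_boost: float = 10.0    # coefficient-learning speedup during burn-in
    tau_quality_s: float = 1.0     # smoothing of the horizon prediction error
    tau_mean_s: float = 2.0        # smoothing of the reference signal mean
    tau_var_s: float = 10.0        # smoothing of the reference signal variance
    max_phase_step: float = 0.01   # per-sample correction clip (rad); must stay
                                   # below omega*dt so the phase can never stall
    quality_slack: float = 0.9     # error/variance ratio mapping to zero quality
    quality_horizon_s: float = 0.1 # look-ahead horizon the quality state scores
    quality_gate: float = 0.2      # below this, tracking is declared lost
    burn_in_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if not (0 < self.f_min_hz < self.f0_hz < self.f_max_hz):
            raise ValueError("require f_min < f0 < f_max")


@dataclass
class PredictorState:
    """Snapshot of the oscillator: phase, frequency, harmonics, quality."""

    phase: float
    frequency_hz: float
    coeffs: np.ndarray            # (1 + 2K,): c0, a1, b1, ..., aK, bK
    omega_t: float
    t: float


class CyclicPredictor:
    """Streaming adaptive oscillator over 500 Hz angle samples."""

    def __init__(self, params: PredictorParams | None = None):
        self.p = params or PredictorParams()
        K = self.p.n_harmonics
        self.phase = 0.0
        self.omega = 2 * np.pi * self.p.f0_hz        # rad/s
        self.w = np.zeros(1 + 2 * K)
        self.mean = 0.0
        self.var = 1e-6
        self.err_pow = 0.0
        self.n = 0
        self._dt = 1.0 / self.p.fs
        self._a_q = 1.0 - np.exp(-self._dt / self.p.tau_quality_s)
        self._a_m = 1.0 - np.exp(-self._dt / self.p.tau_mean_s)
        self._a_v = 1.0 - np.exp(-self._dt / self.p.tau_var_s)
        # ring buffer of horizon predictions: slot (n % H) holds the value
        # predicted H samples ago for the current sample
        self._H = max(1, int(round(self.p.quality_horizon_s * self.p.fs)))
        self._hbuf = np.full(self._H, np.nan)

    # -- helpers ----------------------------------------------------------

    def _regressors(self, phase: float) -> np.ndarray:
        K = self.p.n_harmonics
        k = np.arange(1, K + 1)
        h = np.empty(1 + 2 * K)
        h[0] = 1.0
        h[1::2] = np.cos(k * phase)
        h[2::2] = np.sin(k * phase)
        return h

    def predict_at(self, phase: float) -> float:
        """Harmonic model evaluated at an arbitrary phase."""
        return float(self.w @ self._regressors(phase))

    @property
    def omega_t(self) -> float:
        """Prediction-quality state in [0, 1].

        One minus the smoothed squared error of the 100 ms look-ahead
        prediction, normalized by the smoothed signal variance; the slack
        factor maps any error at or above 90% of the signal variance
        (prediction no better than the mean) to zero.  Scoring a horizon
        rather than one step means an unpredictable input cannot earn
        quality by being chased sample-to-sample.
        """
        q = 1.0 - self.err_pow / (self.p.quality_slack * max(self.var, 1e-12))
        return float(min(1.0, max(0.0, q)))

    @property
    def frequency_hz(self) -> float:
        return self.omega / (2 * np.pi)

    @property
    def ready(self) -> bool:
        return self.n >= int(self.p.burn_in_s * self.p.fs)

    def state(self) -> PredictorState:
        return PredictorState(self.phase, self.frequency_hz, self.w.copy(),
                              self.omega_t, self.n * self._dt)

    # -- core update ------------------------------------------------------

    def step(self, y: float) -> PredictorState:
        """Consume one capture sample; advance phase, adapt, update quality."""
        if not np.isfinite(y):
            raise ValueError("non-finite sample in input stream")
        K = self.p.n_harmonics
        h = self._regressors(self.phase)
        y_hat = float(self.w @ h)
        e = y - y_hat

        # quality bookkeeping: error of the prediction made one horizon ago
        # (falls back to the one-step error until the buffer is warm)
        self.mean += self._a_m * (y - self.mean)
        self.var += self._a_v * ((y - self.mean) ** 2 - self.var)
        y_h = self._hbuf[self.n % self._H]
        e_q = (y - y_h) if np.isfinite(y_h) else e
        self.err_pow += self._a_q * (e_q * e_q - self.err_pow)

        # harmonic coefficients: NLMS.  Learning is boosted while the model
        # bootstraps from zero and afterwards gated by the quality state, so
        # an unpredictable input (noise, a frozen trace) is not slowly
        # memorized, which would mask the quality collapse the gate needs.
        if self.ready:
            q = self.omega_t
            mu = self.p.mu_coeff * q if q > self.p.quality_gate else 0.0
        else:
            mu = self.p.mu_coeff * self.p.burn_in_boost
        self.w += mu * e * h / (h @ h)

        # phase: PLL correction along the model gradient
        k = np.arange(1, K + 1)
        dydphi = float(np.sum(k * (-self.w[1::2] * np.sin(k * self.phase)
                                   + self.w[2::2] * np.cos(k * self.phase))))
        denom = dydphi * dydphi + 0.25 * self.var
        corr = self.p.mu_phase * e * dydphi / max(denom, 1e-12)
        corr = float(np.clip(corr, -self.p.max_phase_step, self.p.max_phase_step))

        # canonical-form anchoring: the NLMS update can slowly rotate the
        # harmonic phasors, which would let the phase/frequency pair drift
        # while one-step predictions stay good (a joint degeneracy).  Rotate
        # the coefficients so the fundamental is a pure negative cosine
        # (angle minimum at phase 0) and fold the rotation into the phase
        # correction, keeping the oscillator solely responsible for timing.
        a1, b1 = self.w[1], self.w[2]
        r1 = np.hypot(a1, b1)
        s = 0.0
        if r1 > 1e-3 * np.sqrt(max(self.var, 1e-12)):
            s = float(np.arctan2(b1, a1)) - np.pi
            s = (s + np.pi) % (2 * np.pi) - np.pi          # wrap to [-pi, pi)
            s = float(np.clip(s, -0.1, 0.1))
            ks = k * s
            cos_ks, sin_ks = np.cos(ks), np.sin(ks)
            a, b = self.w[1::2].copy(), self.w[2::2].copy()
            self.w[1::2] = a * cos_ks + b * sin_ks
            self.w[2::2] = b * cos_ks - a * sin_ks

        # during burn-in the phase advances feedforward at the paced rate
        # (the metronome frequency is known to the renderer); corrections
        # only engage once the harmonic model is established, otherwise the
        # bootstrap transient biases the loop.  They disengage again when
        # quality collapses, so the oscillator free-runs instead of parking
        # its phase on an untrackable input.
        engaged = self.ready and self.omega_t > self.p.quality_gate
        total_corr = (corr - s) if engaged else 0.0
        self.phase += self.omega * self._dt + total_corr
        self.omega += self.p.mu_freq * total_corr / self._dt
        self.omega = float(np.clip(self.omega, 2 * np.pi * self.p.f_min_hz,
                                   2 * np.pi * self.p.f_max_hz))
        self.n += 1
        # store the look-ahead prediction this state makes for the sample one
        # horizon ahead of the one just consumed; it is read back, and scored
        # against the observation, when that sample arrives
        ahead = (self._H - 1) * self._dt
        self._hbuf[(self.n - 1) % self._H] = self.predict_at(self.phase + self.omega * ahead)
        return self.state()


def render_lagged_feedback(
    angle: Trace,
    lag_ms: float,
    params: PredictorParams | None = None,
    display_rate_hz: float = DISPLAY_HZ,
    burn_in_s: float | None = None,
) -> tuple[Trace, np.ndarray]:
    """Offline driver: stream a 500 Hz trace through the predictor and render
    the displayed-angle track at the display rate.

    lag_ms > 0 emits buffered past samples delayed by ``lag_ms`` (linear
    interpolation on the capture buffer); lag_ms < 0 evaluates the harmonic
    reconstruction ahead of the current phase; lag_ms = 0 passes the signal
    through resampled to the display clock.  Returns the displayed track and
    the per-capture-sample quality series ``omega_t``.

    Negative lags require predictor burn-in: the displayed track starts only
    once the oscillator has seen ``burn_in_s`` of data (NaN before that).
    """
    params = params or PredictorParams(fs=angle.fs)
    if lag_ms > MAX_POSITIVE_LAG_MS or -lag_ms > MAX_NEGATIVE_LAG_MS:
        raise ValueError(
            f"lag {lag_ms} ms outside supported range "
            f"[-{MAX_NEGATIVE_LAG_MS}, +{MAX_POSITIVE_LAG_MS}] ms")
    burn = params.burn_in_s if burn_in_s is None else burn_in_s
    if lag_ms < 0 and angle.duration_s <= burn:
        raise ValueError("trace shorter than predictor burn-in; negative lag not ready")

    y = np.asarray(angle.data, dtype=float)
    fs = angle.fs
    dt = 1.0 / fs
    pred = CyclicPredictor(params)
    n_disp = int(np.floor(angle.duration_s * display_rate_hz))
    t_disp = np.arange(n_disp) / display_rate_hz
    displayed = np.full(n_disp, np.nan)
    omega_series = np.empty(y.size)

    lag_s = lag_ms / 1000.0
    j = 0  # next display tick index
    for i in range(y.size):
        pred.step(y[i])
        omega_series[i] = pred.omega_t
        t_now = (i + 1) * dt  # time just after consuming sample i
        while j < n_disp and t_disp[j] < t_now:
            td = t_disp[j]
            if lag_ms > 0 or lag_ms == 0:
                ts = td - lag_s
                if ts < 0:
                    displayed[j] = y[0]
                else:
                    k = min(int(ts * fs), i)          # causal: sample index <= i
                    k1 = min(k + 1, i)
                    frac = ts * fs - k
                    displayed[j] = y[k] + frac * (y[k1] - y[k])
            else:
                if (i + 1) * dt >= burn:
                    # the oscillator phase refers to the next capture instant
                    # (i+1)*dt; lead from there to the display tick plus |lag|
                    ahead = (td - (i + 1) * dt) - lag_s
                    displayed[j] = pred.predict_at(pred.phase + pred.omega * ahead)
            j += 1
    return Trace(display_rate_hz, displayed), omega_series


@dataclass
class LagValidation:
    """Peak normalized cross-correlation and its signed lag."""

    peak: float
    lag_ms: float
    omega_min: float = np.nan
    excluded: bool = False

    def to_dict(self) -> dict:
        return {"peak": self.peak, "lag_ms": self.lag_ms,
                "omega_min": self.omega_min, "excluded": self.excluded}


def validate_lag(
    actual: Trace,
    displayed: Trace,
    max_lag_ms: float = 250.0,
    window_s: tuple[float, float] | None = None,
) -> LagValidation:
    """Cross-correlate the displayed feedback against the actual movement.

    Both signals are restricted to ``window_s`` (their overlap by default),
    interpolated onto the actual trace's capture grid, mean-removed, and
    correlated over integer lags within +/-``max_lag_ms``.  The reported lag
    is positive when the displayed track lags (is delayed relative to) the
    actual movement and negative when it precedes it; the discrete argmax is
    refined by parabolic interpolation.
    """
    fs = actual.fs
    t_a = actual.t
    t_d = displayed.t
    valid = np.isfinite(displayed.data)
    if valid.sum() < 2:
        raise ValueError("displayed track has no valid samples")
    lo = max(t_a[0], t_d[valid][0])
    hi = min(t_a[-1], t_d[valid][-1])
    if window_s is not None:
        lo, hi = max(lo, window_s[0]), min(hi, window_s[1])
    if hi - lo < 2.0 / 2.14:
        raise ValueError("overlapping support shorter than two cycles")

    grid = t_a[(t_a >= lo) & (t_a <= hi)]
    a = np.interp(grid, t_a, actual.data)
    d = np.interp(grid, t_d[valid], displayed.data[valid])
    a = a - a.mean()
    d = d - d.mean()
    if np.allclose(a, 0) or np.allclose(d, 0):
        raise ValueError("degenerate (constant) input: correlation undefined")

    max_shift = int(round(max_lag_ms * fs / 1000.0))
    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.empty(shifts.size)
    n = a.size
    for idx, s in enumerate(shifts):
        # displayed(t) vs actual(t - s/fs): positive s = displayed delayed
        if s >= 0:
            x1, x2 = d[s:], a[: n - s]
        else:
            x1, x2 = d[: n + s], a[-s:]
        denom = np.sqrt(np.dot(x1, x1) * np.dot(x2, x2))
        r[idx] = np.dot(x1, x2) / denom if denom > 0 else 0.0

    k = int(np.argmax(r))
    lag_samples = float(shifts[k])
    peak = float(r[k])
    if 0 < k < r.size - 1:
        # parabolic sub-sample refinement around the discrete peak
        y0, y1, y2 = r[k - 1], r[k], r[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            lag_samples += float(np.clip(delta, -1, 1))
            peak = float(y1 - 0.25 * (y0 - y2) * np.clip(delta, -1, 1))
    return LagValidation(peak=min(peak, 1.0), lag_ms=lag_samples * 1000.0 / fs)


def gate_by_quality(records: pd.DataFrame, threshold: float = OMEGA_THRESHOLD
                    ) -> tuple[pd.DataFrame, float]:
    """Flag trials whose minimum prediction quality fell below threshold.

    Returns the records with an ``excluded`` column set and the exclusion
    fraction computed over negative-lag trials only (positive and zero lags
    need no prediction, hence are never excluded).
    """
    out = records.copy()
    negative = out["lag_ms"] < 0
    out["excluded"] = (negative & (out["omega_min"] < threshold)).astype(int)
    n_neg = int(negative.sum())
    frac = float(out.loc[negative, "excluded"].mean()) if n_neg else 0.0
    return out, frac
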