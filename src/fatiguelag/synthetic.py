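"""Synthetic 2AFC fatigue/delay-perception experiments with known ground truth.

Emulates a paced cyclic finger-flexion paradigm: participants flex and
extend the index finger at 2.14 Hz between target lines while watching an
avatar whose visual feedback is shifted in time (positive lag = delayed,
negative lag = preceding).  On each trial they compare two phases of a test
period and report, two-alternative forced choice, in which phase they felt
more muscle fatigue (fatigue session) or a larger visual asynchrony (delay
session).

The generator produces, for a whole cohort:

* trial schedules for two experimental designs (Experiment 1: lags
  0/+50/+83 ms crossed with metronome sound on/off; Experiment 2: lags
  -50/-33/0/+33/+50 ms, plus a delay session in 17 ms steps),
* flexion-angle traces at 500 Hz (raised-cosine cycles with multiplicative
  lognormal period jitter) and a 60 Hz display track,
* two-channel surface EMG whose spectral median frequency declines with a
  per-block fatigue state,
* binary choices drawn from probit psychometric models with Gaussian
  participant random effects.

Every dataset carries a :class:`GroundTruth` sufficient to recompute the
exact Bernoulli probability of every simulated choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "Trace",
    "ExperimentConfig",
    "ParticipantParams",
    "CohortHyper",
    "GroundTruth",
    "BlockSimulation",
    "experiment1_config",
    "experiment2_config",
    "make_cohort",
    "build_schedule",
    "simulate_block",
    "simulate_choices",
    "build_dataset",
]

CAPTURE_HZ = 500.0
DISPLAY_HZ = 60.0

# sub-stream purposes for deterministic seed derivation
_PURPOSE = {"cohort": 0, "schedule": 1, "kinematics": 2, "emg": 3,
            "choices_fatigue": 4, "choices_delay": 5}


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream: master seed plus a stable integer key path."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


@dataclass
class Trace:
    """A uniformly sampled time series with sampling-rate metadata."""

    fs: float
    data: np.ndarray

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.data.shape[-1]) / self.fs

    @property
    def duration_s(self) -> float:
        return self.data.shape[-1] / self.fs


@dataclass
class TrialLayout:
    """Durations (s) of the periods making up one trial."""

    preparation_s: float
    phase_s: float = 4.0
    gap_s: float = 1.0
    response_s: float = 2.0

    @property
    def test_s(self) -> float:
        return 2 * self.phase_s + self.gap_s

    @property
    def trial_s(self) -> float:
        return self.preparation_s + self.test_s + self.response_s

    def phase_window(self, phase: int) -> tuple[float, float]:
        """(start, end) of test phase 1 or 2, relative to trial onset."""
        if phase == 1:
            return self.preparation_s, self.preparation_s + self.phase_s
        if phase == 2:
            t0 = self.preparation_s + self.phase_s + self.gap_s
            return t0, t0 + self.phase_s
        raise ValueError(f"phase must be 1 or 2, got {phase}")


@dataclass
class ExperimentConfig:
    experiment_id: int
    movement_frequency_hz: float
    lag_conditions_ms: tuple[int, ...]          # comparison lags, fatigue session
    delay_session_lags_ms: tuple[int, ...]      # comparison lags, delay session
    n_participants: int
    blocks_per_participant: int
    delay_session_blocks: int
    trials_per_block: int
    delay_session_trials_per_block: int
    trial_layout: TrialLayout
    sound_conditions: tuple[int, ...]           # (1, 0) if sound is a factor
    target_span_deg: tuple[float, float]        # per-participant amplitude range
    span_reduction: dict[int, float]            # |lag| ms -> fractional reduction
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lay = self.trial_layout
        for d in (lay.preparation_s, lay.phase_s, lay.gap_s, lay.response_s):
            if d <= 0:
                raise ValueError("all trial-layout durations must be positive")
        n_cells = len(self.sound_conditions) * (
            sum(2 for l in self.lag_conditions_ms if l != 0) + (1 if 0 in self.lag_conditions_ms else 0)
        ) if self.experiment_id == 1 else 2 * len(self.lag_conditions_ms)
        if self.trials_per_block != n_cells:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} does not match the "
                f"{n_cells} (lag x phase x sound) cells of the design")
        if self.experiment_id == 2:
            lags = sorted(self.lag_conditions_ms)
            if lags != sorted(-l for l in lags):
                raise ValueError("experiment 2 lag conditions must be symmetric around 0")

    @property
    def block_s(self) -> float:
        return self.trials_per_block * self.trial_layout.trial_s


def experiment1_config(n_participants: int = 14, blocks: int = 15, seed: int = 0) -> ExperimentConfig:
    """Design of Experiment 1: lags 0/+50/+83 ms crossed with sound on/off.

    Blocks of 190 s = 10 trials x (8 s preparation + 9 s test + 2 s response);
    target-span reduction of 3.6% at +50 ms and 6% at +83 ms.
    """
    return ExperimentConfig(
        experiment_id=1,
        movement_frequency_hz=2.14,
        lag_conditions_ms=(0, 50, 83),
        delay_session_lags_ms=(0, 50, 83),
        n_participants=n_participants,
        blocks_per_participant=blocks,
        delay_session_blocks=12,
        trials_per_block=10,
        delay_session_trials_per_block=10,
        trial_layout=TrialLayout(preparation_s=8.0),
        sound_conditions=(1, 0),
        target_span_deg=(38.0, 55.0),
        span_reduction={50: 0.036, 83: 0.06},
        rng_seed=seed,
    )


def experiment2_config(n_participants: int = 14, blocks: int = 15, seed: int = 0) -> ExperimentConfig:
    """Design of Experiment 2: signed lags -50..+50 ms, no sound factor.

    Blocks of 180 s = 10 trials x (7 s preparation + 9 s test + 2 s response);
    the delay session uses lags in 17 ms steps over 10 blocks of 14 trials.
    """
    return ExperimentConfig(
        experiment_id=2,
        movement_frequency_hz=2.14,
        lag_conditions_ms=(-50, -33, 0, 33, 50),
        delay_session_lags_ms=(-50, -33, -17, 0, 17, 33, 50),
        n_participants=n_participants,
        blocks_per_participant=blocks,
        delay_session_blocks=10,
        trials_per_block=10,
        delay_session_trials_per_block=14,
        trial_layout=TrialLayout(preparation_s=7.0),
        sound_conditions=(0,),
        target_span_deg=(38.0, 55.0),
        span_reduction={50: 0.024, 33: 0.016},
        rng_seed=seed,
    )


@dataclass
class CohortHyper:
    """Hyperdistribution of the cohort: psychometric fixed effects,
    random-effect SDs, and physiology parameters.

    Lags enter the linear predictors in milliseconds, so slopes are per ms.
    Defaults place the fatigue choice rate near 0.66 at +50 ms and delay
    detectability near 0.84 at +50 ms, with between-participant spread on
    both bias and slope.
    """

    # fatigue-task psychometric Phi(alpha + a_i + (beta + b_i) x)
    alpha: float = 0.0
    beta: float = 0.008            # per ms
    sd_alpha_i: float = 0.2
    sd_beta_i: float = 0.003
    # delay-detection psychometric Phi(det_alpha + a_i + (det_beta + b_i) x)
    det_alpha: float = 0.0
    det_beta: float = 0.02         # per ms
    sd_det_alpha_i: float = 0.2
    sd_det_beta_i: float = 0.006
    # coefficients on the delay-response predictor P_d (generating models 2/3)
    beta_d: float = 1.0
    sd_alpha_d_i: float = 0.2
    sd_beta_d_i: float = 0.3
    # correlation induced between fatigue and detection slope deviations
    slope_corr: float = 0.0
    # constant additive order bias on the linear predictor, signed by the
    # phase holding the comparison (+delta if phase 1); for pooling tests
    order_bias: float = 0.0
    # movement and EMG physiology
    jitter_cv: float = 0.03
    drift_hz_per_block: float = 1.0
    mf0_mean_hz: float = 110.0
    mf0_sd_hz: float = 5.0
    mf_log_bandwidth: float = 0.35
    emg_scale_mv: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sd_alpha_i", "sd_beta_i", "sd_det_alpha_i", "sd_det_beta_i",
                     "sd_alpha_d_i", "sd_beta_d_i", "mf0_sd_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.slope_corr <= 1.0:
            raise ValueError("slope_corr must lie in [-1, 1]")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        if self.drift_hz_per_block < 0:
            raise ValueError("drift_hz_per_block must be >= 0")


@dataclass
class ParticipantParams:
    """One synthetic participant: psychometric deviations and physiology."""

    id: int
    alpha_i: float
    beta_i: float
    det_alpha_i: float
    det_beta_i: float
    alpha_d_i: float
    beta_d_i: float
    amplitude_deg: float
    jitter_cv: float
    drift_hz_per_block: float
    mf0_hz: float
    mf_log_bandwidth: float
    order_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        if self.drift_hz_per_block < 0:
            raise ValueError("drift rate must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to recompute every choice probability exactly."""

    model_id: int                       # generating model for fatigue choices
    hyper: CohortHyper
    participants: list[ParticipantParams]

    def p_delay(self, pid: int, x_ms: float) -> float:
        """True delay-detection choice probability at lag x (ms)."""
        p = self.participants[pid]
        h = self.hyper
        return float(ndtr(h.det_alpha + p.det_alpha_i + (h.det_beta + p.det_beta_i) * x_ms))

    def p_fatigue(self, pid: int, x_ms: float) -> float:
        """True fatigue choice probability at lag x under the generating model."""
        p = self.participants[pid]
        h = self.hyper
        if self.model_id == 1:
            eta = h.alpha + p.alpha_i + (h.beta + p.beta_i) * x_ms
        elif self.model_id == 2:
            eta = h.alpha + p.alpha_d_i + (h.beta_d + p.beta_d_i) * self.p_delay(pid, x_ms)
        elif self.model_id == 3:
            eta = (h.alpha + p.alpha_i + p.alpha_d_i + (h.beta + p.beta_i) * x_ms
                   + (h.beta_d + p.beta_d_i) * self.p_delay(pid, x_ms))
        else:
            raise ValueError(f"unknown generating model {self.model_id}")
        return float(ndtr(eta))


def make_cohort(
    config: ExperimentConfig,
    hyper: CohortHyper | None = None,
    seed: int | None = None,
    model_id: int = 1,
) -> tuple[list[ParticipantParams], GroundTruth]:
    """Draw a cohort from the Gaussian hyperdistributions.

    Fatigue-slope and detection-slope deviations may be correlated
    (``hyper.slope_corr``); all other random effects are independent.
    Deterministic given the seed.
    """
    hyper = hyper if hyper is not None else CohortHyper()
    if config.n_participants < 1:
        raise ValueError("need at least one participant")
    seed = config.rng_seed if seed is None else seed
    rng = _rng(seed, _PURPOSE["cohort"])

    participants = []
    rho = hyper.slope_corr
    for i in range(config.n_participants):
        # correlated slope deviations via an explicit Cholesky factor, which
        # stays well-defined when either SD is zero
        z1, z2 = rng.standard_normal(2)
        beta_i = hyper.sd_beta_i * z1
        det_beta_i = hyper.sd_det_beta_i * (rho * z1 + np.sqrt(1.0 - rho ** 2) * z2)
        lo, hi = config.target_span_deg
        participants.append(ParticipantParams(
            id=i,
            alpha_i=rng.normal(0.0, hyper.sd_alpha_i),
            beta_i=float(beta_i),
            det_alpha_i=rng.normal(0.0, hyper.sd_det_alpha_i),
            det_beta_i=float(det_beta_i),
            alpha_d_i=rng.normal(0.0, hyper.sd_alpha_d_i),
            beta_d_i=rng.normal(0.0, hyper.sd_beta_d_i),
            amplitude_deg=float(rng.uniform(lo, hi)),
            jitter_cv=hyper.jitter_cv,
            drift_hz_per_block=hyper.drift_hz_per_block,
            mf0_hz=float(rng.normal(hyper.mf0_mean_hz, hyper.mf0_sd_hz)),
            mf_log_bandwidth=hyper.mf_log_bandwidth,
            order_bias=hyper.order_bias,
        ))
    return participants, GroundTruth(model_id=model_id, hyper=hyper, participants=participants)


# ---------------------------------------------------------------------------
# trial schedules
# ---------------------------------------------------------------------------

def _block_cells(config: ExperimentConfig, session: str, rng: np.random.Generator) -> list[dict]:
    """The (lag, phase, sound) cells of one block, in randomized order."""
    lags = (config.lag_conditions_ms if session == "fatigue"
            else config.delay_session_lags_ms)
    cells = []
    if config.experiment_id == 1:
        # nonzero lags appear once per phase; the 0 ms cell appears once with
        # a randomly assigned phase; all crossed with sound
        for sound in config.sound_conditions:
            for lag in lags:
                if lag == 0:
                    cells.append({"lag_ms": 0, "comparison_phase": int(rng.integers(1, 3)),
                                  "sound": sound})
                else:
                    cells.append({"lag_ms": lag, "comparison_phase": 1, "sound": sound})
                    cells.append({"lag_ms": lag, "comparison_phase": 2, "sound": sound})
    else:
        # each signed lag once per phase, no sound factor in the test period
        for lag in lags:
            for phase in (1, 2):
                cells.append({"lag_ms": lag, "comparison_phase": phase, "sound": 0})
    order = rng.permutation(len(cells))
    return [cells[k] for k in order]


def build_schedule(
    config: ExperimentConfig,
    participant_id: int,
    session: str = "fatigue",
    seed: int | None = None,
) -> pd.DataFrame:
    """Randomized trial schedule for one participant and session.

    Columns: block, trial, lag_ms, comparison_phase, sound.
    """
    if session not in ("fatigue", "delay"):
        raise ValueError("session must be 'fatigue' or 'delay'")
    seed = config.rng_seed if seed is None else seed
    n_blocks = (config.blocks_per_participant if session == "fatigue"
                else config.delay_session_blocks)
    rows = []
    for b in range(n_blocks):
        rng = _rng(seed, _PURPOSE["schedule"], participant_id,
                   b, 0 if session == "fatigue" else 1)
        for t, cell in enumerate(_block_cells(config, session, rng)):
            rows.append({"block": b, "trial": t, **cell})
    df = pd.DataFrame(rows)
    expected = (config.trials_per_block if session == "fatigue"
                else config.delay_session_trials_per_block)
    got = df.groupby("block").size().unique()
    if list(got) != [expected]:
        raise RuntimeError(f"schedule produced {got} trials per block, expected {expected}")
    return df


# ---------------------------------------------------------------------------
# kinematics and EMG
# ---------------------------------------------------------------------------

@dataclass
class BlockSimulation:
    """Simulated traces and logs for one experimental block."""

    angle: Trace                 # flexion angle (deg) at 500 Hz
    display: Trace               # 60 Hz track driving the avatar (no added lag)
    emg: Trace                   # shape (2, n): flexor, extensor (mV)
    cycles: pd.DataFrame         # start_s, period_s, amplitude_deg
    segments: pd.DataFrame       # trial, segment, t0_s, t1_s, lag_ms, is_comparison, sound
    median_frequency_target_hz: float


def _trial_segments(config: ExperimentConfig, schedule_block: pd.DataFrame) -> pd.DataFrame:
    lay = config.trial_layout
    rows = []
    for _, tr in schedule_block.iterrows():
        off = tr["trial"] * lay.trial_s
        segs = [
            ("preparation", 0.0, lay.preparation_s, 0, False),
            ("phase1", *lay.phase_window(1), tr["lag_ms"] if tr["comparison_phase"] == 1 else 0,
             tr["comparison_phase"] == 1),
            ("gap", lay.phase_window(1)[1], lay.phase_window(2)[0], 0, False),
            ("phase2", *lay.phase_window(2), tr["lag_ms"] if tr["comparison_phase"] == 2 else 0,
             tr["comparison_phase"] == 2),
            ("response", lay.trial_s - lay.response_s, lay.trial_s, 0, False),
        ]
        for name, t0, t1, lag, is_cmp in segs:
            rows.append({"trial": int(tr["trial"]), "segment": name,
                         "t0_s": off + t0, "t1_s": off + t1,
                         "lag_ms": int(lag), "is_comparison": bool(is_cmp),
                         "sound": int(tr["sound"])})
    return pd.DataFrame(rows)


def _shaped_emg_noise(n: int, fs: float, target_mf_hz: float, log_bw: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise whose in-band [20, 240] Hz spectral median equals
    the target, produced by FFT shaping with a lognormal magnitude profile."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    in_band = (freqs >= 20.0) & (freqs <= 240.0)

    def in_band_median(log_mu: float) -> float:
        s = np.zeros_like(freqs)
        f = freqs[in_band]
        s_band = np.exp(-((np.log(f) - log_mu) ** 2) / (2 * log_bw ** 2)) / f
        cum = np.cumsum(s_band)
        return float(np.interp(0.5 * cum[-1], cum, f))

    # solve for the lognormal location giving the requested in-band median
    lo, hi = np.log(25.0), np.log(235.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if in_band_median(mid) < target_mf_hz:
            lo = mid
        else:
            hi = mid
    log_mu = 0.5 * (lo + hi)

    shape = np.zeros_like(freqs)
    fpos = freqs[in_band]
    shape[in_band] = np.sqrt(np.exp(-((np.log(fpos) - log_mu) ** 2) / (2 * log_bw ** 2)) / fpos)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_block(
    participant: ParticipantParams,
    config: ExperimentConfig,
    block_index: int,
    schedule_block: pd.DataFrame,
    seed: int | None = None,
    session: str = "fatigue",
    emg_scale_mv: float = 0.5,
) -> BlockSimulation:
    """Simulate one block: flexion angle, display track, and two-channel EMG.

    Cycles are raised cosines (angle 0 = extended, amplitude = flexed) whose
    periods are 1/f perturbed by multiplicative lognormal jitter; amplitude
    follows the participant's target span with the configured span reduction
    during comparison phases.  EMG median frequency declines linearly with
    the block index at the participant's drift rate; the flexor channel is
    amplitude-gated by the flexion half-cycle and the extensor by the
    extension half-cycle.
    """
    seed = config.rng_seed if seed is None else seed
    if not set(schedule_block["trial"]) == set(range(len(schedule_block))):
        raise ValueError("schedule block must contain consecutively numbered trials")
    expected = (config.trials_per_block if session == "fatigue"
                else config.delay_session_trials_per_block)
    if len(schedule_block) != expected:
        raise ValueError(
            f"block duration inconsistent with trial layout: {len(schedule_block)} trials, "
            f"expected {expected}")

    segments = _trial_segments(config, schedule_block)
    block_s = len(schedule_block) * config.trial_layout.trial_s
    fs = CAPTURE_HZ
    n = int(round(block_s * fs))
    t = np.arange(n) / fs

    kin_rng = _rng(seed, _PURPOSE["kinematics"], participant.id, block_index,
                   0 if session == "fatigue" else 1)

    # cycle-by-cycle phase: period = (1/f) * lognormal(mean 1, given CV)
    t0_period = 1.0 / config.movement_frequency_hz
    cv = participant.jitter_cv
    if cv > 0:
        sigma2 = np.log1p(cv ** 2)
        mu = -0.5 * sigma2
    starts, periods = [], []
    tc = 0.0
    while tc < block_s:
        jit = float(np.exp(kin_rng.normal(mu, np.sqrt(sigma2)))) if cv > 0 else 1.0
        starts.append(tc)
        periods.append(t0_period * jit)
        tc += periods[-1]
    starts = np.asarray(starts)
    periods = np.asarray(periods)

    # amplitude per cycle from the segment containing the cycle midpoint
    reduction = np.zeros(len(starts))
    mids = starts + periods / 2
    cmp_segs = segments[segments["is_comparison"] & (segments["lag_ms"] != 0)]
    for _, seg in cmp_segs.iterrows():
        mask = (mids >= seg["t0_s"]) & (mids < seg["t1_s"])
        reduction[mask] = config.span_reduction.get(abs(int(seg["lag_ms"])), 0.0)
    amplitudes = participant.amplitude_deg * (1.0 - reduction)

    cyc_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    u = (t - starts[cyc_idx]) / periods[cyc_idx]          # cycle phase in [0, 1)
    angle = amplitudes[cyc_idx] * 0.5 * (1.0 - np.cos(2 * np.pi * u))

    n_disp = int(round(block_s * DISPLAY_HZ))
    t_disp = np.arange(n_disp) / DISPLAY_HZ
    display = np.interp(t_disp, t, angle)

    # EMG: spectrally shaped noise gated by movement phase
    emg_rng = _rng(seed, _PURPOSE["emg"], participant.id, block_index,
                   0 if session == "fatigue" else 1)
    mf_target = max(40.0, participant.mf0_hz - participant.drift_hz_per_block * block_index)
    flex_env = 0.3 + 0.7 * np.maximum(0.0, np.sin(2 * np.pi * u))
    ext_env = 0.3 + 0.7 * np.maximum(0.0, -np.sin(2 * np.pi * u))
    flexor = emg_scale_mv * flex_env * _shaped_emg_noise(
        n, fs, mf_target, participant.mf_log_bandwidth, emg_rng)
    extensor = emg_scale_mv * ext_env * _shaped_emg_noise(
        n, fs, mf_target, participant.mf_log_bandwidth, emg_rng)

    cycles = pd.DataFrame({"start_s": starts, "period_s": periods,
                           "amplitude_deg": amplitudes})
    return BlockSimulation(
        angle=Trace(fs, angle),
        display=Trace(DISPLAY_HZ, display),
        emg=Trace(fs, np.vstack([flexor, extensor])),
        cycles=cycles,
        segments=segments,
        median_frequency_target_hz=mf_target,
    )


def cyclic_trace(
    duration_s: float,
    frequency_hz: float = 2.14,
    amplitude_deg: float = 45.0,
    jitter_cv: float = 0.03,
    seed: int = 0,
    fs: float = CAPTURE_HZ,
    noise_deg: float = 0.0,
) -> tuple[Trace, pd.DataFrame]:
    """A single continuous jittered raised-cosine flexion trace.

    Convenience generator for predictor validation: same cycle machinery as
    :func:`simulate_block` but without a trial schedule.  Returns the trace
    and the realized cycle log (start_s, period_s).
    """
    rng = np.random.default_rng(seed)
    t0_period = 1.0 / frequency_hz
    if jitter_cv > 0:
        sigma2 = np.log1p(jitter_cv ** 2)
        mu = -0.5 * sigma2
    starts, periods = [], []
    tc = 0.0
    while tc < duration_s:
        jit = float(np.exp(rng.normal(mu, np.sqrt(sigma2)))) if jitter_cv > 0 else 1.0
        starts.append(tc)
        periods.append(t0_period * jit)
        tc += periods[-1]
    starts = np.asarray(starts)
    periods = np.asarray(periods)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    u = (t - starts[idx]) / periods[idx]
    angle = amplitude_deg * 0.5 * (1.0 - np.cos(2 * np.pi * u))
    if noise_deg > 0:
        angle = angle + rng.normal(0.0, noise_deg, size=n)
    return Trace(fs, angle), pd.DataFrame({"start_s": starts, "period_s": periods})


# ---------------------------------------------------------------------------
# choices
# ---------------------------------------------------------------------------

def simulate_choices(
    participant: ParticipantParams,
    trial_table: pd.DataFrame,
    truth: GroundTruth,
    task: str = "fatigue",
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw Bernoulli 2AFC choices from the generating psychometric model.

    Adds a ``choice_comparison`` column (1 = comparison interval judged more
    fatiguing / more delayed) and a ``p_true`` column with the exact
    Bernoulli parameter used, so simulation is auditable against the ground
    truth.  An order bias, if configured, shifts the linear predictor by
    +delta when the comparison occupied phase 1 and -delta for phase 2;
    pooling responses over phases cancels it to first order.
    """
    if task not in ("fatigue", "delay"):
        raise ValueError("task must be 'fatigue' or 'delay'")
    if task == "fatigue" and truth.model_id in (2, 3):
        # models 2/3 predict fatigue from the delay-task response probability
        # which must be well-defined for every lag in the table
        pass  # p_delay is analytic here; dependency always satisfiable
    seed = 0 if seed is None else seed
    purpose = _PURPOSE["choices_fatigue" if task == "fatigue" else "choices_delay"]
    rng = _rng(seed, purpose, participant.id)

    out = trial_table.copy()
    x = out["lag_ms"].to_numpy(dtype=float)
    p_fn = truth.p_fatigue if task == "fatigue" else truth.p_delay
    p = np.array([p_fn(participant.id, xi) for xi in x])
    if participant.order_bias != 0.0:
        from scipy.special import ndtri
        sign = np.where(out["comparison_phase"].to_numpy() == 1, 1.0, -1.0)
        p = ndtr(ndtri(np.clip(p, 1e-12, 1 - 1e-12)) + participant.order_bias * sign)
    out["p_true"] = p
    out["choice_comparison"] = (rng.random(len(out)) < p).astype(int)
    return out


def build_dataset(
    config: ExperimentConfig,
    cohort: list[ParticipantParams],
    truth: GroundTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full synthetic experiment: fatigue and delay sessions for the cohort.

    Returns one long trial table with columns participant_id, experiment,
    session, block, trial, sound, lag_ms, comparison_phase,
    choice_comparison, p_true, omega_min, excluded.  Prediction-quality
    fields default to 1.0 / not-excluded; the feedback-rendering stage
    overwrites them for negative-lag trials when traces are simulated.
    """
    seed = config.rng_seed if seed is None else seed
    frames = []
    for p in cohort:
        for session in ("fatigue", "delay"):
            sched = build_schedule(config, p.id, session=session, seed=seed)
            choices = simulate_choices(p, sched, truth, task=session
                                       if session == "delay" else "fatigue", seed=seed)
            choices.insert(0, "participant_id", p.id)
            choices.insert(1, "experiment", config.experiment_id)
            choices.insert(2, "session", session)
            frames.append(choices)
    df = pd.concat(frames, ignore_index=True)
    df["omega_min"] = 1.0
    df["excluded"] = 0
    return df


def iter_block_simulations(
    config: ExperimentConfig,
    cohort: list[ParticipantParams],
    seed: int | None = None,
    session: str = "fatigue",
) -> Iterator[tuple[ParticipantParams, int, BlockSimulation]]:
    """Lazily simulate traces for every (participant, block)."""
    seed = config.rng_seed if seed is None else seed
    n_blocks = (config.blocks_per_participant if session == "fatigue"
                else config.delay_session_blocks)
    for p in cohort:
        for b in range(n_blocks):
            sched = build_schedule(config, p.id, session=session, seed=seed)
            block = sched[sched["block"] == b].reset_index(drop=True)
            yield p, b, simulate_block(p, config, b, block, seed=seed, session=session)
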