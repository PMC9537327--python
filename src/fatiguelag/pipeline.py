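"""End-to-end orchestration: simulate -> render/validate -> metrics -> fits -> stats.

One JSON config file drives a reproducible run.  Every stage writes plain
CSV/JSON into the output directory and the manifest records SHA-256
digests, so identical (config, seed) pairs produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__, glmm, predictor, signal_metrics, stats, synthetic

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "DataError",
    "run_pipeline",
    "read_trials",
    "write_trials",
    "validate_preceding_feedback",
    "movement_metrics",
    "report_text",
]

TRIALS_COLUMNS = [
    "participant_id", "experiment", "session", "block", "trial", "sound",
    "lag_ms", "comparison_phase", "choice_comparison", "omega_min", "excluded",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Malformed data file (exit code 3)."""


class PipelineConfig(BaseModel):
    """Schema of the pipeline JSON config."""

    experiment: int = 1
    n_participants: int = Field(14, ge=2)
    blocks: int = Field(15, ge=1)
    seed: int = 0
    model_id: int = Field(1, ge=1, le=3)
    lag_conditions_ms: list[int] | None = None
    hyper: dict = Field(default_factory=dict)
    feedback_trials_per_lag: int = Field(0, ge=0)
    metrics_participants: int = Field(2, ge=0)
    metrics_blocks: int = Field(2, ge=0)

    @field_validator("experiment")
    @classmethod
    def _check_experiment(cls, v):
        if v not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        return v

    @field_validator("lag_conditions_ms")
    @classmethod
    def _check_lags(cls, v):
        if v is None:
            return v
        for lag in v:
            if lag > predictor.MAX_POSITIVE_LAG_MS or -lag > predictor.MAX_NEGATIVE_LAG_MS:
                raise ValueError(
                    f"lag {lag} ms outside configured bound "
                    f"[-{predictor.MAX_NEGATIVE_LAG_MS:.0f}, "
                    f"+{predictor.MAX_POSITIVE_LAG_MS:.0f}] ms")
        return v

    def experiment_config(self) -> synthetic.ExperimentConfig:
        base = (synthetic.experiment1_config if self.experiment == 1
                else synthetic.experiment2_config)
        cfg = base(n_participants=self.n_participants, blocks=self.blocks,
                   seed=self.seed)
        if self.lag_conditions_ms is not None:
            from dataclasses import replace
            cfg = replace(cfg, lag_conditions_ms=tuple(self.lag_conditions_ms))
        return cfg

    def cohort_hyper(self) -> synthetic.CohortHyper:
        known = set(synthetic.CohortHyper.__dataclass_fields__)
        unknown = set(self.hyper) - known
        if unknown:
            raise ConfigError(f"unknown hyper fields: {sorted(unknown)}")
        return synthetic.CohortHyper(**self.hyper)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(raw, strict=False)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# typed CSV I/O
# ---------------------------------------------------------------------------

def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    df[TRIALS_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table; column order is free but the set must match."""
    df = pd.read_csv(path, encoding="utf-8")
    got, want = set(df.columns), set(TRIALS_COLUMNS)
    if got - want:
        raise DataError(f"unknown columns in {path}: {sorted(got - want)}")
    if want - got:
        raise DataError(f"missing columns in {path}: {sorted(want - got)}")
    num = df[["lag_ms", "choice_comparison", "omega_min"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        raise DataError(f"non-finite values in {path}")
    return df[TRIALS_COLUMNS]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_trace(trace, path: str | Path, columns: list[str]) -> None:
    """Save a Trace as CSV (t_s + named channels) with a JSON sidecar
    recording the sampling rate."""
    path = Path(path)
    data = np.atleast_2d(trace.data)
    if data.shape[0] != len(columns):
        raise DataError(f"trace has {data.shape[0]} channels, "
                        f"got {len(columns)} column names")
    df = pd.DataFrame({"t_s": trace.t})
    for name, ch in zip(columns, data):
        df[name] = ch
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs_hz": trace.fs, "columns": columns}))


def read_trace(path: str | Path):
    """Read a trace written by :func:`write_trace`; returns a Trace."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    missing = [c for c in meta["columns"] if c not in df.columns]
    if missing:
        raise DataError(f"missing trace columns in {path}: {missing}")
    data = df[meta["columns"]].to_numpy(dtype=float).T
    if not np.all(np.isfinite(data)):
        raise DataError(f"non-finite samples in {path}")
    return synthetic.Trace(float(meta["fs_hz"]), data.squeeze())


# ---------------------------------------------------------------------------
# stage: preceding-feedback validation
# ---------------------------------------------------------------------------

def validate_preceding_feedback(
    lags_ms: list[float],
    n_trials: int,
    seed: int,
    jitter_cv: float = 0.03,
    amplitude_deg: float = 45.0,
    burn_in_s: float = 7.0,
    test_s: float = 9.0,
    threshold: float = predictor.OMEGA_THRESHOLD,
) -> pd.DataFrame:
    """Simulate negative-lag trials and score the rendered feedback.

    Each trial is a fresh jittered cyclic trace (burn-in + test window); the
    feedback is rendered at the requested negative lag, the cross-correlation
    peak and its lag are computed over the test window, and the minimum
    quality state over the test window decides exclusion.
    """
    rows = []
    total_s = burn_in_s + test_s
    for lag in lags_ms:
        for k in range(n_trials):
            trial_seed = int(np.random.SeedSequence(
                seed, spawn_key=(int(abs(lag)), k)).generate_state(1)[0] % (2**31))
            trace, _ = synthetic.cyclic_trace(
                total_s, jitter_cv=jitter_cv, amplitude_deg=amplitude_deg,
                seed=trial_seed)
            displayed, omega = predictor.render_lagged_feedback(trace, lag)
            val = predictor.validate_lag(trace, displayed,
                                         window_s=(burn_in_s, total_s))
            omega_min = float(omega[int(burn_in_s * trace.fs):].min())
            rows.append({"lag_ms": lag, "trial": k, "peak": val.peak,
                         "lag_est_ms": val.lag_ms, "omega_min": omega_min})
    df = pd.DataFrame(rows)
    df["excluded"] = (df["omega_min"] < threshold).astype(int)
    return df


# ---------------------------------------------------------------------------
# stage: movement / EMG metrics
# ---------------------------------------------------------------------------

def movement_metrics(
    config: synthetic.ExperimentConfig,
    cohort: list[synthetic.ParticipantParams],
    seed: int,
    n_participants: int | None = None,
    n_blocks: int | None = None,
) -> pd.DataFrame:
    """Per-trial movement and EMG indices with baseline-normalized changes.

    For every trial: amplitude, mean |velocity|, cycle interval, ARV and
    median frequency per channel, in the comparison and the standard phase;
    the per-participant baseline of each index comes from the preparation
    periods of trials without a leading delay.
    """
    sub = cohort[: (n_participants or len(cohort))]
    rows = []
    for p in sub:
        sched = synthetic.build_schedule(config, p.id, session="fatigue", seed=seed)
        blocks = sorted(sched["block"].unique())[: (n_blocks or config.blocks_per_participant)]
        for b in blocks:
            blk = sched[sched["block"] == b].reset_index(drop=True)
            sim = synthetic.simulate_block(p, config, b, blk, seed=seed)
            fs = sim.angle.fs
            emg_f = signal_metrics.emg_preprocess(sim.emg.data[0], fs)
            emg_e = signal_metrics.emg_preprocess(sim.emg.data[1], fs)
            bp_f = signal_metrics.bandpass_filter(sim.emg.data[0], fs)
            bp_e = signal_metrics.bandpass_filter(sim.emg.data[1], fs)
            for _, tr in blk.iterrows():
                segs = sim.segments[sim.segments["trial"] == tr["trial"]]
                out = {"participant_id": p.id, "block": b, "trial": int(tr["trial"]),
                       "lag_ms": int(tr["lag_ms"]), "sound": int(tr["sound"]),
                       "comparison_phase": int(tr["comparison_phase"])}
                for segname in ("phase1", "phase2", "preparation"):
                    seg = segs[segs["segment"] == segname].iloc[0]
                    i0, i1 = int(seg["t0_s"] * fs), int(seg["t1_s"] * fs)
                    role = ("comparison" if seg["is_comparison"] else
                            ("standard" if segname.startswith("phase") else "baseline"))
                    try:
                        mi = signal_metrics.cycle_metrics(sim.angle.data[i0:i1], fs)
                        amp, vel, itv = mi.amplitude_deg, mi.velocity_deg_s, mi.interval_s
                    except ValueError:
                        amp = vel = itv = np.nan
                    out[f"amplitude_{role}"] = amp
                    out[f"velocity_{role}"] = vel
                    out[f"interval_{role}"] = itv
                    out[f"arv_flexor_{role}"] = signal_metrics.arv(emg_f[i0:i1])
                    out[f"arv_extensor_{role}"] = signal_metrics.arv(emg_e[i0:i1])
                    if i1 - i0 >= int(2 * fs):
                        out[f"mf_flexor_{role}"] = signal_metrics.median_frequency(
                            bp_f[i0:i1], fs, prefiltered=True)
                        out[f"mf_extensor_{role}"] = signal_metrics.median_frequency(
                            bp_e[i0:i1], fs, prefiltered=True)
                rows.append(out)
    df = pd.DataFrame(rows)
    # baseline per participant: preparation periods of trials with no leading
    # delay (comparison in phase 2, or zero-lag trials)
    clean = df[(df["comparison_phase"] == 2) | (df["lag_ms"] == 0)]
    for index in ("amplitude", "velocity", "interval", "arv_flexor", "arv_extensor"):
        base = clean.groupby("participant_id")[f"{index}_baseline"].mean()
        df[f"delta_{index}"] = signal_metrics.delta_index(
            df[f"{index}_comparison"].to_numpy(),
            df[f"{index}_standard"].to_numpy(),
            df["participant_id"].map(base).to_numpy(),
        )
    return df


# ---------------------------------------------------------------------------
# stage: psychometrics + inferential statistics
# ---------------------------------------------------------------------------

def fit_psychometrics(trials: pd.DataFrame) -> dict:
    """Fit Models 1-3 to the fatigue session and Model 1 to the delay session."""
    ok = trials[trials["excluded"] == 0]
    fat = ok[ok["session"] == "fatigue"]
    dly = ok[ok["session"] == "delay"]
    p_delay = glmm.delay_predictor_table(dly)
    fits = {1: glmm.fit_probit_glmm(fat, model_id=1)}
    fits[2] = glmm.fit_probit_glmm(fat, model_id=2, p_delay=p_delay)
    fits[3] = glmm.fit_probit_glmm(fat, model_id=3, p_delay=p_delay)
    fit_delay = glmm.fit_probit_glmm(dly, model_id=1)
    ranking = glmm.model_comparison_aic(fits)
    r, pval = glmm.slope_correlation(fits[1], fit_delay)
    return {"fits": fits, "fit_delay": fit_delay, "ranking": ranking,
            "slope_correlation": {"r": r, "p": pval}}


def inferential_report(trials: pd.DataFrame) -> dict:
    """Chance-level t-tests per lag (Holm-adjusted) and the two RM-ANOVAs."""
    ok = trials[trials["excluded"] == 0]
    out: dict = {"tests": []}
    per = {}
    for session in ("fatigue", "delay"):
        tab = glmm.choice_table(ok[ok["session"] == session])
        per[session] = tab
        lags = sorted(tab["lag_ms"].unique())
        results = []
        for lag in lags:
            vals = tab.loc[tab["lag_ms"] == lag, "proportion"]
            results.append(stats.one_sample_t(vals, 0.5,
                                              name=f"{session} lag {lag} ms vs chance"))
        adj = stats.holm_adjust([r.p for r in results])
        for r_, a in zip(results, adj):
            r_.p_adjusted = float(a)
            out["tests"].append(r_.to_dict())
    # two-way RM-ANOVA: visual delay x task
    both = pd.concat([per["fatigue"].assign(task="fatigue"),
                      per["delay"].assign(task="delay")])
    common = set(per["fatigue"]["lag_ms"]) & set(per["delay"]["lag_ms"])
    both = both[both["lag_ms"].isin(common)]
    anova = stats.rm_anova_2way(both, subject="participant_id", factor_a="lag_ms",
                                factor_b="task", value="proportion")
    out["anova_delay_task"] = {k: v.to_dict() for k, v in anova.items()}
    # visual delay x sound, fatigue session only (when sound is a factor)
    fat = ok[ok["session"] == "fatigue"]
    if fat["sound"].nunique() > 1:
        tab = glmm.choice_table(fat, by_sound=True)
        anova_s = stats.rm_anova_2way(tab, subject="participant_id",
                                      factor_a="lag_ms", factor_b="sound",
                                      value="proportion")
        out["anova_delay_sound"] = {k: v.to_dict() for k, v in anova_s.items()}
    # the design's power anchor
    spec = stats.PowerSpec(d=1.0, alpha=0.05, power=0.8)
    out["sample_size"] = {"d": 1.0, "alpha": 0.05, "power": 0.8,
                          "minimal_n": stats.sample_size_t(spec)}
    return out


def report_text(trials: pd.DataFrame, psych: dict, infer: dict,
                feedback: pd.DataFrame | None = None) -> str:
    """Deterministic human-readable summary of a run."""
    lines = ["fatiguelag run report", "=" * 40]
    ok = trials[trials["excluded"] == 0]
    for session in ("fatigue", "delay"):
        tab = glmm.choice_table(ok[ok["session"] == session])
        pooled = tab.groupby("lag_ms")["proportion"].mean()
        lines.append(f"\nchoice probability of comparison ({session} session):")
        for lag, p in pooled.items():
            lines.append(f"  lag {lag:+4d} ms: {p:.3f}")
    lines.append("\nmodel comparison (AIC):")
    for _, row in psych["ranking"].iterrows():
        tag = " <- best" if row["best"] else ""
        lines.append(f"  Model {int(row['model_id'])}: AIC {row['aic']:.1f} "
                     f"(logL {row['loglik']:.1f}, k={int(row['k'])}){tag}")
    sc = psych["slope_correlation"]
    lines.append(f"\nfatigue vs delay sensitivity across participants: "
                 f"r = {sc['r']:.2f}, p = {sc['p']:.2f}")
    if feedback is not None and len(feedback):
        neg = feedback[feedback["lag_ms"] < 0]
        excl = 100.0 * neg["excluded"].mean() if len(neg) else 0.0
        lines.append(f"\npreceding-feedback validation "
                     f"(exclusion {excl:.1f}% of negative-lag trials):")
        kept = neg[neg["excluded"] == 0]
        for lag, grp in kept.groupby("lag_ms"):
            lines.append(f"  lag {lag:+.0f} ms: peak r = {grp['peak'].mean():.3f}, "
                         f"recovered lag = {grp['lag_est_ms'].mean():.1f} ms")
    lines.append(f"\nminimal n (one-sample t, d=1.0, alpha=0.05, power 0.8): "
                 f"{infer['sample_size']['minimal_n']}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path: str | Path, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute every stage and write tables, fits, reports and a manifest."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    exp_cfg = cfg.experiment_config()
    hyper = cfg.cohort_hyper()
    cohort, truth = synthetic.make_cohort(exp_cfg, hyper, seed=cfg.seed,
                                          model_id=cfg.model_id)
    trials = synthetic.build_dataset(exp_cfg, cohort, truth, seed=cfg.seed)

    feedback = None
    if cfg.feedback_trials_per_lag > 0:
        neg_lags = [l for l in exp_cfg.lag_conditions_ms if l < 0]
        if neg_lags:
            feedback = validate_preceding_feedback(
                [float(l) for l in neg_lags], cfg.feedback_trials_per_lag,
                seed=cfg.seed, jitter_cv=hyper.jitter_cv)
            feedback.to_csv(out / "feedback_validation.csv", index=False)

    write_trials(trials, out / "trials.csv")

    metrics = None
    if cfg.metrics_participants > 0 and cfg.metrics_blocks > 0:
        metrics = movement_metrics(exp_cfg, cohort, seed=cfg.seed,
                                   n_participants=cfg.metrics_participants,
                                   n_blocks=cfg.metrics_blocks)
        metrics.to_csv(out / "metrics.csv", index=False)

    psych = fit_psychometrics(trials)
    fits_json = {f"model_{m}": f.to_dict() for m, f in psych["fits"].items()}
    fits_json["delay_session"] = psych["fit_delay"].to_dict()
    fits_json["ranking"] = psych["ranking"].to_dict(orient="records")
    fits_json["slope_correlation"] = psych["slope_correlation"]
    (out / "fits.json").write_text(json.dumps(fits_json, indent=2))

    slopes = pd.DataFrame({
        "participant_id": psych["fits"][1].subject_effects["participant_id"],
        "slope_fatigue": psych["fits"][1].subject_slopes("x").to_numpy(),
        "slope_delay": psych["fit_delay"].subject_slopes("x").to_numpy(),
    })
    slopes.to_csv(out / "slopes.csv", index=False)

    infer = inferential_report(trials)
    (out / "stats_report.json").write_text(json.dumps(infer, indent=2))

    text = report_text(trials, psych, infer, feedback)
    (out / "report.txt").write_text(text)

    artifacts = ["trials.csv", "fits.json", "slopes.csv", "stats_report.json",
                 "report.txt"]
    if feedback is not None:
        artifacts.append("feedback_validation.csv")
    if metrics is not None:
        artifacts.append("metrics.csv")
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True).encode()).hexdigest(),
        "digests": {a: _digest(out / a) for a in artifacts},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"config": cfg, "trials": trials, "psych": psych, "infer": infer,
            "feedback": feedback, "metrics": metrics, "manifest": manifest}
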