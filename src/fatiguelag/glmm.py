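"""Probit mixed-effects psychometrics for 2AFC choice data.

Three nested generalized linear mixed models describe the probability that
a participant judges the comparison interval as more fatiguing, as a
function of the visual-feedback lag x (ms) and/or their own delay-detection
response probability P_d(x):

* Model 1:  P_i(x) = Phi(alpha + a_i + (beta + b_i) x)
* Model 2:  P_i(x) = Phi(alpha + ad_i + (beta_d + bd_i) P_d_i(x))
* Model 3:  P_i(x) = Phi(alpha + a_i + ad_i + (beta + b_i) x
                         + (beta_d + bd_i) P_d_i(x))

Random effects are independent Gaussians per participant (diagonal
covariance).  The marginal likelihood integrates them out; we maximize its
Laplace approximation: for each participant the random-effect vector is
profiled to its posterior mode by Newton iterations, and the Gaussian
curvature correction is applied.  Models are compared by
AIC = -2 logL + 2k with k = (number of fixed effects) + (number of
variance components): 4, 4 and 7 for Models 1-3.

The reported log-likelihood is that of the individual Bernoulli trials
(no binomial coefficient), so it is invariant to whether trials are passed
one per row or aggregated into counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import pearsonr, norm
import statsmodels.api as sm

__all__ = [
    "GLMMFit",
    "choice_table",
    "delay_predictor_table",
    "fit_probit_glmm",
    "model_comparison_aic",
    "slope_correlation",
]

MODEL_PARAM_COUNT = {1: 4, 2: 4, 3: 7}  # fixed effects + variance components


# ---------------------------------------------------------------------------
# response aggregation
# ---------------------------------------------------------------------------

def choice_table(records: pd.DataFrame, by_sound: bool = False) -> pd.DataFrame:
    """Choice proportions per (participant, lag[, sound]) cell.

    Responses to comparison stimuli shown in the first and the second phase
    of the test period are pooled (merged), removing order bias to first
    order.  Excluded trials must be removed upstream.
    """
    req = {"participant_id", "lag_ms", "choice_comparison"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    keys = ["participant_id", "lag_ms"] + (["sound"] if by_sound else [])
    g = records.groupby(keys, as_index=False).agg(
        n_trials=("choice_comparison", "size"),
        n_chosen=("choice_comparison", "sum"),
    )
    g["proportion"] = g["n_chosen"] / g["n_trials"]
    return g


def delay_predictor_table(delay_records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant empirical delay-detection proportions P_d_i(x).

    Proportions of exactly 0 or 1 are pulled in by half a trial
    (0.5/n continuity adjustment) so probit linear predictors stay finite.
    """
    tab = choice_table(delay_records)
    shrink = 0.5 / tab["n_trials"]
    tab["p_delay"] = tab["proportion"].clip(lower=shrink, upper=1.0 - shrink)
    return tab[["participant_id", "lag_ms", "p_delay"]]


# ---------------------------------------------------------------------------
# model matrices
# ---------------------------------------------------------------------------

def _model_columns(model_id: int) -> tuple[list[str], list[str]]:
    """(fixed-effect columns, random-effect columns) in design order."""
    if model_id == 1:
        return ["const", "x"], ["const", "x"]
    if model_id == 2:
        return ["const", "p_d"], ["const", "p_d"]
    if model_id == 3:
        # two intercept random effects (fatigue- and delay-linked), as the
        # union of the Model 1 and Model 2 structures
        return ["const", "x", "p_d"], ["const", "const2", "x", "p_d"]
    raise ValueError(f"model_id must be 1, 2 or 3, got {model_id}")


def _build_arrays(records: pd.DataFrame, model_id: int,
                  p_delay: pd.DataFrame | None):
    """Aggregate to per-(participant, cell) binomial counts and stack padded
    per-subject design arrays: X (S,L,p), Z (S,L,q), y, n (S,L)."""
    df = records.copy()
    if model_id in (2, 3):
        if p_delay is None:
            raise ValueError(
                f"Model {model_id} requires delay-task response probabilities "
                "(p_delay); fit the delay session first")
        df = df.merge(p_delay, on=["participant_id", "lag_ms"], how="left")
        if df["p_delay"].isna().any():
            bad = df.loc[df["p_delay"].isna(), "lag_ms"].unique()
            raise ValueError(f"no delay-task probability for lags {sorted(bad)}")
    keys = ["participant_id", "lag_ms"] + (["p_delay"] if model_id in (2, 3) else [])
    cells = df.groupby(keys, as_index=False).agg(
        y=("choice_comparison", "sum"), n=("choice_comparison", "size"))

    subjects = np.sort(cells["participant_id"].unique())
    if subjects.size < 2:
        raise ValueError("need >= 2 participants")
    fixed_cols, rand_cols = _model_columns(model_id)
    L = cells.groupby("participant_id").size().max()
    S, p, q = subjects.size, len(fixed_cols), len(rand_cols)
    X = np.zeros((S, L, p))
    Z = np.zeros((S, L, q))
    y = np.zeros((S, L))
    n = np.zeros((S, L))
    for si, subj in enumerate(subjects):
        sub = cells[cells["participant_id"] == subj]
        if sub["lag_ms"].nunique() < 2:
            raise ValueError(
                f"participant {subj} has trials at a single predictor level; "
                "slope not identifiable")
        m = len(sub)
        cols = {"const": np.ones(m), "const2": np.ones(m),
                "x": sub["lag_ms"].to_numpy(dtype=float)}
        if model_id in (2, 3):
            cols["p_d"] = sub["p_delay"].to_numpy(dtype=float)
        X[si, :m] = np.column_stack([cols[c] for c in fixed_cols])
        Z[si, :m] = np.column_stack([cols[c] for c in rand_cols])
        y[si, :m] = sub["y"].to_numpy(dtype=float)
        n[si, :m] = sub["n"].to_numpy(dtype=float)
    return subjects, fixed_cols, rand_cols, X, Z, y, n


# ---------------------------------------------------------------------------
# Bernoulli-probit derivatives (stable via log_ndtr)
# ---------------------------------------------------------------------------

def _probit_terms(eta, y, n):
    """Log-likelihood, first and negative-second derivatives wrt eta,
    elementwise for binomial counts y of n with success prob Phi(eta)."""
    logphi = norm.logpdf(eta)
    lcdf = log_ndtr(eta)
    lsf = log_ndtr(-eta)
    ll = y * lcdf + (n - y) * lsf
    s_pos = np.exp(logphi - lcdf)      # phi/Phi
    s_neg = np.exp(logphi - lsf)       # phi/(1-Phi)
    u = y * s_pos - (n - y) * s_neg
    w = y * s_pos * (eta + s_pos) + (n - y) * s_neg * (s_neg - eta)
    return ll, u, np.maximum(w, 0.0)


def _laplace_loglik(gamma, sd, X, Z, y, n, b0=None, tol=1e-9, max_iter=100):
    """Laplace-approximate marginal log-likelihood, batched over subjects.

    Returns (total logL, posterior-mode random effects b_hat (S, q)).
    """
    S, L, q = Z.shape
    d_inv = 1.0 / np.maximum(sd, 1e-12) ** 2          # (q,)
    b = np.zeros((S, q)) if b0 is None else b0.copy()

    def penalized(bm):
        eta = np.einsum("slp,p->sl", X, gamma) + np.einsum("slq,sq->sl", Z, bm)
        ll, u, w = _probit_terms(eta, y, n)
        pen = ll.sum(axis=1) - 0.5 * np.sum(bm * bm * d_inv, axis=1)
        return pen, u, w

    pen, u, w = penalized(b)
    for _ in range(max_iter):
        grad = np.einsum("slq,sl->sq", Z, u) - b * d_inv
        H = np.einsum("slq,sl,slr->sqr", Z, w, Z) + np.diag(d_inv)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        if np.max(np.abs(grad) / (1.0 + np.abs(b) * d_inv)) < tol:
            break
        # per-subject backtracking to guarantee ascent of the penalized ll
        alpha = np.ones(S)
        for _ in range(30):
            b_new = b + alpha[:, None] * step
            pen_new, u_new, w_new = penalized(b_new)
            bad = pen_new < pen - 1e-12
            if not bad.any():
                break
            alpha[bad] *= 0.5
        b, pen, u, w = b_new, pen_new, u_new, w_new

    eta = np.einsum("slp,p->sl", X, gamma) + np.einsum("slq,sq->sl", Z, b)
    ll, _, w = _probit_terms(eta, y, n)
    ztwz = np.einsum("slq,sl,slr->sqr", Z, w, Z)
    # log det(I + D Z'WZ) with D = diag(sd^2)
    M = np.eye(q)[None] + (sd ** 2)[None, :, None] * ztwz
    sign, logdet = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        return -np.inf, b
    total = float(np.sum(ll) - 0.5 * np.sum(b * b * d_inv) - 0.5 * np.sum(logdet))
    return total, b


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMMFit:
    """A fitted probit mixed model."""

    model_id: int
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    re_sd: dict[str, float]
    subject_effects: pd.DataFrame     # posterior-mode deviations per subject
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_subjects: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.fixed_effects) + len(self.re_sd)

    def subject_slopes(self, column: str = "x") -> pd.Series:
        """Participant-level slopes beta + b_i on the given predictor."""
        fixed_name = {"x": "beta", "p_d": "beta_d"}[column]
        return self.fixed_effects[fixed_name] + self.subject_effects[column]

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "fixed_effects": self.fixed_effects,
            "fixed_se": self.fixed_se,
            "re_sd": self.re_sd,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


_FIXED_NAMES = {"const": "alpha", "x": "beta", "p_d": "beta_d"}
_RE_NAMES = {"const": "sd_alpha_i", "const2": "sd_alpha_d_i",
             "x": "sd_beta_i", "p_d": "sd_beta_d_i"}

LOG_SD_MIN, LOG_SD_MAX = -8.0, 3.0


def fit_probit_glmm(
    records: pd.DataFrame,
    model_id: int = 1,
    p_delay: pd.DataFrame | None = None,
    compute_se: bool = True,
    fix_re_sd: float | None = None,
) -> GLMMFit:
    """Maximize the Laplace-approximated marginal likelihood.

    ``records`` needs participant_id, lag_ms, choice_comparison (0/1) — one
    row per trial or pre-aggregated rows repeated per trial.  Models 2 and 3
    additionally need ``p_delay`` (from :func:`delay_predictor_table`).
    Deterministic: starting values come from a plain probit fit and the
    optimizer is quasi-Newton with fixed tolerances.

    ``fix_re_sd`` pins every random-effect SD at the given value instead of
    estimating it (profiling the variance components); at (near) zero the
    model degenerates to an ordinary probit regression.
    """
    subjects, fixed_cols, rand_cols, X, Z, y, n = _build_arrays(
        records, model_id, p_delay)
    S, L, p = X.shape
    q = Z.shape[2]

    # condition the problem: scale non-constant columns to unit SD
    mask = n > 0
    scale_x = np.ones(p)
    for j, c in enumerate(fixed_cols):
        if c not in ("const", "const2"):
            s = X[:, :, j][mask].std()
            scale_x[j] = s if s > 0 else 1.0
    scale_z = np.ones(q)
    for j, c in enumerate(rand_cols):
        if c not in ("const", "const2"):
            s = Z[:, :, j][mask].std()
            scale_z[j] = s if s > 0 else 1.0
    Xs = X / scale_x
    Zs = Z / scale_z

    # starting values: no-random-effect probit on the pooled cells
    flat = mask.ravel()
    glm = sm.GLM(
        np.column_stack([y.ravel()[flat], (n - y).ravel()[flat]]),
        Xs.reshape(-1, p)[flat],
        family=sm.families.Binomial(link=sm.families.links.Probit()),
    ).fit()
    gamma0 = np.asarray(glm.params, dtype=float)
    fixed_sd_s = None if fix_re_sd is None else np.maximum(fix_re_sd, 1e-8) * scale_z
    if fixed_sd_s is None:
        theta0 = np.concatenate([gamma0, np.full(q, np.log(0.3))])
        bounds = [(None, None)] * p + [(LOG_SD_MIN, LOG_SD_MAX)] * q
    else:
        theta0 = gamma0
        bounds = [(None, None)] * p

    def negll(theta):
        gamma = theta[:p]
        sd = fixed_sd_s if fixed_sd_s is not None else np.exp(theta[p:])
        ll, _ = _laplace_loglik(gamma, sd, Xs, Zs, y, n)
        return -ll

    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    theta = res.x
    gamma_s = theta[:p]
    sd_s = fixed_sd_s if fixed_sd_s is not None else np.exp(theta[p:])
    loglik, b_hat_s = _laplace_loglik(gamma_s, sd_s, Xs, Zs, y, n)

    gamma = gamma_s / scale_x
    sd = sd_s / scale_z
    b_hat = b_hat_s / scale_z

    se = np.full(p, np.nan)
    if compute_se:
        try:
            from statsmodels.tools.numdiff import approx_hess1
            H = approx_hess1(theta, negll)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0)) / scale_x
        except np.linalg.LinAlgError:
            pass

    fixed = {_FIXED_NAMES[c]: float(g) for c, g in zip(fixed_cols, gamma)}
    fixed_se = {_FIXED_NAMES[c]: float(s) for c, s in zip(fixed_cols, se)}
    re_sd = {_RE_NAMES[c]: float(s) for c, s in zip(rand_cols, sd)}
    subj = pd.DataFrame(b_hat, columns=rand_cols)
    subj.insert(0, "participant_id", subjects)

    k = len(fixed) + len(re_sd)
    assert k == MODEL_PARAM_COUNT[model_id]
    n_obs = int(n.sum())
    return GLMMFit(
        model_id=model_id,
        fixed_effects=fixed,
        fixed_se=fixed_se,
        re_sd=re_sd,
        subject_effects=subj,
        loglik=float(loglik),
        aic=float(-2.0 * loglik + 2.0 * k),
        converged=bool(res.success),
        n_obs=n_obs,
        n_subjects=int(S),
        diagnostics={"optimizer_message": str(res.message),
                     "n_iter": int(res.nit)},
    )


def model_comparison_aic(fits: dict[int, GLMMFit] | list[GLMMFit]) -> pd.DataFrame:
    """AIC ranking across fitted models (lowest AIC first)."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError("models were fit to different response vectors")
    tab = pd.DataFrame({
        "model_id": [f.model_id for f in fits],
        "k": [f.k for f in fits],
        "loglik": [f.loglik for f in fits],
        "aic": [f.aic for f in fits],
        "converged": [f.converged for f in fits],
    }).sort_values("aic", kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    tab["best"] = tab["delta_aic"] == 0.0
    return tab


def slope_correlation(fit_fatigue: GLMMFit, fit_delay: GLMMFit,
                      column: str = "x") -> tuple[float, float]:
    """Pearson correlation of participant-level slopes across the two tasks."""
    sf = fit_fatigue.subject_effects.set_index("participant_id")
    sd_ = fit_delay.subject_effects.set_index("participant_id")
    common = sf.index.intersection(sd_.index)
    if len(common) != len(sf) or len(common) != len(sd_):
        raise ValueError("participant sets differ between fits")
    a = fit_fatigue.fixed_effects["beta"] + sf.loc[common, column]
    b = fit_delay.fixed_effects["beta"] + sd_.loc[common, column]
    r, pval = pearsonr(a, b)
    return float(r), float(pval)
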