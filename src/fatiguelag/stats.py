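"""Hypothesis-testing layer for within-subject psychophysics designs.

One-sample / paired t-tests with Cohen's d, Bonferroni-Holm multiplicity
control, two-way fully-crossed repeated-measures ANOVA with partial eta
squared, and power / sample-size analysis for t-tests via the noncentral
t distribution.

Everything operates on plain numpy arrays or long-format pandas frames;
results are returned as :class:`TestResult` records that serialize to the
``stats_report.json`` schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PowerSpec",
    "one_sample_t",
    "paired_t",
    "holm_adjust",
    "bonferroni_adjust",
    "rm_anova_2way",
    "power_t",
    "sample_size_t",
]


@dataclass
class TestResult:
    """A single inferential test: statistic, df, p, effect size."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    effect_size_name: str
    method: str
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["df"] = list(self.df)
        return d


@dataclass
class PowerSpec:
    """Design parameters for a t-test power analysis.

    ``d`` is Cohen's d (standardized mean difference), ``alpha`` the
    two-sided (or one-sided) significance level, ``power`` the target
    probability of rejecting under the alternative.
    """

    d: float
    alpha: float = 0.05
    power: float = 0.8
    two_sided: bool = True
    family: str = "one-sample"  # paired reduces to one-sample on differences

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power must be in (0, 1), got {self.power}")


def one_sample_t(values: Sequence[float], mu0: float = 0.0, name: str = "one-sample t") -> TestResult:
    """One-sample t-test against ``mu0`` with Cohen's d = (mean - mu0) / sd.

    The test the choice probabilities are compared with chance level (0.5) by.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    n = x.size
    m = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        # degenerate: all values identical
        t = 0.0 if m == mu0 else np.inf * np.sign(m - mu0)
        p = 1.0 if m == mu0 else 0.0
        d = 0.0 if m == mu0 else np.inf * np.sign(m - mu0)
    else:
        t = (m - mu0) / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
        d = (m - mu0) / sd
    return TestResult(name, float(t), (n - 1,), float(p), float(d), "cohen_d", "one-sample t")


def paired_t(a: Sequence[float], b: Sequence[float], name: str = "paired t") -> TestResult:
    """Paired t-test: one-sample test on the differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(a - b, 0.0, name=name)
    res.method = "paired t"
    return res


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotone nondecreasing adjusted values along the sorted order, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bonferroni_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Plain Bonferroni: p * m, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def rm_anova_2way(
    data: pd.DataFrame,
    subject: str = "subject",
    factor_a: str = "A",
    factor_b: str = "B",
    value: str = "value",
) -> dict[str, TestResult]:
    """Two-way fully-crossed repeated-measures ANOVA.

    Classical within-subject decomposition: each effect (A, B, A x B) is
    tested against its own subject-by-effect interaction stratum.  Partial
    eta squared is SS_effect / (SS_effect + SS_error).  One value per
    (subject, A, B) cell is required; missing cells raise (no imputation).

    Returns a dict with keys ``factor_a``, ``factor_b`` and
    ``"{factor_a}*{factor_b}"``.
    """
    df = data[[subject, factor_a, factor_b, value]].copy()
    if df[value].isna().any() or not np.all(np.isfinite(df[value].to_numpy(dtype=float))):
        raise ValueError("non-finite values in ANOVA table")
    # pivot to subject x (A,B) cell means; any hole is a design error
    wide = df.pivot_table(index=subject, columns=[factor_a, factor_b], values=value,
                          aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("design is not fully crossed: missing subject x cell combinations")
    n = wide.shape[0]
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    # cube Y[subject, A, B]
    y = np.empty((n, a, b))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[:, i, j] = wide[(al, bl)].to_numpy(dtype=float)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_a = y.mean(axis=(0, 2))          # factor A level means
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)              # (n, a)
    m_sb = y.mean(axis=1)              # (n, b)
    m_ab = y.mean(axis=0)              # (a, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
         + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand) ** 2
    )

    # internal consistency of the decomposition
    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    resid = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_sa + ss_sb + ss_sab)
    if abs(resid) > 1e-10 * max(1.0, ss_total):
        raise AssertionError(f"SS decomposition does not close: residual {resid:g}")

    def effect(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> TestResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if ms_err > 0:
            f = ms_eff / ms_err
            p = sps.f.sf(f, df_eff, df_err)
        else:
            f = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        denom = ss_eff + ss_err
        pes = ss_eff / denom if denom > 0 else 0.0
        return TestResult(name, float(f), (float(df_eff), float(df_err)), float(p),
                          float(pes), "partial_eta_sq", "rm-anova")

    return {
        factor_a: effect(factor_a, ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        factor_b: effect(factor_b, ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        f"{factor_a}*{factor_b}": effect(f"{factor_a}*{factor_b}", ss_ab,
                                         (a - 1) * (b - 1), ss_sab,
                                         (n - 1) * (a - 1) * (b - 1)),
    }


def power_t(n: int, spec: PowerSpec) -> float:
    """Power of a one-sample (or paired-on-differences) t-test at sample size n.

    Exact via the noncentral t distribution with noncentrality d * sqrt(n)
    and df = n - 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    nc = spec.d * np.sqrt(n)
    if spec.two_sided:
        crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
        power = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
    else:
        crit = sps.t.ppf(1.0 - spec.alpha, df)
        power = sps.nct.sf(crit, df, nc) if spec.d > 0 else sps.nct.cdf(-crit, df, nc)
    return float(power)


def sample_size_t(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest n with power_t(n, spec) >= spec.power."""
    if spec.d == 0.0:
        raise ValueError("effect size d must be nonzero for a sample-size computation")
    for n in range(2, n_max + 1):
        if power_t(n, spec) >= spec.power:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {spec.power}")
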