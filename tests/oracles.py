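"""Independent reference implementations used only as test oracles.

Each function here re-derives a quantity from its definition (brute force,
quadrature, enumeration, or simulation), sharing no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import ndtr
from scipy.stats import t as t_dist


def probit_loglik(eta, y, n):
    p = np.clip(ndtr(eta), 1e-300, 1 - 1e-16)
    return np.sum(y * np.log(p) + (n - y) * np.log1p(-p))


def aghq_loglik(gamma, sd, X, Z, y, n, n_nodes=31):
    """Adaptive Gauss-Hermite marginal log-likelihood of the probit GLMM.

    Mode located by coordinate-free Newton on a numerically differentiated
    penalized objective (scipy), curvature by finite differences; the
    integral is a tensor-product GH rule recentred and rescaled at the mode.
    """
    from scipy.optimize import minimize

    S, L, q = Z.shape
    nodes, wts = hermgauss(n_nodes)
    grid = np.array(list(itertools.product(nodes, repeat=q)))
    wgrid = np.prod(np.array(list(itertools.product(wts, repeat=q))), axis=1)
    sd = np.asarray(sd, dtype=float)
    total = 0.0
    for i in range(S):

        def neg_pen(b, i=i):
            eta = X[i] @ gamma + Z[i] @ b
            return -(probit_loglik(eta, y[i], n[i])
                     - 0.5 * np.sum((b / sd) ** 2))

        res = minimize(neg_pen, np.zeros(q), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        b_hat = res.x
        # finite-difference Hessian of the negative penalized objective
        eps = 1e-5
        H = np.zeros((q, q))
        for a in range(q):
            for b_ in range(q):
                e_a = np.zeros(q); e_a[a] = eps
                e_b = np.zeros(q); e_b[b_] = eps
                H[a, b_] = (neg_pen(b_hat + e_a + e_b) - neg_pen(b_hat + e_a - e_b)
                            - neg_pen(b_hat - e_a + e_b) + neg_pen(b_hat - e_a - e_b)
                            ) / (4 * eps * eps)
        Lc = np.linalg.cholesky(np.linalg.inv(0.5 * (H + H.T)))
        pts = b_hat[None, :] + np.sqrt(2.0) * grid @ Lc.T
        eta = X[i] @ gamma + pts @ Z[i].T
        p = np.clip(ndtr(eta), 1e-300, 1 - 1e-16)
        ll = np.sum(y[i] * np.log(p) + (n[i] - y[i]) * np.log1p(-p), axis=1)
        logprior = (-0.5 * np.sum((pts / sd) ** 2, axis=1)
                    - 0.5 * q * np.log(2 * np.pi) - np.sum(np.log(sd)))
        logint = ll + logprior + np.sum(grid ** 2, axis=1)
        m = logint.max()
        total += (np.log(np.sum(wgrid * np.exp(logint - m))) + m
                  + 0.5 * q * np.log(2.0) + np.sum(np.log(np.diag(Lc))))
    return float(total)


def holm_brute(pvals):
    """Holm adjustment straight from the step-down definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adj[idx] = running_max
    return adj


def rm_anova_brute(y):
    """Two-way within-subject ANOVA by explicit definitional sums of squares.

    ``y`` is a (subjects, a, b) cube.  Returns dict of
    effect -> (F, df1, df2, p, partial eta squared).
    """
    from scipy.stats import f as f_dist

    n, a, b = y.shape
    grand = y.mean()
    ss = {}
    ss["A"] = sum(n * b * (y[:, i, :].mean() - grand) ** 2 for i in range(a))
    ss["B"] = sum(n * a * (y[:, :, j].mean() - grand) ** 2 for j in range(b))
    ss["AB"] = sum(
        n * (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand) ** 2
        for i in range(a) for j in range(b))
    ss["SA"] = sum(
        b * (y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand) ** 2
        for s in range(n) for i in range(a))
    ss["SB"] = sum(
        a * (y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + grand) ** 2
        for s in range(n) for j in range(b))
    ss["SAB"] = sum(
        (y[s, i, j] - y[s, i, :].mean() - y[s, :, j].mean() - y[:, i, j].mean()
         + y[s].mean() + y[:, i, :].mean() + y[:, :, j].mean() - grand) ** 2
        for s in range(n) for i in range(a) for j in range(b))
    out = {}
    for eff, err, df1, df2 in [("A", "SA", a - 1, (n - 1) * (a - 1)),
                               ("B", "SB", b - 1, (n - 1) * (b - 1)),
                               ("AB", "SAB", (a - 1) * (b - 1),
                                (n - 1) * (a - 1) * (b - 1))]:
        F = (ss[eff] / df1) / (ss[err] / df2)
        p = f_dist.sf(F, df1, df2)
        pes = ss[eff] / (ss[eff] + ss[err])
        out[eff] = (F, df1, df2, p, pes)
    return out


def power_t_mc(n, d, alpha, n_rep, rng):
    """Monte-Carlo power of the two-sided one-sample t-test."""
    x = rng.standard_normal((n_rep, n)) + d
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    t = m / (s / np.sqrt(n))
    crit = t_dist.ppf(1 - alpha / 2, n - 1)
    return float(np.mean(np.abs(t) > crit))


def xcorr_brute(a, b, max_shift):
    """Normalized cross-correlation by direct per-shift computation.

    Returns (best integer shift, peak value) where positive shift means
    ``b`` lags ``a``.
    """
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    best = (None, -np.inf)
    nmin = min(a.size, b.size)
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            x1, x2 = b[s:nmin], a[: nmin - s]
        else:
            x1, x2 = b[: nmin + s], a[-s:nmin]
        r = np.dot(x1, x2) / np.sqrt(np.dot(x1, x1) * np.dot(x2, x2))
        if r > best[1]:
            best = (s, r)
    return best
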