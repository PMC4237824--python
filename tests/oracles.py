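"""Independent brute-force oracles used to validate the package estimators.

These deliberately avoid the implementation's algebraic shortcuts: the
variance components come from a generic REML optimization over the full
2n x 2n covariance matrix, and the Patlak coefficients from explicitly
formed normal equations per pixel.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def reml_variance_components(y1: np.ndarray, y2: np.ndarray):
    """Brute-force REML fit of the balanced random-intercept model.

    Maximizes the restricted log-likelihood of y ~ N(mu * 1, V) with
    V = sigma_b^2 * ZZ' + sigma_w^2 * I over (log sigma_b^2, log sigma_w^2)
    using a generic optimizer and dense linear algebra.
    Returns (mu_hat, sigma_b, sigma_w).
    """
    n = y1.size
    y = np.concatenate([y1, y2])
    z = np.zeros((2 * n, n))
    z[np.arange(n), np.arange(n)] = 1.0
    z[n + np.arange(n), np.arange(n)] = 1.0
    x = np.ones((2 * n, 1))

    def neg2_reml(params):
        vb, vw = np.exp(params)
        v = vb * (z @ z.T) + vw * np.eye(2 * n)
        sign, logdet = np.linalg.slogdet(v)
        vi = np.linalg.inv(v)
        xtvx = x.T @ vi @ x
        beta = np.linalg.solve(xtvx, x.T @ vi @ y)
        r = y - x @ beta
        return float(logdet + np.log(xtvx[0, 0]) + r @ vi @ r)

    best = None
    for start in ([-4.0, -4.0], [-8.0, -4.0], [-2.0, -6.0]):
        res = optimize.minimize(neg2_reml, start, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    vb, vw = np.exp(best.x)
    v = vb * (z @ z.T) + vw * np.eye(2 * n)
    vi = np.linalg.inv(v)
    mu = float(np.squeeze(x.T @ vi @ y) / np.squeeze(x.T @ vi @ x))
    return mu, float(np.sqrt(vb)), float(np.sqrt(vw))


def patlak_normal_equations(conc_pixel: np.ndarray, cp: np.ndarray,
                            times_s: np.ndarray):
    """Patlak coefficients for one pixel by explicitly formed and solved
    normal equations (trapezoidal AIF integral in minutes)."""
    t_min = times_s / 60.0
    integral = np.zeros_like(cp)
    for k in range(1, cp.size):
        integral[k] = integral[k - 1] + 0.5 * (cp[k] + cp[k - 1]) * (t_min[k] - t_min[k - 1])
    x = np.column_stack([integral, cp])
    xtx = x.T @ x
    xty = x.T @ conc_pixel
    beta = np.linalg.solve(xtx, xty)
    return float(beta[0]), float(beta[1])


def spearman_by_hand(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size)
        ranks[order] = np.arange(1, v.size + 1, dtype=float)
        for val in np.unique(v):
            sel = v == val
            ranks[sel] = ranks[sel].mean()
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
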