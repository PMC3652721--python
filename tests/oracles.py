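"""Independent reference implementations used only by the test suite.

The adaptive Gauss-Hermite quadrature (AGQ) fitter below is written directly
from the marginal-likelihood definition of a one-random-intercept binomial
logit model and shares no code with the package's Laplace engine: modes are
found by bisection-safeguarded Newton on the scalar integrand, the integral
is evaluated by adaptive Gauss-Hermite quadrature in log space, and the
parameters are optimized derivative-free.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp


def _group_loglik_agq(y, eta_fixed, sd, nodes, logw):
    """log integral over one group's random intercept, adaptive GH."""
    if sd < 1e-6:  # degenerate prior: integral collapses onto u = 0
        return float(np.sum(y * eta_fixed - np.logaddexp(0.0, eta_fixed)))
    s2 = sd * sd

    def h(u):  # log integrand (conditional ll + normal prior)
        eta = eta_fixed + u
        return (
            np.sum(y * eta - np.logaddexp(0.0, eta))
            - 0.5 * u * u / s2
            - 0.5 * np.log(2 * np.pi * s2)
        )

    # scalar Newton for the mode, with damping
    u = 0.0
    for _ in range(100):
        p = expit(eta_fixed + u)
        g = np.sum(y - p) - u / s2
        hess = -(np.sum(p * (1 - p)) + 1.0 / s2)
        step = -g / hess
        while not np.isfinite(h(u + step)) or h(u + step) < h(u) - 1e-12:
            step *= 0.5
            if abs(step) < 1e-14:
                break
        u += step
        if abs(g) < 1e-12:
            break
    p = expit(eta_fixed + u)
    curv = np.sum(p * (1 - p)) + 1.0 / s2
    tau = 1.0 / np.sqrt(curv)
    # adaptive nodes u_k = mode + sqrt(2) tau t_k ; integral in log space
    uk = u + np.sqrt(2.0) * tau * nodes
    hk = np.array([h(v) for v in uk])
    return logsumexp(logw + nodes**2 + hk) + 0.5 * np.log(2.0) + np.log(tau)


def agq_loglik(beta, log_s2, y, X, groups, n_nodes=25):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
    sd = np.exp(0.5 * log_s2)
    nodes, weights = hermgauss(n_nodes)
    logw = np.log(weights)
    eta = X @ beta
    total = 0.0
    for j in np.unique(groups):
        m = groups == j
        total += _group_loglik_agq(y[m], eta[m], sd, nodes, logw)
    return float(total)


def fit_agq(y, X, groups, n_nodes=25, log_s2_start=-1.5):
    """Maximum likelihood fit of (beta, sigma2) under the AGQ likelihood."""
    p = X.shape[1]

    def nll(theta):
        val = agq_loglik(theta[:p], theta[p], y, X, groups, n_nodes)
        return -val if np.isfinite(val) else 1e12

    theta0 = np.concatenate([np.zeros(p), [log_s2_start]])
    res = optimize.minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10, "adaptive": True},
    )
    # one restart from the found point guards against premature simplex collapse
    res2 = optimize.minimize(
        nll,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10, "adaptive": True},
    )
    best = res2 if res2.fun < res.fun else res
    return {
        "beta": best.x[:p],
        "sigma2": float(np.exp(best.x[p])),
        "loglik": -float(best.fun),
    }
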