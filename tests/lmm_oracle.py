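"""Brute-force maximum-likelihood oracle for the linear mixed model.

Evaluates the marginal Gaussian likelihood directly — for each participant i,
y_i ~ N(X_i β, Z_i G Z_iᵀ + σ² I) — with β profiled out by generalized least
squares at each variance-parameter value, and maximizes over the variance
parameters with derivative-free Nelder–Mead from several starts. Shares no
code path with the package's model fitting.
"""

import numpy as np
from scipy import optimize, stats


def _split(y, X, Z, groups):
    out = []
    for g in np.unique(groups):
        m = groups == g
        out.append((y[m], X[m], Z[m]))
    return out


def marginal_loglik(parts, beta, G, sigma2):
    ll = 0.0
    for yi, Xi, Zi in parts:
        V = Zi @ G @ Zi.T + sigma2 * np.eye(len(yi))
        ll += stats.multivariate_normal.logpdf(yi, mean=Xi @ beta, cov=V)
    return ll


def _gls_beta(parts, G, sigma2):
    p = parts[0][1].shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for yi, Xi, Zi in parts:
        V = Zi @ G @ Zi.T + sigma2 * np.eye(len(yi))
        Vi = np.linalg.inv(V)
        A += Xi.T @ Vi @ Xi
        b += Xi.T @ Vi @ yi
    return np.linalg.solve(A, b)


def _minimize(nll, starts):
    best = np.inf
    for start in starts:
        res = optimize.minimize(
            nll, start, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 20000, "maxfev": 20000},
        )
        best = min(best, res.fun)
    return best


def brute_force_ml_loglik(y, X, Z, groups):
    """Maximized marginal log-likelihood (ML) for a 2-column random structure.

    The ML optimum may sit on the boundary of the variance space (a zero
    variance component), which a log-parametrized search can only approach;
    the boundary sub-models — slope-only, intercept-only, and no random
    effects at all — are therefore maximized explicitly as well and the
    overall maximum returned.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    parts = _split(y, X, Z, np.asarray(groups))

    def nll_full(theta):
        sd0, sd1, sig = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[3])
        rho = np.tanh(theta[2])
        G = np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])
        try:
            beta = _gls_beta(parts, G, sig**2)
            return -marginal_loglik(parts, beta, G, sig**2)
        except np.linalg.LinAlgError:
            return np.inf

    def nll_single(theta, which):
        sd, sig = np.exp(theta[0]), np.exp(theta[1])
        G = np.zeros((2, 2))
        G[which, which] = sd**2
        try:
            beta = _gls_beta(parts, G, sig**2)
            return -marginal_loglik(parts, beta, G, sig**2)
        except np.linalg.LinAlgError:
            return np.inf

    best = _minimize(
        nll_full,
        [
            [np.log(0.15), np.log(0.05), 0.0, np.log(0.35)],
            [np.log(0.3), np.log(0.1), 0.0, np.log(0.2)],
            [np.log(0.05), np.log(0.02), 0.5, np.log(0.5)],
        ],
    )
    for which in (0, 1):
        best = min(
            best,
            _minimize(
                lambda th: nll_single(th, which),
                [[np.log(0.15), np.log(0.35)], [np.log(0.02), np.log(0.2)]],
            ),
        )

    # perfectly correlated intercept and slope (rank-one G, rho = ±1)
    def nll_rank1(theta, sign):
        sd0, sd1, sig = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])
        v = np.array([sd0, sign * sd1])
        G = np.outer(v, v)
        try:
            beta = _gls_beta(parts, G, sig**2)
            return -marginal_loglik(parts, beta, G, sig**2)
        except np.linalg.LinAlgError:
            return np.inf

    for sign in (1.0, -1.0):
        best = min(
            best,
            _minimize(
                lambda th: nll_rank1(th, sign),
                [
                    [np.log(0.15), np.log(0.05), np.log(0.35)],
                    [np.log(0.02), np.log(0.01), np.log(0.2)],
                ],
            ),
        )
    # no random effects at all: plain OLS, closed form
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sig2 = float(resid @ resid) / n
    ols_ll = -0.5 * n * (np.log(2 * np.pi * sig2) + 1.0)
    best = min(best, -ols_ll)
    return -best
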