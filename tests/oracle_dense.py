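"""Independent dense-matrix reference for the variance-component score test.

Everything here is written against explicit n x n matrices with plain
inverses — no shared code with the package's low-rank engine — so that
agreement between the two is a genuine cross-check.
"""

import numpy as np
from scipy.stats import chi2


def dense_projection(X, sigmas, taus, sigma2):
    """P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 for V = sum tau S + s2 I."""
    n = X.shape[0]
    V = sigma2 * np.eye(n)
    for t, S in zip(taus, sigmas):
        V = V + t * S
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    return Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv


def dense_score_test(y, X, nuisance_sigmas, taus, sigma2, target):
    """(Q, kappa, nu, p) for the score test of adding ``target`` to the
    null model with the given (already fitted) variance parameters."""
    n, p_fix = X.shape
    P = dense_projection(X, nuisance_sigmas, taus, sigma2)
    Py = P @ y
    Q = 0.5 * float(y @ P @ target @ Py)
    e = 0.5 * float(np.trace(P @ target))
    PT = P @ target
    Itt = 0.5 * float(np.trace(PT @ PT))
    thetas = list(nuisance_sigmas) + [np.eye(n)]
    m = len(thetas)
    I_tth = np.array([0.5 * np.trace(PT @ P @ th) for th in thetas])
    I_thth = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            I_thth[i, j] = 0.5 * np.trace(P @ thetas[i] @ P @ thetas[j])
    itilde = Itt - float(I_tth @ np.linalg.solve(I_thth, I_tth))
    nu_resid = n - p_fix
    itilde *= nu_resid / (nu_resid + 2.0)
    kappa = itilde / (2.0 * e)
    nu = 2.0 * e**2 / itilde
    p = float(chi2.sf(Q / kappa, nu))
    return Q, kappa, nu, p


def dense_reml_loglik(y, X, sigmas, taus, sigma2):
    n = X.shape[0]
    V = sigma2 * np.eye(n)
    for t, S in zip(taus, sigmas):
        V = V + t * S
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtVX)
    return -0.5 * (ld_V + ld_X + float(y @ P @ y))
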