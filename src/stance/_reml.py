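"""Restricted maximum likelihood for Gaussian variance-component models.

The model is y ~ N(X beta, V) with V = sum_j tau_j Sigma_j + sigma^2 I and
each Sigma_j supplied through a root Z_j (Sigma_j = Z_j Z_j^T). All linear
algebra runs in the span of the concatenated roots via the Woodbury
identity, so one kernel eigendecomposition is shared across thousands of
per-gene fits; the results are identical (to working precision) to the
naive dense computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["GLSFactor", "RemlResult", "fit_reml", "variance_score_test"]


class GLSFactor:
    """Factored generalized-least-squares operator for fixed (tau, sigma2).

    Provides V^{-1} products, REML projection products P = V^{-1} -
    V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}, the REML log-likelihood, and the
    trace functionals needed by Fisher scoring and score tests — all without
    forming any n x n matrix.
    """

    def __init__(self, roots: list[np.ndarray], taus: np.ndarray, sigma2: float, X: np.ndarray):
        self.roots = roots
        self.taus = np.asarray(taus, dtype=float)
        self.sigma2 = float(sigma2)
        self.X = X
        n = X.shape[0]
        self.n = n
        active = [np.sqrt(t) * Z for t, Z in zip(self.taus, roots) if t > 0]
        self.Zs = np.hstack(active) if active else np.empty((n, 0))
        c = self.Zs.shape[1]
        if c:
            G = self.Zs.T @ self.Zs
            M = self.sigma2 * np.eye(c) + G
            self._M_cho = cho_factor(M)
            s, self._logdet_M = np.linalg.slogdet(M)
        else:
            self._M_cho = None
            self._logdet_M = 0.0
        self.Wx = self.vinv(X)  # V^{-1} X
        XtVX = X.T @ self.Wx
        self._XtVX_cho = cho_factor(XtVX)
        s, self._logdet_XtVX = np.linalg.slogdet(XtVX)

    # -- core products ---------------------------------------------------
    def vinv(self, B: np.ndarray) -> np.ndarray:
        if self.Zs.shape[1] == 0:
            return B / self.sigma2
        return (B - self.Zs @ cho_solve(self._M_cho, self.Zs.T @ B)) / self.sigma2

    def p_mult(self, B: np.ndarray) -> np.ndarray:
        """P B where P X = 0 and P V P = P (the REML projection)."""
        VB = self.vinv(B)
        return VB - self.Wx @ cho_solve(self._XtVX_cho, self.Wx.T @ B)

    @property
    def logdet_V(self) -> float:
        c = self.Zs.shape[1]
        return (self.n - c) * np.log(self.sigma2) + self._logdet_M

    def reml_loglik(self, y: np.ndarray) -> float:
        Py = self.p_mult(y)
        return -0.5 * (self.logdet_V + self._logdet_XtVX + float(y @ Py))

    # -- trace functionals ------------------------------------------------
    def trace_p(self) -> tuple[float, float]:
        """(tr P, tr P^2) via the low-rank correction to sigma^{-2} I."""
        blocks = []
        if self.Zs.shape[1]:
            Minv = cho_solve(self._M_cho, np.eye(self.Zs.shape[1]))
            blocks.append((self.Zs, Minv / self.sigma2))
        p = self.X.shape[1]
        XtVX_inv = cho_solve(self._XtVX_cho, np.eye(p))
        blocks.append((self.Wx, XtVX_inv))
        N = np.hstack([b[0] for b in blocks])
        sizes = [b[0].shape[1] for b in blocks]
        S = np.zeros((sum(sizes), sum(sizes)))
        off = 0
        for (m, (_, s)) in zip(sizes, blocks):
            S[off : off + m, off : off + m] = s
            off += m
        T = S @ (N.T @ N)
        trB = float(np.trace(T))
        trB2 = float(np.sum(T * T.T))
        tr_p = self.n / self.sigma2 - trB
        tr_p2 = self.n / self.sigma2**2 - 2.0 * trB / self.sigma2 + trB2
        return tr_p, tr_p2


@dataclass
class RemlResult:
    """Constrained REML estimates of (tau_1..tau_m, sigma2)."""

    taus: np.ndarray
    sigma2: float
    beta: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    factor: GLSFactor


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    n, p = X.shape
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design matrix")
    r = y - X @ beta
    return beta, float(r @ r) / (n - p)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    roots: list[np.ndarray],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RemlResult:
    """Fisher-scoring REML with non-negativity projection.

    Components whose estimate is pinned at zero with a negative score are
    held at the boundary; step-halving safeguards each update. On the rare
    failure to improve the restricted likelihood the last iterate is
    returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    m = len(roots)
    beta0, s2_ols = _ols(y, X)
    if s2_ols <= 0 or not np.isfinite(s2_ols):
        fac = GLSFactor(roots, np.zeros(m), max(s2_ols, 1e-12), X)
        return RemlResult(np.zeros(m), max(s2_ols, 1e-12), beta0, True, 0, -np.inf, fac)
    if m == 0:
        fac = GLSFactor([], np.zeros(0), s2_ols, X)
        beta = cho_solve(fac._XtVX_cho, fac.Wx.T @ y)
        return RemlResult(np.zeros(0), s2_ols, beta, True, 0, fac.reml_loglik(y), fac)

    # split the marginal variance evenly across components at start
    scales = np.array([np.sum(Z * Z) / n for Z in roots])  # tr(Sigma_j)/n
    taus = np.where(scales > 1e-12, 0.5 * s2_ols / (m * np.maximum(scales, 1e-12)), 0.0)
    sigma2 = 0.5 * s2_ols
    floor = 1e-10 * s2_ols

    fac = GLSFactor(roots, taus, sigma2, X)
    ll = fac.reml_loglik(y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py = fac.p_mult(y)
        U = [fac.p_mult(Z) for Z in roots]  # P Z_j
        tr_p, tr_p2 = fac.trace_p()
        # score: s_j = -1/2 (tr(P V_j) - y' P V_j P y), V_j = Sigma_j or I
        score = np.empty(m + 1)
        for j, Z in enumerate(roots):
            score[j] = -0.5 * (np.sum(Z * U[j]) - float(np.sum((Z.T @ Py) ** 2)))
        score[m] = -0.5 * (tr_p - float(Py @ Py))
        # expected information: F_jk = 1/2 tr(P V_j P V_k)
        F = np.empty((m + 1, m + 1))
        for i in range(m):
            for j in range(i, m):
                F[i, j] = F[j, i] = 0.5 * float(np.sum((roots[i].T @ U[j]) ** 2))
            F[i, m] = F[m, i] = 0.5 * float(np.sum(U[i] * U[i]))
        F[m, m] = 0.5 * tr_p2
        theta = np.append(taus, sigma2)
        # hold boundary components with inward-pointing negative scores
        free = ~((theta[:m] <= floor) & (score[:m] < 0))
        free = np.append(free, True)
        idx = np.flatnonzero(free)
        delta = np.zeros(m + 1)
        sub = F[np.ix_(idx, idx)]
        sub = sub + 1e-10 * np.eye(len(idx)) * max(np.trace(sub) / len(idx), 1.0)
        delta[idx] = np.linalg.solve(sub, score[idx])

        step = 1.0
        improved = False
        for _ in range(12):
            cand = theta + step * delta
            cand[:m] = np.maximum(cand[:m], 0.0)
            cand[m] = max(cand[m], floor)
            cand_fac = GLSFactor(roots, cand[:m], cand[m], X)
            cand_ll = cand_fac.reml_loglik(y)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12 * (abs(ll) + 1):
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        dll = cand_ll - ll
        taus, sigma2, fac, ll = cand[:m], cand[m], cand_fac, cand_ll
        if abs(dll) < tol * (abs(ll) + 1.0):
            converged = True
            break

    taus = np.where(taus <= 2 * floor, 0.0, taus)
    fac = GLSFactor(roots, taus, sigma2, X)
    beta = cho_solve(fac._XtVX_cho, fac.Wx.T @ y)
    return RemlResult(taus, sigma2, beta, converged, it, fac.reml_loglik(y), fac)


def variance_score_test(
    y: np.ndarray,
    factor: GLSFactor,
    target_root: np.ndarray,
    nuisance_roots: list[np.ndarray],
) -> tuple[float, float, float, np.ndarray]:
    """Score statistic for adding one variance component to a null model.

    Returns (Q, e, itilde, lambdas) where
      Q       = 1/2 y' P Sigma_t P y,
      e       = 1/2 tr(P Sigma_t)             (null mean of Q),
      itilde  = efficient information          (null variance of Q, adjusted
                for estimating the nuisance variance parameters),
      lambdas = eigenvalues of 1/2 Z_t' P Z_t  (weights of the exact
                weighted-chi-square null distribution, for Imhof/Davies).
    """
    Zt = target_root
    Py = factor.p_mult(y)
    ZtPy = Zt.T @ Py
    Q = 0.5 * float(ZtPy @ ZtPy)
    Ut = factor.p_mult(Zt)
    ZtUt = Zt.T @ Ut
    e = 0.5 * float(np.trace(ZtUt))
    Itt = 0.5 * float(np.sum(ZtUt * ZtUt.T))
    m = len(nuisance_roots)
    tr_p, tr_p2 = factor.trace_p()
    I_tth = np.empty(m + 1)
    I_thth = np.empty((m + 1, m + 1))
    Uj = [factor.p_mult(Z) for Z in nuisance_roots]
    for j, Z in enumerate(nuisance_roots):
        I_tth[j] = 0.5 * float(np.sum((Z.T @ Ut) ** 2))
        for i in range(j, m):
            Zi = nuisance_roots[i]
            I_thth[i, j] = I_thth[j, i] = 0.5 * float(np.sum((Zi.T @ Uj[j]) ** 2))
        I_thth[j, m] = I_thth[m, j] = 0.5 * float(np.sum(Uj[j] * Uj[j]))
    I_tth[m] = 0.5 * float(np.sum(Ut * Ut))
    I_thth[m, m] = 0.5 * tr_p2
    try:
        itilde = Itt - float(I_tth @ np.linalg.solve(I_thth, I_tth))
    except np.linalg.LinAlgError:
        itilde = Itt - float(I_tth @ np.linalg.lstsq(I_thth, I_tth, rcond=None)[0])
    lambdas = 0.5 * np.linalg.eigvalsh(0.5 * (ZtUt + ZtUt.T))
    return Q, e, itilde, lambdas
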