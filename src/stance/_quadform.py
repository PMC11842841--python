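"""Tail probabilities for quadratic forms in Gaussian variables.

Two routes are provided for P(Q > q) where Q = sum_i lambda_i chi^2_1:

* Satterthwaite moment matching to a scaled chi-square kappa * chi^2_nu —
  the default, cheap and accurate in the moderate tail;
* numerical inversion of the characteristic function (Imhof's formula),
  an effectively exact reference used for verification.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.stats import chi2

__all__ = ["satterthwaite_pvalue", "imhof_pvalue"]

P_FLOOR = 1e-300


def satterthwaite_pvalue(Q: float, mean: float, variance_adj: float) -> tuple[float, float, float]:
    """Scaled chi-square tail for a variance-component score statistic.

    Matches E[Q] = ``mean`` and Var[Q] = ``variance_adj`` (the efficient
    information, i.e. the variance adjusted for estimating the null-model
    parameters) to kappa * chi^2_nu:

        kappa = variance / (2 * mean),   nu = 2 * mean^2 / variance.

    Returns (kappa, nu, p). Degenerate moments (mean or variance <= 0,
    meaning there is no spatial information in the target) yield p = 1.
    """
    if mean <= 0 or variance_adj <= 0 or not np.isfinite(mean * variance_adj):
        return (np.nan, np.nan, 1.0)
    kappa = variance_adj / (2.0 * mean)
    nu = 2.0 * mean**2 / variance_adj
    p = float(chi2.sf(Q / kappa, nu))
    return (kappa, nu, max(p, P_FLOOR))


def imhof_pvalue(q: float, lambdas: np.ndarray, rtol: float = 1e-9) -> float:
    """P(sum_i lambda_i chi^2_1 > q) by Imhof's inversion integral.

    p = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du
    with theta(u) = (1/2) sum arctan(lambda_i u) - q u / 2 and
    rho(u) = prod (1 + lambda_i^2 u^2)^(1/4).

    Weights may have either sign (needed for the exact scale-free form of
    the studentized statistic, a difference of weighted chi-squares).
    """
    lam = np.asarray(lambdas, dtype=float)
    scale = np.abs(lam).max(initial=0.0)
    lam = lam[np.abs(lam) > 1e-14 * max(scale, 1.0)]
    if lam.size == 0:
        return 1.0
    if q <= 0 and np.all(lam >= 0):
        return 1.0
    if q >= 0 and np.all(lam <= 0):
        return float(P_FLOOR)

    def integrand(u):
        u = np.atleast_1d(u)
        theta = 0.5 * np.sum(np.arctan(np.outer(u, lam)), axis=1) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p(np.outer(u, lam) ** 2), axis=1)
        return np.sin(theta) * np.exp(-log_rho) / u

    # upper limit where the envelope 1/(u rho(u)) is negligible
    upper = 1.0 / max(scale, 1e-300)
    while _log_envelope(upper, lam) > np.log(1e-17):
        upper *= 2.0
        if not np.isfinite(upper):
            break
    val, _ = integrate.quad(
        lambda u: float(integrand(u)[0]), 0.0, upper,
        epsabs=1e-13, epsrel=rtol, limit=300,
    )
    p = 0.5 + val / np.pi
    return float(min(max(p, P_FLOOR), 1.0))


def _log_envelope(u: float, lam: np.ndarray) -> float:
    return -np.log(u) - 0.25 * float(np.sum(np.log1p((lam * u) ** 2)))
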