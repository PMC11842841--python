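"""Variance-component score tests for spatially variable genes.

The model for one gene's normalized expression y over n spots is

    y = X beta + pi_1 * gamma_1(s) + ... + pi_K * gamma_K(s) + eps,
    gamma_k ~ MVN(0, tau_k K),   eps ~ MVN(0, sigma_eps^2 I),

where K is a distance-based spatial kernel and pi_k the proportion of cell
type k at each spot, so Cov(y) = sum_k tau_k Sigma_k + sigma_eps^2 I with
Sigma_k = diag(pi_k) K diag(pi_k).

Stage 1 (overall test) tests H0: tau_1 = ... = tau_K = 0 against "at least
one nonzero" — rejection declares a unified-type SVG (utSVG), covering both
genes spatially variable overall (SVGs) and within cell types (ctSVGs).
Stage 2 (individual test) tests H0: tau_k = 0 for one cell type at a time
among the utSVGs, with the other K-1 components REML-fitted as nuisance.

Both stages use the score statistic Q = 1/2 y' P Sigma_target P y with a
Satterthwaite scaled chi-square null approximation (an exact Imhof/Davies
inversion is available for verification), aggregate p-values across a
bandwidth grid by the Cauchy combination rule, and control FDR by
Benjamini-Yekutieli.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._quadform import P_FLOOR, imhof_pvalue, satterthwaite_pvalue
from ._reml import GLSFactor, RemlResult, fit_reml, variance_score_test
from .dataset import SpatialDataset, normalize_counts
from .kernels import SpatialKernel, build_kernel, default_bandwidths

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentSet",
    "NullModelFit",
    "ScoreTestResult",
    "GeneScoreTest",
    "TwoStageResult",
    "build_components",
    "fit_null_ols",
    "fit_null_reml",
    "score_statistic",
    "scaled_chisq_pvalue",
    "cauchy_combine",
    "by_adjust",
    "overall_test",
    "individual_test",
    "run_two_stage",
    "OverallSVGTest",
    "CellTypeSVGTest",
    "TwoStageSVGTest",
]

_DEGENERATE_VAR = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class ComponentSet:
    """The K cell-type spatial covariance components for one kernel.

    Sigma_k = diag(pi_k) K diag(pi_k); the components are carried through
    their roots Z_k = diag(pi_k) Z0 with K = Z0 Z0' so that per-gene fits
    can share one kernel eigendecomposition.
    """

    kernel: SpatialKernel
    composition: np.ndarray  # n x K

    @property
    def n_components(self) -> int:
        return self.composition.shape[1]

    @property
    def roots(self) -> list[np.ndarray]:
        Z0 = self.kernel.root()
        return [self.composition[:, k : k + 1] * Z0 for k in range(self.n_components)]

    @property
    def sigmas(self) -> list[np.ndarray]:
        """Dense Sigma_k matrices (small-n convenience/debugging)."""
        K = self.kernel.matrix
        return [
            (self.composition[:, k : k + 1] * K) * self.composition[:, k][None, :]
            for k in range(self.n_components)
        ]

    def overall_target(self) -> np.ndarray:
        """sum_k Sigma_k = K  elementwise*  (Pi Pi^T) — the stage-1 target."""
        return self.kernel.matrix * (self.composition @ self.composition.T)


@dataclass
class NullModelFit:
    """Fitted null model for one gene (OLS or REML with nuisance taus)."""

    beta_hat: np.ndarray
    sigma2_hat: float
    nuisance_tau_hat: np.ndarray
    factor: GLSFactor
    converged: bool = True
    n_iter: int = 0

    @property
    def degenerate(self) -> bool:
        return self.sigma2_hat <= _DEGENERATE_VAR

    def projection(self) -> np.ndarray:
        """Dense P-hat (small-n debugging; P X = 0, P V P = P)."""
        return self.factor.p_mult(np.eye(self.factor.n))


@dataclass
class ScoreTestResult:
    """One gene x one hypothesis x one bandwidth."""

    statistic: float
    scale: float
    df: float
    p_value: float
    bandwidth: float
    method: str = "satterthwaite"


@dataclass
class GeneScoreTest:
    """Bandwidth-aggregated test for one gene."""

    gene_id: str
    p_value: float
    per_bandwidth: list[ScoreTestResult] = field(default_factory=list)


@dataclass
class TwoStageResult:
    """Output of the unified two-stage procedure."""

    gene_ids: list[str]
    cell_type_ids: list[str]
    overall_p: np.ndarray
    overall_p_adj: np.ndarray
    utsvg_flags: np.ndarray
    utsvg_gene_ids: list[str]
    individual_p: np.ndarray  # (#utSVG) x K
    individual_p_adj: np.ndarray
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "overall_p": self.overall_p,
                "overall_p_adj": self.overall_p_adj,
                "utsvg_flag": self.utsvg_flags,
            }
        ).set_index("gene_id")
        for j, ct in enumerate(self.cell_type_ids):
            df[f"p_{ct}"] = np.nan
            df[f"p_adj_{ct}"] = np.nan
            df.loc[self.utsvg_gene_ids, f"p_{ct}"] = self.individual_p[:, j]
            df.loc[self.utsvg_gene_ids, f"p_adj_{ct}"] = self.individual_p_adj[:, j]
        return df.reset_index()


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------
def build_components(ds: SpatialDataset, kernel: SpatialKernel) -> ComponentSet:
    if kernel.n_spots != ds.n_spots:
        raise ValueError(
            f"kernel size {kernel.n_spots} does not match dataset n={ds.n_spots}"
        )
    return ComponentSet(kernel=kernel, composition=ds.composition)


def fit_null_ols(y: np.ndarray, X: np.ndarray) -> NullModelFit:
    """Stage-1 null: fixed effects only; sigma2 = RSS / (n - p) (REML)."""
    res = fit_reml(y, X, roots=[])
    return NullModelFit(
        beta_hat=res.beta,
        sigma2_hat=res.sigma2,
        nuisance_tau_hat=np.zeros(0),
        factor=res.factor,
        converged=True,
        n_iter=0,
    )


def fit_null_reml(
    y: np.ndarray, X: np.ndarray, nuisance: list[np.ndarray] | ComponentSet
) -> NullModelFit:
    """Stage-2 null: REML fit of the nuisance variance components.

    ``nuisance`` is a list of component roots (Z_j with Sigma_j = Z_j Z_j').
    On non-convergence the OLS null is used instead — conservative, since
    unmodelled nuisance spatial variance inflates sigma2 rather than the
    score.
    """
    roots = nuisance.roots if isinstance(nuisance, ComponentSet) else list(nuisance)
    res = fit_reml(y, X, roots=roots)
    if not res.converged:
        warnings.warn("REML null fit did not converge; falling back to OLS null")
        ols = fit_reml(y, X, roots=[])
        return NullModelFit(
            beta_hat=ols.beta,
            sigma2_hat=ols.sigma2,
            nuisance_tau_hat=np.zeros(len(roots)),
            factor=ols.factor,
            converged=False,
            n_iter=res.n_iter,
        )
    return NullModelFit(
        beta_hat=res.beta,
        sigma2_hat=res.sigma2,
        nuisance_tau_hat=res.taus,
        factor=res.factor,
        converged=True,
        n_iter=res.n_iter,
    )


def _as_root(target: np.ndarray) -> np.ndarray:
    """Root Z with target = Z Z' (eigendecomposition, zeros dropped)."""
    w, U = np.linalg.eigh(0.5 * (target + target.T))
    keep = w > 1e-12 * max(w.max(initial=0.0), 0.0)
    return U[:, keep] * np.sqrt(w[keep])


def score_statistic(y: np.ndarray, fit: NullModelFit, target: np.ndarray) -> float:
    """Q = 1/2 y' P Sigma_target P y (target given densely)."""
    if fit.degenerate:
        raise ValueError("constant gene: degenerate null fit (sigma2 = 0)")
    Py = fit.factor.p_mult(np.asarray(y, dtype=float))
    return 0.5 * float(Py @ (target @ Py))


def scaled_chisq_pvalue(
    y: np.ndarray,
    fit: NullModelFit,
    target: np.ndarray,
    bandwidth: float = np.nan,
    method: str = "satterthwaite",
    nuisance_roots: list[np.ndarray] | None = None,
) -> ScoreTestResult:
    """Moment-matched (or exact) p-value for the score statistic."""
    if fit.degenerate:
        return ScoreTestResult(0.0, np.nan, np.nan, 1.0, bandwidth, method)
    Zt = _as_root(np.asarray(target, dtype=float))
    Q, e, itilde, lambdas = variance_score_test(
        np.asarray(y, dtype=float),
        fit.factor,
        Zt,
        nuisance_roots if nuisance_roots is not None else [],
    )
    itilde *= _small_sample_factor(fit.factor)
    if method == "davies":
        p = _davies_pvalue(Q, lambdas, fit.factor)
        kappa, nu, _ = satterthwaite_pvalue(Q, e, itilde)
        return ScoreTestResult(Q, kappa, nu, p, bandwidth, "davies")
    kappa, nu, p = satterthwaite_pvalue(Q, e, itilde)
    return ScoreTestResult(Q, kappa, nu, p, bandwidth, "satterthwaite")


def _davies_pvalue(Q: float, lambdas: np.ndarray, factor) -> float:
    """Exact weighted-chi-square tail for the score statistic.

    Under an OLS null (no fitted variance components) the studentized
    statistic is an exact ratio of quadratic forms, so its tail is a signed
    weighted chi-square evaluated at zero — scale-free, accounting for the
    estimation of sigma^2 exactly. With REML-fitted nuisance components the
    plug-in weighted chi-square is used instead.
    """
    if factor.Zs.shape[1] == 0:
        nu = factor.n - factor.X.shape[1]
        lam = lambdas[lambdas > 1e-13 * max(lambdas.max(initial=0.0), 0.0)]
        weights = np.concatenate([lam - Q / nu, np.full(nu - len(lam), -Q / nu)])
        if not np.any(weights > 0):
            return 1.0
        return imhof_pvalue(0.0, weights)
    return imhof_pvalue(Q, lambdas)


def _small_sample_factor(factor) -> float:
    """Finite-sample deflation nu/(nu+2) of the matched variance.

    Exact for the OLS null, where the studentized statistic is a ratio of
    quadratic forms whose null law is that of nu * u' B u with u uniform on
    the residual sphere; applied uniformly so the K = 1 individual test
    coincides with the overall test.
    """
    nu = factor.n - factor.X.shape[1]
    return nu / (nu + 2.0)


def cauchy_combine(pvals) -> float:
    """Cauchy combination of dependent p-values (ACAT rule).

    T = mean(tan(pi (0.5 - p_i))); combined p = 0.5 - arctan(T)/pi.
    A single p-value is returned unchanged (to numerical precision).
    """
    p = np.clip(np.atleast_1d(np.asarray(pvals, dtype=float)), 1e-15, 1 - 1e-15)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    T = float(np.mean(np.tan(np.pi * (0.5 - p))))
    out = 0.5 - np.arctan(T) / np.pi
    return float(min(max(out, P_FLOOR), 1.0))


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (any dependence)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


# ---------------------------------------------------------------------------
# stage 1: vectorized overall test
# ---------------------------------------------------------------------------
def _resolve_kernels(ds: SpatialDataset, kernel_kind, bandwidth, n_bandwidths):
    if bandwidth == "auto" or bandwidth is None:
        bws = default_bandwidths(ds.coords, n_bandwidths)
    else:
        bws = [float(b) for b in np.atleast_1d(bandwidth)]
    return [build_kernel(ds.coords, kernel_kind, b) for b in bws]


def _expression_matrix(ds: SpatialDataset) -> np.ndarray:
    if ds.normalized is None:
        ds = normalize_counts(ds)
    return ds.normalized


def _stage1_pvalues(
    Y: np.ndarray,
    X: np.ndarray,
    components: list[ComponentSet],
    method: str = "satterthwaite",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene per-bandwidth stage-1 p-values, fully vectorized over genes.

    Returns (pmat of shape (q, n_bandwidths), Q of same shape).
    """
    Y = np.atleast_2d(Y)
    q, n = Y.shape
    p = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    proj = X @ XtX_inv @ X.T
    R = Y - Y @ proj  # residuals, q x n
    rss = np.sum(R * R, axis=1)
    sigma2 = rss / (n - p)
    ok = sigma2 > _DEGENERATE_VAR

    nu = n - p
    pmat = np.ones((q, len(components)))
    Qmat = np.zeros((q, len(components)))
    for b, comp in enumerate(components):
        SigT = comp.overall_target()
        MSig = SigT - proj @ SigT
        B = MSig - MSig @ proj  # M SigT M
        a = float(np.trace(B))
        bb = float(np.sum(B * B))
        S = np.sum((R @ SigT) * R, axis=1)  # r' SigT r per gene
        with np.errstate(divide="ignore", invalid="ignore"):
            Qmat[:, b] = np.where(ok, S / (2.0 * sigma2**2), 0.0)
            T = np.where(ok, S / sigma2, 0.0)  # studentized, scale-free
        # exact null moments of T = nu * (u'Bu / u'Mu), u uniform on the
        # residual sphere: E = tr(B), Var = 2 nu/(nu+2) (tr B^2 - tr(B)^2/nu)
        var_T = 2.0 * nu / (nu + 2.0) * (bb - a * a / nu)
        if a <= 0 or var_T <= 0:
            continue
        if method == "davies":
            w = np.linalg.eigvalsh(0.5 * (B + B.T))
            w = w[w > 1e-13 * w.max()]
            for g in np.flatnonzero(ok):
                pmat[g, b] = _exact_davies_ols(T[g], nu, w)
        else:
            kappa = var_T / (2.0 * a)
            df = 2.0 * a * a / var_T
            pmat[ok, b] = np.maximum(chi2.sf(T[ok] / kappa, df), P_FLOOR)
    return pmat, Qmat


def _exact_davies_ols(T: float, nu: int, eigs_B: np.ndarray) -> float:
    """Exact tail of the studentized statistic under the OLS null.

    P(T > t) = P(z' (B - (t/nu) M) z > 0) for z standard normal — a signed
    weighted chi-square evaluated at zero by Imhof inversion; the unknown
    error scale cancels in the ratio.
    """
    c = T / nu
    weights = np.concatenate([eigs_B - c, np.full(nu - len(eigs_B), -c)])
    if not np.any(weights > 0):
        return 1.0
    return imhof_pvalue(0.0, weights)


def overall_test(
    ds: SpatialDataset,
    kernels: list[SpatialKernel] | None = None,
    method: str = "satterthwaite",
    kernel_kind: str = "gaussian",
    bandwidth="auto",
    n_bandwidths: int | None = None,
) -> list[GeneScoreTest]:
    """Stage-1 overall test of all K spatial variance components per gene."""
    if kernels is None:
        kernels = _resolve_kernels(ds, kernel_kind, bandwidth, n_bandwidths)
    Y = _expression_matrix(ds)
    comps = [build_components(ds, k) for k in kernels]
    pmat, Qmat = _stage1_pvalues(Y, ds.covariates, comps, method=method)
    results = []
    for g, gid in enumerate(ds.gene_ids):
        per_bw = [
            ScoreTestResult(Qmat[g, b], np.nan, np.nan, pmat[g, b], k.bandwidth, method)
            for b, k in enumerate(kernels)
        ]
        results.append(GeneScoreTest(gid, cauchy_combine(pmat[g]), per_bw))
    return results


# ---------------------------------------------------------------------------
# stage 2: individual tests
# ---------------------------------------------------------------------------
def individual_test(
    ds: SpatialDataset,
    utsvg_genes: list[str] | None = None,
    cell_type: int | str = 0,
    kernels: list[SpatialKernel] | None = None,
    method: str = "satterthwaite",
    kernel_kind: str = "gaussian",
    bandwidth="auto",
    n_bandwidths: int | None = None,
) -> list[GeneScoreTest]:
    """Stage-2 test of tau_k = 0 for one cell type, gene by gene.

    The null model keeps the other K-1 cell-type components, REML-fitted as
    nuisance; with K = 1 and a constant composition this reduces exactly to
    the overall test (a plain kernel SVG score test).
    """
    if kernels is None:
        kernels = _resolve_kernels(ds, kernel_kind, bandwidth, n_bandwidths)
    if isinstance(cell_type, str):
        k_idx = ds.cell_type_ids.index(cell_type)
    else:
        k_idx = int(cell_type)
    if not 0 <= k_idx < ds.n_cell_types:
        raise ValueError(f"cell type index {k_idx} out of range")
    Y = _expression_matrix(ds)
    gene_lookup = {g: i for i, g in enumerate(ds.gene_ids)}
    if utsvg_genes is None:
        utsvg_genes = list(ds.gene_ids)
    missing = [g for g in utsvg_genes if g not in gene_lookup]
    if missing:
        raise ValueError(f"unknown gene ids: {missing[:5]}")
    X = ds.covariates

    per_kernel = []
    for kern in kernels:
        comp = build_components(ds, kern)
        roots = comp.roots
        per_kernel.append(
            (kern, roots[k_idx], [roots[j] for j in range(ds.n_cell_types) if j != k_idx])
        )

    results = []
    for gid in utsvg_genes:
        y = Y[gene_lookup[gid]]
        per_bw = []
        for kern, target_root, nuis_roots in per_kernel:
            fit = fit_null_reml(y, X, nuis_roots)
            if fit.degenerate:
                per_bw.append(
                    ScoreTestResult(0.0, np.nan, np.nan, 1.0, kern.bandwidth, method)
                )
                continue
            Q, e, itilde, lambdas = variance_score_test(
                y, fit.factor, target_root, nuis_roots
            )
            itilde *= _small_sample_factor(fit.factor)
            if method == "davies":
                p = _davies_pvalue(Q, lambdas, fit.factor)
                kappa, nu, _ = satterthwaite_pvalue(Q, e, itilde)
            else:
                kappa, nu, p = satterthwaite_pvalue(Q, e, itilde)
            per_bw.append(ScoreTestResult(Q, kappa, nu, p, kern.bandwidth, method))
        results.append(
            GeneScoreTest(gid, cauchy_combine([r.p_value for r in per_bw]), per_bw)
        )
    return results


# ---------------------------------------------------------------------------
# the unified two-stage procedure
# ---------------------------------------------------------------------------
def run_two_stage(
    ds: SpatialDataset,
    alpha: float = 0.05,
    kernels: list[SpatialKernel] | None = None,
    method: str = "satterthwaite",
    kernel_kind: str = "gaussian",
    bandwidth="auto",
    n_bandwidths: int | None = None,
) -> TwoStageResult:
    """Stage-1 overall test with BY FDR, then stage-2 tests on the utSVGs.

    Stage-2 BY adjustment is applied within each cell type across the
    utSVG family.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if kernels is None:
        kernels = _resolve_kernels(ds, kernel_kind, bandwidth, n_bandwidths)
    stage1 = overall_test(ds, kernels=kernels, method=method)
    overall_p = np.array([r.p_value for r in stage1])
    overall_adj = by_adjust(overall_p)
    flags = overall_adj <= alpha
    ut_genes = [g for g, f in zip(ds.gene_ids, flags) if f]

    K = ds.n_cell_types
    ind_p = np.ones((len(ut_genes), K))
    ind_adj = np.ones((len(ut_genes), K))
    if ut_genes:
        for k in range(K):
            res_k = individual_test(
                ds, utsvg_genes=ut_genes, cell_type=k, kernels=kernels, method=method
            )
            ind_p[:, k] = [r.p_value for r in res_k]
            ind_adj[:, k] = by_adjust(ind_p[:, k])
    return TwoStageResult(
        gene_ids=list(ds.gene_ids),
        cell_type_ids=list(ds.cell_type_ids),
        overall_p=overall_p,
        overall_p_adj=overall_adj,
        utsvg_flags=flags,
        utsvg_gene_ids=ut_genes,
        individual_p=ind_p,
        individual_p_adj=ind_adj,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------
class _KernelMixin:
    def _kernels(self, ds: SpatialDataset) -> list[SpatialKernel]:
        return _resolve_kernels(ds, self.kernel, self.bandwidth, self.n_bandwidths)


class OverallSVGTest(BaseEstimator, _KernelMixin):
    """Stage-1 overall spatial variance-component score test.

    Parameters
    ----------
    kernel : {"gaussian", "laplacian", "matern32"}, default="gaussian"
    bandwidth : "auto" or float or sequence of float
        "auto" selects the median-distance rule-of-thumb grid.
    n_bandwidths : int or None
        Grid size under "auto"; None means 5 for n < 1000 spots, else 1.
    method : {"satterthwaite", "davies"}
    alpha : float, FDR level for the utSVG call.

    Attributes (after ``fit``)
    --------------------------
    p_values_, p_adjusted_ : ndarray (q,) raw and BY-adjusted p-values
    significant_ : boolean ndarray (q,)
    results_ : list of GeneScoreTest with per-bandwidth detail
    """

    def __init__(
        self,
        kernel: str = "gaussian",
        bandwidth="auto",
        n_bandwidths: int | None = None,
        method: str = "satterthwaite",
        alpha: float = 0.05,
    ):
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.n_bandwidths = n_bandwidths
        self.method = method
        self.alpha = alpha

    def fit(self, dataset: SpatialDataset, y=None):
        kernels = self._kernels(dataset)
        self.bandwidths_ = [k.bandwidth for k in kernels]
        self.results_ = overall_test(dataset, kernels=kernels, method=self.method)
        self.gene_ids_ = list(dataset.gene_ids)
        self.p_values_ = np.array([r.p_value for r in self.results_])
        self.p_adjusted_ = by_adjust(self.p_values_)
        self.significant_ = self.p_adjusted_ <= self.alpha
        return self


class CellTypeSVGTest(BaseEstimator, _KernelMixin):
    """Stage-2 cell-type-specific score test (tau_k = 0 vs > 0).

    ``cell_type=None`` tests every cell type and fills the (genes x K)
    matrix ``p_matrix_``; otherwise a single column is computed.
    """

    def __init__(
        self,
        cell_type: int | str | None = None,
        kernel: str = "gaussian",
        bandwidth="auto",
        n_bandwidths: int | None = None,
        method: str = "satterthwaite",
        alpha: float = 0.05,
    ):
        self.cell_type = cell_type
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.n_bandwidths = n_bandwidths
        self.method = method
        self.alpha = alpha

    def fit(self, dataset: SpatialDataset, y=None, genes: list[str] | None = None):
        kernels = self._kernels(dataset)
        self.bandwidths_ = [k.bandwidth for k in kernels]
        self.gene_ids_ = list(genes) if genes is not None else list(dataset.gene_ids)
        if self.cell_type is None:
            types = list(range(dataset.n_cell_types))
        elif isinstance(self.cell_type, str):
            types = [dataset.cell_type_ids.index(self.cell_type)]
        else:
            types = [int(self.cell_type)]
        self.cell_type_ids_ = [dataset.cell_type_ids[k] for k in types]
        cols, adj_cols, self.results_ = [], [], {}
        for k in types:
            res = individual_test(
                dataset,
                utsvg_genes=self.gene_ids_,
                cell_type=k,
                kernels=kernels,
                method=self.method,
            )
            self.results_[dataset.cell_type_ids[k]] = res
            pk = np.array([r.p_value for r in res])
            cols.append(pk)
            adj_cols.append(by_adjust(pk))
        self.p_matrix_ = np.column_stack(cols)
        self.p_adjusted_ = np.column_stack(adj_cols)
        return self


class TwoStageSVGTest(BaseEstimator, _KernelMixin):
    """The unified two-stage procedure: utSVG detection then ctSVG tests.

    After ``fit``: ``overall_p_``, ``overall_p_adj_``, ``utsvg_mask_``,
    ``utsvg_gene_ids_``, ``individual_p_`` (#utSVG x K),
    ``individual_p_adj_`` and ``result_`` (a TwoStageResult).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        kernel: str = "gaussian",
        bandwidth="auto",
        n_bandwidths: int | None = None,
        method: str = "satterthwaite",
    ):
        self.alpha = alpha
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.n_bandwidths = n_bandwidths
        self.method = method

    def fit(self, dataset: SpatialDataset, y=None):
        kernels = self._kernels(dataset)
        self.bandwidths_ = [k.bandwidth for k in kernels]
        res = run_two_stage(
            dataset, alpha=self.alpha, kernels=kernels, method=self.method
        )
        self.result_ = res
        self.gene_ids_ = res.gene_ids
        self.overall_p_ = res.overall_p
        self.overall_p_adj_ = res.overall_p_adj
        self.utsvg_mask_ = res.utsvg_flags
        self.utsvg_gene_ids_ = res.utsvg_gene_ids
        self.individual_p_ = res.individual_p
        self.individual_p_adj_ = res.individual_p_adj
        return self
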