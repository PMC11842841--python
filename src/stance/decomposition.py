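"""Per-gene variance decomposition across cell-type spatial effects.

Fits the full mixed model (all K cell-type components plus residual error)
by constrained REML and reports, for each gene, the share of total variance
attributed to each cell type's spatial effect — the data behind stacked
variance bar plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._reml import fit_reml
from .dataset import SpatialDataset
from .kernels import SpatialKernel, build_kernel, default_bandwidths
from .testing import ComponentSet, build_components, _expression_matrix

__all__ = [
    "VarianceDecomposition",
    "estimate_components",
    "top_genes_table",
    "VarianceComponents",
]


@dataclass
class VarianceDecomposition:
    """REML estimates (tau_1..tau_K, sigma2) and variance shares.

    The share of component k is tau_k * tr(Sigma_k) / n — its average
    marginal variance per spot — divided by the total average marginal
    variance including sigma2; the last entry of ``proportions`` is the
    error share. Proportions are nonnegative and sum to one.
    """

    gene_id: str
    tau_hat: np.ndarray
    sigma2_hat: float
    proportions: np.ndarray  # K + 1, error last
    converged: bool
    n_iter: int = 0


def estimate_components(
    y: np.ndarray,
    X: np.ndarray,
    components: ComponentSet,
    gene_id: str = "",
) -> VarianceDecomposition:
    """Constrained REML over (tau_1..tau_K, sigma2) for one gene."""
    roots = components.roots
    scales = np.array([np.sum(Z * Z) / len(y) for Z in roots])  # tr(Sigma_k)/n
    if np.all(scales <= 0):
        raise ValueError("all components are zero; model not identifiable")
    res = fit_reml(np.asarray(y, dtype=float), X, roots)
    contrib = res.taus * scales
    total = contrib.sum() + res.sigma2
    if total <= 0:
        props = np.append(np.zeros(len(roots)), 1.0)
    else:
        props = np.append(contrib, res.sigma2) / total
    props = np.clip(props, 0.0, None)
    props = props / props.sum()
    return VarianceDecomposition(
        gene_id=gene_id,
        tau_hat=res.taus,
        sigma2_hat=res.sigma2,
        proportions=props,
        converged=res.converged,
        n_iter=res.n_iter,
    )


def top_genes_table(
    results: list[VarianceDecomposition],
    cell_type_index: int,
    n_top: int = 20,
    p_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rank genes by the variance share of one cell type (descending).

    Ties are broken by smaller individual-test p-value (when supplied),
    then by gene id, so the ranking does not depend on input order.
    """
    rows = [
        {
            "gene_id": r.gene_id,
            "proportion": r.proportions[cell_type_index],
            "tau": r.tau_hat[cell_type_index],
            "p_value": (p_values or {}).get(r.gene_id, np.nan),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df["_p"] = df["p_value"].fillna(np.inf)
    df = df.sort_values(
        ["proportion", "_p", "gene_id"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="_p")
    return df.head(n_top).reset_index(drop=True)


class VarianceComponents(BaseEstimator):
    """Sklearn-style estimator computing per-gene variance decompositions.

    After ``fit``: ``tau_`` (genes x K), ``sigma2_`` (genes,),
    ``proportions_`` (genes x (K+1), error last), ``converged_``,
    ``gene_ids_``; ``to_frame()`` assembles the TSV-ready table.
    """

    def __init__(
        self,
        kernel: str = "gaussian",
        bandwidth: float | str = "auto",
    ):
        self.kernel = kernel
        self.bandwidth = bandwidth

    def fit(self, dataset: SpatialDataset, y=None, genes: list[str] | None = None):
        if self.bandwidth == "auto":
            bw = default_bandwidths(dataset.coords, 1)[0]
        else:
            bw = float(self.bandwidth)
        kern = build_kernel(dataset.coords, self.kernel, bw)
        comp = build_components(dataset, kern)
        Y = _expression_matrix(dataset)
        lookup = {g: i for i, g in enumerate(dataset.gene_ids)}
        gene_list = list(genes) if genes is not None else list(dataset.gene_ids)
        self.bandwidth_ = bw
        self.gene_ids_ = gene_list
        self.cell_type_ids_ = list(dataset.cell_type_ids)
        self.results_ = [
            estimate_components(Y[lookup[g]], dataset.covariates, comp, gene_id=g)
            for g in gene_list
        ]
        self.tau_ = np.array([r.tau_hat for r in self.results_])
        self.sigma2_ = np.array([r.sigma2_hat for r in self.results_])
        self.proportions_ = np.array([r.proportions for r in self.results_])
        self.converged_ = np.array([r.converged for r in self.results_])
        return self

    def to_frame(self) -> pd.DataFrame:
        cols = {"gene_id": self.gene_ids_}
        for j, ct in enumerate(self.cell_type_ids_):
            cols[f"tau_{ct}"] = self.tau_[:, j]
        cols["sigma2"] = self.sigma2_
        for j, ct in enumerate(self.cell_type_ids_):
            cols[f"prop_{ct}"] = self.proportions_[:, j]
        cols["prop_error"] = self.proportions_[:, -1]
        return pd.DataFrame(cols)
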