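"""Small plotting helpers: stacked variance bars and p-value QQ plots."""

from __future__ import annotations

import numpy as np

__all__ = ["stacked_variance_plot", "pvalue_qq_plot"]


def stacked_variance_plot(frame, cell_type_ids, ax=None, n_top: int = 20):
    """Stacked bars of per-gene variance shares (one bar per gene).

    ``frame`` is the output of :meth:`VarianceComponents.to_frame`,
    already restricted/ordered to the genes of interest.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, n_top * 0.4), 4))
    sub = frame.head(n_top)
    bottom = np.zeros(len(sub))
    for ct in list(cell_type_ids) + ["error"]:
        vals = sub[f"prop_{ct}"].to_numpy()
        ax.bar(sub["gene_id"], vals, bottom=bottom, label=ct)
        bottom += vals
    ax.set_ylabel("variance share")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="x-small", ncol=2)
    ax.tick_params(axis="x", rotation=90, labelsize="x-small")
    return ax


def pvalue_qq_plot(pvals, ax=None, label: str | None = None):
    """Observed vs expected -log10 p under the uniform null, with the
    pointwise 95% band from the order-statistics beta distribution."""
    import matplotlib.pyplot as plt
    from scipy.stats import beta

    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    exp = (np.arange(1, m + 1) - 0.5) / m
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    lo = beta.ppf(0.025, np.arange(1, m + 1), m - np.arange(1, m + 1) + 1)
    hi = beta.ppf(0.975, np.arange(1, m + 1), m - np.arange(1, m + 1) + 1)
    ax.fill_between(-np.log10(exp), -np.log10(hi), -np.log10(lo), color="0.9")
    ax.plot(-np.log10(exp), -np.log10(np.clip(p, 1e-300, 1)), ".", ms=3, label=label)
    lim = -np.log10(1.0 / m)
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if label:
        ax.legend()
    return ax
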