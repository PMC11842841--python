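"""Spatial transcriptomics data container, IO and preprocessing.

The central object is :class:`SpatialDataset`, which jointly indexes a
gene x spot count matrix, the 2D spot coordinates, the per-spot cell-type
composition matrix ``Pi`` (rows on the simplex; one-hot at single-cell
resolution) and an optional covariate matrix ``X``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "read_spatial_dataset",
    "write_spatial_dataset",
    "filter_dataset",
    "normalize_counts",
]

_COMPOSITION_IO_TOL = 1e-3  # deconvolution tools emit rounded proportions
_COMPOSITION_TOL = 1e-6


@dataclass
class SpatialDataset:
    """Jointly indexed expression counts, coordinates and cell-type mix.

    Parameters
    ----------
    counts : ndarray of shape (q, n)
        Non-negative integer counts, genes as rows.
    coords : ndarray of shape (n, 2)
        Spot centers, in whatever length units the platform reports.
    composition : ndarray of shape (n, K)
        Per-spot cell-type proportions; each row sums to 1.
    covariates : ndarray of shape (n, p), optional
        Fixed-effect design matrix; defaults to an intercept column.
    normalized : ndarray of shape (q, n), optional
        Continuous expression, filled by :func:`normalize_counts`.
    """

    counts: np.ndarray
    coords: np.ndarray
    composition: np.ndarray
    covariates: np.ndarray | None = None
    normalized: np.ndarray | None = None
    gene_ids: list[str] = field(default_factory=list)
    spot_ids: list[str] = field(default_factory=list)
    cell_type_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.composition = np.asarray(self.composition, dtype=float)
        q, n = self.counts.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(q)]
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if not self.cell_type_ids:
            self.cell_type_ids = [f"type_{k}" for k in range(self.composition.shape[1])]
        if self.covariates is None:
            self.covariates = np.ones((n, 1))
        else:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n and self.covariates.shape[1] == n:
                self.covariates = self.covariates.T
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cell_types(self) -> int:
        return self.composition.shape[1]

    def validate(self) -> None:
        q, n = self.counts.shape
        if n < 2:
            raise ValueError("need at least 2 spots")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match n={n} spots"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.composition.shape[0] != n:
            raise ValueError("composition rows do not match number of spots")
        if self.composition.shape[1] < 1:
            raise ValueError("need at least one cell type")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.composition < -_COMPOSITION_TOL) or np.any(
            self.composition > 1 + _COMPOSITION_TOL
        ):
            raise ValueError("composition entries must lie in [0, 1]")
        row_sums = self.composition.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > _COMPOSITION_TOL):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"composition row {bad} sums to {row_sums[bad]:.6g}, not 1"
            )
        if len(self.gene_ids) != q:
            raise ValueError("gene_ids length does not match counts")
        if self.covariates.shape[0] != n:
            raise ValueError("covariates rows do not match number of spots")

    @property
    def is_single_cell(self) -> bool:
        """True when every composition row is one-hot (cell resolution)."""
        return bool(
            np.all(np.isclose(self.composition.max(axis=1), 1.0, atol=_COMPOSITION_TOL))
        )

    # -- subsetting ------------------------------------------------------
    def subset(self, genes: np.ndarray | None = None, spots: np.ndarray | None = None) -> "SpatialDataset":
        """Return a copy restricted to boolean/index masks of genes/spots."""
        g = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        s = np.arange(self.n_spots) if spots is None else np.asarray(spots)
        if g.dtype == bool:
            g = np.flatnonzero(g)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        return SpatialDataset(
            counts=self.counts[np.ix_(g, s)],
            coords=self.coords[s],
            composition=self.composition[s],
            covariates=self.covariates[s],
            normalized=None if self.normalized is None else self.normalized[np.ix_(g, s)],
            gene_ids=[self.gene_ids[i] for i in g],
            spot_ids=[self.spot_ids[i] for i in s],
            cell_type_ids=list(self.cell_type_ids),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (spots as observations)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T,
            obs=pd.DataFrame(
                self.composition,
                index=self.spot_ids,
                columns=self.cell_type_ids,
            ),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.normalized is not None:
            adata.layers["normalized"] = self.normalized.T
        return adata


def _read_counts(path: Path) -> pd.DataFrame:
    """Counts as gene x spot DataFrame from MTX (+sidecars) or dense CSV/TSV."""
    path = Path(path)
    if path.suffix == ".mtx" or path.name.endswith(".mtx.gz"):
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.parent
        feat = stem / "features.tsv"
        if not feat.exists():
            feat = stem / "genes.tsv"
        bar = stem / "barcodes.tsv"
        if feat.exists():
            genes = pd.read_csv(feat, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        else:
            genes = [f"gene_{i}" for i in range(mat.shape[0])]
        if bar.exists():
            spots = pd.read_csv(bar, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        else:
            spots = [f"spot_{i}" for i in range(mat.shape[1])]
        return pd.DataFrame(np.asarray(mat), index=genes, columns=spots)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_indexed(path: Path) -> pd.DataFrame:
    sep = "\t" if Path(path).suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def read_spatial_dataset(
    counts_path,
    coords_path,
    composition_path,
    covariates_path=None,
    strict: bool = False,
) -> SpatialDataset:
    """Assemble a :class:`SpatialDataset` from on-disk components.

    Spots are aligned by id across files; spots missing from any file are
    dropped with a warning (or raise when ``strict``). Composition rows are
    renormalized when their sum is within 1e-3 of 1, else an error is raised.
    """
    counts = _read_counts(Path(counts_path))
    coords = _read_indexed(Path(coords_path))
    comp = _read_indexed(Path(composition_path))
    if coords.shape[1] < 2:
        raise ValueError(f"{coords_path}: expected columns (spot_id, x, y)")
    cov = _read_indexed(Path(covariates_path)) if covariates_path else None

    common = [s for s in counts.columns if s in coords.index and s in comp.index]
    if cov is not None:
        common = [s for s in common if s in cov.index]
    n_union = len(set(counts.columns) | set(coords.index) | set(comp.index))
    if not common:
        raise ValueError("no common spot ids across input files")
    if len(common) < n_union:
        msg = f"dropping {n_union - len(common)} spots missing from some input file"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
        logger.warning(msg)

    counts = counts[common]
    if np.any(counts.to_numpy() < 0):
        raise ValueError(f"{counts_path}: negative counts")
    comp_mat = comp.loc[common].to_numpy(dtype=float)
    sums = comp_mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _COMPOSITION_IO_TOL):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"{composition_path}: composition row for spot {common[bad]} "
            f"sums to {sums[bad]:.4g} (beyond tolerance {_COMPOSITION_IO_TOL})"
        )
    needs = np.abs(sums - 1.0) > 1e-12  # leave already-exact rows untouched
    comp_mat[needs] = comp_mat[needs] / sums[needs, None]

    return SpatialDataset(
        counts=counts.to_numpy(dtype=float),
        coords=coords.loc[common].iloc[:, :2].to_numpy(dtype=float),
        composition=comp_mat,
        covariates=None if cov is None else cov.loc[common].to_numpy(dtype=float),
        gene_ids=list(counts.index),
        spot_ids=list(common),
        cell_type_ids=list(comp.columns),
    )


def write_spatial_dataset(ds: SpatialDataset, out_dir) -> None:
    """Write counts/coords/composition (full precision, round-trippable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.counts, index=ds.gene_ids, columns=ds.spot_ids).to_csv(
        out / "counts.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(
        ds.coords, index=pd.Index(ds.spot_ids, name="spot_id"), columns=["x", "y"]
    ).to_csv(out / "coords.csv", float_format="%.17g")
    pd.DataFrame(
        ds.composition,
        index=pd.Index(ds.spot_ids, name="spot_id"),
        columns=ds.cell_type_ids,
    ).to_csv(out / "composition.csv", float_format="%.17g")


def filter_dataset(
    ds: SpatialDataset, min_spot_total: int = 10, min_expr_frac: float = 0.1
) -> SpatialDataset:
    """Quality control: drop shallow spots, then rarely expressed genes.

    Spots with total count below ``min_spot_total`` are removed first; genes
    with nonzero expression in fewer than ``min_expr_frac`` of the remaining
    spots are then removed. Defaults follow the common convention of
    requiring >=10 counts per spot and expression in >=10% of spots.
    """
    if min_spot_total < 0 or not 0 <= min_expr_frac <= 1:
        raise ValueError("invalid QC thresholds")
    spot_keep = ds.counts.sum(axis=0) >= min_spot_total
    if not spot_keep.any():
        raise ValueError("empty dataset after QC: all spots removed")
    sub = ds.subset(spots=spot_keep)
    expr_frac = (sub.counts > 0).mean(axis=1)
    gene_keep = expr_frac >= min_expr_frac
    if not gene_keep.any():
        raise ValueError("empty dataset after QC: all genes removed")
    return sub.subset(genes=gene_keep)


def normalize_counts(ds: SpatialDataset, method: str = "pearson") -> SpatialDataset:
    """Populate ``normalized`` with a depth-corrected continuous matrix.

    ``pearson`` (default): analytic Pearson residuals under a depth x gene
    negative-binomial null (overdispersion theta = 100), clipped at
    +/- sqrt(n). Residuals have approximately unit variance at every spot
    regardless of its sequencing depth, which matters for the downstream
    homoskedastic Gaussian model: spots aggregating few cells would
    otherwise carry inflated noise that a spatial test can mistake for
    signal.
    ``log_cpm_median``: per-spot size factor = spot total / median spot
    total; normalized value = log(count / size_factor + 1).
    ``log1p_size_factor``: counts-per-10k then log1p (scanpy convention).

    Gene-wise centering is deliberately not applied; the intercept in the
    downstream fixed-effect design absorbs the mean.
    """
    totals = ds.counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("spot with zero total count; run filter_dataset first")
    if method == "pearson":
        theta = 100.0
        grand = ds.counts.sum()
        mu = ds.counts.sum(axis=1, keepdims=True) * (totals[None, :] / grand)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = (ds.counts - mu) / np.sqrt(mu + mu**2 / theta)
        norm = np.where(np.isfinite(norm), norm, 0.0)
        clip = np.sqrt(ds.n_spots)
        norm = np.clip(norm, -clip, clip)
    elif method == "log_cpm_median":
        size = totals / np.median(totals)
        norm = np.log(ds.counts / size[None, :] + 1.0)
    elif method == "log1p_size_factor":
        norm = np.log1p(ds.counts * 1e4 / totals[None, :])
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return replace(ds, normalized=norm)
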