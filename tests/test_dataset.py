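import dataclasses

import numpy as np
import pandas as pd
import pytest

from stance import (
    SpatialDataset,
    filter_dataset,
    normalize_counts,
    read_spatial_dataset,
    write_spatial_dataset,
)

from conftest import make_dataset


def _write_inputs(tmp_path, counts, coords, comp, spot_ids, gene_ids, ct_ids):
    cpath = tmp_path / "counts.csv"
    pd.DataFrame(counts, index=gene_ids, columns=spot_ids).to_csv(cpath)
    spath = tmp_path / "coords.csv"
    pd.DataFrame(coords, index=pd.Index(spot_ids, name="spot_id"), columns=["x", "y"]).to_csv(spath)
    ppath = tmp_path / "composition.csv"
    pd.DataFrame(comp, index=pd.Index(spot_ids, name="spot_id"), columns=ct_ids).to_csv(ppath)
    return cpath, spath, ppath


class TestReadDataset:
    def test_round_trip_construction(self, tmp_path):
        counts = np.arange(12).reshape(3, 4).astype(float)
        coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]])
        comp = np.tile([0.4, 0.6], (4, 1))
        paths = _write_inputs(
            tmp_path, counts, coords, comp,
            ["s1", "s2", "s3", "s4"], ["g1", "g2", "g3"], ["A", "B"],
        )
        ds = read_spatial_dataset(*paths)
        assert (ds.n_genes, ds.n_spots, ds.n_cell_types) == (3, 4, 2)
        np.testing.assert_array_equal(ds.counts, counts)
        np.testing.assert_array_equal(ds.coords, coords)

    def test_intersection_drops_missing_spots_with_warning(self, tmp_path):
        counts = np.ones((2, 4))
        coords = np.random.default_rng(0).uniform(size=(5, 2))
        comp = np.tile([0.5, 0.5], (5, 1))
        spot5 = ["s1", "s2", "s3", "s4", "s5"]
        pd.DataFrame(counts, index=["g1", "g2"], columns=spot5[:4]).to_csv(tmp_path / "c.csv")
        pd.DataFrame(coords, index=pd.Index(spot5, name="spot_id"), columns=["x", "y"]).to_csv(tmp_path / "s.csv")
        pd.DataFrame(comp, index=pd.Index(spot5, name="spot_id"), columns=["A", "B"]).to_csv(tmp_path / "p.csv")
        with pytest.warns(UserWarning, match="dropping 1 spots"):
            ds = read_spatial_dataset(tmp_path / "c.csv", tmp_path / "s.csv", tmp_path / "p.csv")
        assert ds.n_spots == 4

    def test_bad_composition_row_sum_rejected(self, tmp_path):
        counts = np.ones((2, 2))
        coords = np.array([[0, 0], [1, 1.0]])
        comp = np.array([[0.6, 0.6], [0.5, 0.5]])
        paths = _write_inputs(tmp_path, counts, coords, comp, ["s1", "s2"], ["g1", "g2"], ["A", "B"])
        with pytest.raises(ValueError, match="sums to 1.2"):
            read_spatial_dataset(*paths)

    def test_write_read_round_trip_bit_exact(self, tmp_path):
        ds = make_dataset(n=10, q=5, seed=3, normalized=False)
        write_spatial_dataset(ds, tmp_path)
        back = read_spatial_dataset(
            tmp_path / "counts.tsv", tmp_path / "coords.csv", tmp_path / "composition.csv"
        )
        np.testing.assert_array_equal(back.counts, ds.counts)
        np.testing.assert_array_equal(back.coords, ds.coords)
        np.testing.assert_array_equal(back.composition, ds.composition)

    def test_mtx_with_sidecars(self, tmp_path):
        from scipy import io as spio
        from scipy import sparse

        counts = sparse.csr_matrix(np.array([[0, 2, 0], [1, 0, 3.0]]))
        spio.mmwrite(tmp_path / "counts.mtx", counts)
        (tmp_path / "features.tsv").write_text("gA\ngB\n")
        (tmp_path / "barcodes.tsv").write_text("s1\ns2\ns3\n")
        coords = np.array([[0, 0], [0, 1], [1, 0.0]])
        comp = np.tile([0.3, 0.7], (3, 1))
        pd.DataFrame(coords, index=pd.Index(["s1", "s2", "s3"], name="spot_id"),
                     columns=["x", "y"]).to_csv(tmp_path / "coords.csv")
        pd.DataFrame(comp, index=pd.Index(["s1", "s2", "s3"], name="spot_id"),
                     columns=["A", "B"]).to_csv(tmp_path / "composition.csv")
        ds = read_spatial_dataset(
            tmp_path / "counts.mtx", tmp_path / "coords.csv", tmp_path / "composition.csv"
        )
        assert ds.gene_ids == ["gA", "gB"]
        np.testing.assert_array_equal(ds.counts, counts.toarray())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SpatialDataset(
                counts=np.array([[1.0, -2.0]]),
                coords=np.zeros((2, 2)),
                composition=np.tile([1.0], (2, 1)),
            )


class TestFilter:
    def test_hand_worked_example(self):
        # totals per spot: 1, 2, 8 (all >= 1); gene 0 expressed in 1/3 < 0.5
        ds = SpatialDataset(
            counts=np.array([[0, 0, 5], [1, 2, 3.0]]),
            coords=np.array([[0, 0], [0, 1], [1, 0.0]]),
            composition=np.tile([0.5, 0.5], (3, 1)),
        )
        out = filter_dataset(ds, min_spot_total=1, min_expr_frac=0.5)
        assert out.gene_ids == ["gene_1"]
        assert out.n_spots == 3

    def test_no_thresholds_identity(self, small_dataset):
        out = filter_dataset(small_dataset, 0, 0.0)
        np.testing.assert_array_equal(out.counts, small_dataset.counts)

    def test_full_presence_boundary(self):
        ds = SpatialDataset(
            counts=np.array([[1, 0], [2, 3.0]]),
            coords=np.array([[0, 0], [1, 1.0]]),
            composition=np.ones((2, 1)),
        )
        out = filter_dataset(ds, 0, 1.0)
        assert out.gene_ids == ["gene_1"]

    def test_idempotent(self):
        ds = make_dataset(n=30, q=20, seed=1, normalized=False, counts_scale=2)
        once = filter_dataset(ds, 30, 0.5)
        twice = filter_dataset(once, 30, 0.5)
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_empty_after_qc_raises(self, small_dataset):
        with pytest.raises(ValueError, match="empty dataset"):
            filter_dataset(small_dataset, 10**9, 0.0)


class TestNormalize:
    def test_equal_totals_log_is_log1p(self):
        counts = np.array([[1, 1], [3, 3.0]])  # both spots total 4
        ds = SpatialDataset(
            counts=counts, coords=np.array([[0, 0], [1, 1.0]]),
            composition=np.ones((2, 1)),
        )
        out = normalize_counts(ds, "log_cpm_median")
        np.testing.assert_allclose(out.normalized, np.log(counts + 1))

    def test_zero_count_maps_to_zero_under_log_methods(self):
        ds = SpatialDataset(
            counts=np.array([[0, 2], [4, 2.0]]),
            coords=np.array([[0, 0], [1, 1.0]]),
            composition=np.ones((2, 1)),
        )
        for method in ("log_cpm_median", "log1p_size_factor"):
            out = normalize_counts(ds, method)
            assert out.normalized[0, 0] == 0.0

    def test_size_factors_from_spot_totals(self):
        counts = np.array([[100, 200, 300.0]])
        ds = SpatialDataset(
            counts=counts,
            coords=np.array([[0, 0], [0, 1], [1, 0.0]]),
            composition=np.ones((3, 1)),
        )
        out = normalize_counts(ds, "log_cpm_median")
        expected = np.log(counts / np.array([0.5, 1.0, 1.5]) + 1)
        np.testing.assert_allclose(out.normalized, expected)

    def test_monotone_within_spot(self):
        ds = make_dataset(n=12, q=15, seed=2, normalized=False)
        for method in ("log_cpm_median", "log1p_size_factor"):
            out = normalize_counts(ds, method)
            for j in range(ds.n_spots):
                order = np.argsort(ds.counts[:, j], kind="stable")
                vals = out.normalized[order, j]
                assert np.all(np.diff(vals) >= -1e-12)

    def test_pearson_residuals_depth_invariant_variance(self):
        # two depth groups; residual spread should not track depth
        r = np.random.default_rng(5)
        depth = np.repeat([5.0, 50.0], 30)
        counts = r.poisson(depth[None, :] * np.ones((400, 1)))
        ds = SpatialDataset(
            counts=counts.astype(float),
            coords=r.uniform(size=(60, 2)),
            composition=np.ones((60, 1)),
        )
        out = normalize_counts(ds, "pearson")
        sd = out.normalized.std(axis=0)
        assert 0.5 < sd[:30].mean() / sd[30:].mean() < 2.0

    def test_zero_total_spot_rejected(self):
        ds = SpatialDataset(
            counts=np.array([[0, 2.0]]),
            coords=np.array([[0, 0], [1, 1.0]]),
            composition=np.ones((2, 1)),
        )
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(ds)


class TestInvariants:
    def test_single_cell_mode_flag(self):
        comp = np.eye(3)[np.array([0, 1, 2, 1])]
        ds = SpatialDataset(
            counts=np.ones((2, 4)), coords=np.random.default_rng(0).uniform(size=(4, 2)),
            composition=comp,
        )
        assert ds.is_single_cell

    def test_coords_must_be_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            SpatialDataset(
                counts=np.ones((1, 2)),
                coords=np.array([[0, np.nan], [1, 1.0]]),
                composition=np.ones((2, 1)),
            )

    def test_to_anndata_round_trip_shapes(self, small_dataset):
        adata = small_dataset.to_anndata()
        assert adata.shape == (small_dataset.n_spots, small_dataset.n_genes)
        np.testing.assert_array_equal(adata.obsm["spatial"], small_dataset.coords)
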