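import numpy as np
import pytest

from stance.simulate import (
    FOLD_CHANGE_GROUPS,
    CellLevelData,
    SimulationConfig,
    aggregate_to_spots,
    assign_cell_types,
    assign_domains_sim1,
    assign_domains_sim2,
    misspecify_composition,
    simulate_cells,
    simulate_dataset,
    simulate_expression,
    _nb_draw,
)


class TestCells:
    def test_deterministic_under_seed(self):
        a = simulate_cells(500, 7)
        b = simulate_cells(500, 7)
        np.testing.assert_array_equal(a, b)

    def test_unit_square(self):
        c = simulate_cells(2000, 1)
        assert np.all((c >= 0) & (c <= 1))

    def test_poisson_count_concentration(self):
        c = simulate_cells(10000, 3)
        assert abs(len(c) - 10000) < 4 * np.sqrt(10000)


class TestDomains:
    def test_background_default_and_disc_membership(self):
        coords = np.random.default_rng(0).uniform(0, 1, (3000, 2))
        labels, geom = assign_domains_sim1(coords, 5)
        centers, radii = geom["centers"], geom["radii"]
        d2 = np.linalg.norm(coords - centers[0], axis=1) <= radii[0]
        d3 = np.linalg.norm(coords - centers[1], axis=1) <= radii[1]
        assert np.all(labels[~d2 & ~d3] == 1)
        small = 2 if radii[0] <= radii[1] else 3
        assert np.all(labels[d2 & d3] == small)

    def test_radii_in_stated_range(self):
        for seed in range(20):
            coords = np.random.default_rng(seed).uniform(0, 1, (50, 2))
            _, geom = assign_domains_sim1(coords, seed)
            assert np.all((geom["radii"] >= 0.1) & (geom["radii"] <= 0.5))

    def test_sim2_two_domains_radius_range(self):
        coords = np.random.default_rng(1).uniform(0, 1, (1000, 2))
        labels, geom = assign_domains_sim2(coords, 9)
        assert set(np.unique(labels)) <= {1, 2}
        assert 0.2 <= geom["radii"][0] <= 0.4


class TestCellTypes:
    @pytest.mark.parametrize(
        "scenario,probs",
        [("s1", (0.15, 0.15, 0.70)), ("s2", (0.3, 0.3, 0.4)), ("s3", (0.45, 0.45, 0.1))],
    )
    def test_scenario_shares(self, scenario, probs):
        doms = np.ones(100_000, dtype=int)
        labels = assign_cell_types(doms, "sim1_null", scenario, 0)
        for k, p in enumerate(probs, start=1):
            share = (labels == k).mean()
            assert abs(share - p) < 3 * np.sqrt(p * (1 - p) / len(doms))

    def test_sim2_fixed_shares(self):
        doms = np.ones(50_000, dtype=int)
        labels = assign_cell_types(doms, "sim2", "s2", 0)
        np.testing.assert_allclose(
            [(labels == k).mean() for k in (1, 2, 3)], [0.1, 0.3, 0.6], atol=0.02
        )

    def test_alt3_domain_restricted_pairs(self):
        doms = np.repeat([1, 2, 3], 2000)
        labels = assign_cell_types(doms, "sim1_alt3", "s2", 4)
        assert set(labels[doms == 1]) <= {1, 2}
        assert set(labels[doms == 2]) <= {2, 3}
        assert set(labels[doms == 3]) <= {1, 3}
        assert abs((labels[doms == 1] == 1).mean() - 0.5) < 0.05


class TestExpression:
    def test_nb_variance_formula(self):
        rng = np.random.default_rng(0)
        x = _nb_draw(rng, np.ones(100_000), 0.7)
        var = 1 + 1 / 0.7
        assert abs(x.mean() - 1) < 0.02
        assert abs(x.var() - var) / var < 0.05

    def test_zero_fold_change_is_point_mass(self):
        rng = np.random.default_rng(0)
        assert np.all(_nb_draw(rng, np.zeros(100), 0.7) == 0)

    def _cells(self, design, n=4000, seed=2):
        coords = simulate_cells(n, seed)
        if design == "sim2":
            doms, geom = assign_domains_sim2(coords, seed)
        else:
            doms, geom = assign_domains_sim1(coords, seed)
        types = assign_cell_types(doms, design, "s2", seed)
        return CellLevelData(coords, doms, types, domain_geometry=geom)

    def test_alt2_zero_domains(self):
        cells = simulate_expression(self._cells("sim1_alt2"), "sim1_alt2", 0.7, 1)
        t1_d2 = (cells.type_labels == 1) & (cells.domain_labels == 2)
        t2_d1 = (cells.type_labels == 2) & (cells.domain_labels == 1)
        ctsvg = cells.gene_truth["role"] == "ctsvg"
        assert np.all(cells.counts[np.ix_(ctsvg, t1_d2)] == 0)
        assert np.all(cells.counts[np.ix_(ctsvg, t2_d1)] == 0)

    @pytest.mark.parametrize(
        "design,expected",
        [
            ("sim1_null", {"marker": 300, "null": 700}),
            ("sim1_alt1", {"marker": 300, "svg": 600, "null": 100}),
            ("sim1_alt2", {"marker": 300, "ctsvg": 700}),
            ("sim1_alt3", {"svg_marker": 600, "null": 400}),
            ("sim2", {"marker": 300, "ctsvg": 600, "null": 100}),
        ],
    )
    def test_gene_truth_partitions(self, design, expected):
        cells = simulate_expression(self._cells(design, n=500), design, 0.7, 1)
        roles, counts = np.unique(cells.gene_truth["role"], return_counts=True)
        assert dict(zip(roles, counts)) == expected

    def test_fold_change_groups_recorded(self):
        cells = simulate_expression(self._cells("sim2"), "sim2", 1.5, 1)
        ct = cells.gene_truth[cells.gene_truth["role"] == "ctsvg"]
        for fc in FOLD_CHANGE_GROUPS:
            assert (ct["fold_change"] == fc).sum() == 150  # 50 per type


class TestAggregation:
    @pytest.mark.parametrize("grid,n_expected", [(0.03125, 1024), (0.05, 400)])
    def test_grid_counts(self, grid, n_expected):
        m = int(np.ceil(1 / grid))
        assert m * m == n_expected

    def test_count_conservation_and_composition(self):
        cells = simulate_expression(
            TestExpression()._cells("sim2", n=1000), "sim2", 0.7, 3
        )
        ds = aggregate_to_spots(cells, 0.05)
        np.testing.assert_array_equal(
            ds.counts.sum(axis=1), cells.counts.sum(axis=1)
        )
        np.testing.assert_allclose(ds.composition.sum(axis=1), 1.0, atol=1e-12)
        assert ds.n_spots <= 400
        assert np.all((ds.coords >= 0) & (ds.coords <= 1))

    def test_spot_coordinates_are_member_centroids(self):
        coords = np.array([[0.01, 0.01], [0.03, 0.03], [0.9, 0.9]])
        cells = CellLevelData(
            coords,
            np.ones(3, dtype=int),
            np.array([1, 2, 1]),
            counts=np.array([[1, 2, 3.0]]),
        )
        ds = aggregate_to_spots(cells, 0.05)
        assert ds.n_spots == 2
        np.testing.assert_allclose(ds.coords[0], [0.02, 0.02])
        np.testing.assert_allclose(ds.composition[0], [0.5, 0.5])


class TestMisspecify:
    def test_four_fake_types_on_simplex(self):
        ds, _ = simulate_dataset(SimulationConfig(design="sim1_null", n_cells=400, seed=1))
        out = misspecify_composition(ds, 2)
        assert out.n_cell_types == 4
        np.testing.assert_allclose(out.composition.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_and_flat_mean(self):
        ds, _ = simulate_dataset(SimulationConfig(design="sim1_null", n_cells=2000, seed=1))
        a = misspecify_composition(ds, 5)
        b = misspecify_composition(ds, 5)
        np.testing.assert_array_equal(a.composition, b.composition)
        np.testing.assert_allclose(a.composition.mean(axis=0), 0.25, atol=0.05)


class TestPipelinePurity:
    def test_full_generator_is_pure_function_of_seed(self):
        cfg = SimulationConfig(design="sim2", n_cells=500, dispersion=1.5, seed=11)
        d1, c1 = simulate_dataset(cfg)
        d2, c2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.counts, d2.counts)
        np.testing.assert_array_equal(d1.coords, d2.coords)
        np.testing.assert_array_equal(c1.gene_truth["fold_change"], c2.gene_truth["fold_change"])

    def test_design_defaults(self):
        c1 = SimulationConfig(design="sim1_null")
        assert (c1.n_cells, c1.grid_size) == (10000, 0.03125)
        c2 = SimulationConfig(design="sim2")
        assert (c2.n_cells, c2.grid_size) == (4000, 0.05)

    def test_sim2_rejects_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            SimulationConfig(design="sim2", scenario="s1")
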