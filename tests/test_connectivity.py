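"""IIC, dIIC and its decomposition, scenario sweeps and dispersal
sensitivity, checked against hand-derived values and brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import box

from conftest import (
    brute_force_iic,
    floyd_warshall_nl,
    graph_edge_index_pairs,
    random_patch_graph,
)
from habconn import (
    SimulationSpec,
    SpeciesProfile,
    build_hex_grid,
    diic,
    diic_components,
    dispersal_sensitivity,
    gen_habitat_raster,
    habitat_fractions,
    iic,
    iic_numerator,
    label_patches,
    node_importance_table,
    scenario_sweep,
)
from habconn.patches import PatchGraph


def single_patch_graph(area, A_L):
    return PatchGraph(np.array([1]), np.array([area]), {}, A_L=A_L,
                      dispersal_distance_km=1.0)


class TestIic:
    def test_single_patch_filling_landscape(self):
        assert iic(single_patch_graph(10.0, 10.0)) == 1.0

    def test_two_disconnected_unit_patches(self):
        g = PatchGraph(np.array([1, 2]), np.array([1.0, 1.0]), {}, A_L=10.0,
                       dispersal_distance_km=1.0)
        assert iic(g) == pytest.approx(0.02)

    def test_three_node_path_hand_value(self, path3_graph):
        # ordered pairs: 3 diagonal + 4 x 1/2 (adjacent) + 2 x 1/3 (ends)
        assert iic_numerator(path3_graph) == pytest.approx(17 / 3, abs=1e-12)
        assert iic(path3_graph) == pytest.approx(17 / 300, abs=1e-12)

    def test_zero_landscape_area_rejected(self):
        with pytest.raises(ValueError):
            PatchGraph(np.array([1]), np.array([1.0]), {}, A_L=0.0,
                       dispersal_distance_km=1.0)


class TestDiic:
    def test_only_node_is_everything(self):
        assert diic(single_patch_graph(5.0, 20.0), 1) == pytest.approx(100.0)

    def test_isolated_node_loses_only_its_diagonal_term(self):
        g = PatchGraph(np.array([1, 2, 3]), np.array([2.0, 1.0, 1.0]),
                       {(2, 3): 0.5}, A_L=20.0, dispersal_distance_km=1.0)
        num = iic_numerator(g)
        assert diic(g, 1) == pytest.approx(100 * 4.0 / num, abs=1e-12)

    def test_middle_of_path_hand_value(self, path3_graph):
        assert diic(path3_graph, 2) == pytest.approx(100 * (17 / 3 - 2) / (17 / 3))

    def test_unknown_node_rejected(self, path3_graph):
        with pytest.raises(ValueError, match="unknown"):
            diic(path3_graph, 9)


class TestDecomposition:
    def test_isolated_node_pure_intra(self):
        g = PatchGraph(np.array([1, 2, 3]), np.array([2.0, 1.0, 1.0]),
                       {(2, 3): 0.5}, A_L=20.0, dispersal_distance_km=1.0)
        intra, flux, conn = diic_components(g, 1)
        assert flux == 0.0 and conn == 0.0
        assert intra == pytest.approx(diic(g, 1))

    def test_leaf_has_no_connector_role(self, path3_graph):
        _, _, conn = diic_components(path3_graph, 1)
        assert conn == pytest.approx(0.0, abs=1e-12)

    def test_middle_of_path_hand_values(self, path3_graph):
        intra, flux, conn = diic_components(path3_graph, 2)
        num = 17 / 3
        assert intra == pytest.approx(100 * 1 / num)        # ~17.65
        assert flux == pytest.approx(100 * 2 / num)         # ~35.29
        assert conn == pytest.approx(100 * (2 / 3) / num)   # ~11.76
        assert intra + flux + conn == pytest.approx(diic(path3_graph, 2))

    @pytest.mark.parametrize("seed", range(10))
    def test_sums_to_diic_on_random_graphs(self, seed):
        g = random_patch_graph(np.random.default_rng(seed), n_max=25)
        for nid in g.node_ids:
            parts = diic_components(g, int(nid))
            assert sum(parts) == pytest.approx(diic(g, int(nid)), abs=1e-9)
            assert parts[0] >= 0 and parts[1] >= 0 and parts[2] >= -1e-12

    def test_table_matches_per_node_calls(self, path3_graph):
        table = node_importance_table(path3_graph)
        for _, row in table.iterrows():
            assert row["dIIC_pct"] == pytest.approx(diic(path3_graph, int(row["id"])))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_iic_and_diic_match_brute_force(self, seed):
        g = random_patch_graph(np.random.default_rng(1000 + seed), n_max=30)
        nl = floyd_warshall_nl(g.n, graph_edge_index_pairs(g))
        assert iic(g) == pytest.approx(brute_force_iic(g.node_areas, nl, g.A_L),
                                       abs=1e-12)
        nid = int(g.node_ids[seed % g.n])
        sub = g.without_node(nid)
        nl_sub = floyd_warshall_nl(sub.n, graph_edge_index_pairs(sub))
        expected = 100 * (
            brute_force_iic(g.node_areas, nl, g.A_L)
            - brute_force_iic(sub.node_areas, nl_sub, g.A_L)
        ) / brute_force_iic(g.node_areas, nl, g.A_L)
        assert diic(g, nid) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_importance_overlap_lower_bound(self, seed):
        g = random_patch_graph(np.random.default_rng(50 + seed), n_max=15)
        total = sum(diic(g, int(nid)) for nid in g.node_ids)
        assert total >= 100 * (g.node_areas**2).max() / iic_numerator(g) - 1e-9


class TestHabitatRemovalMonotonicity:
    @pytest.mark.parametrize("seed", range(4))
    def test_deleting_a_cell_never_raises_iic(self, seed):
        hab = gen_habitat_raster(SimulationSpec(20, 20, 1.0, 0.3, 1.0, seed=seed))
        A_L = 400.0
        base = iic(build_graph_from(hab, A_L))
        rng = np.random.default_rng(seed)
        cells = np.argwhere(hab.values == 1)
        for r, c in cells[rng.choice(len(cells), size=5, replace=False)]:
            trimmed = hab.copy()
            trimmed.values[r, c] = 0
            assert iic(build_graph_from(trimmed, A_L)) <= base + 1e-15


def build_graph_from(hab, A_L, dispersal=1.5):
    from habconn import build_graph

    return build_graph(label_patches(hab), dispersal, A_L)


class TestSweeps:
    def _setup(self, seed=3):
        hab = gen_habitat_raster(SimulationSpec(40, 40, 4.5, 0.35, 2.5, seed=seed))
        region = box(0, 0, 180, 180)
        grid = habitat_fractions(build_hex_grid(region, 1200.0), hab)
        return hab, grid, 1600 * 20.25

    def test_zero_threshold_equals_unfiltered(self):
        hab, grid, A_L = self._setup()
        table = scenario_sweep(hab, grid, [0.0], SpeciesProfile("s", "both"), A_L)
        assert table["iic"].iloc[0] == pytest.approx(iic(build_graph_from(hab, A_L, 1.0)))

    def test_threshold_above_all_fractions_gives_zero(self):
        hab, grid, A_L = self._setup()
        table = scenario_sweep(hab, grid, [0.99], SpeciesProfile("s", "both"), A_L)
        assert table["iic"].iloc[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_iic_monotone_in_scenario_threshold(self, seed):
        hab, grid, A_L = self._setup(seed)
        table = scenario_sweep(
            hab, grid, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7],
            SpeciesProfile("s", "both"), A_L,
        )
        vals = table["iic"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-15)

    def test_unsorted_thresholds_rejected(self):
        hab, grid, A_L = self._setup()
        with pytest.raises(ValueError, match="ascending"):
            scenario_sweep(hab, grid, [0.3, 0.1], SpeciesProfile("s", "both"), A_L)


class TestDispersalSensitivity:
    def test_repeated_distance_identical(self):
        hab = gen_habitat_raster(SimulationSpec(20, 20, 1.0, 0.3, 1.0, seed=2))
        ps = label_patches(hab)
        t = dispersal_sensitivity(ps, [1.0, 1.0], 400.0)
        assert t["iic"].iloc[0] == t["iic"].iloc[1]

    def test_below_all_gaps_diagonal_only(self):
        ps = label_patches(
            gen_habitat_raster(SimulationSpec(15, 15, 1.0, 0.2, 0.0, seed=7))
        )
        a = ps.areas()
        t = dispersal_sensitivity(ps, [1e-9], 225.0)
        assert t["iic"].iloc[0] == pytest.approx((a**2).sum() / 225.0**2)

    def test_above_all_gaps_complete_graph(self):
        ps = label_patches(
            gen_habitat_raster(SimulationSpec(15, 15, 1.0, 0.2, 0.0, seed=7))
        )
        a = ps.areas()
        t = dispersal_sensitivity(ps, [1e4], 225.0)
        off_diag = np.outer(a, a).sum() - (a**2).sum()
        expected = ((a**2).sum() + off_diag / 2.0) / 225.0**2
        assert t["iic"].iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_iic_non_decreasing_in_distance(self, seed):
        ps = label_patches(
            gen_habitat_raster(SimulationSpec(25, 25, 1.0, 0.3, 1.5, seed=seed))
        )
        t = dispersal_sensitivity(ps, [0.5, 1.0, 1.5, 3.0, 6.0], 625.0)
        assert np.all(np.diff(t["iic"].to_numpy()) >= -1e-15)
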