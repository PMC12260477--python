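"""Patch labeling, inter-patch distances, graph construction, CONEFOR I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import floyd_warshall_nl, graph_edge_index_pairs, random_patch_graph
from habconn import (
    GridRaster,
    SimulationSpec,
    build_graph,
    gen_habitat_raster,
    interpatch_distance,
    label_patches,
    read_conefor,
    write_conefor,
)


def braster(values, cell=1.0):
    return GridRaster(np.asarray(values), cell, kind="binary")


class TestLabelPatches:
    def test_empty_raster(self):
        assert len(label_patches(braster(np.zeros((5, 5))))) == 0

    def test_single_cell(self):
        r = braster(np.eye(3, dtype=int) * np.array([1, 0, 0]), cell=2.0)
        ps = label_patches(r)
        assert len(ps) == 1
        assert ps.patches[0].area_km2 == 4.0

    def test_diagonal_touching_depends_on_connectivity(self):
        r = braster([[1, 0], [0, 1]])
        assert len(label_patches(r, connectivity=8)) == 1
        assert len(label_patches(r, connectivity=4)) == 2

    def test_ids_follow_row_major_first_cell(self):
        r = braster([[0, 0, 1], [1, 0, 1], [1, 0, 0]])
        ps = label_patches(r, connectivity=4)
        firsts = [min(p.cells) for p in ps.patches]
        assert firsts == sorted(firsts)

    @pytest.mark.parametrize("seed", range(4))
    def test_area_conservation(self, seed):
        hab = gen_habitat_raster(SimulationSpec(30, 30, 2.0, 0.4, 1.5, seed=seed))
        ps = label_patches(hab)
        assert ps.total_area_km2 == pytest.approx(hab.values.sum() * 4.0)
        covered = set().union(*(p.cells for p in ps.patches)) if ps.patches else set()
        assert len(covered) == hab.values.sum()


class TestInterpatchDistance:
    def test_orthogonally_adjacent_edge_distance_zero(self):
        # hand-built patch set: labeling would merge touching cells
        from habconn.patches import Patch, PatchSet

        labels = np.array([[1, 2]])
        ps = PatchSet(
            patches=[
                Patch(1, frozenset({(0, 0)}), 1.0),
                Patch(2, frozenset({(0, 1)}), 1.0),
            ],
            labels=labels,
            cell_size_km=1.0,
        )
        assert interpatch_distance(ps, 1, 2, metric="edge") == 0.0

    def test_diagonally_adjacent_cells_in_different_patches(self):
        # 4-connectivity splits a diagonal pair; their centers are sqrt(2) apart
        ps = label_patches(braster([[1, 0], [0, 1]]), connectivity=4)
        d = interpatch_distance(ps, 1, 2, metric="edge")
        assert d == pytest.approx(max(0.0, np.sqrt(2) - 1.0))

    def test_two_cell_gap_edge_distance(self):
        ps = label_patches(braster([[1, 0, 1]]))
        assert interpatch_distance(ps, 1, 2, metric="edge") == pytest.approx(1.0)

    def test_centroid_three_four_five(self):
        v = np.zeros((5, 4), dtype=int)
        v[4, 0] = 1   # center (0.5, 0.5)
        v[0, 3] = 1   # center (3.5, 4.5)
        ps = label_patches(braster(v))
        assert interpatch_distance(ps, 1, 2, metric="centroid") == pytest.approx(5.0)

    def test_same_patch_rejected(self):
        ps = label_patches(braster([[1]]))
        with pytest.raises(ValueError):
            interpatch_distance(ps, 1, 1)


class TestBuildGraph:
    def test_single_patch(self):
        g = build_graph(label_patches(braster([[1]])), 1.0, A_L=10.0)
        assert g.n == 1 and not g.edges
        assert np.array_equal(g.nl, [[0.0]])

    def test_collinear_path_topology(self):
        # patches at columns 0, 2, 4: consecutive edge gaps 1 km, ends 3 km
        ps = label_patches(braster([[1, 0, 1, 0, 1]]))
        g = build_graph(ps, 1.0, A_L=10.0)
        assert set(g.edges) == {(1, 2), (2, 3)}
        assert g.nl[0, 2] == 2.0

    def test_disconnected_components_infinite(self):
        ps = label_patches(braster([[1, 0, 0, 0, 0, 0, 1]]))
        g = build_graph(ps, 1.0, A_L=10.0)
        assert not g.edges
        assert np.isinf(g.nl[0, 1])

    def test_al_below_habitat_rejected(self):
        with pytest.raises(ValueError, match="A_L"):
            build_graph(label_patches(braster([[1, 1]])), 1.0, A_L=1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_edge_set_monotone_in_dispersal(self, seed):
        hab = gen_habitat_raster(SimulationSpec(25, 25, 1.0, 0.3, 1.0, seed=seed))
        ps = label_patches(hab)
        prev = set()
        for d in (0.5, 1.0, 2.0, 4.0):
            g = build_graph(ps, d, A_L=1000.0)
            assert prev <= set(g.edges)
            prev = set(g.edges)

    @pytest.mark.parametrize("metric", ["edge", "centroid"])
    def test_edges_match_pairwise_distance_rule(self, metric):
        hab = gen_habitat_raster(SimulationSpec(15, 15, 1.0, 0.25, 1.0, seed=5))
        ps = label_patches(hab)
        d_thr = 2.5
        g = build_graph(ps, d_thr, A_L=500.0, metric=metric)
        for i in range(1, len(ps) + 1):
            for j in range(i + 1, len(ps) + 1):
                d = interpatch_distance(ps, i, j, metric=metric)
                assert ((i, j) in g.edges) == (d <= d_thr)
                if (i, j) in g.edges:
                    assert g.edges[(i, j)] == pytest.approx(d)


class TestLinkCounts:
    @pytest.mark.parametrize("seed", range(6))
    def test_bfs_matches_floyd_warshall_oracle(self, seed):
        g = random_patch_graph(np.random.default_rng(seed), n_max=50)
        oracle = floyd_warshall_nl(g.n, graph_edge_index_pairs(g))
        assert np.array_equal(g.nl, oracle)


class TestConeforIO:
    def test_empty_graph_round_trip(self, tmp_path):
        g = random_patch_graph(np.random.default_rng(99), n_max=1)
        write_conefor(g, tmp_path / "n.txt", tmp_path / "c.txt")
        back = read_conefor(tmp_path / "n.txt", tmp_path / "c.txt", g.A_L)
        assert np.array_equal(back.node_ids, g.node_ids)

    def test_two_node_files(self, tmp_path):
        from habconn.patches import PatchGraph

        g = PatchGraph(np.array([1, 2]), np.array([4.0, 1.0]), {(1, 2): 0.5},
                       A_L=10.0, dispersal_distance_km=1.0)
        write_conefor(g, tmp_path / "n.txt", tmp_path / "c.txt")
        assert len((tmp_path / "n.txt").read_text().splitlines()) == 2
        assert (tmp_path / "c.txt").read_text().splitlines() == ["1\t2\t0.5"]

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_exact(self, seed, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("conefor")
        g = random_patch_graph(np.random.default_rng(seed), n_max=20)
        write_conefor(g, tmp / "n.txt", tmp / "c.txt")
        back = read_conefor(tmp / "n.txt", tmp / "c.txt", g.A_L)
        assert np.array_equal(back.node_ids, g.node_ids)
        assert np.array_equal(back.node_areas, g.node_areas)
        assert set(back.edges) == set(g.edges)

    @pytest.mark.parametrize(
        "nodes,conns,match",
        [
            ("1\t2.0\n1\t3.0\n", "", "duplicate"),
            ("1\t2.0\n", "1\t5\t0.5\n", "unknown"),
            ("1\n", "", "expected"),
            ("1\t2.0\n", "1\t1\n", "expected"),
        ],
    )
    def test_malformed_files_report_line(self, tmp_path, nodes, conns, match):
        (tmp_path / "n.txt").write_text(nodes)
        (tmp_path / "c.txt").write_text(conns)
        with pytest.raises(ValueError, match=match):
            read_conefor(tmp_path / "n.txt", tmp_path / "c.txt", 100.0)
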