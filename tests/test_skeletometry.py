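import networkx as nx
import numpy as np
import pytest
from scipy.ndimage import label
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import bellman_ford

from lenruler.io_core import SeedFlag
from lenruler.skeletometry import (build_graph, endpoints, geodesic,
                                   intersections, radicle_pixel_length, thin,
                                   vertex_graph_distance)


def raster_from_pixels(pixels, shape=(10, 10)):
    m = np.zeros(shape, bool)
    for x, y in pixels:
        m[y, x] = True
    return m


def brute_force_adjacency(raster, diagonal_weight=2.0):
    """Independent all-pairs 8-neighbour test (oracle for build_graph/geodesic)."""
    ys, xs = np.nonzero(raster)
    pix = list(zip(xs.tolist(), ys.tolist()))
    n = len(pix)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = abs(pix[i][0] - pix[j][0])
            dy = abs(pix[i][1] - pix[j][1])
            if max(dx, dy) == 1:
                W[i, j] = 1.0 if dx + dy == 1 else diagonal_weight
    return pix, W


class TestThin:
    def test_one_pixel_line_is_fixed(self):
        m = np.zeros((5, 20), bool)
        m[2, 3:17] = True
        assert (thin(m) == m).all()

    def test_empty_in_empty_out(self):
        assert not thin(np.zeros((6, 6), bool)).any()

    def test_rectangle_skeleton_subset_connected_idempotent(self):
        m = np.zeros((10, 24), bool)
        m[2:8, 2:22] = True
        s = thin(m)
        assert (s <= m).all()
        # 8-connectivity oracle: exactly one labelled component
        _, n = label(s, structure=np.ones((3, 3)))
        assert n == 1
        assert (thin(s) == s).all()


class TestBuildGraph:
    def test_collinear_pixels(self):
        g = build_graph(raster_from_pixels([(1, 1), (2, 1), (3, 1)]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))

    def test_diagonal_edge_weighs_two(self):
        g = build_graph(raster_from_pixels([(0, 0), (1, 1)]))
        assert g.number_of_edges() == 1
        assert g[(0, 0)][(1, 1)]["weight"] == 2

    def test_adjacency_matches_brute_force(self, rng):
        raster = rng.random((12, 12)) < 0.3
        g = build_graph(raster)
        pix, W = brute_force_adjacency(raster)
        idx = {p: i for i, p in enumerate(pix)}
        assert g.number_of_nodes() == len(pix)
        for i, u in enumerate(pix):
            for j, v in enumerate(pix):
                if W[i, j]:
                    assert g.has_edge(u, v) and g[u][v]["weight"] == W[i, j]
        assert g.number_of_edges() == int((W > 0).sum()) // 2


class TestDegreeSets:
    def test_path_graph_ends(self):
        g = build_graph(raster_from_pixels([(1, 1), (2, 1), (3, 1)]))
        assert endpoints(g) == {(1, 1), (3, 1)}
        assert intersections(g) == set()

    def test_diagonal_cross(self):
        pix = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (0, 4), (1, 3), (3, 1), (4, 0)]
        g = build_graph(raster_from_pixels(pix))
        assert endpoints(g) == {(0, 0), (4, 4), (0, 4), (4, 0)}
        assert intersections(g) == {(2, 2)}
        assert g.degree[(2, 2)] == 4

    def test_random_raster_matches_degree_oracle(self, rng):
        raster = rng.random((12, 12)) < 0.25
        g = build_graph(raster)
        pix, W = brute_force_adjacency(raster)
        deg = (W > 0).sum(axis=1)
        assert endpoints(g) == {p for p, d in zip(pix, deg) if d == 1}
        assert intersections(g) == {p for p, d in zip(pix, deg) if d >= 3}


class TestVertexGraphDistance:
    def test_three_four_five(self):
        g = build_graph(raster_from_pixels([(3, 4)]))
        assert vertex_graph_distance((0, 0), g) == 5.0

    def test_membership_gives_zero(self):
        g = build_graph(raster_from_pixels([(2, 2), (3, 3)]))
        assert vertex_graph_distance((2, 2), g) == 0.0

    def test_matches_exhaustive_scan(self, rng):
        raster = rng.random((20, 20)) < 0.5
        g = build_graph(raster)
        v = (25, -3)
        expected = min(np.hypot(u[0] - v[0], u[1] - v[1]) for u in g.nodes)
        assert vertex_graph_distance(v, g) == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            vertex_graph_distance((0, 0), nx.Graph())


class TestGeodesic:
    def test_same_vertex_is_zero(self):
        g = build_graph(raster_from_pixels([(1, 1), (2, 1)]))
        assert geodesic(g, (1, 1), (1, 1)) == 0.0

    def test_orthogonal_path(self):
        g = build_graph(raster_from_pixels([(i, 2) for i in range(5)]))
        assert geodesic(g, (0, 2), (4, 2)) == 4.0

    def test_diagonal_path_weighs_double(self):
        g = build_graph(raster_from_pixels([(i, i) for i in range(5)]))
        assert geodesic(g, (0, 0), (4, 4)) == 8.0

    def test_sqrt2_weight_gives_euclidean_polyline(self):
        g = build_graph(raster_from_pixels([(i, i) for i in range(5)]),
                        diagonal_weight=np.sqrt(2))
        assert geodesic(g, (0, 0), (4, 4)) == pytest.approx(4 * np.sqrt(2))

    def test_disconnected_raises(self):
        g = build_graph(raster_from_pixels([(0, 0), (5, 5)]))
        with pytest.raises(ValueError):
            geodesic(g, (0, 0), (5, 5))

    @pytest.mark.parametrize("weight", [2.0, np.sqrt(2)])
    def test_matches_bellman_ford_oracle(self, rng, weight):
        for _ in range(10):
            raster = rng.random((15, 15)) < 0.35
            if not raster.any():
                continue
            g = build_graph(raster, diagonal_weight=weight)
            pix, W = brute_force_adjacency(raster, diagonal_weight=weight)
            D = bellman_ford(csr_matrix(W), directed=True)  # W symmetric
            idx = {p: i for i, p in enumerate(pix)}
            nodes = list(g.nodes)
            for _ in range(5):
                u, v = (nodes[k] for k in rng.integers(0, len(nodes), 2))
                expected = D[idx[u], idx[v]]
                if np.isinf(expected):
                    with pytest.raises(ValueError):
                        geodesic(g, u, v)
                else:
                    assert geodesic(g, u, v) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_triangle_inequality(self, rng):
        raster = rng.random((15, 15)) < 0.45
        g = build_graph(raster)
        comp = max(nx.connected_components(g), key=len)
        nodes = sorted(comp)[:8]
        for u in nodes:
            for v in nodes:
                assert geodesic(g, u, v) == geodesic(g, v, u)
                for w in nodes[:4]:
                    assert (geodesic(g, u, v)
                            <= geodesic(g, u, w) + geodesic(g, w, v) + 1e-9)

    def test_path_weight_equals_step_count_identity(self, rng):
        # on any path: weight = #orthogonal + d * #diagonal steps
        raster = rng.random((15, 15)) < 0.4
        g = build_graph(raster, diagonal_weight=2.0)
        comp = max(nx.connected_components(g), key=len)
        nodes = sorted(comp)
        u, v = nodes[0], nodes[-1]
        path = nx.dijkstra_path(g, u, v, weight="weight")
        ortho = sum(1 for a, b in zip(path, path[1:])
                    if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1)
        diag = len(path) - 1 - ortho
        assert geodesic(g, u, v) == ortho + 2 * diag


def disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


class TestRadiclePixelLength:
    def test_empty_radicle_flags_no_radicle(self):
        coat = disk_mask((30, 30), 15, 15, 8)
        m = radicle_pixel_length(coat, np.zeros((30, 30), bool))
        assert m.pixel_length == 0.0
        assert SeedFlag.NO_RADICLE in m.flags

    def test_straight_bar_fallback_length(self):
        # disk coat, 1-px horizontal bar of 41 px overlapping the coat by 1 px
        coat = disk_mask((60, 120), 20, 30, 10)
        radicle = np.zeros((60, 120), bool)
        radicle[30, 30:71] = True       # x = 30..70 inclusive, 41 px
        m = radicle_pixel_length(coat, radicle)
        assert SeedFlag.NO_INTERSECTION_FALLBACK in m.flags
        assert m.pixel_length == pytest.approx(40, abs=2)
        assert m.p_e == (70, 30)        # the tip farthest from the coat

    def test_branched_skeleton_matches_exhaustive_candidate_oracle(self):
        coat = disk_mask((60, 120), 20, 30, 10)
        radicle = np.zeros((60, 120), bool)
        radicle[30, 31:81] = True       # main axis
        radicle[18:30, 55] = True       # vertical branch -> junction at (55, 30)
        m = radicle_pixel_length(coat, radicle)
        # oracle: enumerate every (endpoint, intersection) candidate pair
        s_s, s_r = thin(coat), thin(radicle)
        g_s, g_r = build_graph(s_s), build_graph(s_r)
        ends = sorted(endpoints(g_r), key=lambda v: (v[1], v[0]))
        d = [vertex_graph_distance(e, g_s) for e in ends]
        p_e = ends[int(np.argmax(d))]
        comp = nx.node_connected_component(g_r, p_e)
        inters = sorted((v for v in intersections(g_r) if v in comp),
                        key=lambda v: (v[1], v[0]))
        assert inters, "fixture must produce a junction"
        di = [vertex_graph_distance(v, g_s) for v in inters]
        p_i = inters[int(np.argmin(di))]
        assert m.p_e == p_e and m.p_i == p_i
        assert m.pixel_length == geodesic(g_r, p_e, p_i)
        assert SeedFlag.NO_INTERSECTION_FALLBACK not in m.flags

    def test_translation_invariance(self):
        coat = disk_mask((60, 120), 20, 30, 10)
        radicle = np.zeros((60, 120), bool)
        radicle[30, 30:66] = True
        base = radicle_pixel_length(coat, radicle)
        shifted = radicle_pixel_length(np.roll(coat, (7, 13), (0, 1)),
                                       np.roll(radicle, (7, 13), (0, 1)))
        assert shifted.pixel_length == base.pixel_length

    def test_rotation_90_invariance(self):
        coat = disk_mask((120, 120), 30, 60, 10)
        radicle = np.zeros((120, 120), bool)
        radicle[60, 40:96] = True
        base = radicle_pixel_length(coat, radicle)
        rot = radicle_pixel_length(np.rot90(coat), np.rot90(radicle))
        assert rot.pixel_length == base.pixel_length

    def test_oblique_with_sqrt2_close_to_euclidean(self):
        # 45-degree radicle, sqrt(2) metric: length within 5% of true length
        coat = disk_mask((120, 120), 30, 30, 10)
        radicle = np.zeros((120, 120), bool)
        for k in range(40):
            radicle[38 + k, 38 + k] = True
        true_len = 39 * np.sqrt(2)
        m = radicle_pixel_length(coat, radicle, diagonal_weight=np.sqrt(2))
        assert m.pixel_length == pytest.approx(true_len, rel=0.05)

    def test_disconnected_components_flagged(self):
        coat = disk_mask((60, 120), 20, 30, 10)
        radicle = np.zeros((60, 120), bool)
        radicle[30, 31:61] = True
        radicle[5, 100:110] = True      # stray blob far from the coat
        m = radicle_pixel_length(coat, radicle)
        assert SeedFlag.SKELETON_DISCONNECTED in m.flags
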