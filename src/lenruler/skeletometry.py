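"""Skeletonization, skeleton graphs, and geodesic radicle pixel length.

A binary mask is thinned (Zhang–Suen) to a one-pixel-wide skeleton. The
skeleton is viewed as a weighted graph: one vertex per skeleton pixel, an
edge between 8-neighbouring pixels, weight 1 for an orthogonal step and a
configurable weight (default 2; sqrt(2) gives the Euclidean polyline metric)
for a diagonal step. Endpoints are degree-1 vertices, intersection points
degree >= 3.

The radicle pixel length is the geodesic (weighted shortest-path) distance
on the radicle skeleton between

* ``p_e`` — the radicle endpoint farthest (Euclidean point-to-set distance)
  from the seed-coat skeleton, i.e. the radicle tip, and
* ``p_i`` — the radicle intersection point closest to the coat skeleton,
  i.e. the junction where the radicle leaves the coat. Unbranched radicle
  skeletons have no intersection point; the vertex closest to the coat
  skeleton is used instead and the measurement flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .io_core import SeedFlag

DEFAULT_DIAGONAL_WEIGHT = 2.0

# (x, y) pixel coordinate; graph vertices are such tuples
Pixel = tuple[int, int]


@dataclass(frozen=True)
class RadicleMeasurement:
    """Output of the radicle-length algorithm for one seed."""

    p_e: Pixel | None
    p_i: Pixel | None
    pixel_length: float
    flags: frozenset[SeedFlag] = field(default_factory=frozenset)


def thin(mask: np.ndarray) -> np.ndarray:
    """Zhang–Suen thinning of a binary mask; output is a subset of the input
    and a fixed point of re-thinning."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return skeletonize(mask, method="zhang")


def build_graph(
    skeleton: np.ndarray, diagonal_weight: float = DEFAULT_DIAGONAL_WEIGHT
) -> nx.Graph:
    """Weighted 8-neighbourhood graph of a skeleton raster.

    Vertices are ``(x, y)`` tuples; orthogonal edges weigh 1, diagonal edges
    ``diagonal_weight``.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    g = nx.Graph()
    ys, xs = np.nonzero(skeleton)
    pix = set(zip(xs.tolist(), ys.tolist()))
    g.add_nodes_from(pix)
    for x, y in pix:
        # right, down, and the two down-diagonals: each undirected edge once
        for dx, dy, w in ((1, 0, 1.0), (0, 1, 1.0),
                          (1, 1, diagonal_weight), (-1, 1, diagonal_weight)):
            nb = (x + dx, y + dy)
            if nb in pix:
                g.add_edge((x, y), nb, weight=w)
    return g


def endpoints(graph: nx.Graph) -> set[Pixel]:
    """Degree-1 vertices (skeleton tips)."""
    return {v for v, d in graph.degree() if d == 1}


def intersections(graph: nx.Graph) -> set[Pixel]:
    """Vertices of degree 3 or more (skeleton junctions)."""
    return {v for v, d in graph.degree() if d >= 3}


def vertex_graph_distance(v: Pixel, other: nx.Graph) -> float:
    """Minimum Euclidean distance from vertex ``v`` to any vertex of ``other``."""
    if other.number_of_nodes() == 0:
        raise ValueError("vertex_graph_distance: empty graph")
    pts = np.array(list(other.nodes), dtype=np.float64)
    return float(np.min(np.hypot(pts[:, 0] - v[0], pts[:, 1] - v[1])))


def geodesic(graph: nx.Graph, u: Pixel, v: Pixel) -> float:
    """Sum of edge weights along the shortest path between ``u`` and ``v``."""
    if u not in graph or v not in graph:
        raise ValueError("geodesic: vertex not in graph")
    try:
        return float(nx.dijkstra_path_length(graph, u, v, weight="weight"))
    except nx.NetworkXNoPath:
        raise ValueError(f"geodesic: {u} and {v} lie in different components")


def _distances_to_graph(vertices: list[Pixel], other: nx.Graph) -> np.ndarray:
    pts = np.array(list(other.nodes), dtype=np.float64)
    tree = cKDTree(pts)
    q = np.array(vertices, dtype=np.float64)
    d, _ = tree.query(q)
    return np.atleast_1d(d)


def _lex_key(v: Pixel) -> tuple[int, int]:
    # deterministic tie-break: smallest (row, col) = (y, x)
    return (v[1], v[0])


def radicle_pixel_length(
    coat_mask: np.ndarray,
    radicle_mask: np.ndarray,
    diagonal_weight: float = DEFAULT_DIAGONAL_WEIGHT,
) -> RadicleMeasurement:
    """Radicle pixel length from per-seed coat and radicle masks.

    Thins both masks, builds their skeleton graphs, selects the tip ``p_e``
    (endpoint farthest from the coat skeleton) and junction ``p_i``
    (intersection closest to the coat skeleton, restricted to the connected
    component of ``p_e``), and returns the geodesic distance between them.

    Degenerate cases: an empty radicle mask or skeleton yields length 0 with
    flag ``no_radicle``; a component without intersections falls back to the
    vertex nearest the coat skeleton (flag ``no_intersection_fallback``);
    extra skeleton components are ignored and flagged
    ``skeleton_disconnected``. Ties in either selection are broken by the
    smallest (row, col) coordinate.
    """
    coat_mask = np.asarray(coat_mask, dtype=bool)
    radicle_mask = np.asarray(radicle_mask, dtype=bool)
    if not coat_mask.any():
        raise ValueError("radicle_pixel_length: empty coat mask")
    flags: set[SeedFlag] = set()
    if not radicle_mask.any():
        return RadicleMeasurement(None, None, 0.0, frozenset({SeedFlag.NO_RADICLE}))

    s_s = thin(coat_mask)
    s_r = thin(radicle_mask)
    if not s_r.any():
        return RadicleMeasurement(None, None, 0.0, frozenset({SeedFlag.NO_RADICLE}))
    if not s_s.any():
        # a coat mask so small it thins away: use the mask itself as reference
        s_s = coat_mask
    g_s = build_graph(s_s, diagonal_weight)
    g_r = build_graph(s_r, diagonal_weight)

    if nx.number_connected_components(g_r) > 1:
        flags.add(SeedFlag.SKELETON_DISCONNECTED)

    ends = endpoints(g_r)
    if not ends:
        # cycle skeleton (no degree-1 vertex): every vertex is a candidate tip
        ends = set(g_r.nodes)
    end_list = sorted(ends, key=_lex_key)
    d_end = _distances_to_graph(end_list, g_s)
    p_e = end_list[int(np.argmax(d_end))]  # lexicographic order breaks ties

    component = nx.node_connected_component(g_r, p_e)
    inters = [v for v in intersections(g_r) if v in component]
    if inters:
        cand = sorted(inters, key=_lex_key)
    else:
        flags.add(SeedFlag.NO_INTERSECTION_FALLBACK)
        cand = sorted(component, key=_lex_key)
    d_cand = _distances_to_graph(cand, g_s)
    p_i = cand[int(np.argmin(d_cand))]

    l_p = geodesic(g_r, p_e, p_i)
    return RadicleMeasurement(p_e, p_i, l_p, frozenset(flags))
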