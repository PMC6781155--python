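"""Skeleton-graph utilities shared by segmentation and midline extraction."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class DegenerateSkeletonError(RuntimeError):
    """Skeleton has no endpoints (cycle) or too few pixels for a midline."""


def pixel_graph(skeleton: np.ndarray) -> nx.Graph:
    """8-connected graph over skeleton pixels; edge weights are Euclidean steps."""
    g = nx.Graph()
    coords = set(map(tuple, np.argwhere(skeleton)))
    for r, c in coords:
        g.add_node((r, c))
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in coords:
                g.add_edge((r, c), nb, weight=math.hypot(dr, dc))
    return g


def prune_spurs(g: nx.Graph, spur_px: float) -> nx.Graph:
    """Iteratively remove side branches shorter than ``spur_px``.

    A spur is a path from an endpoint (degree 1) to the nearest junction
    (degree >= 3); only spurs strictly shorter than the threshold are removed,
    so the main axis survives. Returns a pruned copy.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for ep in [n for n in g.nodes if g.degree(n) == 1]:
            if ep not in g:
                continue
            path = [ep]
            length = 0.0
            node = ep
            prev = None
            while True:
                nbrs = [n for n in g.neighbors(node) if n != prev]
                if g.degree(node) >= 3 or not nbrs:
                    break
                prev, node = node, nbrs[0]
                length += g[prev][node]["weight"]
                if g.degree(node) >= 3:
                    break
                path.append(node)
                if length >= spur_px:
                    break
            if g.degree(node) >= 3 and length < spur_px:
                g.remove_nodes_from(path)
                changed = True
    return g


def endpoints(g: nx.Graph) -> list[tuple[int, int]]:
    return sorted(n for n in g.nodes if g.degree(n) == 1)


def branch_points(g: nx.Graph) -> list[tuple[int, int]]:
    return sorted(n for n in g.nodes if g.degree(n) >= 3)


def longest_geodesic_path(g: nx.Graph) -> tuple[list[tuple[int, int]], float]:
    """Longest shortest path between skeleton endpoints.

    Searches within the largest connected component; ties are broken by
    lexicographic order of the (sorted) endpoint pair for determinism.
    Raises DegenerateSkeletonError for cyclic or near-empty skeletons.
    """
    if g.number_of_nodes() < 2:
        raise DegenerateSkeletonError("degenerate skeleton: fewer than 2 pixels")
    comp = max(nx.connected_components(g), key=lambda s: (len(s), sorted(s)[0]))
    sub = g.subgraph(comp)
    eps = endpoints(sub)
    if not eps:
        raise DegenerateSkeletonError("degenerate skeleton: no endpoints (cycle)")
    best: tuple[float, tuple, tuple] | None = None
    for src in eps:
        dist = nx.single_source_dijkstra_path_length(sub, src, weight="weight")
        for dst in eps:
            if dst <= src:
                continue
            d = dist.get(dst)
            if d is None:
                continue
            key = (-d, src, dst)
            if best is None or key < best:
                best = key
    if best is None:
        raise DegenerateSkeletonError("degenerate skeleton: single endpoint")
    length = -best[0]
    path = nx.dijkstra_path(sub, best[1], best[2], weight="weight")
    return path, float(length)
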