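"""Shared fixtures and brute-force oracles for the suite.

Oracles here are deliberately naive (per-source BFS, exhaustive subset
enumeration) and independent of the library's own code paths.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pytest

from netprox import generate_scenario


def single_source_bfs(g: nx.Graph, source) -> dict:
    """Textbook single-source BFS, written independently of the package."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in g.adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def brute_min_distance_to_set(g: nx.Graph, sources) -> dict:
    """Elementwise minimum over per-source BFS maps — the multi-source oracle."""
    out: dict = {}
    for s in sources:
        for node, d in single_source_bfs(g, s).items():
            if node not in out or d < out[node]:
                out[node] = d
    return out


def brute_closest_distance(g: nx.Graph, S, T) -> float:
    """Mean over targets of the per-target nearest-source BFS distance."""
    dists = []
    for t in T:
        d = single_source_bfs(g, t)
        reachable = [d[s] for s in S if s in d]
        if reachable:
            dists.append(min(reachable))
    return sum(dists) / len(dists)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 50) -> nx.Graph:
    """Largest component of a sparse random graph, nodes named as strings."""
    n = int(rng.integers(5, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.25))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    comp = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    g = g.subgraph(comp).copy()
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})


@pytest.fixture
def path5() -> nx.Graph:
    """Path graph 1–2–3–4–5 with string node names."""
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in g.nodes()})


@pytest.fixture(scope="session")
def small_scenario():
    """Compact synthetic study reused across unit tests (cheap to screen)."""
    return generate_scenario(
        seed=7,
        n_nodes=200,
        attachment=3,
        module_size=15,
        n_proximal=4,
        n_distal=4,
        targets_per_compound=(5, 10),
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The reference scenario at its default parameters."""
    return generate_scenario(seed=2024)
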