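"""Protein–protein interaction graph: loading, cleaning, and path machinery.

The interactome is an undirected simple graph whose nodes are opaque protein
identifiers (Entrez IDs or gene symbols — the package never translates them;
an optional two-column mapping file can be applied at load time). It is the
metric space for every distance in the screen: ``d(s, t)`` is the unweighted
shortest-path (hop) length. Proximity analysis is restricted to the largest
connected component so that all pairwise distances are finite.

Degree bins group nodes of similar connectivity so that null-model sampling
can replace a protein with a random protein of comparable degree, which keeps
the randomization from being dominated by hubs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import AnalysisError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "load_edge_list",
    "load_node_mapping",
    "largest_connected_component",
    "multi_source_shortest_paths",
    "DegreeBins",
    "build_degree_bins",
]


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def load_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    mapping: Mapping[str, str] | None = None,
    header: bool = False,
) -> nx.Graph:
    """Read a two-column delimited edge list into an undirected simple graph.

    Lines beginning with ``#`` are comments.  Self-loops and duplicate
    (unordered) pairs are dropped silently with a logged count; identifiers
    are stripped of surrounding whitespace.  ``delimiter=None`` sniffs tab,
    then comma, then whitespace from the first data line.  ``mapping``
    optionally translates node identifiers on the fly; identifiers absent
    from the mapping are kept as-is.

    Raises
    ------
    ValidationError
        If the file is unreadable or a data line has fewer than two fields
        (the message names the offending line number).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read edge list {path}: {exc}") from exc

    g = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    first_data_line = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if first_data_line:
            if delimiter is None:
                delimiter = _sniff_delimiter(line)
            first_data_line = False
            if header:
                continue
        fields = [f.strip() for f in line.split(delimiter) if f.strip()]
        if len(fields) < 2:
            raise ValidationError(
                f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        if mapping is not None:
            u = mapping.get(u, u)
            v = mapping.get(v, v)
        if u == v:
            n_self_loops += 1
            continue
        if g.has_edge(u, v):
            n_duplicates += 1
            continue
        g.add_edge(u, v)
    if n_self_loops or n_duplicates:
        logger.info(
            "dropped %d self-loop(s) and %d duplicate edge(s) from %s",
            n_self_loops, n_duplicates, path,
        )
    logger.info(
        "loaded interactome %s: %d nodes, %d edges",
        path, g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def load_node_mapping(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column (source_id, target_id) identifier mapping file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read mapping file {path}: {exc}") from exc
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter is None:
            delimiter = _sniff_delimiter(line)
        fields = [f.strip() for f in line.split(delimiter) if f.strip()]
        if len(fields) < 2:
            raise ValidationError(
                f"{path}:{lineno}: mapping line needs 2 fields, got {len(fields)}"
            )
        mapping[fields[0]] = fields[1]
    return mapping


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (ties: component containing
    the lexicographically smallest member node). Empty graph passes through."""
    if g.number_of_nodes() == 0:
        return g.copy()
    components = [
        (len(c), min(c)) + (c,) for c in nx.connected_components(g)
    ]
    # Largest size wins; among equal sizes the lexicographically smallest
    # member decides, so the choice is reproducible across runs.
    components.sort(key=lambda t: (-t[0], t[1]))
    keep = components[0][2]
    dropped = g.number_of_nodes() - len(keep)
    if dropped:
        logger.info("largest component keeps %d nodes; %d discarded", len(keep), dropped)
    return g.subgraph(keep).copy()


def adjacency_dict(g: nx.Graph) -> dict:
    """Plain dict-of-lists adjacency; cached by callers that run many BFS sweeps."""
    return {v: list(g.adj[v]) for v in g}


def _bfs_from(adj: Mapping, sources: Iterable) -> dict:
    """Multi-source breadth-first hop distances over a dict adjacency."""
    dist = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        du = dist[u] + 1
        for w in adj[u]:
            if w not in dist:
                dist[w] = du
                queue.append(w)
    return dist


def multi_source_shortest_paths(g: nx.Graph, sources: Iterable) -> dict:
    """Hop distance from every reachable node to its nearest source.

    One breadth-first sweep started from all sources at once realizes the
    inner minimum of the closest-distance measure. Sources map to 0;
    unreachable nodes are absent from the result.

    Raises
    ------
    ValidationError
        If ``sources`` is empty or contains a node not in ``g`` (named).
    """
    sources = set(sources)
    if not sources:
        raise ValidationError("sources must be non-empty")
    missing = sources - set(g.nodes)
    if missing:
        raise ValidationError(f"source node(s) not in graph: {sorted(missing)[:5]}")
    return _bfs_from(adjacency_dict(g), sources)


@dataclass(frozen=True)
class DegreeBins:
    """Partition of the network's nodes into contiguous degree intervals.

    ``intervals[i] = (lo, hi)`` and ``members[i]`` is a sorted tuple of the
    nodes whose degree falls in that interval. Intervals are disjoint,
    ascending, and jointly cover every observed degree; after merging, every
    bin holds at least ``min_bin_size`` nodes.
    """

    intervals: tuple[tuple[int, int], ...]
    members: tuple[tuple, ...]
    min_bin_size: int

    def bin_index(self, degree: int) -> int:
        """Index of the interval containing ``degree``.

        Degrees between observed values fall into the interval whose range
        spans them; degrees outside all intervals clamp to the nearest bin.
        """
        for i, (lo, hi) in enumerate(self.intervals):
            if lo <= degree <= hi:
                return i
        if degree < self.intervals[0][0]:
            return 0
        return len(self.intervals) - 1


def build_degree_bins(g: nx.Graph, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes into ascending degree intervals of at least ``min_bin_size``.

    Distinct degree values are scanned in ascending order and pooled into one
    interval until it holds ``min_bin_size`` nodes; a trailing undersized
    interval is merged into its predecessor. With ``min_bin_size=1`` each
    distinct degree keeps its own bin.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot bin an empty graph")
    if min_bin_size < 1:
        raise ValidationError("min_bin_size must be >= 1")
    if min_bin_size > g.number_of_nodes():
        raise ValidationError(
            f"min_bin_size={min_bin_size} exceeds node count {g.number_of_nodes()}"
        )
    by_degree: dict[int, list] = {}
    for v, d in g.degree():
        by_degree.setdefault(d, []).append(v)
    degrees = sorted(by_degree)

    intervals: list[tuple[int, int]] = []
    members: list[list] = []
    cur_nodes: list = []
    cur_lo: int | None = None
    for d in degrees:
        if cur_lo is None:
            cur_lo = d
        cur_nodes.extend(by_degree[d])
        if len(cur_nodes) >= min_bin_size:
            intervals.append((cur_lo, d))
            members.append(cur_nodes)
            cur_nodes = []
            cur_lo = None
    if cur_nodes:
        if intervals:
            lo, _ = intervals[-1]
            intervals[-1] = (lo, degrees[-1])
            members[-1] = members[-1] + cur_nodes
        else:
            intervals.append((cur_lo, degrees[-1]))
            members.append(cur_nodes)
    if any(len(m) < min_bin_size for m in members):
        raise AnalysisError("degree binning produced an undersized bin")
    return DegreeBins(
        intervals=tuple(intervals),
        members=tuple(tuple(sorted(m)) for m in members),
        min_bin_size=min_bin_size,
    )
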