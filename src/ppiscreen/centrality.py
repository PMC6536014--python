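"""Node-centrality statistics on unweighted undirected graphs.

Implements the four statistics used to rank genes in a PPI network —
degree (D), betweenness (BC), closeness (CC), and stress — with a single
BFS-based accumulation pass per source node (Brandes' algorithm, extended to
count shortest paths for stress).  Edge confidence scores never enter these
computations; distance is hop count.

Conventions for disconnected graphs follow Cytoscape's NetworkAnalyzer:

* betweenness is normalized per connected component by
  ``(n_c - 1) * (n_c - 2) / 2`` where ``n_c`` is the component size, so
  values stay in [0, 1]; nodes in components of size <= 2 get 0;
* closeness of node ``v`` in a component of size ``n_c > 1`` is
  ``(n_c - 1) / sum of distances``; isolated nodes get 0;
* stress counts, for each node, the shortest paths between unordered node
  pairs that cross it as an interior vertex — an exact integer.

A brute-force enumerator over all shortest paths (:func:`brute_force_metrics`)
provides an independent oracle for small graphs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator

import pandas as pd

from .errors import GraphTooLargeError
from .graph_model import InteractionNetwork, NodeMetrics, connected_components

BRUTE_FORCE_MAX_NODES = 12


@dataclass(frozen=True)
class CentralityTable:
    """One :class:`NodeMetrics` record per node, computed on one snapshot."""

    records: tuple[NodeMetrics, ...]

    def __post_init__(self):
        genes = [m.gene for m in self.records]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene in centrality table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NodeMetrics]:
        return iter(self.records)

    def __getitem__(self, gene: str) -> NodeMetrics:
        for m in self.records:
            if m.gene == gene:
                return m
        raise KeyError(gene)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(m.gene for m in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [m.gene for m in self.records],
                "degree": [m.degree for m in self.records],
                "betweenness": [m.betweenness for m in self.records],
                "closeness": [m.closeness for m in self.records],
                "stress": [m.stress for m in self.records],
                "component_size": [m.component_size for m in self.records],
            }
        )


def degree_centrality(net: InteractionNetwork) -> dict[str, int]:
    """Incident-edge count per node (0 for isolated nodes)."""
    return {v: net.degree(v) for v in net.sorted_nodes()}


def _bfs_shortest_paths(
    net: InteractionNetwork, source: str
) -> tuple[list[str], dict[str, int], dict[str, int], dict[str, list[str]]]:
    """Single-source BFS returning visit order (a stack), hop distances,
    shortest-path counts sigma, and shortest-path predecessor lists.

    Neighbor iteration is sorted so accumulation order — hence floating-point
    rounding in the callers — is reproducible run to run.
    """
    dist = {source: 0}
    sigma = {source: 1}
    preds: dict[str, list[str]] = {source: []}
    order: list[str] = []
    queue = deque([source])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in sorted(net.neighbors(v)):
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                preds[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, dist, sigma, preds


def betweenness_centrality(
    net: InteractionNetwork, normalized: bool = True
) -> dict[str, float]:
    """Betweenness via Brandes' dependency accumulation.

    With ``normalized`` (default), each node's raw unordered-pair betweenness
    is divided by ``(n_c - 1)(n_c - 2) / 2`` for its component of size
    ``n_c``; components of size <= 2 yield 0.  With ``normalized=False`` the
    raw unordered-pair sums are returned.
    """
    bc = {v: 0.0 for v in net.nodes}
    for s in net.sorted_nodes():
        order, _, sigma, preds = _bfs_shortest_paths(net, s)
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was seen from both endpoints
    for v in bc:
        bc[v] /= 2.0
    if normalized:
        parts = connected_components(net)
        for comp in parts.components:
            n_c = len(comp)
            denom = (n_c - 1) * (n_c - 2) / 2.0
            for v in comp:
                bc[v] = bc[v] / denom if denom > 0 else 0.0
    return {v: bc[v] for v in net.sorted_nodes()}


def closeness_centrality(net: InteractionNetwork) -> dict[str, float]:
    """Reciprocal mean intra-component distance: ``(n_c - 1) / sum d(v, u)``
    over the node's own component; 0 for isolated nodes."""
    cc: dict[str, float] = {}
    for v in net.sorted_nodes():
        _, dist, _, _ = _bfs_shortest_paths(net, v)
        total = sum(dist.values())
        cc[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return cc


def stress_centrality(
    net: InteractionNetwork, count_ordered: bool = False
) -> dict[str, int]:
    """Number of shortest paths crossing each node as an interior vertex,
    each distinct unordered-pair path counted once (exact integers).

    ``count_ordered=True`` counts each path from both directions (doubled
    values), matching tools that sum over ordered pairs.
    """
    stress = {v: 0 for v in net.nodes}
    for s in net.sorted_nodes():
        order, _, sigma, preds = _bfs_shortest_paths(net, s)
        # x[v] = number of shortest-path-DAG paths from v to any target below
        x = {v: 0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                x[v] += 1 + x[w]
            if w != s:
                stress[w] += sigma[w] * x[w]
    if not count_ordered:
        for v in stress:
            assert stress[v] % 2 == 0
            stress[v] //= 2
    return {v: stress[v] for v in net.sorted_nodes()}


def all_metrics(net: InteractionNetwork) -> CentralityTable:
    """All four statistics plus component size, from one graph snapshot.

    One BFS per source feeds every statistic, so the columns are mutually
    consistent by construction.
    """
    parts = connected_components(net)
    comp_size = {v: len(comp) for comp in parts.components for v in comp}

    bc_raw = {v: 0.0 for v in net.nodes}
    stress2 = {v: 0 for v in net.nodes}  # ordered-pair counts (to halve)
    closeness: dict[str, float] = {}

    for s in net.sorted_nodes():
        order, dist, sigma, preds = _bfs_shortest_paths(net, s)
        total = sum(dist.values())
        closeness[s] = (len(dist) - 1) / total if total > 0 else 0.0
        delta = {v: 0.0 for v in order}
        x = {v: 0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
                x[v] += 1 + x[w]
            if w != s:
                bc_raw[w] += delta[w]
                stress2[w] += sigma[w] * x[w]

    records = []
    for v in net.sorted_nodes():
        n_c = comp_size[v]
        denom = (n_c - 1) * (n_c - 2) / 2.0
        records.append(
            NodeMetrics(
                gene=v,
                degree=net.degree(v),
                betweenness=(bc_raw[v] / 2.0) / denom if denom > 0 else 0.0,
                closeness=closeness[v],
                stress=stress2[v] // 2,
                component_size=n_c,
            )
        )
    return CentralityTable(records=tuple(records))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _enumerate_shortest_paths(
    net: InteractionNetwork, s: str, t: str
) -> list[tuple[str, ...]]:
    """All shortest s-t paths by explicit backtracking over BFS predecessors."""
    _, dist, _, preds = _bfs_shortest_paths(net, s)
    if t not in dist:
        return []

    def back(node: str) -> list[tuple[str, ...]]:
        if node == s:
            return [(s,)]
        return [p + (node,) for pred in preds[node] for p in back(pred)]

    return back(t)


def brute_force_metrics(net: InteractionNetwork) -> CentralityTable:
    """Same contract as :func:`all_metrics`, computed by exhaustively
    enumerating every shortest path of every node pair.  Exact rational
    arithmetic for betweenness.  Refuses graphs above
    ``BRUTE_FORCE_MAX_NODES`` nodes."""
    if net.n_nodes() > BRUTE_FORCE_MAX_NODES:
        raise GraphTooLargeError(
            f"brute-force oracle limited to {BRUTE_FORCE_MAX_NODES} nodes, "
            f"got {net.n_nodes()}"
        )
    parts = connected_components(net)
    comp_size = {v: len(comp) for comp in parts.components for v in comp}
    nodes = net.sorted_nodes()

    bc_frac = {v: Fraction(0) for v in nodes}
    stress = {v: 0 for v in nodes}
    dist_sum = {v: 0 for v in nodes}

    for i, s in enumerate(nodes):
        _, dist, _, _ = _bfs_shortest_paths(net, s)
        dist_sum[s] = sum(dist.values())
        for t in nodes[i + 1 :]:
            paths = _enumerate_shortest_paths(net, s, t)
            if not paths:
                continue
            for path in paths:
                for interior in path[1:-1]:
                    stress[interior] += 1
                    bc_frac[interior] += Fraction(1, len(paths))

    records = []
    for v in nodes:
        n_c = comp_size[v]
        denom = Fraction((n_c - 1) * (n_c - 2), 2)
        records.append(
            NodeMetrics(
                gene=v,
                degree=net.degree(v),
                betweenness=float(bc_frac[v] / denom) if denom > 0 else 0.0,
                closeness=(n_c - 1) / dist_sum[v] if dist_sum[v] > 0 else 0.0,
                stress=stress[v],
                component_size=n_c,
            )
        )
    return CentralityTable(records=tuple(records))
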