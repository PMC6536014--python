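"""Domain types and I/O for gene lists, scored interaction tables, and reports.

The central container is :class:`InteractionNetwork`, an undirected simple
graph over gene symbols with optional per-edge confidence scores on the
STRING combined-score scale (integers in [0, 1000]).  Networks are built by
intersecting a query gene list (typically differentially expressed genes)
with the node universe of a scored edge table, keeping recognized genes as
nodes even when none of their interactions survive the confidence cutoff.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import (
    ConfigurationError,
    EdgeTableParseError,
    EmptyGeneListError,
)

logger = logging.getLogger(__name__)

#: default STRING combined-score cutoff ("medium confidence")
DEFAULT_SCORE_THRESHOLD = 400

REPORT_METRICS = ("degree", "betweenness", "closeness", "stress")


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered key for the edge between ``a`` and ``b``."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneList:
    """Ordered, case-normalized, duplicate-free collection of gene symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self):
        if any(not s for s in self.symbols):
            raise ValueError("gene symbols must be non-empty strings")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene symbols must be unique")

    @classmethod
    def from_iterable(cls, symbols: Iterable[str]) -> "GeneList":
        """Build a GeneList, upper-casing and deduplicating while preserving
        order of first appearance."""
        seen: dict[str, None] = {}
        n_dup = 0
        for raw in symbols:
            sym = _norm(raw)
            if not sym:
                continue
            if sym in seen:
                n_dup += 1
            else:
                seen[sym] = None
        if n_dup:
            logger.info("gene list: dropped %d duplicate symbol(s)", n_dup)
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


class InteractionNetwork:
    """Undirected simple graph over gene symbols with optional edge scores.

    Self-loops are rejected, edges are unordered (``(a, b) == (b, a)``), and
    nodes may be isolated.  Scores, when present, are confidence integers in
    [0, 1000].
    """

    def __init__(self):
        self._adj: dict[str, set[str]] = {}
        self._scores: dict[tuple[str, str], int] = {}

    # -- construction -------------------------------------------------

    def add_node(self, symbol: str) -> None:
        self._adj.setdefault(symbol, set())

    def add_edge(self, a: str, b: str, score: int | None = None) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a}")
        self.add_node(a)
        self.add_node(b)
        self._adj[a].add(b)
        self._adj[b].add(a)
        if score is not None:
            if not 0 <= score <= 1000:
                raise ValueError(f"score out of [0, 1000]: {score}")
            self._scores[edge_key(a, b)] = score

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._adj)

    def edges(self) -> set[tuple[str, str]]:
        return {edge_key(a, b) for a, nbrs in self._adj.items() for b in nbrs}

    def score(self, a: str, b: str) -> int | None:
        return self._scores.get(edge_key(a, b))

    def neighbors(self, symbol: str) -> set[str]:
        return set(self._adj[symbol])

    def degree(self, symbol: str) -> int:
        return len(self._adj[symbol])

    def n_nodes(self) -> int:
        return len(self._adj)

    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_node(self, symbol: str) -> bool:
        return symbol in self._adj

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes()}, n_edges={self.n_edges()})"

    def subgraph(self, keep: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``keep`` (symbols absent from the network are
        ignored); scores carried over."""
        keep_set = {s for s in keep if s in self._adj}
        sub = InteractionNetwork()
        for node in keep_set:
            sub.add_node(node)
            for nbr in self._adj[node]:
                if nbr in keep_set:
                    sub.add_edge(node, nbr, self.score(node, nbr))
        return sub


@dataclass(frozen=True)
class ComponentPartition:
    """Disjoint connected components plus the index of the largest one."""

    components: tuple[frozenset[str], ...]
    main_index: int

    @property
    def main(self) -> frozenset[str]:
        return self.components[self.main_index]

    def n_isolated(self) -> int:
        return sum(1 for c in self.components if len(c) == 1)

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class NodeMetrics:
    """Per-gene centrality record: degree (D), betweenness (BC),
    closeness (CC), stress, and the size of the node's component."""

    gene: str
    degree: int
    betweenness: float
    closeness: float
    stress: int
    component_size: int

    def __post_init__(self):
        if self.degree < 0 or self.stress < 0:
            raise ValueError("degree and stress must be non-negative")
        if not (0.0 <= self.betweenness <= 1.0 + 1e-12):
            raise ValueError(f"betweenness out of [0,1]: {self.betweenness}")
        if not (0.0 <= self.closeness <= 1.0 + 1e-12):
            raise ValueError(f"closeness out of [0,1]: {self.closeness}")

    def value(self, metric: str) -> float:
        if metric not in REPORT_METRICS:
            raise ConfigurationError(f"unknown metric: {metric!r}")
        return getattr(self, metric)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> GeneList:
    """Read a plain-text gene list: one symbol per line, blank lines and
    ``#`` comment lines ignored, symbols upper-cased and deduplicated in
    order of first appearance.

    Raises :class:`EmptyGeneListError` when nothing survives filtering.
    """
    lines = Path(path).read_text().splitlines()
    symbols = [ln for ln in (s.strip() for s in lines) if ln and not ln.startswith("#")]
    genes = GeneList.from_iterable(symbols)
    if len(genes) == 0:
        raise EmptyGeneListError(f"empty gene list: {path}")
    logger.info("gene list %s: %d unique symbols", path, len(genes))
    return genes


def _parse_edge_rows(path: Path) -> list[tuple[int, str, str, int]]:
    rows: list[tuple[int, str, str, int]] = []
    first_record = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise EdgeTableParseError(
                    lineno, f"expected 3 columns, found {len(parts)}"
                )
            a, b, score_str = parts
            try:
                score = int(score_str)
            except ValueError:
                if first_record:
                    # header line: third column non-numeric
                    first_record = False
                    continue
                raise EdgeTableParseError(
                    lineno, f"non-integer score: {score_str!r}"
                ) from None
            first_record = False
            if not 0 <= score <= 1000:
                raise EdgeTableParseError(lineno, f"score out of [0, 1000]: {score}")
            rows.append((lineno, _norm(a), _norm(b), score))
    return rows


def read_edge_table(
    path: str | Path, score_threshold: int = DEFAULT_SCORE_THRESHOLD
) -> InteractionNetwork:
    """Read a STRING-export-style edge table (``nodeA nodeB combined_score``,
    whitespace-separated, optional header auto-detected by a non-numeric
    third column) into an :class:`InteractionNetwork`.

    Reciprocal duplicate rows are collapsed keeping the maximum score, then
    only edges with score >= ``score_threshold`` are retained.  Self-loop
    rows never yield an edge but do register their endpoint as a node when
    they pass the threshold.
    """
    if not 0 <= score_threshold <= 1000:
        raise ConfigurationError(
            f"score_threshold out of [0, 1000]: {score_threshold}"
        )
    rows = _parse_edge_rows(Path(path))

    best: dict[tuple[str, str], int] = {}
    for _, a, b, score in rows:
        key = edge_key(a, b)
        if key not in best or score > best[key]:
            best[key] = score

    net = InteractionNetwork()
    n_kept = 0
    for (a, b), score in best.items():
        if score < score_threshold:
            continue
        net.add_node(a)
        if a == b:
            continue  # self-loop: endpoint kept, edge dropped
        net.add_edge(a, b, score)
        n_kept += 1
    if not net.n_nodes():
        logger.warning(
            "edge table %s: no rows survive threshold %d; empty network",
            path,
            score_threshold,
        )
    logger.info(
        "edge table %s: %d rows, %d unique pairs, %d edges at threshold %d",
        path,
        len(rows),
        len(best),
        n_kept,
        score_threshold,
    )
    return net


def build_network(
    genes: GeneList, universe: InteractionNetwork
) -> tuple[InteractionNetwork, set[str]]:
    """Induce the query sub-network: keep query genes present anywhere in the
    edge source's node universe (isolated if no incident edge survived), and
    report genes absent from the universe as unrecognized."""
    recognized = [g for g in genes if universe.has_node(g)]
    unrecognized = {g for g in genes if not universe.has_node(g)}
    net = universe.subgraph(recognized)
    if unrecognized:
        logger.warning(
            "build_network: %d query gene(s) not recognized in the edge "
            "universe: %s",
            len(unrecognized),
            ", ".join(sorted(unrecognized)),
        )
    logger.info(
        "build_network: %d/%d genes recognized, %d edges",
        len(recognized),
        len(genes),
        net.n_edges(),
    )
    return net, unrecognized


def connected_components(net: InteractionNetwork) -> ComponentPartition:
    """Undirected connected components via breadth-first traversal.

    Isolated nodes become singleton components.  ``main_index`` points at a
    largest component; size ties are broken toward the component whose
    lexicographically smallest member sorts first.
    """
    seen: set[str] = set()
    components: list[frozenset[str]] = []
    for start in net.sorted_nodes():
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        comp = {start}
        while queue:
            node = queue.popleft()
            for nbr in net.neighbors(node):
                if nbr not in seen:
                    seen.add(nbr)
                    comp.add(nbr)
                    queue.append(nbr)
        components.append(frozenset(comp))
    if not components:
        return ComponentPartition(components=(), main_index=-1)
    main_index = min(
        range(len(components)), key=lambda i: (-len(components[i]), min(components[i]))
    )
    return ComponentPartition(components=tuple(components), main_index=main_index)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def rank_metrics(
    metrics: Sequence[NodeMetrics], ranked_by: str
) -> list[NodeMetrics]:
    """Deterministic ranking: metric descending, then gene symbol ascending."""
    if ranked_by not in REPORT_METRICS:
        raise ConfigurationError(f"unknown metric: {ranked_by!r}")
    return sorted(metrics, key=lambda m: (-m.value(ranked_by), m.gene))


def write_metrics_report(
    metrics: Sequence[NodeMetrics],
    ranked_by: str,
    path: str | Path,
    annotations: Mapping[str, str] | None = None,
) -> None:
    """Write the ranked per-gene table: columns R, name, description, D,
    BC (2 decimals), CC (2 decimals), Stress.  Descriptions are empty unless
    an annotation mapping supplies them."""
    if not metrics:
        raise ValueError("metrics must be non-empty")
    ranked = rank_metrics(metrics, ranked_by)
    annotations = annotations or {}
    with open(path, "w") as fh:
        fh.write("R\tname\tdescription\tD\tBC\tCC\tStress\n")
        for rank, m in enumerate(ranked, start=1):
            fh.write(
                f"{rank}\t{m.gene}\t{annotations.get(m.gene, '')}\t"
                f"{m.degree}\t{m.betweenness:.2f}\t{m.closeness:.2f}\t{m.stress}\n"
            )


def read_annotations(path: str | Path) -> dict[str, str]:
    """Optional two-column TSV (symbol <tab> description) for the report's
    description column."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sym, _, desc = line.partition("\t")
        out[_norm(sym)] = desc.strip()
    return out


def write_edge_table(net: InteractionNetwork, path: str | Path) -> None:
    """Write the network back out in the 3-column scored format; round-trips
    through :func:`read_edge_table` at threshold 0.

    Isolated nodes are encoded as self-loop rows, which the reader registers
    as nodes while dropping the loop edge — the node set survives the trip.
    """
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with open(path, "w") as fh:
        fh.write("nodeA\tnodeB\tcombined_score\n")
        for a, b in sorted(net.edges()):
            score = net.score(a, b)
            fh.write(f"{a}\t{b}\t{score if score is not None else 999}\n")
        for node in isolated:
            fh.write(f"{node}\t{node}\t999\n")
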