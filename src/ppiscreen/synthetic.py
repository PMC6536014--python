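"""Seeded ground-truth network generator for pipeline testing.

Real query-gene networks built from interactome databases typically show a
heavy-tailed (scale-free-like) degree distribution, a dominant connected
component, and a handful of query genes with no recognized interactions.
This module emulates exactly that shape: a preferential-attachment
(Barabási–Albert-style) main component, optional planted high-degree /
high-betweenness nodes with known identity, and a configurable count of
isolated nodes — so the screening cascade can be tested against a known
ground truth without any database download.

An Erdős–Rényi generator of matched density is included as a null model for
heavy-tail contrast checks.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from statistics import pvariance

from .errors import ConfigurationError, NetworkTooSmallError
from .graph_model import GeneList, InteractionNetwork, write_edge_table

FIXTURE_SCORE = 999  # constant fixture confidence: any threshold <= 999 keeps the graph


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Generator parameters.

    ``n_connected`` nodes grow by preferential attachment with ``attachment``
    edges per new node; ``n_planted`` of them are then additionally wired to
    a ``planted_coverage`` fraction of the connected nodes; ``n_isolated``
    edge-free nodes are appended.  Everything is a pure function of ``seed``.
    """

    n_connected: int
    attachment: int = 2
    n_isolated: int = 0
    n_planted: int = 0
    planted_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_connected < 1:
            raise ConfigurationError("n_connected must be >= 1")
        if not 1 <= self.attachment < self.n_connected:
            raise ConfigurationError(
                "attachment must satisfy 1 <= attachment < n_connected"
            )
        if self.n_isolated < 0:
            raise ConfigurationError("n_isolated must be >= 0")
        if not 0 <= self.n_planted <= self.n_connected:
            raise ConfigurationError("n_planted must be in [0, n_connected]")
        if not 0.0 < self.planted_coverage <= 1.0:
            raise ConfigurationError("planted_coverage must be in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Identities of the planted central nodes for a generated network."""

    planted_nodes: frozenset[str]
    spec: SyntheticNetworkSpec


@dataclass(frozen=True)
class DegreeTailSummary:
    """Descriptive heavy-tail summary of the non-isolated part of a network."""

    max_degree: int
    degree_variance: float
    fraction_low_degree: float  # fraction of non-isolated nodes with degree <= 2


def _label(i: int) -> str:
    return f"GENE{i:04d}"


def generate(spec: SyntheticNetworkSpec) -> tuple[InteractionNetwork, GroundTruth]:
    """Generate a network and its ground truth from ``spec``.

    Growth starts from a star on ``attachment + 1`` nodes; each subsequent
    node attaches to ``attachment`` distinct existing nodes sampled
    proportionally to degree (repeated-nodes urn).  Planted nodes are then
    wired to ``ceil(planted_coverage * (n_connected - 1))`` distinct partners
    sampled without replacement, guaranteeing their degree is at least that
    count.  All edges carry the constant fixture score.
    """
    rng = random.Random(spec.seed)
    net = InteractionNetwork()
    connected = [_label(i + 1) for i in range(spec.n_connected)]
    m = spec.attachment

    # seed star keeps the growing graph connected from the first step
    for node in connected[: m + 1]:
        net.add_node(node)
    urn: list[str] = []
    for leaf in connected[1 : m + 1]:
        net.add_edge(connected[0], leaf, FIXTURE_SCORE)
        urn += [connected[0], leaf]

    for node in connected[m + 1 :]:
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(rng.choice(urn))
        for t in sorted(targets):
            net.add_edge(node, t, FIXTURE_SCORE)
            urn += [node, t]

    planted = rng.sample(connected, spec.n_planted)
    if spec.n_planted:
        k = math.ceil(spec.planted_coverage * (spec.n_connected - 1))
        for p in planted:
            others = [v for v in connected if v != p]
            for partner in rng.sample(others, k):
                if not net.has_edge(p, partner):
                    net.add_edge(p, partner, FIXTURE_SCORE)

    for i in range(spec.n_isolated):
        net.add_node(_label(spec.n_connected + i + 1))

    return net, GroundTruth(planted_nodes=frozenset(planted), spec=spec)


def generate_null(n: int, n_edges: int, seed: int = 0) -> InteractionNetwork:
    """Erdős–Rényi G(n, M) null network of matched size/density, for
    contrasting against the heavy-tailed generator."""
    if n < 2 or n_edges < 0 or n_edges > n * (n - 1) // 2:
        raise ConfigurationError("invalid null-model size")
    rng = random.Random(seed)
    nodes = [_label(i + 1) for i in range(n)]
    net = InteractionNetwork()
    for v in nodes:
        net.add_node(v)
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
    for a, b in rng.sample(pairs, n_edges):
        net.add_edge(a, b, FIXTURE_SCORE)
    return net


def degree_tail_check(net: InteractionNetwork) -> DegreeTailSummary:
    """Descriptive summary of the degree tail over non-isolated nodes (no
    hypothesis test).  Requires at least 10 non-isolated nodes."""
    degrees = [net.degree(v) for v in net.sorted_nodes() if net.degree(v) > 0]
    if len(degrees) < 10:
        raise NetworkTooSmallError(
            f"need >= 10 non-isolated nodes, got {len(degrees)}"
        )
    return DegreeTailSummary(
        max_degree=max(degrees),
        degree_variance=pvariance(degrees),
        fraction_low_degree=sum(1 for d in degrees if d <= 2) / len(degrees),
    )


def write_fixture(
    net: InteractionNetwork, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write a loadable fixture: scored edge table (isolated nodes encoded as
    self-loop rows), gene-list file, and a flat key-value truth manifest.
    Returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges_path = out / "edges.tsv"
    genes_path = out / "genes.txt"
    truth_path = out / "truth.txt"

    write_edge_table(net, edges_path)
    genes = GeneList.from_iterable(net.sorted_nodes())
    genes_path.write_text("\n".join(genes) + "\n")
    spec = truth.spec
    truth_path.write_text(
        "planted={}\n"
        "n_connected={}\nattachment={}\nn_isolated={}\nn_planted={}\n"
        "planted_coverage={}\nseed={}\n".format(
            ",".join(sorted(truth.planted_nodes)),
            spec.n_connected,
            spec.attachment,
            spec.n_isolated,
            spec.n_planted,
            spec.planted_coverage,
            spec.seed,
        )
    )
    return {"edges": edges_path, "genes": genes_path, "truth": truth_path}
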