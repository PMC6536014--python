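"""Hub / bottleneck / hub-bottleneck / central-node selection cascade.

The screening procedure ranks genes of a PPI network by topology and
nominates candidates in four nested stages:

1. **hubs** — top fraction of nodes by degree (default top 10 %);
2. **bottlenecks** — top-k nodes by betweenness centrality (default k = 10);
3. **hub-bottlenecks** — the intersection of the two;
4. **central nodes** — hub-bottlenecks that additionally appear in the
   top-k lists by both closeness centrality and stress (the cross-validation
   step; k defaults to the hub-set size).

By default the cascade runs on the main connected component only, since
fraction-based cutoffs are most meaningful there; ``scope`` switches to the
whole network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import floor

from .centrality import CentralityTable, all_metrics
from .errors import ConfigurationError, DegenerateNetworkError
from .graph_model import REPORT_METRICS, InteractionNetwork, connected_components

SCOPES = ("main_component", "whole_network")


@dataclass(frozen=True)
class ScreeningConfig:
    """All thresholds of the selection cascade.

    ``crossval_k=None`` means "use the hub-set size", which makes the
    closeness/stress cross-validation as stringent as the hub cut itself.
    """

    hub_fraction: float = 0.10
    bottleneck_k: int = 10
    crossval_k: int | None = None
    scope: str = "main_component"
    expand_ties: bool = False

    def __post_init__(self):
        if not 0.0 < self.hub_fraction <= 1.0:
            raise ConfigurationError(
                f"hub_fraction must be in (0, 1], got {self.hub_fraction}"
            )
        if self.bottleneck_k < 1:
            raise ConfigurationError("bottleneck_k must be >= 1")
        if self.crossval_k is not None and self.crossval_k < 1:
            raise ConfigurationError("crossval_k must be >= 1")
        if self.scope not in SCOPES:
            raise ConfigurationError(
                f"scope must be one of {SCOPES}, got {self.scope!r}"
            )


@dataclass(frozen=True)
class ScreeningResult:
    """The four nested gene sets with their ranking-metric values, plus the
    configuration (cross-validation k resolved) that produced them."""

    hubs: tuple[str, ...]
    bottlenecks: tuple[str, ...]
    hub_bottlenecks: tuple[str, ...]
    central_nodes: tuple[str, ...]
    hub_values: tuple[float, ...]
    bottleneck_values: tuple[float, ...]
    config: ScreeningConfig
    table: CentralityTable

    def __post_init__(self):
        if set(self.hub_bottlenecks) != set(self.hubs) & set(self.bottlenecks):
            raise ValueError("hub_bottlenecks must equal hubs ∩ bottlenecks")
        if not set(self.central_nodes) <= set(self.hub_bottlenecks):
            raise ValueError("central_nodes must be a subset of hub_bottlenecks")

    def to_text(self) -> str:
        """Structured serialization: one section per set, ranked rows."""
        lines = [
            "# screening result",
            f"# hub_fraction={self.config.hub_fraction}",
            f"# bottleneck_k={self.config.bottleneck_k}",
            f"# crossval_k={self.config.crossval_k}",
            f"# scope={self.config.scope}",
            f"# expand_ties={self.config.expand_ties}",
        ]
        lines.append(f"[hubs] n={len(self.hubs)} metric=degree")
        for rank, (g, v) in enumerate(zip(self.hubs, self.hub_values), 1):
            lines.append(f"{rank}\t{g}\t{v:g}")
        lines.append(f"[bottlenecks] n={len(self.bottlenecks)} metric=betweenness")
        for rank, (g, v) in enumerate(zip(self.bottlenecks, self.bottleneck_values), 1):
            lines.append(f"{rank}\t{g}\t{v:.6f}")
        lines.append(f"[hub_bottlenecks] n={len(self.hub_bottlenecks)}")
        for rank, g in enumerate(self.hub_bottlenecks, 1):
            lines.append(f"{rank}\t{g}")
        lines.append(f"[central_nodes] n={len(self.central_nodes)}")
        for rank, g in enumerate(self.central_nodes, 1):
            lines.append(f"{rank}\t{g}")
        return "\n".join(lines) + "\n"


def _ranked(table: CentralityTable, metric: str) -> list:
    if metric not in REPORT_METRICS:
        raise ConfigurationError(f"unknown metric: {metric!r}")
    return sorted(table, key=lambda m: (-m.value(metric), m.gene))


def _take_top(ranked: list, metric: str, k: int, expand_ties: bool) -> tuple[str, ...]:
    k = min(k, len(ranked))
    if expand_ties and k < len(ranked):
        cutoff = ranked[k - 1].value(metric)
        while k < len(ranked) and ranked[k].value(metric) == cutoff:
            k += 1
    return tuple(m.gene for m in ranked[:k])


def select_top_fraction(
    table: CentralityTable, metric: str, fraction: float, expand_ties: bool = False
) -> tuple[str, ...]:
    """Top ``max(1, floor(fraction * n))`` genes by ``metric``; cutoff ties
    broken symbol-ascending, or all included when ``expand_ties``."""
    if len(table) == 0:
        raise ConfigurationError("cannot select from an empty table")
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    ranked = _ranked(table, metric)
    k = max(1, floor(fraction * len(ranked)))
    return _take_top(ranked, metric, k, expand_ties)


def select_top_k(
    table: CentralityTable, metric: str, k: int, expand_ties: bool = False
) -> tuple[str, ...]:
    """Top ``min(k, n)`` genes by ``metric``; same tie policy as
    :func:`select_top_fraction`."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    return _take_top(_ranked(table, metric), metric, k, expand_ties)


def intersect_hub_bottleneck(
    hubs: tuple[str, ...], bottlenecks: tuple[str, ...]
) -> tuple[str, ...]:
    """Genes that are both hubs and bottlenecks, ordered by hub rank."""
    bset = set(bottlenecks)
    return tuple(g for g in hubs if g in bset)


def cross_validate_central(
    hb: tuple[str, ...], table: CentralityTable, crossval_k: int, expand_ties: bool = False
) -> tuple[str, ...]:
    """Keep the hub-bottlenecks present in BOTH the top-``crossval_k``
    closeness list and the top-``crossval_k`` stress list (hub order kept)."""
    top_cc = set(select_top_k(table, "closeness", crossval_k, expand_ties))
    top_stress = set(select_top_k(table, "stress", crossval_k, expand_ties))
    return tuple(g for g in hb if g in top_cc and g in top_stress)


def screen(net: InteractionNetwork, config: ScreeningConfig | None = None) -> ScreeningResult:
    """Run the full cascade on ``net`` under ``config``.

    With ``scope='main_component'`` the centrality table is computed on the
    largest connected component only; a network whose largest component is a
    single node (or an empty network) is degenerate.
    """
    config = config or ScreeningConfig()
    if net.n_nodes() == 0:
        raise DegenerateNetworkError("empty network")
    if config.scope == "main_component":
        parts = connected_components(net)
        if len(parts.main) <= 1:
            raise DegenerateNetworkError(
                "main component has a single node; nothing to rank"
            )
        scoped = net.subgraph(parts.main)
    else:
        scoped = net

    table = all_metrics(scoped)
    hubs = select_top_fraction(table, "degree", config.hub_fraction, config.expand_ties)
    bottlenecks = select_top_k(
        table, "betweenness", config.bottleneck_k, config.expand_ties
    )
    hb = intersect_hub_bottleneck(hubs, bottlenecks)
    crossval_k = config.crossval_k if config.crossval_k is not None else len(hubs)
    central = cross_validate_central(hb, table, crossval_k, config.expand_ties)
    return ScreeningResult(
        hubs=hubs,
        bottlenecks=bottlenecks,
        hub_bottlenecks=hb,
        central_nodes=central,
        hub_values=tuple(float(table[g].degree) for g in hubs),
        bottleneck_values=tuple(table[g].betweenness for g in bottlenecks),
        config=replace(config, crossval_k=crossval_k),
        table=table,
    )
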