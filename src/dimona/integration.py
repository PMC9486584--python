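"""Path-based integrated interaction scores.

The semi-local integration step replaces an edge's raw weight by a score
that pools the strength of alternative routes between its endpoints. For an
edge (u, v) the integrated interaction score is

    s(u, v) = sum over l = 1..L of
              mean over simple paths of length l from u to v of
              product of the edge weights along the path,

where L is the maximum path length considered (default 3). Paths are simple
(no repeated node) and each undirected path counts once; a length with no
paths contributes zero. The l = 1 term is the direct edge's own weight, so
with L = 1 the transform is the identity. With all |weights| <= 1 every path
product lies in [-1, 1], hence |s| <= L.

Scoring an edge costs O(degree^(L-1)) path enumerations; by default scores
are only computed for edges incident to drug-target nodes, which is all the
downstream drug scoring reads. Other edges keep their raw weight and are
flagged as not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

import networkx as nx
import pandas as pd

from .io import DrugTargetMap
from .multilayer import MultiLayerNetwork

__all__ = [
    "IntegrationConfig",
    "IntegratedNetwork",
    "enumerate_simple_paths",
    "integrated_score_edge",
    "integrate_network",
    "write_integrated_edge_list",
]


@dataclass
class IntegrationConfig:
    """Settings of the path-integration step.

    ``max_path_length`` (L) bounds the detour length pooled into each score;
    ``restrict_to_targets`` limits computation to drug-target-incident edges.
    """

    max_path_length: int = 3
    restrict_to_targets: bool = True

    def __post_init__(self) -> None:
        if self.max_path_length < 1:
            raise ValueError("max_path_length must be >= 1")


@dataclass
class IntegratedNetwork:
    """A multi-layer network whose edges carry integrated interaction scores.

    Edge attributes: ``weight`` (raw), ``score`` (integrated, or the raw
    weight when not computed), ``computed`` (bool flag), ``edge_type``.
    """

    condition: str
    graph: nx.Graph
    max_path_length: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def score_of(self, u, v) -> float:
        return self.graph.edges[u, v]["score"]


def enumerate_simple_paths(
    net: MultiLayerNetwork | nx.Graph, u, v, length: int
) -> list[list]:
    """All simple paths of exactly ``length`` edges between u and v.

    Each path is a node sequence starting at u and ending at v with no
    repeated node; every geometrically distinct undirected path appears once.
    """
    g = net.graph if isinstance(net, MultiLayerNetwork) else net
    if u == v:
        raise ValueError("path endpoints must differ")
    if length < 1:
        raise ValueError("path length must be >= 1")
    return [
        p for p in nx.all_simple_paths(g, u, v, cutoff=length) if len(p) == length + 1
    ]


def _score_edge(g: nx.Graph, u, v, L: int) -> float:
    """Sum over lengths 1..L of the mean path-product between u and v."""
    # One DFS with cutoff L yields all simple paths up to length L at once;
    # start from the lower-degree endpoint to shrink the search tree.
    if g.degree(v) < g.degree(u):
        u, v = v, u
    sums = [0.0] * (L + 1)
    counts = [0] * (L + 1)
    for path in nx.all_simple_paths(g, u, v, cutoff=L):
        l = len(path) - 1
        prod = 1.0
        for a, b in zip(path, islice(path, 1, None)):
            prod *= g.edges[a, b]["weight"]
        sums[l] += prod
        counts[l] += 1
    return sum(sums[l] / counts[l] for l in range(1, L + 1) if counts[l])


def integrated_score_edge(
    net: MultiLayerNetwork, u, v, cfg: IntegrationConfig | None = None
) -> float:
    """Integrated interaction score of one existing edge."""
    cfg = cfg or IntegrationConfig()
    if not net.graph.has_edge(u, v):
        raise ValueError(f"edge {u} - {v} not present in the network")
    return _score_edge(net.graph, u, v, cfg.max_path_length)


def _target_nodes(net: MultiLayerNetwork, targets: DrugTargetMap) -> set:
    nodes = set(net.graph.nodes)
    return {t for ts in targets.entries.values() for t in ts if t in nodes}


def integrate_network(
    net: MultiLayerNetwork,
    cfg: IntegrationConfig | None = None,
    targets: DrugTargetMap | None = None,
) -> IntegratedNetwork:
    """Score a condition's multi-layer network.

    With ``restrict_to_targets`` (default), only edges incident to at least
    one mapped drug-target node are scored; it is an error to request the
    restriction when no target maps into the network. Unscored edges retain
    their raw weight with ``computed=False``.
    """
    cfg = cfg or IntegrationConfig()
    if cfg.restrict_to_targets:
        if targets is None or len(targets) == 0:
            raise ValueError(
                "restrict_to_targets requires a non-empty drug-target map"
            )
        tnodes = _target_nodes(net, targets)
        if not tnodes:
            raise ValueError("no drug target maps to a node of the network")
    else:
        tnodes = None

    g = net.graph.copy()
    for u, v, data in g.edges(data=True):
        compute = tnodes is None or u in tnodes or v in tnodes
        data["computed"] = compute
        data["score"] = (
            _score_edge(net.graph, u, v, cfg.max_path_length)
            if compute
            else data["weight"]
        )
    return IntegratedNetwork(
        condition=net.condition, graph=g, max_path_length=cfg.max_path_length
    )


def write_integrated_edge_list(net: IntegratedNetwork, path, sep: str = "\t") -> None:
    """Export as TSV: node_a, node_b, raw_weight, integrated_score, computed_flag, edge_type."""
    rows = [
        {
            "node_a": f"{u[0]}:{u[1]}",
            "node_b": f"{v[0]}:{v[1]}",
            "raw_weight": d["weight"],
            "integrated_score": d["score"],
            "computed_flag": d["computed"],
            "edge_type": "-".join(d["edge_type"]),
        }
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "node_a",
            "node_b",
            "raw_weight",
            "integrated_score",
            "computed_flag",
            "edge_type",
        ],
    ).to_csv(path, sep=sep, index=False)
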