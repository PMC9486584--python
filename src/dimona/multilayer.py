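"""Assembly of per-layer networks into one heterogeneous multi-layer graph.

Nodes of the multi-layer network are ``(layer_name, feature_id)`` pairs: the
same feature name in two layers (an mRNA and its protein, say) is two
distinct nodes. Intra-layer edges carry the correlation-derived weights
unchanged; inter-layer edges come from connector rules encoding prior
knowledge — either name identity between two layers at a fixed weight
(central-dogma links such as mRNA-protein or protein-phosphosite), or an
explicit pair table with per-pair weights (e.g. curated protein-metabolite
interactions). Graphs are undirected throughout; each condition is assembled
separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .layers import LayerNetwork

__all__ = [
    "ConnectorSpec",
    "MultiLayerNetwork",
    "connect_same_name",
    "connect_pairs",
    "assemble",
    "read_connector_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class ConnectorSpec:
    """One inter-layer connection rule.

    ``mode='same_name'`` joins identically named features of ``layer_a`` and
    ``layer_b`` with ``fixed_weight``; ``mode='pair_table'`` joins the listed
    ``(feature_a, feature_b, weight)`` pairs.
    """

    mode: str
    layer_a: str
    layer_b: str
    fixed_weight: float = 1.0
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in {"same_name", "pair_table"}:
            raise ValueError(f"unknown connector mode {self.mode!r}")
        if self.layer_a == self.layer_b:
            raise ValueError("connector must join two different layers")
        for a, b, w in self.pairs:
            if not pd.notna(w) or w in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite connector weight for pair ({a}, {b})")


@dataclass
class MultiLayerNetwork:
    """Heterogeneous multi-layer network of one condition.

    Nodes are ``(layer, feature)`` tuples; each edge carries ``weight`` and an
    ``edge_type`` tag naming the (sorted) layer pair it joins.
    """

    condition: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_type_census(self) -> dict[tuple[str, str], int]:
        census: dict[tuple[str, str], int] = {}
        for _, _, t in self.graph.edges(data="edge_type"):
            census[t] = census.get(t, 0) + 1
        return census


def _edge_type(layer_a: str, layer_b: str) -> tuple[str, str]:
    return tuple(sorted((layer_a, layer_b)))  # type: ignore[return-value]


def connect_same_name(
    layers: list[LayerNetwork],
    layer_a: str,
    layer_b: str,
    fixed_weight: float = 1.0,
) -> list[tuple[tuple[str, str], tuple[str, str], float]]:
    """Inter-layer edges joining identically named features of two layers."""
    by_name = {ln.layer_name: ln for ln in layers}
    for name in (layer_a, layer_b):
        if name not in by_name:
            raise ValueError(f"unknown layer {name!r}")
    shared = set(by_name[layer_a].graph.nodes) & set(by_name[layer_b].graph.nodes)
    return [
        ((layer_a, f), (layer_b, f), fixed_weight) for f in sorted(shared)
    ]


def connect_pairs(
    layers: list[LayerNetwork],
    spec: ConnectorSpec,
) -> list[tuple[tuple[str, str], tuple[str, str], float]]:
    """Inter-layer edges from an explicit pair table.

    Pairs whose endpoints are absent from the networks are skipped; the
    skipped count is logged, not fatal (prior-knowledge tables routinely
    reference features filtered out upstream).
    """
    by_name = {ln.layer_name: ln for ln in layers}
    for name in (spec.layer_a, spec.layer_b):
        if name not in by_name:
            raise ValueError(f"unknown layer {name!r}")
    nodes_a = set(by_name[spec.layer_a].graph.nodes)
    nodes_b = set(by_name[spec.layer_b].graph.nodes)
    edges, skipped = [], 0
    for fa, fb, w in spec.pairs:
        if fa in nodes_a and fb in nodes_b:
            edges.append(((spec.layer_a, fa), (spec.layer_b, fb), float(w)))
        else:
            skipped += 1
    if skipped:
        logger.info(
            "connector %s-%s: skipped %d pairs with missing endpoints",
            spec.layer_a,
            spec.layer_b,
            skipped,
        )
    return edges


def assemble(
    layers: list[LayerNetwork],
    connectors: list[ConnectorSpec] | None = None,
) -> MultiLayerNetwork:
    """Union the layer networks of one condition and add connector edges.

    The node set is the disjoint union of layer nodes (keyed by layer);
    intra-layer edge weights pass through unchanged. A connector edge
    duplicating an existing edge is rejected (the graph is not a multigraph).
    Inter-layer weights outside [-1, 1] trigger a warning because downstream
    path integration assumes correlation-scale weights.
    """
    connectors = connectors or []
    conditions = {ln.condition for ln in layers}
    if len(conditions) != 1:
        raise ValueError(f"layers mix conditions: {sorted(conditions)}")
    condition = conditions.pop()
    seen_layers = set()
    for ln in layers:
        if ln.layer_name in seen_layers:
            raise ValueError(f"layer {ln.layer_name!r} listed twice")
        seen_layers.add(ln.layer_name)

    g = nx.Graph()
    for ln in layers:
        t = _edge_type(ln.layer_name, ln.layer_name)
        g.add_nodes_from((ln.layer_name, f) for f in ln.graph.nodes)
        for u, v, w in ln.graph.edges(data="weight"):
            g.add_edge(
                (ln.layer_name, u), (ln.layer_name, v), weight=w, edge_type=t
            )

    for spec in connectors:
        if spec.mode == "same_name":
            edges = connect_same_name(
                layers, spec.layer_a, spec.layer_b, spec.fixed_weight
            )
        else:
            edges = connect_pairs(layers, spec)
        t = _edge_type(spec.layer_a, spec.layer_b)
        for u, v, w in edges:
            if g.has_edge(u, v):
                raise ValueError(
                    f"duplicate connector edge {u} - {v}; multigraphs are not supported"
                )
            if abs(w) > 1:
                warnings.warn(
                    f"connector edge {u} - {v} has |weight| {abs(w)} > 1; "
                    "integrated scores may exceed their nominal range",
                    stacklevel=2,
                )
            g.add_edge(u, v, weight=w, edge_type=t)

    return MultiLayerNetwork(condition=condition, graph=g)


def read_connector_pairs(path, sep: str = "\t") -> list[ConnectorSpec]:
    """Read a connector pair table (layer_a, node_a, layer_b, node_b, weight).

    Returns one pair_table :class:`ConnectorSpec` per distinct layer pair.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"layer_a", "node_a", "layer_b", "node_b", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"connector table needs columns {sorted(required)}")
    specs = []
    for (la, lb), grp in df.groupby(["layer_a", "layer_b"], sort=True):
        specs.append(
            ConnectorSpec(
                mode="pair_table",
                layer_a=str(la),
                layer_b=str(lb),
                pairs=[
                    (str(r.node_a), str(r.node_b), float(r.weight))
                    for r in grp.itertuples(index=False)
                ],
            )
        )
    return specs
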