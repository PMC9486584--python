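"""Differential network and differential drug response scores.

The two conditions' integrated networks are contrasted edge-wise: the
differential network is the union graph whose edges carry
``d = s_A - s_B`` (condition A is whichever is passed first, recorded in the
result), with an edge absent from one condition contributing a score of zero
there. Nodes of either network are included.

A drug's differential drug response score is the absolute value of the mean
(or median) of ``d`` over all edges incident to any of its targets — each
edge counted once even when it touches two targets of the same drug. Drugs
with no target-incident edges receive no score and are reported as unscored
rather than silently dropped. The scored drugs are ranked by descending
score; this ranking is the pipeline's main output. ``explain_drug`` breaks a
score back down into the per-target incident edges and their per-condition
scores, the trace that makes a prediction auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import DrugTargetMap
from .integration import IntegratedNetwork

__all__ = [
    "DifferentialNetwork",
    "differential_network",
    "drug_response_score",
    "rank_drugs",
    "explain_drug",
]

logger = logging.getLogger(__name__)


@dataclass
class DifferentialNetwork:
    """Union graph of the two conditions with per-edge score differences.

    Edge attributes: ``diff`` (= score in A minus score in B), ``score_a``,
    ``score_b``, ``raw_diff`` (difference of raw, un-integrated weights, used
    by the PageRank baseline), ``provenance`` ('A', 'B' or 'both'),
    ``computed`` (True when the integrated score was computed in every
    condition containing the edge), ``edge_type``.
    """

    condition_a: str
    condition_b: str
    graph: nx.Graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def differential_network(
    intA: IntegratedNetwork, intB: IntegratedNetwork
) -> DifferentialNetwork:
    """Contrast two integrated networks into one differential network."""
    if intA.condition == intB.condition:
        raise ValueError("differential network needs two distinct conditions")
    g = nx.Graph()
    g.add_nodes_from(intA.graph.nodes)
    g.add_nodes_from(intB.graph.nodes)
    edges = set(map(frozenset, intA.graph.edges)) | set(
        map(frozenset, intB.graph.edges)
    )
    for e in edges:
        u, v = tuple(e)
        in_a = intA.graph.has_edge(u, v)
        in_b = intB.graph.has_edge(u, v)
        da = intA.graph.edges[u, v] if in_a else None
        db = intB.graph.edges[u, v] if in_b else None
        s_a = da["score"] if in_a else 0.0
        s_b = db["score"] if in_b else 0.0
        w_a = da["weight"] if in_a else 0.0
        w_b = db["weight"] if in_b else 0.0
        computed = all(d["computed"] for d in (da, db) if d is not None)
        g.add_edge(
            u,
            v,
            diff=s_a - s_b,
            score_a=s_a,
            score_b=s_b,
            raw_diff=w_a - w_b,
            provenance="both" if in_a and in_b else ("A" if in_a else "B"),
            computed=computed,
            edge_type=(da or db)["edge_type"],
        )
    return DifferentialNetwork(
        condition_a=intA.condition, condition_b=intB.condition, graph=g
    )


def _incident_diffs(diff: DifferentialNetwork, target_nodes) -> list[float]:
    """diff values of the union of edges incident to any target node."""
    g = diff.graph
    seen = set()
    out = []
    for t in sorted(target_nodes):
        if t not in g:
            continue
        for u, v, d in g.edges(t, data="diff"):
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                out.append(d)
    return out


def drug_response_score(
    diff: DifferentialNetwork,
    targets,
    aggregator: str = "mean",
) -> float | None:
    """|mean| (or |median|) of differential scores over target-incident edges.

    ``targets`` is a set of ``(layer, feature)`` nodes. Returns ``None``
    (unscored) when no incident edge exists. Targets that do not resolve to a
    network node are logged and ignored.
    """
    if aggregator not in {"mean", "median"}:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    targets = set(targets)
    unresolved = {t for t in targets if t not in diff.graph}
    if unresolved:
        logger.info("%d drug targets not present in the network", len(unresolved))
    diffs = _incident_diffs(diff, targets - unresolved)
    if not diffs:
        return None
    agg = np.mean if aggregator == "mean" else np.median
    return float(abs(agg(diffs)))


def rank_drugs(
    diff: DifferentialNetwork,
    targets: DrugTargetMap,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Score and rank every drug of the target map.

    Returns a DataFrame with columns ``drug_id, score, n_edges, rank,
    unscored``, scored drugs first in descending score order (ties broken
    lexicographically by drug id, ranks 1..k), unscored drugs after with no
    rank.
    """
    rows = []
    for drug in targets.drugs:
        tnodes = {t for t in targets.targets_of(drug) if t in diff.graph}
        diffs = _incident_diffs(diff, tnodes)
        score = drug_response_score(diff, targets.targets_of(drug), aggregator)
        rows.append(
            {
                "drug_id": drug,
                "score": score if score is not None else np.nan,
                "n_edges": len(diffs),
                "unscored": score is None,
            }
        )
    df = pd.DataFrame(rows, columns=["drug_id", "score", "n_edges", "unscored"])
    scored = df[~df["unscored"]].sort_values(
        ["score", "drug_id"], ascending=[False, True], kind="mergesort"
    )
    scored = scored.assign(rank=np.arange(1, len(scored) + 1))
    unscored = df[df["unscored"]].assign(rank=np.nan).sort_values("drug_id")
    out = pd.concat([scored, unscored], ignore_index=True)
    return out[["drug_id", "score", "n_edges", "rank", "unscored"]]


def explain_drug(
    diff: DifferentialNetwork,
    intA: IntegratedNetwork,
    intB: IntegratedNetwork,
    drug: str,
    targets: DrugTargetMap,
) -> dict:
    """Trace a drug's score back to its targets' individual edges.

    Returns ``{'drug_id', 'edges': DataFrame, 'summary': DataFrame}``. The
    edge table has one row per (target, incident edge) with the per-condition
    integrated scores and their difference; the summary has per-target edge
    counts and mean |d| (a target absent from the network, or with no
    differential edges, appears with zero counts — 'no interaction
    differences'). The union of edge rows over targets is exactly the edge
    set aggregated by :func:`drug_response_score`.
    """
    if drug not in targets:
        raise KeyError(f"unknown drug {drug!r}")
    g = diff.graph
    edge_rows = []
    summary_rows = []
    for t in sorted(targets.targets_of(drug)):
        incident = list(g.edges(t, data=True)) if t in g else []
        for u, v, d in incident:
            partner = v if u == t else u
            edge_rows.append(
                {
                    "target": f"{t[0]}:{t[1]}",
                    "partner": f"{partner[0]}:{partner[1]}",
                    "edge_type": "-".join(d["edge_type"]),
                    "score_a": d["score_a"],
                    "score_b": d["score_b"],
                    "differential": d["diff"],
                }
            )
        summary_rows.append(
            {
                "target": f"{t[0]}:{t[1]}",
                "in_network": t in g,
                "n_edges": len(incident),
                "mean_abs_differential": (
                    float(np.mean([abs(d["diff"]) for _, _, d in incident]))
                    if incident
                    else 0.0
                ),
            }
        )
    return {
        "drug_id": drug,
        "condition_a": diff.condition_a,
        "condition_b": diff.condition_b,
        "edges": pd.DataFrame(
            edge_rows,
            columns=[
                "target",
                "partner",
                "edge_type",
                "score_a",
                "score_b",
                "differential",
            ],
        ),
        "summary": pd.DataFrame(
            summary_rows,
            columns=["target", "in_network", "n_edges", "mean_abs_differential"],
        ),
    }
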