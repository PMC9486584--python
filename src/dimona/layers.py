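"""Condition-specific single-layer correlation networks and their reduction.

Each omics layer yields, per condition, a complete weighted graph whose edge
weights are pairwise correlations (Spearman by default, to damp outliers and
capture monotone nonlinear relationships) between feature abundance profiles,
computed over pairwise-complete observations. The dense graph is then reduced
to the edges with the largest absolute weights, by one of three criteria:

* ``average_degree`` — keep the top ``round(n * target_degree / 2)`` edges;
* ``density`` — keep the top ``round(target_density * n * (n - 1) / 2)`` edges;
* ``scale_free`` — pick the hard threshold on |weight| that makes the degree
  distribution closest to a power law (log-log linear fit of p(k) on k,
  R-squared signed negative when the slope is positive).

For two-condition analyses, ``harmonize_scale_free`` searches a threshold
grid for a cut pair that reaches the scale-free fit target in both groups
while keeping the two reduced networks as similar in size as possible, so the
downstream differential contrast is not dominated by a size imbalance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix

__all__ = [
    "LayerNetwork",
    "ReductionSpec",
    "correlation_network",
    "reduce_network",
    "fit_scale_free_r2",
    "harmonize_scale_free",
    "write_edge_list",
]


@dataclass
class LayerNetwork:
    """Undirected weighted graph over one layer's features, one condition.

    Edge weights are correlations in [-1, 1]; absent edges mean the pair was
    either cut during reduction or had no defined correlation.
    """

    layer_name: str
    condition: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (u, v): d["weight"] for u, v, d in self.graph.edges(data=True)
        }

    def _replace(self, graph: nx.Graph) -> "LayerNetwork":
        return LayerNetwork(self.layer_name, self.condition, graph)


@dataclass
class ReductionSpec:
    """Parameters of one network-reduction criterion.

    Exactly the parameters of the chosen ``method`` are consulted:
    ``target_degree`` for ``average_degree``, ``target_density`` for
    ``density``, and ``r2_target``/``threshold_grid``/``relax_step`` for
    ``scale_free``.
    """

    method: str = "scale_free"
    target_degree: float | None = None
    target_density: float | None = None
    r2_target: float = 0.8
    threshold_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.1, 0.9 + 1e-9, 0.02), 10))
    )
    relax_step: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in {"average_degree", "density", "scale_free"}:
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.method == "average_degree" and not self.target_degree:
            raise ValueError("average_degree reduction needs target_degree > 0")
        if self.method == "density" and self.target_density is None:
            raise ValueError("density reduction needs target_density")
        if self.method == "scale_free":
            if not 0 < self.r2_target <= 1:
                raise ValueError("r2_target must lie in (0, 1]")
            if len(self.threshold_grid) == 0:
                raise ValueError("threshold_grid is empty")


def correlation_network(
    m: OmicsMatrix,
    method: str = "spearman",
    min_pairs: int = 5,
) -> LayerNetwork:
    """Build the complete correlation graph over a layer's features.

    Correlations use pairwise-complete observations; a pair with fewer than
    ``min_pairs`` complete observations, or with zero variance in either
    profile (undefined correlation), carries no edge.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown correlation method {method!r}")
    if m.n_features < 2 or m.n_samples < 2:
        raise ValueError("correlation needs at least 2 features and 2 samples")

    # samples x features orientation for pandas' pairwise-complete corr
    corr = m.data.T.corr(method=method, min_periods=min_pairs)
    g = nx.Graph()
    g.add_nodes_from(m.feature_ids)
    feats = m.feature_ids
    cmat = corr.to_numpy()
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            w = cmat[i, j]
            if np.isfinite(w):
                g.add_edge(feats[i], feats[j], weight=float(w))
    return LayerNetwork(m.layer_name, m.condition, g)


def _keep_top_edges(net: LayerNetwork, k: int) -> LayerNetwork:
    """Keep the k edges of largest |weight|; ties at the cut are all kept."""
    edges = sorted(
        net.graph.edges(data="weight"),
        key=lambda e: abs(e[2]),
        reverse=True,
    )
    if k >= len(edges):
        if k > len(edges):
            warnings.warn(
                f"reduction target implies {k} edges but only {len(edges)} exist; "
                "keeping all",
                stacklevel=3,
            )
        return net._replace(net.graph.copy())
    if k <= 0:
        kept = []
    else:
        cut = abs(edges[k - 1][2])
        kept = [e for e in edges if abs(e[2]) >= cut]
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_weighted_edges_from(kept)
    return net._replace(g)


def _apply_cut(net: LayerNetwork, cut: float) -> LayerNetwork:
    """Keep edges with |weight| >= cut."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_weighted_edges_from(
        (u, v, w) for u, v, w in net.graph.edges(data="weight") if abs(w) >= cut
    )
    return net._replace(g)


def fit_scale_free_r2(degree_histogram: dict[int, int]) -> tuple[float, float]:
    """Goodness of fit of a degree distribution to a power law.

    Regresses log10 p(k) on log10 k over occupied positive-degree bins and
    returns ``(signed_r2, slope)``: the regression R-squared, sign-flipped to
    negative when the slope is positive (a rising degree distribution is the
    opposite of scale-free). Needs at least two distinct positive degrees.
    """
    ks = np.array(sorted(k for k, c in degree_histogram.items() if k > 0 and c > 0))
    if len(ks) < 2:
        raise ValueError("scale-free fit needs >= 2 occupied positive-degree bins")
    counts = np.array([degree_histogram[k] for k in ks], dtype=float)
    p = counts / counts.sum()
    fit = stats.linregress(np.log10(ks), np.log10(p))
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    return (-r2 if slope > 0 else r2), slope


def _network_signed_r2(net: LayerNetwork) -> float:
    """Signed scale-free R2 of a network, -inf when the fit is undefined."""
    hist: dict[int, int] = {}
    for _, d in net.graph.degree():
        if d > 0:
            hist[d] = hist.get(d, 0) + 1
    try:
        signed_r2, _ = fit_scale_free_r2(hist)
    except ValueError:
        return -math.inf
    return signed_r2


def reduce_network(net: LayerNetwork, spec: ReductionSpec) -> LayerNetwork:
    """Reduce a dense correlation network to its strongest edges.

    Thresholding is on absolute weight so strong negative correlations
    survive; retained weights keep their sign and value. When the count
    implied by ``average_degree``/``density`` falls inside a block of equal
    |weight|, all tied edges are kept (deterministic, order-independent).
    """
    if net.n_edges == 0:
        raise ValueError("cannot reduce an empty network")
    n = net.n_nodes
    if spec.method == "average_degree":
        k = round(n * spec.target_degree / 2)
        return _keep_top_edges(net, k)
    if spec.method == "density":
        k = round(spec.target_density * n * (n - 1) / 2)
        return _keep_top_edges(net, k)
    # scale_free: lowest grid cut whose reduced network reaches the R2 target
    # (mirrors hard-threshold picking); fall back to the best-fitting cut.
    best_cut, best_r2 = None, -math.inf
    for cut in spec.threshold_grid:
        reduced = _apply_cut(net, cut)
        r2 = _network_signed_r2(reduced)
        if r2 >= spec.r2_target:
            return reduced
        if r2 > best_r2:
            best_cut, best_r2 = cut, r2
    warnings.warn(
        f"no grid cut reaches signed R2 >= {spec.r2_target}; "
        f"using best cut {best_cut} (R2 = {best_r2:.3f})",
        stacklevel=2,
    )
    return _apply_cut(net, best_cut)


def harmonize_scale_free(
    netA: LayerNetwork,
    netB: LayerNetwork,
    spec: ReductionSpec,
) -> tuple[float, float, LayerNetwork, LayerNetwork]:
    """Pick per-condition hard thresholds that are scale-free AND size-matched.

    Among grid cut pairs whose reduced networks reach ``signed_r2 >=
    r2_target`` in both conditions, selects the pair minimizing the edge-count
    gap ``|E_A - E_B|`` (ties: lexicographically smallest cut pair). If no
    pair qualifies, the R2 target is relaxed in ``relax_step`` decrements with
    a warning. Returns ``(cutA, cutB, reducedA, reducedB)``.
    """
    if netA.layer_name != netB.layer_name:
        raise ValueError("harmonization requires networks over the same layer")
    if len(spec.threshold_grid) == 0:
        raise ValueError("threshold grid is empty")

    def profile(net: LayerNetwork) -> list[tuple[float, LayerNetwork, float, int]]:
        out = []
        for cut in spec.threshold_grid:
            red = _apply_cut(net, cut)
            out.append((cut, red, _network_signed_r2(red), red.n_edges))
        return out

    profA, profB = profile(netA), profile(netB)
    target = spec.r2_target
    while True:
        candidates = [
            (abs(ecA - ecB), cutA, cutB, redA, redB)
            for cutA, redA, r2A, ecA in profA
            if r2A >= target
            for cutB, redB, r2B, ecB in profB
            if r2B >= target
        ]
        if candidates:
            gap, cutA, cutB, redA, redB = min(
                candidates, key=lambda c: (c[0], c[1], c[2])
            )
            return cutA, cutB, redA, redB
        target = round(target - spec.relax_step, 10)
        if target <= 0:
            raise ValueError(
                "no threshold pair attains any positive scale-free fit target"
            )
        warnings.warn(
            f"no cut pair reaches signed R2 target; relaxing to {target}",
            stacklevel=2,
        )


def write_edge_list(net: LayerNetwork, path, sep: str = "\t") -> None:
    """Export a layer network as a (node_a, node_b, weight) table."""
    rows = [
        {"node_a": u, "node_b": v, "weight": w}
        for u, v, w in net.graph.edges(data="weight")
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep=sep, index=False
    )
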