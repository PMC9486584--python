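"""End-to-end orchestration: omics matrices in, ranked drug table out.

``run_pipeline`` chains the stages for the two conditions:

1. per-layer correlation networks (Spearman, pairwise-complete),
2. reduction to the strongest |weight| edges (shared spec; for scale-free
   reduction the cut pair is harmonized across the two conditions),
3. assembly into heterogeneous multi-layer networks via connector rules,
4. path-based integrated interaction scores around the drug targets,
5. differential network (condition A minus condition B),
6. differential drug response scores and ranking.

It returns the intermediate artifacts alongside the ranking so callers can
inspect, export, or explain any stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .differential import DifferentialNetwork, differential_network, rank_drugs
from .integration import IntegratedNetwork, IntegrationConfig, integrate_network
from .io import DrugTargetMap, OmicsMatrix
from .layers import LayerNetwork, ReductionSpec, correlation_network, harmonize_scale_free, reduce_network
from .multilayer import ConnectorSpec, MultiLayerNetwork, assemble

__all__ = ["PipelineResult", "run_pipeline", "default_same_name_connectors"]


@dataclass
class PipelineResult:
    """All artifacts of one two-condition run."""

    condition_a: str
    condition_b: str
    layer_networks: dict[str, dict[str, LayerNetwork]]  # condition -> layer -> net
    multilayer: dict[str, MultiLayerNetwork]
    integrated: dict[str, IntegratedNetwork]
    differential: DifferentialNetwork
    ranking: pd.DataFrame


def default_same_name_connectors(
    layer_names: list[str], fixed_weight: float = 1.0
) -> list[ConnectorSpec]:
    """Chain consecutive layers with same-name connectors of a fixed weight.

    Mirrors the central-dogma chain (mRNA - protein - phosphosite) when the
    layers are listed in that order.
    """
    return [
        ConnectorSpec(
            mode="same_name", layer_a=a, layer_b=b, fixed_weight=fixed_weight
        )
        for a, b in zip(layer_names, layer_names[1:])
    ]


def run_pipeline(
    omics: dict[str, dict[str, OmicsMatrix]],
    targets: DrugTargetMap,
    reduction: ReductionSpec | None = None,
    connectors: list[ConnectorSpec] | None = None,
    integration: IntegrationConfig | None = None,
    correlation_method: str = "spearman",
    min_pairs: int = 5,
    aggregator: str = "mean",
) -> PipelineResult:
    """Run the full differential drug prioritization pipeline.

    ``omics`` maps condition -> layer -> :class:`OmicsMatrix` for exactly two
    conditions (the first is condition A of the differential). Connectors
    default to same-name links between consecutive layers with weight 1.
    """
    if len(omics) != 2:
        raise ValueError("pipeline requires exactly two conditions")
    cond_a, cond_b = omics.keys()
    layer_names = list(omics[cond_a])
    if set(layer_names) != set(omics[cond_b]):
        raise ValueError("both conditions must provide the same layers")
    reduction = reduction or ReductionSpec(method="average_degree", target_degree=10)
    integration = integration or IntegrationConfig()
    if connectors is None:
        connectors = default_same_name_connectors(layer_names)

    layer_nets: dict[str, dict[str, LayerNetwork]] = {cond_a: {}, cond_b: {}}
    for layer in layer_names:
        dense_a = correlation_network(
            omics[cond_a][layer], method=correlation_method, min_pairs=min_pairs
        )
        dense_b = correlation_network(
            omics[cond_b][layer], method=correlation_method, min_pairs=min_pairs
        )
        if reduction.method == "scale_free":
            _, _, red_a, red_b = harmonize_scale_free(dense_a, dense_b, reduction)
        else:
            red_a = reduce_network(dense_a, reduction)
            red_b = reduce_network(dense_b, reduction)
        layer_nets[cond_a][layer] = red_a
        layer_nets[cond_b][layer] = red_b

    multilayer = {
        c: assemble(list(layer_nets[c].values()), connectors)
        for c in (cond_a, cond_b)
    }
    integrated = {
        c: integrate_network(multilayer[c], integration, targets)
        for c in (cond_a, cond_b)
    }
    diff = differential_network(integrated[cond_a], integrated[cond_b])
    ranking = rank_drugs(diff, targets, aggregator=aggregator)
    return PipelineResult(
        condition_a=cond_a,
        condition_b=cond_b,
        layer_networks=layer_nets,
        multilayer=multilayer,
        integrated=integrated,
        differential=diff,
        ranking=ranking,
    )
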