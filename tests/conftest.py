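import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dimona import FixtureSpec, OmicsMatrix
from dimona.multilayer import MultiLayerNetwork


def make_matrix(values, features=None, samples=None, layer="protein", condition="A"):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return OmicsMatrix(
        layer_name=layer,
        condition=condition,
        data=pd.DataFrame(values, index=features, columns=samples),
    )


def make_mln(edges, condition="A", layer="p"):
    """Multi-layer network from (u, v, w) triples of bare feature names."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge((layer, u), (layer, v), weight=float(w), edge_type=(layer, layer))
    return MultiLayerNetwork(condition=condition, graph=g)


@pytest.fixture
def small_spec():
    """Downsized fixture spec for fast unit tests."""
    return FixtureSpec(
        layers=(("mrna", 60), ("protein", 60), ("phosphosite", 60)),
        n_samples=30,
        n_blocks=6,
        perturbed_blocks=(0, 1),
        n_drugs=12,
        frac_differential=0.5,
        seed=7,
    )
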