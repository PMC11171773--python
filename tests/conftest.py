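import numpy as np
import pytest

from tcsignal.expression import ExpressionSeries
from tcsignal.pkn import Edge, KnowledgeNetwork, Mechanism, Sign


def make_series(values, timepoints, replicates, genes=None):
    """ExpressionSeries from a genes x (timepoints*replicates) array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(1, values.shape[0] + 1)]
    samples, groups = [], {}
    for tp in timepoints:
        for r in range(1, replicates + 1):
            name = f"{tp}_r{r}"
            samples.append(name)
            groups[name] = tp
    return ExpressionSeries(list(genes), samples, values, groups, list(timepoints))


def simple_net(edges, mechanism=Mechanism.TRANSCRIPTIONAL):
    """KnowledgeNetwork from (source, target, sign) triples."""
    net = KnowledgeNetwork()
    for item in edges:
        src, dst, sign = item if len(item) == 3 else (*item, Sign.ACTIVATION)
        net.add_edge(Edge(src, dst, sign, mechanism))
    return net


@pytest.fixture
def toy_regulatory_net():
    return simple_net([
        ("A", "B", Sign.ACTIVATION),
        ("A", "C", Sign.ACTIVATION),
        ("B", "D", Sign.REPRESSION),
        ("C", "D", Sign.ACTIVATION),
        ("D", "E", Sign.ACTIVATION),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
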