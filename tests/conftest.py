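import numpy as np
import pytest

from dimsum.interactome import Interactome


def build_interactome(edges, nodes=(), source="T"):
    """Hand-build an interactome from an edge iterable."""
    net = Interactome()
    for n in nodes:
        net.add_node(n)
    for a, b in edges:
        net.add_edge(a, b, sources=(source,))
    return net


def random_interactome(rng: np.random.Generator, n_nodes: int, p_edge: float):
    """Random gene-labelled graph for oracle suites."""
    genes = [f"G{i:03d}" for i in range(n_nodes)]
    net = Interactome()
    for g in genes:
        net.add_node(g)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                net.add_edge(genes[i], genes[j], sources=("R",))
    return net, genes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def path_triangle_net():
    """A -- B -- C -- D chain plus the A--C chord."""
    return build_interactome([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
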