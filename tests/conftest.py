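import random

import pytest
from hypothesis import HealthCheck, settings

from nicd.network import GeneNetwork, GeneSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def toy5() -> GeneNetwork:
    """Five-gene universe: d1–c1, o1–c1, d1–c2, plus isolated x5.

    With single-gene seed sets {d1}, {o1}, c1 is the only primary candidate;
    exact null candidacy probability of c1 under 1+1 gene-mode sampling from
    the 5-node universe is 4/25.
    """
    return GeneNetwork.from_edges(
        [("d1", "c1"), ("o1", "c1"), ("d1", "c2")], nodes=["x5"]
    )


def brute_force_candidates(net: GeneNetwork, set_a: GeneSet, set_b: GeneSet,
                           exclude_seeds: bool = True) -> set[str]:
    """Independent double-loop oracle for primary-candidate identification."""
    a = set_a.genes & net.nodes
    b = set_b.genes & net.nodes
    edge_set = net.edges
    out = set()
    for g in net.nodes:
        nbrs = {h for h in net.nodes if frozenset((g, h)) in edge_set}
        if nbrs & a and nbrs & b:
            if exclude_seeds and (g in a or g in b):
                continue
            out.add(g)
    return out


def random_network(rng: random.Random, n_nodes: int, edge_prob: float) -> GeneNetwork:
    genes = [f"g{i}" for i in range(n_nodes)]
    edges = [
        (genes[i], genes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    return GeneNetwork.from_edges(edges, nodes=genes)
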