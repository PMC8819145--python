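import numpy as np
import pytest

from lnspf.io import PPINetwork
from lnspf.synthetic import SyntheticSpec, generate


@pytest.fixture
def triangle_tail_net():
    """The worked example graph: triangle a-b-c with a tail c-d."""
    return PPINetwork.from_edge_pairs([("a", "b"), ("b", "c"), ("a", "c"),
                                       ("c", "d")])


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic benchmark shared by pipeline-level tests."""
    return generate(SyntheticSpec(n_proteins=80, n_essential=16, seed=3))


def naive_neighbor_sets(net):
    ng = {p: net.neighbors(p) for p in net.proteins}
    th = {p: set().union(*(ng[k] for k in ng[p])) if ng[p] else set()
          for p in net.proteins}
    return ng, th


def naive_topology(net):
    """Set-based re-computation of TP1/TP2, independent of the package path."""
    ng, th = naive_neighbor_sets(net)

    def tz1(i, j):
        if j not in ng[i] or not ng[i]:
            return 0.0
        return len(ng[i] & ng[j]) / len(ng[i])

    def tz2(i, j):
        if j not in ng[i] or not th[i]:
            return 0.0
        return len(th[i] & ng[j]) / len(th[i])

    tp1 = {p: sum(tz1(p, j) for j in ng[p]) for p in net.proteins}
    tp2 = {p: sum(tz2(p, j) for j in ng[p]) for p in net.proteins}
    return tp1, tp2


def random_network(n, p, seed, prefix="n"):
    rng = np.random.default_rng(seed)
    names = [f"{prefix}{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add(frozenset((names[i], names[j])))
    return PPINetwork(names, edges)
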