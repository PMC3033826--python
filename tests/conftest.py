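import numpy as np
import pytest

from odnet.network import BipartiteMetabolicNetwork, ReactionNetwork
from odnet.synthetic import toy_fixture, union_network


@pytest.fixture
def chain4_union() -> ReactionNetwork:
    """4-reaction chain, ODs [2, 2, 1, 1]."""
    return union_network(toy_fixture("chain4"))


@pytest.fixture
def star_union() -> ReactionNetwork:
    """Hub (OD 5) with leaves of OD 1, 2, 3."""
    return union_network(toy_fixture("star"))


@pytest.fixture
def twocore_union() -> ReactionNetwork:
    """Two OD-2 chains of 3 reactions bridged by one OD-1 reaction."""
    return union_network(toy_fixture("twocore"))


def random_bipartite(rng: np.random.Generator, max_reactions: int = 200):
    """Random bipartite metabolic network for projection oracles."""
    n_r = int(rng.integers(2, max_reactions + 1))
    n_m = int(rng.integers(2, max_reactions + 51))
    net = BipartiteMetabolicNetwork()
    net.reactions = {f"r{i}" for i in range(n_r)}
    net.metabolites = {f"m{i}" for i in range(n_m)}
    n_links = int(rng.integers(n_r, 3 * n_r + 1))
    for _ in range(n_links):
        m = f"m{rng.integers(n_m)}"
        r = f"r{rng.integers(n_r)}"
        if rng.random() < 0.5:
            net.substrate_links.add((m, r))
        else:
            net.product_links.add((r, m))
    net.membership = {r: frozenset({"orgA"}) for r in net.reactions}
    return net


def random_od_network(rng: np.random.Generator, max_nodes: int = 300,
                      od_max: int = 10) -> ReactionNetwork:
    """Random sparse directed graph with uniform random OD labels."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = {f"r{i}" for i in range(n)}
    m = int(rng.integers(0, 2 * n + 1))
    edges = set()
    for _ in range(m):
        a, b = rng.integers(n, size=2)
        if a != b:
            edges.add((f"r{a}", f"r{b}"))
    od = {v: int(rng.integers(1, od_max + 1)) for v in nodes}
    return ReactionNetwork(nodes=nodes, edges=edges, od=od)


class UnionFind:
    """Independent disjoint-set oracle for the coarse-graining partition."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in out.values()}


def unionfind_partition(net: ReactionNetwork, width: int):
    """Partition into same-OD-bin connected components via union-find."""
    od = net.od
    uf = UnionFind(net.nodes)
    for a, b in net.edges:
        if (od[a] - 1) // width == (od[b] - 1) // width:
            uf.union(a, b)
    return uf.groups()
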