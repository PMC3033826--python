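"""Same-OD coarse-graining, the reshuffling null and core-size measures.

Reactions that are connected (ignoring edge direction) and fall in the same
organism-degree bin are collapsed into one *super node*.  With bin width 1
two neighbours merge only when their ODs are exactly equal; wider bins
(e.g. 10 or 50) compensate for OD sparseness in large multi-organism unions.
Two super nodes are joined when at least one reaction in each is linked to
the other.

The significance of same-OD clustering is measured against a null in which
OD values are randomly reshuffled over the fixed topology, via the z-score

    Z = (s_bar - mu_rand) / sigma_rand

where ``s_bar`` is the observed mean super-node size and ``mu_rand``,
``sigma_rand`` the mean and standard deviation of that statistic across
reshuffled replicates.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AnnotationError, DegenerateNullError
from .network import ReactionNetwork


@dataclass(frozen=True)
class SuperNode:
    id: str
    members: frozenset[str]
    od_bin: int
    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SuperNodeGraph:
    """Coarse-grained partition of a reaction network.

    ``n_odmax`` counts the reactions in the top occupied OD bin and
    ``source_n_nodes`` the reactions in the source network, so core-size
    ratios can be formed without the original network at hand.
    """

    supernodes: list[SuperNode]
    edges: set[tuple[str, str]]
    od_bin_width: int
    source_n_nodes: int
    n_odmax: int

    @property
    def sizes(self) -> list[int]:
        return [sn.size for sn in self.supernodes]

    def mean_size(self) -> float:
        return float(np.mean(self.sizes)) if self.supernodes else float("nan")

    def to_json(self) -> str:
        obj = {
            "od_bin_width": self.od_bin_width,
            "source_n_nodes": self.source_n_nodes,
            "n_odmax": self.n_odmax,
            "supernodes": [
                {
                    "id": sn.id,
                    "od_bin": sn.od_bin,
                    "size": sn.size,
                    "members": sorted(sn.members),
                }
                for sn in self.supernodes
            ],
            "edges": sorted(map(list, self.edges)),
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for sn in self.supernodes:
            g.add_node(sn.id, size=sn.size, od_bin=sn.od_bin)
        g.add_edges_from(sorted(self.edges))
        nx.write_graphml(g, str(path))


@dataclass(frozen=True)
class SuperNodeZScore:
    """Observed mean super-node size against the OD-reshuffling null."""

    mean_size: float
    null_mean: float
    null_sd: float
    z: float
    n_randomizations: int
    rng_seed: int | None = None


@dataclass(frozen=True)
class CoreSizeReport:
    """Size of the largest top-OD-bin super node, in absolute and relative terms.

    ``ratio_total`` = s_core / N_tot measures the core against the whole
    union; ``ratio_odmax`` = s_core / N_ODmax measures how clustered the
    top-OD reactions are among themselves.
    """

    s_core: int
    ratio_total: float
    ratio_odmax: float
    od_bin_width: int


def od_bin_index(od: int, width: int) -> int:
    """1-based bin index with boundaries anchored at 1: 1..w, w+1..2w, ..."""
    return (od - 1) // width + 1


def coarse_grain(net: ReactionNetwork, od_bin_width: int = 1) -> SuperNodeGraph:
    """Collapse connected same-OD-bin reactions into super nodes.

    Super nodes are the connected components (undirected view) of each OD
    bin's induced subgraph, found by an iterative depth-first search over
    sorted node ids; super-node ids are assigned in discovery order.
    """
    if od_bin_width < 1:
        raise ValueError("od_bin_width must be >= 1")
    if not net.nodes:
        return SuperNodeGraph([], set(), od_bin_width, 0, 0)
    od = net.require_od()
    bin_of = {n: od_bin_index(od[n], od_bin_width) for n in net.nodes}
    adj = net.undirected_adjacency()

    assignment: dict[str, str] = {}
    supernodes: list[SuperNode] = []
    for start in sorted(net.nodes):
        if start in assignment:
            continue
        sid = f"sn{len(supernodes):05d}"
        b = bin_of[start]
        members: set[str] = set()
        stack = [start]
        while stack:
            v = stack.pop()
            if v in members:
                continue
            members.add(v)
            assignment[v] = sid
            for u in adj[v]:
                if u not in members and u not in assignment and bin_of[u] == b:
                    stack.append(u)
        supernodes.append(SuperNode(sid, frozenset(members), b))

    edges = {
        tuple(sorted((assignment[a], assignment[b])))
        for a, b in net.edges
        if assignment[a] != assignment[b]
    }
    top_bin = max(bin_of.values())
    n_odmax = sum(1 for n in net.nodes if bin_of[n] == top_bin)
    return SuperNodeGraph(supernodes, edges, od_bin_width, len(net.nodes), n_odmax)


def size_histogram(sg: SuperNodeGraph, cumulative: bool = False) -> dict[int, int]:
    """Counts of super nodes per size; cumulative gives counts of size >= s."""
    counts = Counter(sg.sizes)
    if not cumulative:
        return dict(counts)
    if not counts:
        return {}
    out: dict[int, int] = {}
    total = 0
    for s in range(max(counts), 0, -1):
        total += counts.get(s, 0)
        out[s] = total
    return dict(sorted(out.items()))


def zscore_from_moments(mean_size: float, null_mean: float, null_sd: float) -> float:
    """Z = (s_bar - mu_rand) / sigma_rand; undefined for a zero-variance null."""
    if null_sd <= 0.0:
        raise DegenerateNullError("null standard deviation must be positive")
    return (mean_size - null_mean) / null_sd


def reshuffle_od(
    net: ReactionNetwork, rng: np.random.Generator | int | None = None
) -> ReactionNetwork:
    """Randomly permute OD values over the unchanged topology.

    The OD multiset and every edge are preserved; organism membership is
    dropped because a permuted OD no longer corresponds to any species list.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    od = net.require_od()
    nodes = sorted(net.nodes)
    values = np.array([od[n] for n in nodes])
    shuffled = values[rng.permutation(len(values))]
    return ReactionNetwork(
        nodes=set(net.nodes),
        edges=set(net.edges),
        od={n: int(v) for n, v in zip(nodes, shuffled)},
        membership=None,
    )


def supernode_zscore(
    net: ReactionNetwork,
    od_bin_width: int = 1,
    n_randomizations: int = 20,
    rng: np.random.Generator | int | None = None,
) -> SuperNodeZScore:
    """Z-score of the observed mean super-node size against the reshuffling null.

    Each replicate reshuffles the ODs, recomputes the partition from scratch
    and records its mean super-node size; the null mean and standard
    deviation (sample sd, ddof=1) standardise the observed value.  A null
    with zero variance (e.g. all ODs equal) raises
    :class:`~odnet.errors.DegenerateNullError`.
    """
    if n_randomizations < 2:
        raise ValueError("n_randomizations must be >= 2")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s_bar = coarse_grain(net, od_bin_width).mean_size()
    null_means = np.array(
        [
            coarse_grain(reshuffle_od(net, rng), od_bin_width).mean_size()
            for _ in range(n_randomizations)
        ]
    )
    mu = float(null_means.mean())
    sd = float(null_means.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNullError(
            "reshuffling null has zero variance; z-score undefined"
        )
    return SuperNodeZScore(
        mean_size=s_bar,
        null_mean=mu,
        null_sd=sd,
        z=zscore_from_moments(s_bar, mu, sd),
        n_randomizations=n_randomizations,
        rng_seed=seed,
    )


def core_sizes(sg: SuperNodeGraph) -> CoreSizeReport:
    """Largest top-OD-bin super node, relative to N_tot and to N_ODmax."""
    if not sg.supernodes:
        raise AnnotationError("empty super-node graph has no core")
    top_bin = max(sn.od_bin for sn in sg.supernodes)
    s_core = max(sn.size for sn in sg.supernodes if sn.od_bin == top_bin)
    return CoreSizeReport(
        s_core=s_core,
        ratio_total=s_core / sg.source_n_nodes,
        ratio_odmax=s_core / sg.n_odmax,
        od_bin_width=sg.od_bin_width,
    )
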