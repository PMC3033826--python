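"""Bipartite metabolic networks and their reaction-reaction projection.

A metabolism is represented as a bipartite graph with metabolite and reaction
nodes.  A directed link runs from a metabolite to every reaction that consumes
it (substrate link) and from a reaction to every metabolite it produces
(product link).  Each reaction carries the set of organisms whose metabolism
contains it; the size of that set is the reaction's *organism degree* (OD).

The analysis operates on the projected reaction-reaction network: a directed
edge r1 -> r2 exists whenever some metabolite is a product of r1 and a
substrate of r2.  Ubiquitous currency metabolites (water, ATP, NADH, ...)
would dominate this projection, so metabolites whose total bipartite degree
exceeds a threshold are pruned before projecting.
"""

from __future__ import annotations

import copy
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import AnnotationError, FormatError, MembershipError

#: Column order of the reaction-table TSV dialect (version 1).  Substrates,
#: products and organisms are ";"-separated id lists.  Reversible reactions
#: must be encoded once, in their canonical direction.
REACTION_TABLE_COLUMNS = ("reaction_id", "substrates", "products", "organisms")


@dataclass
class BipartiteMetabolicNetwork:
    """Metabolites + reactions with directed substrate/product links.

    Attributes
    ----------
    metabolites, reactions
        Node id sets (disjoint namespaces are the caller's responsibility).
    substrate_links
        Set of ``(metabolite_id, reaction_id)`` pairs: metabolite consumed by
        the reaction.
    product_links
        Set of ``(reaction_id, metabolite_id)`` pairs: metabolite produced by
        the reaction.
    membership
        Map reaction id -> frozenset of organism ids carrying the reaction.
        Reactions absent from the map (or mapped to an empty set) have no
        organism annotation; projecting such a network yields no OD values.
    """

    metabolites: set[str] = field(default_factory=set)
    reactions: set[str] = field(default_factory=set)
    substrate_links: set[tuple[str, str]] = field(default_factory=set)
    product_links: set[tuple[str, str]] = field(default_factory=set)
    membership: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for m, r in self.substrate_links:
            if m not in self.metabolites or r not in self.reactions:
                raise FormatError(f"substrate link ({m}, {r}) has unknown endpoint")
        for r, m in self.product_links:
            if m not in self.metabolites or r not in self.reactions:
                raise FormatError(f"product link ({r}, {m}) has unknown endpoint")
        unknown = set(self.membership) - self.reactions
        if unknown:
            raise FormatError(f"membership for unknown reactions: {sorted(unknown)[:5]}")

    def metabolite_degree(self, metabolite: str) -> int:
        """Total bipartite connectivity: substrate links + product links."""
        return sum(1 for m, _ in self.substrate_links if m == metabolite) + sum(
            1 for _, m in self.product_links if m == metabolite
        )

    def substrates_of(self, reaction: str) -> set[str]:
        return {m for m, r in self.substrate_links if r == reaction}

    def products_of(self, reaction: str) -> set[str]:
        return {m for r, m in self.product_links if r == reaction}

    def copy(self) -> "BipartiteMetabolicNetwork":
        return copy.deepcopy(self)


@dataclass
class ReactionNetwork:
    """Directed reaction-reaction projection with optional OD annotation.

    ``od[r]`` is the organism degree of reaction ``r`` (number of organisms
    containing it).  When ``membership`` is present, ``od`` is derived from it
    and the two are kept consistent.  The graph is simple: no self-loops, no
    parallel edges.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    od: dict[str, int] | None = None
    membership: dict[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.membership is not None and self.od is None:
            self.od = {r: len(orgs) for r, orgs in self.membership.items()}

    def validate(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-loop on {a}")
            if a not in self.nodes or b not in self.nodes:
                raise FormatError(f"edge ({a}, {b}) has unknown endpoint")
        if self.od is not None:
            if set(self.od) != self.nodes:
                raise AnnotationError("od annotation does not cover the node set")
            if any(v < 1 for v in self.od.values()):
                raise AnnotationError("organism degrees must be >= 1")
        if self.membership is not None:
            if self.od is None:
                raise AnnotationError("membership present but od missing")
            for r, orgs in self.membership.items():
                if self.od.get(r) != len(orgs):
                    raise AnnotationError(f"od({r}) != |membership({r})|")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def require_od(self) -> dict[str, int]:
        if self.od is None:
            raise AnnotationError("network has no organism-degree annotation")
        return self.od

    def undirected_adjacency(self) -> dict[str, set[str]]:
        """Adjacency of the undirected view (direction ignored)."""
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        if self.od is not None:
            nx.set_node_attributes(g, self.od, "od")
        return g

    def to_undirected_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        if self.od is not None:
            nx.set_node_attributes(g, self.od, "od")
        return g

    def giant_weak_component(self) -> "ReactionNetwork":
        """Restriction to the largest weakly connected component."""
        if not self.nodes:
            return ReactionNetwork()
        comps = nx.weakly_connected_components(self.to_networkx())
        giant = max(comps, key=lambda c: (len(c), min(c)))
        return self.subnetwork(giant)

    def subnetwork(self, nodes: Iterable[str]) -> "ReactionNetwork":
        keep = set(nodes)
        unknown = keep - self.nodes
        if unknown:
            raise MembershipError(f"unknown reactions: {sorted(unknown)[:5]}")
        return ReactionNetwork(
            nodes=keep,
            edges={(a, b) for a, b in self.edges if a in keep and b in keep},
            od=None if self.od is None else {r: self.od[r] for r in keep},
            membership=None
            if self.membership is None
            else {r: self.membership[r] for r in keep},
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")


def read_reaction_table(
    path: str | Path, *, allow_empty_organisms: bool = False
) -> BipartiteMetabolicNetwork:
    """Read a reaction-table TSV into a bipartite metabolic network.

    The dialect has a header row ``reaction_id  substrates  products
    organisms`` with ";"-separated id lists.  Duplicate reaction ids and (by
    default) empty organism fields are rejected, naming the offending row.
    Background universes with no organism annotation can be read with
    ``allow_empty_organisms=True``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REACTION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    net = BipartiteMetabolicNetwork()
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rid = row.reaction_id.strip()
        if not rid:
            raise FormatError(f"{path}: row {i}: empty reaction_id")
        if rid in seen:
            raise FormatError(f"{path}: row {i}: duplicate reaction id {rid!r}")
        seen.add(rid)
        subs = [s for s in row.substrates.split(";") if s]
        prods = [s for s in row.products.split(";") if s]
        orgs = frozenset(s for s in row.organisms.split(";") if s)
        if not orgs and not allow_empty_organisms:
            raise FormatError(f"{path}: row {i}: empty organism field for {rid!r}")
        net.reactions.add(rid)
        for m in subs:
            net.metabolites.add(m)
            net.substrate_links.add((m, rid))
        for m in prods:
            net.metabolites.add(m)
            net.product_links.add((rid, m))
        if orgs:
            net.membership[rid] = orgs
    return net


def write_reaction_table(net: BipartiteMetabolicNetwork, path: str | Path) -> None:
    """Write the reaction-table TSV; inverse of :func:`read_reaction_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(REACTION_TABLE_COLUMNS) + "\n")
        for rid in sorted(net.reactions):
            subs = ";".join(sorted(net.substrates_of(rid)))
            prods = ";".join(sorted(net.products_of(rid)))
            orgs = ";".join(sorted(net.membership.get(rid, frozenset())))
            fh.write(f"{rid}\t{subs}\t{prods}\t{orgs}\n")


def prune_currency_metabolites(
    net: BipartiteMetabolicNetwork, threshold: int = 10
) -> BipartiteMetabolicNetwork:
    """Remove currency metabolites before projection.

    A metabolite is removed, together with all its links, when its total
    bipartite connectivity (substrate links + product links) is strictly
    greater than ``threshold``; a metabolite of degree exactly ``threshold``
    survives.  Reactions are never removed.  Returns a new network.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    degree: dict[str, int] = defaultdict(int)
    for m, _ in net.substrate_links:
        degree[m] += 1
    for _, m in net.product_links:
        degree[m] += 1
    keep = {m for m in net.metabolites if degree[m] <= threshold}
    return BipartiteMetabolicNetwork(
        metabolites=set(keep),
        reactions=set(net.reactions),
        substrate_links={(m, r) for m, r in net.substrate_links if m in keep},
        product_links={(r, m) for r, m in net.product_links if m in keep},
        membership=dict(net.membership),
    )


def project_to_reactions(
    net: BipartiteMetabolicNetwork, *, require_od: bool = False
) -> ReactionNetwork:
    """Project the bipartite network onto reactions.

    A directed edge r1 -> r2 is created iff some metabolite is a product of
    r1 and a substrate of r2.  Self-loops are discarded and parallel edges
    collapsed.  Organism degree is attached when every reaction carries a
    non-empty organism set; with ``require_od=True`` a missing annotation is
    an error instead of silently yielding an unannotated network.
    """
    producers: dict[str, set[str]] = defaultdict(set)
    consumers: dict[str, set[str]] = defaultdict(set)
    for r, m in net.product_links:
        producers[m].add(r)
    for m, r in net.substrate_links:
        consumers[m].add(r)

    edges: set[tuple[str, str]] = set()
    for m in net.metabolites:
        for r1 in producers.get(m, ()):
            for r2 in consumers.get(m, ()):
                if r1 != r2:
                    edges.add((r1, r2))

    annotated = net.membership and all(
        net.membership.get(r) for r in net.reactions
    )
    if require_od and not annotated:
        bad = sorted(r for r in net.reactions if not net.membership.get(r))
        raise AnnotationError(
            f"reactions without organism membership: {bad[:5]}"
        )
    membership = (
        {r: net.membership[r] for r in net.reactions} if annotated else None
    )
    return ReactionNetwork(nodes=set(net.reactions), edges=edges, membership=membership)


def build_union(
    organism_sets: Mapping[str, Iterable[str]],
    universe_projection: ReactionNetwork,
) -> ReactionNetwork:
    """Pool many organisms' reaction sets into one OD-tagged union network.

    The node set is the union of the organism reaction sets, edges are the
    universe-projection edges restricted to it, and ``od(r)`` counts the
    organisms containing ``r``.
    """
    membership: dict[str, set[str]] = defaultdict(set)
    for org, reactions in organism_sets.items():
        for r in reactions:
            if r not in universe_projection.nodes:
                raise MembershipError(
                    f"organism {org!r} carries unknown reaction {r!r}"
                )
            membership[r].add(org)
    nodes = set(membership)
    edges = {
        (a, b) for a, b in universe_projection.edges if a in nodes and b in nodes
    }
    return ReactionNetwork(
        nodes=nodes,
        edges=edges,
        membership={r: frozenset(orgs) for r, orgs in membership.items()},
    )


def od_species_consistency(
    net: ReactionNetwork,
) -> tuple[float, list[tuple[str, str]]]:
    """How well OD equality predicts organism-set identity between neighbours.

    Over all adjacent (undirected) node pairs with equal OD, returns the
    fraction whose organism sets are exactly identical, plus the discordant
    pairs.  Returns fraction 1.0 when no such pair exists.
    """
    if net.membership is None:
        raise AnnotationError("organism membership required for consistency check")
    od = net.require_od()
    pairs = {tuple(sorted(e)) for e in net.edges}
    same_od_pairs = [(a, b) for a, b in sorted(pairs) if od[a] == od[b]]
    discordant = [
        (a, b)
        for a, b in same_od_pairs
        if net.membership[a] != net.membership[b]
    ]
    if not same_od_pairs:
        return 1.0, []
    frac = 1.0 - len(discordant) / len(same_od_pairs)
    return frac, discordant
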